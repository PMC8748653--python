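"""Gaussian-mixture clustering in phasor space and codeword decoding.

Puncta (or pixels) are clustered in the 4D spectral/lifetime phasor space
(or 2D lifetime-only space for single-channel panels) with a Gaussian
mixture carrying one extra component for autofluorescence and noise.
Components are matched to codeword signatures by Hungarian assignment on
centroid distance.  Decoding applies the error-rejection rules in order:
puncta seen in more than two spectral channels are "overlapping" (optical
crowding); single-channel puncta are "undetermined" unless the codebook
defines a singleton codeword on that channel; surviving puncta take the
codeword of the maximum-posterior component consistent with their channel
presence, provided the posterior clears the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

from .codebook import Codebook, expected_signature
from .detect import PunctaRecord, _ellipsoid_offsets, detect_puncta
from .phasor import PhasorField, PhotonStack, transform_stack

__all__ = [
    "GmmModel",
    "fit_gmm",
    "assign_pixels",
    "puncta_phasor",
    "decode_puncta",
    "component_fraction",
    "classify_stack",
    "summarize_labels",
    "UNDETERMINED",
    "OVERLAPPING",
    "AUTOFLUORESCENCE",
]

UNDETERMINED = "undetermined"
OVERLAPPING = "overlapping"
AUTOFLUORESCENCE = "autofluorescence"

_COV_FLOOR = 1e-6


@dataclass
class GmmModel:
    """Fitted mixture: means, covariances, weights, component→codeword map."""

    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    weights: np.ndarray  # (K,)
    mapping: list[str]  # per component: target name or "autofluorescence"
    use_spectral: bool = True  # 4D if True, else lifetime-only 2D

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    def _sk(self) -> GaussianMixture:
        gm = GaussianMixture(n_components=self.n_components, covariance_type="full")
        gm.weights_ = self.weights
        gm.means_ = self.means
        gm.covariances_ = self.covariances
        gm.precisions_cholesky_ = _precisions_cholesky(self.covariances)
        return gm

    def posterior(self, points: np.ndarray) -> np.ndarray:
        """(n, K) posterior probabilities of component membership."""
        return self._sk().predict_proba(np.atleast_2d(points))

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "means": self.means.tolist(),
                    "covariances": self.covariances.tolist(),
                    "weights": self.weights.tolist(),
                    "mapping": self.mapping,
                    "use_spectral": self.use_spectral,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path) -> "GmmModel":
        d = json.loads(Path(path).read_text())
        return cls(
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            weights=np.array(d["weights"]),
            mapping=list(d["mapping"]),
            use_spectral=bool(d["use_spectral"]),
        )


def _precisions_cholesky(covariances: np.ndarray) -> np.ndarray:
    out = np.empty_like(covariances)
    for k, cov in enumerate(covariances):
        out[k] = np.linalg.inv(np.linalg.cholesky(cov)).T
    return out


def signature_table(
    codebook: Codebook, rep_frequency: float, use_spectral: bool = True
) -> tuple[list[str], np.ndarray]:
    """Targets and their expected phasor centroids (4D, or 2D lifetime-only)."""
    targets = codebook.targets
    sigs = np.array(
        [
            expected_signature(codebook.codewords[t], codebook, rep_frequency)[1]
            for t in targets
        ]
    )
    if not use_spectral:
        sigs = sigs[:, 2:]
    return targets, sigs


def fit_gmm(
    points: np.ndarray,
    n_components: int,
    seed: int = 0,
    signatures: np.ndarray | None = None,
    signature_names: list[str] | None = None,
    use_spectral: bool = True,
) -> GmmModel:
    """EM-fit a full-covariance mixture; deterministic given the seed.

    When codeword ``signatures`` are given, component means are initialised
    at the expected centroids (plus the data mean for each extra
    autofluorescence/noise component) and components are matched to
    codewords afterwards by Hungarian assignment on mean–signature
    distance; leftover components map to "autofluorescence".  A covariance
    floor guards against EM degeneracy on tight clusters.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} points to fit {n_components} components"
        )
    kwargs: dict = {}
    if signatures is not None:
        sig = np.atleast_2d(signatures)
        n_extra = n_components - len(sig)
        if n_extra < 0:
            raise ValueError("more signatures than components")
        extra = np.repeat(points.mean(axis=0, keepdims=True), n_extra, axis=0)
        kwargs["means_init"] = np.vstack([sig, extra])
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=_COV_FLOOR,
        random_state=seed,
        n_init=1 if signatures is not None else 5,
        **kwargs,
    ).fit(points)

    mapping = [AUTOFLUORESCENCE] * n_components
    if signatures is not None and signature_names is not None:
        sig = np.atleast_2d(signatures)
        cost = np.linalg.norm(gm.means_[None, :, :] - sig[:, None, :], axis=-1)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            mapping[c] = signature_names[r]
    return GmmModel(
        means=gm.means_,
        covariances=gm.covariances_,
        weights=gm.weights_,
        mapping=mapping,
        use_spectral=use_spectral,
    )


def assign_pixels(model: GmmModel, phasor_field: PhasorField):
    """Per-voxel component label (argmax posterior) and posterior vector.

    Only valid voxels are evaluated; invalid voxels get label −1 and zero
    posterior.  Pretrained models may contain components empty in this
    field — that is fine, posteriors simply vanish there.
    """
    p4 = phasor_field.phasor_4d()
    pts = p4 if model.use_spectral else p4[..., 2:]
    valid = phasor_field.valid
    flat = pts[valid]
    labels = np.full(valid.shape, -1, dtype=int)
    post = np.zeros(valid.shape + (model.n_components,), dtype=float)
    if len(flat):
        pp = model.posterior(flat)
        labels[valid] = pp.argmax(axis=1)
        post[valid] = pp
    return labels, post


def puncta_phasor(
    punctum: PunctaRecord,
    phasor_field: PhasorField,
    sigma_um: tuple[float, float] = (0.2, 0.5),
) -> np.ndarray | None:
    """Intensity-weighted mean 4D phasor over the punctum's 2σ ellipsoid.

    Returns None (punctum undetermined) when no member voxel is valid.
    """
    dx, dy, dz = phasor_field.voxel_um
    s_xy, s_z = sigma_um
    oz, oy, ox = _ellipsoid_offsets((2 * s_z / dz, 2 * s_xy / dy, 2 * s_xy / dx))
    z, y, x = punctum.centroid_voxel
    nz, ny, nx = phasor_field.valid.shape
    zz, yy, xx = z + oz, y + oy, x + ox
    keep = (zz >= 0) & (zz < nz) & (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
    zz, yy, xx = zz[keep], yy[keep], xx[keep]
    valid = phasor_field.valid[zz, yy, xx]
    if not valid.any():
        return None
    zz, yy, xx = zz[valid], yy[valid], xx[valid]
    w = phasor_field.intensity[zz, yy, xx]
    p = phasor_field.phasor_4d()[zz, yy, xx]
    return (w[:, None] * p).sum(axis=0) / w.sum()


def decode_puncta(
    punctum: PunctaRecord,
    model: GmmModel,
    codebook: Codebook,
    posterior_threshold: float = 0.5,
) -> tuple[str, float]:
    """Apply the error-rejection rules and assign a codeword label.

    Order: (1) more than two channels → overlapping; (2) fewer than two
    channels with no singleton codeword on that channel → undetermined;
    (3) otherwise the codeword of the maximum-posterior component whose
    channel set matches the punctum's channel presence, if its posterior
    clears the threshold; assignment to the autofluorescence component, a
    sub-threshold posterior, or a missing phasor → undetermined.

    Returns (label, posterior of the winning component).
    """
    chans = punctum.channel_presence
    if len(chans) > 2:
        return OVERLAPPING, 0.0
    if len(chans) < 2:
        if len(chans) == 0 or next(iter(chans)) not in codebook.singleton_channels():
            return UNDETERMINED, 0.0
    if punctum.mean_phasor is None:
        return UNDETERMINED, 0.0

    pts = punctum.mean_phasor if model.use_spectral else punctum.mean_phasor[2:]
    post = model.posterior(pts)[0]
    consistent = [
        k
        for k, name in enumerate(model.mapping)
        if name != AUTOFLUORESCENCE and codebook.channel_set(name) == chans
    ]
    if not consistent:
        return UNDETERMINED, float(post.max())
    best = max(consistent, key=lambda k: post[k])
    if post[best] < posterior_threshold:
        return UNDETERMINED, float(post[best])
    return model.mapping[best], float(post[best])


def component_fraction(p, endpoint_a, endpoint_b) -> float:
    """Photon-weighted share of component a in a two-species phasor.

    Scalar projection of (p − b) onto the chord (a − b), normalised by the
    squared chord length and clamped to [0, 1]; off-chord offsets project
    orthogonally onto the chord.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(endpoint_a, dtype=float)
    b = np.asarray(endpoint_b, dtype=float)
    chord = a - b
    L2 = float(chord @ chord)
    if L2 == 0.0:
        raise ValueError("chord endpoints coincide")
    return float(np.clip((p - b) @ chord / L2, 0.0, 1.0))


def summarize_labels(labels) -> dict:
    """Bookkeeping per decoding category; percentages of total detected."""
    labels = list(labels)
    total = len(labels)
    n_und = sum(1 for l in labels if l == UNDETERMINED)
    n_ovl = sum(1 for l in labels if l == OVERLAPPING)
    n_assigned = total - n_und - n_ovl
    per_target: dict[str, int] = {}
    for l in labels:
        if l not in (UNDETERMINED, OVERLAPPING):
            per_target[l] = per_target.get(l, 0) + 1
    out = {
        "total": total,
        "assigned": n_assigned,
        UNDETERMINED: n_und,
        OVERLAPPING: n_ovl,
        "per_target": per_target,
    }
    if total:
        out["undetermined_pct"] = 100.0 * n_und / total
        out["overlapping_pct"] = 100.0 * n_ovl / total
    return out


def classify_stack(
    stack: PhotonStack,
    codebook: Codebook,
    model: GmmModel | None = None,
    min_photons: int = 10,
    posterior_threshold: float = 0.5,
    use_spectral: bool = True,
    seed: int = 0,
    sigma_um: tuple[float, float] = (0.2, 0.5),
    min_prominence: float | None = None,
    channel_snr_threshold: float = 3.0,
) -> tuple[pd.DataFrame, dict, GmmModel]:
    """Full decode pass: transform → detect → mean phasor → assign → decode.

    When no pretrained model is given, one is fitted on the detected
    puncta's mean phasors with one extra component for autofluorescence.
    Returns (puncta table, summary counts, model); the summary conserves
    counts: assigned + undetermined + overlapping = total.
    """
    phasor_field = transform_stack(stack, min_photons=min_photons)
    channel_stacks = stack.channel_marginal().astype(float)
    records, filtered, background = detect_puncta(
        channel_stacks,
        voxel_um=stack.voxel_um,
        sigma_um=sigma_um,
        min_prominence=min_prominence,
        channel_snr_threshold=channel_snr_threshold,
    )
    for rec in records:
        rec.mean_phasor = puncta_phasor(rec, phasor_field, sigma_um)

    targets, sigs = signature_table(codebook, stack.rep_frequency, use_spectral)
    if model is None:
        pts = np.array(
            [r.mean_phasor for r in records if r.mean_phasor is not None]
        )
        if not use_spectral and len(pts):
            pts = pts[:, 2:]
        n_comp = len(targets) + 1
        if len(pts) >= 10 * n_comp:
            model = fit_gmm(
                pts, n_comp, seed=seed, signatures=sigs,
                signature_names=targets, use_spectral=use_spectral,
            )
        else:
            # too few puncta to train: fall back to the expected signatures
            d = sigs.shape[1]
            model = GmmModel(
                means=np.vstack([sigs, sigs.mean(axis=0, keepdims=True)]),
                covariances=np.repeat(
                    (np.eye(d) * 1e-3)[None], len(targets) + 1, axis=0
                ),
                weights=np.full(len(targets) + 1, 1.0 / (len(targets) + 1)),
                mapping=targets + [AUTOFLUORESCENCE],
                use_spectral=use_spectral,
            )

    rows = []
    for rec in records:
        label, post = decode_puncta(rec, model, codebook, posterior_threshold)
        rec.label, rec.posterior = label, post
        x_um, y_um, z_um = rec.centroid_um
        ph = rec.mean_phasor if rec.mean_phasor is not None else [np.nan] * 4
        rows.append(
            {
                "id": rec.punctum_id,
                "z": rec.centroid_voxel[0],
                "y": rec.centroid_voxel[1],
                "x": rec.centroid_voxel[2],
                "x_um": x_um,
                "y_um": y_um,
                "z_um": z_um,
                "size": rec.size,
                "brightness": rec.brightness,
                "prominence": rec.prominence,
                "channels": ",".join(map(str, sorted(rec.channel_presence))),
                "spectral_g": ph[0],
                "spectral_s": ph[1],
                "lifetime_g": ph[2],
                "lifetime_s": ph[3],
                "label": label,
                "posterior": post,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "id", "z", "y", "x", "x_um", "y_um", "z_um", "size", "brightness",
            "prominence", "channels", "spectral_g", "spectral_s", "lifetime_g",
            "lifetime_s", "label", "posterior",
        ],
    )
    summary = summarize_labels(table["label"]) if len(table) else summarize_labels([])
    return table, summary, model
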