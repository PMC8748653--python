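"""3D puncta detection from intensity stacks.

The pipeline: estimate a slowly varying background with a large median
filter (10× the expected punctum size), matched-filter the
background-subtracted stack with a Gaussian of the punctum size, find
strict local maxima of the filtered stack (the discrete realisation of
zero gradient with negative divergence), and measure each retained
punctum: size, absolute brightness, prominence, and per-channel presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima

__all__ = [
    "PunctaRecord",
    "estimate_background",
    "prominence_map",
    "find_local_maxima",
    "measure_puncta",
    "detect_puncta",
    "robust_noise_scale",
]


@dataclass
class PunctaRecord:
    """One detected transcript candidate."""

    punctum_id: int
    centroid_voxel: tuple[int, int, int]  # (z, y, x)
    centroid_um: tuple[float, float, float]  # (x, y, z)
    size: int  # voxels above half prominence
    brightness: float  # background-subtracted photons in the 2σ ellipsoid
    prominence: float  # filtered-image peak value
    channel_presence: frozenset[int]
    at_edge: bool = False
    mean_phasor: np.ndarray | None = None  # (spectral g,s, lifetime g,s)
    label: str | None = None
    posterior: float | None = None
    extras: dict = field(default_factory=dict)


def _window_voxels(puncta_size_um: float, voxel_um, factor: float) -> tuple[int, int, int]:
    """Odd-rounded per-axis window of ``factor`` × the punctum size."""
    dx, dy, dz = voxel_um
    out = []
    for d in (dz, dy, dx):
        w = int(round(factor * puncta_size_um / d))
        out.append(max(w + (w + 1) % 2, 1))  # odd, ≥1
    return tuple(out)  # (z, y, x)


def estimate_background(
    intensity_stack: np.ndarray,
    puncta_size_um: float = 0.25,
    voxel_um=(0.1, 0.1, 0.3),
    window_factor: float = 10.0,
) -> np.ndarray:
    """Voxelwise median over a window 10× the expected punctum size.

    Reflect padding at edges.  Falls back to the global median (with a
    warning) when the window exceeds the stack extent.
    """
    if puncta_size_um <= 0:
        raise ValueError("puncta_size_um must be positive")
    stack = np.asarray(intensity_stack, dtype=float)
    win = _window_voxels(puncta_size_um, voxel_um, window_factor)
    if any(w > s for w, s in zip(win, stack.shape)):
        warnings.warn(
            "background window exceeds stack extent; using global median",
            stacklevel=2,
        )
        return np.full_like(stack, np.median(stack))
    # the background is low-frequency by construction: on large stacks the
    # median is evaluated on a decimated grid and interpolated back, which
    # leaves smooth backgrounds unchanged at a fraction of the cost
    stride = tuple(max(1, w // 8) for w in win)
    if stack.size > 400_000 and max(stride) > 1:
        coarse = stack[:: stride[0], :: stride[1], :: stride[2]]
        cwin = tuple(max(w // s, 3) | 1 for w, s in zip(win, stride))
        bg_c = ndimage.median_filter(coarse, size=cwin, mode="reflect")
        zoom = [s / c for s, c in zip(stack.shape, bg_c.shape)]
        return ndimage.zoom(bg_c, zoom, order=1, mode="nearest", grid_mode=True)
    return ndimage.median_filter(stack, size=win, mode="reflect")


def prominence_map(
    intensity_stack: np.ndarray,
    background: np.ndarray,
    puncta_size_um: float = 0.25,
    voxel_um=(0.1, 0.1, 0.3),
    clip: bool = True,
) -> np.ndarray:
    """Gaussian matched filter of the background-subtracted stack.

    σ per axis is the punctum size in voxel units (anisotropy respected);
    negative values are clipped to zero unless ``clip`` is False (the
    unclipped field is what noise-scale estimation needs — clipping first
    would halve the distribution and bias the MAD low).
    """
    stack = np.asarray(intensity_stack, dtype=float)
    if stack.shape != np.asarray(background).shape:
        raise ValueError("intensity and background shapes differ")
    dx, dy, dz = voxel_um
    sigma = (puncta_size_um / dz, puncta_size_um / dy, puncta_size_um / dx)
    filtered = ndimage.gaussian_filter(stack - background, sigma=sigma, mode="reflect")
    return np.clip(filtered, 0.0, None) if clip else filtered


def robust_noise_scale(filtered_stack: np.ndarray) -> float:
    """MAD-based noise scale of a filtered stack (Gaussian-consistent)."""
    x = np.asarray(filtered_stack, dtype=float).ravel()
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def find_local_maxima(
    filtered_stack: np.ndarray, min_prominence: float
) -> list[tuple[int, int, int]]:
    """Strict maxima of the 26-neighborhood with value ≥ min_prominence.

    Plateaus (connected regions of equal value that are regional maxima)
    are reduced to their centroid voxel.
    """
    if min_prominence < 0:
        raise ValueError("min_prominence must be non-negative")
    f = np.asarray(filtered_stack, dtype=float)
    if f.size == 0 or not np.any(f > 0):
        return []
    mask = local_maxima(f, connectivity=3, allow_borders=True)
    mask &= f >= min_prominence
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    centers = ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    return [tuple(int(round(v)) for v in c) for c in centers]


def _ellipsoid_offsets(radius_vox: tuple[float, float, float]):
    rz, ry, rx = (max(r, 0.5) for r in radius_vox)
    bz, by, bx = (int(np.ceil(r)) for r in (rz, ry, rx))
    zz, yy, xx = np.mgrid[-bz : bz + 1, -by : by + 1, -bx : bx + 1]
    inside = (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0
    return zz[inside], yy[inside], xx[inside]


def measure_puncta(
    maxima: list[tuple[int, int, int]],
    channel_stacks: np.ndarray,
    filtered_stack: np.ndarray,
    background: np.ndarray,
    puncta_size_um: float = 0.25,
    voxel_um=(0.1, 0.1, 0.3),
    channel_snr_threshold: float = 3.0,
    sigma_um: tuple[float, float] = (0.2, 0.5),
    channel_min_fraction: float = 0.1,
) -> list[PunctaRecord]:
    """Measure each local maximum into an (unlabeled) PunctaRecord.

    brightness: background-subtracted photon sum over the 2σ ellipsoid.
    size: voxels in that ellipsoid above half the peak prominence.
    channel_presence: channels whose background-subtracted photon sum over
    the ellipsoid reaches ``channel_snr_threshold`` × the Poisson noise of
    the local background (floored at 1 photon) AND carries at least
    ``channel_min_fraction`` of the punctum's photons — the latter keeps
    sub-percent spectral spillover from neighbouring channels out of the
    presence set.
    Edge puncta are measured over the clipped ellipsoid and flagged.
    """
    channel_stacks = np.asarray(channel_stacks, dtype=float)  # (Z, Y, X, C)
    if channel_stacks.ndim != 4:
        raise ValueError("channel_stacks must be (Z, Y, X, C)")
    nz, ny, nx, n_chan = channel_stacks.shape
    intensity = channel_stacks.sum(axis=-1)
    dx, dy, dz = voxel_um
    s_xy, s_z = sigma_um
    radius_vox = (2 * s_z / dz, 2 * s_xy / dy, 2 * s_xy / dx)
    oz, oy, ox = _ellipsoid_offsets(radius_vox)

    # channel background fractions estimated from the global stack medians
    chan_med = np.median(channel_stacks.reshape(-1, n_chan), axis=0)

    records = []
    for i, (z, y, x) in enumerate(maxima):
        zz, yy, xx = z + oz, y + oy, x + ox
        keep = (zz >= 0) & (zz < nz) & (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
        at_edge = not keep.all()
        zz, yy, xx = zz[keep], yy[keep], xx[keep]
        n_vox = len(zz)

        prom = float(filtered_stack[z, y, x])
        bg_local = background[zz, yy, xx]
        brightness = float((intensity[zz, yy, xx] - bg_local).sum())
        size = int(
            np.count_nonzero(filtered_stack[zz, yy, xx] >= 0.5 * prom)
        )

        present = set()
        sig_total = 0.0
        sig_by_chan = []
        for c in range(n_chan):
            sig = float((channel_stacks[zz, yy, xx, c] - chan_med[c]).sum())
            sig_by_chan.append(sig)
            sig_total += max(sig, 0.0)
        for c in range(n_chan):
            noise = float(np.sqrt(max(n_vox * chan_med[c], 1.0)))
            frac_ok = sig_by_chan[c] >= channel_min_fraction * sig_total
            if sig_by_chan[c] / noise >= channel_snr_threshold and frac_ok:
                present.add(c)

        records.append(
            PunctaRecord(
                punctum_id=i,
                centroid_voxel=(z, y, x),
                centroid_um=((x + 0.0) * dx, (y + 0.0) * dy, (z + 0.0) * dz),
                size=size,
                brightness=brightness,
                prominence=prom,
                channel_presence=frozenset(present),
                at_edge=at_edge,
            )
        )
    return records


def detect_puncta(
    channel_stacks: np.ndarray,
    puncta_size_um: float = 0.25,
    voxel_um=(0.1, 0.1, 0.3),
    min_prominence: float | None = None,
    noise_sigma_factor: float = 8.0,
    channel_snr_threshold: float = 3.0,
    sigma_um: tuple[float, float] = (0.2, 0.5),
    channel_min_fraction: float = 0.1,
) -> tuple[list[PunctaRecord], np.ndarray, np.ndarray]:
    """Full detection pass: background → prominence → maxima → measurement.

    When ``min_prominence`` is None it defaults to the filtered field's
    median plus ``noise_sigma_factor`` × its robust (MAD) noise scale.  The
    factor of 8 accommodates the heavier-than-Gaussian tail of
    matched-filtered Poisson noise (noise maxima reach ~6–7 robust sigmas
    on photon-sparse stacks) while staying far below real puncta, whose
    prominences sit tens of sigmas up even at the dimmest simulated
    intensities.

    Returns (records, filtered_stack, background).
    """
    channel_stacks = np.asarray(channel_stacks, dtype=float)
    intensity = channel_stacks.sum(axis=-1)
    background = estimate_background(intensity, puncta_size_um, voxel_um)
    raw = prominence_map(intensity, background, puncta_size_um, voxel_um, clip=False)
    filtered = np.clip(raw, 0.0, None)
    if min_prominence is None:
        # the filtered field keeps a positive baseline at low photon rates
        # (a median filter under-reports the mean of skewed Poisson noise),
        # so the threshold sits noise_sigma_factor robust sigmas above the
        # field's own median rather than above zero
        baseline = float(np.median(raw))
        min_prominence = max(
            baseline + noise_sigma_factor * robust_noise_scale(raw), 1e-6
        )
    maxima = find_local_maxima(filtered, min_prominence)
    records = measure_puncta(
        maxima,
        channel_stacks,
        filtered,
        background,
        puncta_size_um,
        voxel_um,
        channel_snr_threshold,
        sigma_um,
        channel_min_fraction,
    )
    return records, filtered, background
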