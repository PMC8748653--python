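"""Stack and table I/O, run configuration, and the end-to-end pipeline.

Photon stacks travel as multi-page TIFF with a YAML sidecar declaring the
axis layout (Z, Y, X, C, Tbin) and the physical metadata (voxel size,
repetition frequency, channel edges); sidecar values override any file
tags.  Every pipeline output carries the seed and a config hash so a run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cells import (
    assign_puncta_to_cells,
    grow_territories,
    segment_nuclei,
    territory_table,
)
from .classify import GmmModel, classify_stack
from .codebook import Codebook
from .phasor import PhasorField, PhotonStack, transform_stack

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_phasor_field",
    "run_pipeline",
]

_AXES = "ZYXCT"  # T = arrival-time bin


def write_stack(stack: PhotonStack, path) -> Path:
    """Write a photon stack as TIFF + YAML sidecar; returns sidecar path."""
    path = Path(path)
    tifffile.imwrite(path, stack.counts, metadata={"axes": _AXES})
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "axes": _AXES,
                "voxel_um": list(stack.voxel_um),
                "rep_frequency": float(stack.rep_frequency),
                "channel_edges": [float(v) for v in stack.channel_edges],
            }
        )
    )
    return sidecar


def read_stack(path, sidecar=None) -> PhotonStack:
    """Read a photon stack; metadata comes from the sidecar config.

    Raises a format error when the array is not 5D or metadata is missing.
    """
    path = Path(path)
    counts = tifffile.imread(path)
    if counts.ndim != 5:
        raise ValueError(
            f"expected 5 axes ({_AXES}); found {counts.ndim} with shape {counts.shape}"
        )
    if sidecar is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata required: no sidecar config at {sidecar} "
            "(voxel_um, rep_frequency, channel_edges)"
        )
    meta = yaml.safe_load(sidecar.read_text())
    return PhotonStack(
        counts=counts,
        voxel_um=tuple(meta["voxel_um"]),
        rep_frequency=float(meta["rep_frequency"]),
        channel_edges=np.array(meta["channel_edges"], dtype=float),
    )


def write_phasor_field(field_: PhasorField, path) -> None:
    """Float TIFF, 5 planes per z: spectral g/s, lifetime g/s, intensity."""
    planes = np.stack(
        [
            field_.spectral_g,
            field_.spectral_s,
            field_.lifetime_g,
            field_.lifetime_s,
            field_.intensity.astype(float),
        ],
        axis=1,
    ).astype(np.float32)
    tifffile.imwrite(Path(path), planes, metadata={"axes": "ZCYX"})


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    stack_path: str
    codebook_path: str
    output_dir: str
    sidecar_path: str | None = None
    nuclear_stack_path: str | None = None
    model_path: str | None = None
    min_photons: int = 10
    min_prominence: float | None = None
    channel_snr_threshold: float = 3.0
    posterior_threshold: float = 0.5
    use_spectral: bool = True
    puncta_size_um: float = 0.25
    psf_sigma_um: tuple[float, float] = (0.2, 0.5)
    min_nucleus_volume_um3: float = 30.0
    seed: int = 0

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "psf_sigma_um" in d:
            d["psf_sigma_um"] = tuple(d["psf_sigma_um"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run transform → detect → classify → decode (→ cells) and write outputs.

    Outputs in ``output_dir``: phasor_field.tif, puncta.csv, summary.json,
    model.json, and per_cell_counts.csv + territories.tif when a nuclear
    stack is supplied.  Deterministic given the seed.  Returns the summary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stack = read_stack(config.stack_path, config.sidecar_path)
    codebook = Codebook.load(config.codebook_path)
    model = GmmModel.load(config.model_path) if config.model_path else None

    field_ = transform_stack(stack, min_photons=config.min_photons)
    write_phasor_field(field_, out / "phasor_field.tif")

    table, summary, model = classify_stack(
        stack,
        codebook,
        model=model,
        min_photons=config.min_photons,
        posterior_threshold=config.posterior_threshold,
        use_spectral=config.use_spectral,
        seed=config.seed,
        sigma_um=config.psf_sigma_um,
        min_prominence=config.min_prominence,
        channel_snr_threshold=config.channel_snr_threshold,
    )
    model.save(out / "model.json")
    table.to_csv(out / "puncta.csv", index=False)

    if config.nuclear_stack_path:
        nuclear = tifffile.imread(config.nuclear_stack_path)
        nuclei = segment_nuclei(
            nuclear,
            voxel_um=stack.voxel_um,
            min_nucleus_volume_um3=config.min_nucleus_volume_um3,
        )
        if nuclei.max() > 0:
            territories = grow_territories(nuclei, voxel_um=stack.voxel_um)
            tifffile.imwrite(out / "territories.tif", territories.astype(np.int32))
            per_cell = assign_puncta_to_cells(table, territories)
            per_cell.to_csv(out / "per_cell_counts.csv", index=False)
            summary["n_cells"] = int(nuclei.max())
            summary["territory_volumes_um3"] = {
                t.cell_id: t.territory_volume_um3
                for t in territory_table(territories, nuclei, stack.voxel_um)
            }

    summary["seed"] = config.seed
    summary["config_hash"] = config.config_hash()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
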