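"""Fluorophore panels and combinatorial codewords.

Each target transcript is encoded by an unordered pair of fluorophores
drawn from a panel of N dyes, so the number of addressable targets grows
quadratically, N(N−1)/2.  Singleton codewords (one dye) are also supported
for small panels that mix single- and double-labelled targets; they are
flagged because they disable the single-channel rejection rule on their
channel.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .phasor import PhasorPoint, single_exponential_position

__all__ = [
    "FluorophoreSpec",
    "Codebook",
    "n_pairs",
    "build_codebook",
    "expected_signature",
    "channel_unit_point",
]


def n_pairs(n_fluorophores: int) -> int:
    """Number of unordered dye pairs, (n² − n)/2."""
    if n_fluorophores < 1:
        raise ValueError("need at least one fluorophore")
    return (n_fluorophores * n_fluorophores - n_fluorophores) // 2


@dataclass(frozen=True)
class FluorophoreSpec:
    """One dye: emission spectrum summary, lifetime, and dominant channel."""

    name: str
    emission_center: float  # nm
    emission_sigma: float  # nm
    lifetime_tau: float  # ns
    channel: int

    def __post_init__(self) -> None:
        if self.lifetime_tau <= 0:
            raise ValueError(f"{self.name}: lifetime must be positive")
        if self.emission_sigma <= 0:
            raise ValueError(f"{self.name}: emission sigma must be positive")
        if self.channel < 0:
            raise ValueError(f"{self.name}: channel index must be non-negative")


@dataclass
class Codebook:
    """Panel of fluorophores plus target → codeword mapping.

    Codewords are unordered pairs of dye names, or single names when
    singleton codewords are explicitly allowed.
    """

    fluorophores: list[FluorophoreSpec]
    codewords: dict[str, tuple[str, ...]]
    negative_controls: list[str] = field(default_factory=list)
    n_channels: int | None = None

    def __post_init__(self) -> None:
        names = [f.name for f in self.fluorophores]
        if len(set(names)) != len(names):
            raise ValueError("duplicate fluorophore names")
        if self.n_channels is None:
            self.n_channels = max((f.channel for f in self.fluorophores), default=-1) + 1
        for f in self.fluorophores:
            if f.channel >= self.n_channels:
                raise ValueError(f"{f.name}: channel {f.channel} outside panel")
        seen: set[tuple[str, ...]] = set()
        norm: dict[str, tuple[str, ...]] = {}
        for target, cw in self.codewords.items():
            cw = tuple(sorted(cw)) if not isinstance(cw, str) else (cw,)
            if len(cw) not in (1, 2):
                raise ValueError(f"{target}: codewords are single dyes or pairs")
            if len(cw) == 2 and cw[0] == cw[1]:
                raise ValueError(f"{target}: pair must use two distinct dyes")
            for name in cw:
                if name not in names:
                    raise KeyError(f"{target}: unknown fluorophore {name!r}")
            if cw in seen:
                raise ValueError(f"duplicate codeword {cw}")
            seen.add(cw)
            norm[target] = cw
        self.codewords = norm

    def fluor(self, name: str) -> FluorophoreSpec:
        for f in self.fluorophores:
            if f.name == name:
                return f
        raise KeyError(f"unknown fluorophore {name!r}")

    @property
    def targets(self) -> list[str]:
        return list(self.codewords)

    def singleton_channels(self) -> set[int]:
        """Channels on which a singleton codeword is defined (single-channel
        puncta on these channels are decodable rather than rejected)."""
        return {
            self.fluor(cw[0]).channel
            for cw in self.codewords.values()
            if len(cw) == 1
        }

    def channel_set(self, target: str) -> frozenset[int]:
        return frozenset(self.fluor(n).channel for n in self.codewords[target])

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "fluorophores": [
                {
                    "name": f.name,
                    "emission_center": f.emission_center,
                    "emission_sigma": f.emission_sigma,
                    "lifetime_tau": f.lifetime_tau,
                    "channel": f.channel,
                }
                for f in self.fluorophores
            ],
            "codewords": {t: list(cw) for t, cw in self.codewords.items()},
            "negative_controls": list(self.negative_controls),
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        return cls(
            fluorophores=[FluorophoreSpec(**f) for f in d["fluorophores"]],
            codewords={t: tuple(cw) for t, cw in d["codewords"].items()},
            negative_controls=list(d.get("negative_controls", [])),
            n_channels=d.get("n_channels"),
        )

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "Codebook":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def build_codebook(
    fluorophores: list[FluorophoreSpec],
    target_names: list[str],
    pairs: dict[str, tuple[str, ...]] | None = None,
    allow_singletons: bool = False,
    negative_controls: list[str] | None = None,
) -> Codebook:
    """Assign each target a distinct dye pair.

    Without explicit ``pairs`` the assignment is deterministic lexicographic
    over the sorted dye names.  Capacity is n_pairs(len(fluorophores)); a
    request beyond it raises ``ValueError``.
    """
    if pairs is not None:
        for t, cw in pairs.items():
            if len(cw) == 1 and not allow_singletons:
                raise ValueError(f"{t}: singleton codewords not allowed here")
        return Codebook(fluorophores, dict(pairs), negative_controls or [])

    capacity = n_pairs(len(fluorophores))
    if len(target_names) > capacity:
        raise ValueError(
            f"{len(target_names)} targets exceed capacity {capacity} "
            f"of {len(fluorophores)} fluorophores"
        )
    names = sorted(f.name for f in fluorophores)
    all_pairs = list(itertools.combinations(names, 2))
    codewords = {t: all_pairs[i] for i, t in enumerate(target_names)}
    return Codebook(fluorophores, codewords, negative_controls or [])


def channel_unit_point(channel: int, n_channels: int, harmonic: int = 1) -> PhasorPoint:
    """Unit-circle spectral position of a dye confined to one channel."""
    ang = 2.0 * np.pi * harmonic * (channel + 0.5) / n_channels
    return PhasorPoint(float(np.cos(ang)), float(np.sin(ang)))


def expected_signature(
    codeword: tuple[str, ...],
    codebook: Codebook,
    rep_frequency: float,
    harmonic: int = 1,
) -> tuple[frozenset[int], np.ndarray]:
    """Expected channel set and 4D phasor centroid of a codeword.

    For a pair the centroid is the equal-photon (½:½) midpoint of the two
    single-dye positions, in both spectral and lifetime phasor space; a
    singleton's signature is the dye's own position.  Returns
    (channel_set, [spectral g, spectral s, lifetime g, lifetime s]).
    """
    specs = [codebook.fluor(n) for n in codeword]
    chans = frozenset(f.channel for f in specs)
    lt = [
        single_exponential_position(f.lifetime_tau, rep_frequency, harmonic)
        for f in specs
    ]
    sp = [channel_unit_point(f.channel, codebook.n_channels, harmonic) for f in specs]
    lt_c = np.mean([p.as_array() for p in lt], axis=0)
    sp_c = np.mean([p.as_array() for p in sp], axis=0)
    return chans, np.concatenate([sp_c, lt_c])
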