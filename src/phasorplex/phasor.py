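"""Lifetime and spectral phasor transforms.

The phasor transform maps a per-pixel histogram — photon arrival times for
lifetime, or photon counts per spectral channel for spectra — onto a point
(g, s) given by the first-harmonic cosine/sine projections of the normalised
histogram.  It is fit-free: no decay model is assumed, and the coordinates
are independent of the total photon count.  Single-exponential decays lie on
the universal semicircle g² + s² = g; mixtures fall on chords between their
components at the photon-fraction position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhotonStack",
    "PhasorPoint",
    "PhasorField",
    "lifetime_phasor",
    "spectral_phasor",
    "transform_stack",
    "single_exponential_position",
    "universal_circle_projection",
    "LONG_LIFETIME",
]

#: Sentinel returned by :func:`universal_circle_projection` for phasors with
#: g ≤ 0, whose phase lifetime is beyond the first-quadrant range.
LONG_LIFETIME = float("inf")


@dataclass(frozen=True)
class PhasorPoint:
    """A point in (g, s) phasor space (dimensionless)."""

    g: float
    s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.s], dtype=float)


@dataclass
class PhotonStack:
    """Per-voxel photon counts indexed (z, y, x, channel, time_bin).

    Parameters
    ----------
    counts
        Non-negative integer array of shape (Z, Y, X, C, B).
    voxel_um
        Physical voxel size (dx, dy, dz) in µm.
    rep_frequency
        Laser repetition frequency in Hz; the stimulation period is
        T = 1/rep_frequency and the first-harmonic angular frequency
        ω = 2π·rep_frequency.
    channel_edges
        Wavelength bin edges in nm, length C+1, strictly increasing.
    """

    counts: np.ndarray
    voxel_um: tuple[float, float, float]
    rep_frequency: float
    channel_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 5:
            raise ValueError(
                f"counts must be 5D (z, y, x, channel, time_bin); got shape {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel dimensions must be positive")
        if self.rep_frequency <= 0:
            raise ValueError("rep_frequency must be positive")
        if self.channel_edges is None:
            # default: unit-spaced nominal edges
            self.channel_edges = np.arange(self.n_channels + 1, dtype=float)
        self.channel_edges = np.asarray(self.channel_edges, dtype=float)
        if len(self.channel_edges) != self.n_channels + 1:
            raise ValueError("channel_edges must have length channels + 1")
        if np.any(np.diff(self.channel_edges) <= 0):
            raise ValueError("channel_edges must be strictly increasing")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def n_channels(self) -> int:
        return self.counts.shape[3]

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[4]

    @property
    def period_ns(self) -> float:
        return 1e9 / self.rep_frequency

    def intensity(self) -> np.ndarray:
        """Total photons per voxel (sum over channel and time axes)."""
        return self.counts.sum(axis=(3, 4))

    def time_marginal(self) -> np.ndarray:
        """(Z, Y, X, B) photon arrival-time histograms."""
        return self.counts.sum(axis=3)

    def channel_marginal(self) -> np.ndarray:
        """(Z, Y, X, C) spectral histograms."""
        return self.counts.sum(axis=4)


@dataclass
class PhasorField:
    """Per-voxel 4D phasor coordinates plus intensity and validity mask.

    ``spectral_g/s`` and ``lifetime_g/s`` are NaN where ``valid`` is False
    (intensity below the minimum photon threshold); valid entries are finite.
    """

    spectral_g: np.ndarray
    spectral_s: np.ndarray
    lifetime_g: np.ndarray
    lifetime_s: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    voxel_um: tuple[float, float, float]
    rep_frequency: float

    def phasor_4d(self) -> np.ndarray:
        """(Z, Y, X, 4) array ordered (spectral g, spectral s, lifetime g, lifetime s)."""
        return np.stack(
            [self.spectral_g, self.spectral_s, self.lifetime_g, self.lifetime_s], axis=-1
        )


def _first_harmonic(weights: np.ndarray, angles: np.ndarray, axis: int = -1):
    total = weights.sum(axis=axis)
    g = (weights * np.cos(angles)).sum(axis=axis)
    s = (weights * np.sin(angles)).sum(axis=axis)
    return g, s, total


def lifetime_phasor(histogram, period_ns: float, harmonic: int = 1) -> PhasorPoint:
    """Phasor of a photon arrival-time histogram.

    Bin k is taken to be centred at t_k = (k + ½)·T/B (B bins spanning one
    stimulation period T), and

        g = Σ c_k cos(2π h t_k / T) / Σ c_k
        s = Σ c_k sin(2π h t_k / T) / Σ c_k

    Raises ``ValueError`` on an empty histogram; callers transforming whole
    stacks mark such voxels invalid instead.
    """
    c = np.asarray(histogram, dtype=float)
    if period_ns <= 0:
        raise ValueError("period must be positive")
    if c.sum() <= 0:
        raise ValueError("empty histogram has no defined phasor")
    b = c.shape[0]
    t = (np.arange(b) + 0.5) * period_ns / b
    ang = 2.0 * np.pi * harmonic * t / period_ns
    g, s, total = _first_harmonic(c, ang)
    return PhasorPoint(g / total, s / total)


def spectral_phasor(channel_histogram, harmonic: int = 1) -> PhasorPoint:
    """Phasor of a spectral histogram.

    Channel c of C maps to the unit-circle angle θ_c = 2π·h·(c+½)/C; the
    phasor is the intensity-weighted mean of those unit vectors.
    """
    counts = np.asarray(channel_histogram, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty histogram has no defined phasor")
    n = counts.shape[0]
    ang = 2.0 * np.pi * harmonic * (np.arange(n) + 0.5) / n
    g, s, total = _first_harmonic(counts, ang)
    return PhasorPoint(g / total, s / total)


def transform_stack(
    stack: PhotonStack, harmonic: int = 1, min_photons: int = 10
) -> PhasorField:
    """Apply both phasor transforms to every voxel of a photon stack.

    Voxels with fewer than ``min_photons`` total photons are marked invalid
    and carry NaN phasors — they never reach downstream clustering.
    """
    time_hist = stack.time_marginal().astype(float)
    chan_hist = stack.channel_marginal().astype(float)
    intensity = time_hist.sum(axis=-1)
    valid = intensity >= max(min_photons, 1)

    b = stack.n_time_bins
    t_ang = 2.0 * np.pi * harmonic * (np.arange(b) + 0.5) / b
    c = stack.n_channels
    c_ang = 2.0 * np.pi * harmonic * (np.arange(c) + 0.5) / c

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(intensity > 0, intensity, np.nan)
        lg = time_hist @ np.cos(t_ang) / denom
        ls = time_hist @ np.sin(t_ang) / denom
        sg = chan_hist @ np.cos(c_ang) / denom
        ss = chan_hist @ np.sin(c_ang) / denom
    for arr in (lg, ls, sg, ss):
        arr[~valid] = np.nan

    return PhasorField(
        spectral_g=sg,
        spectral_s=ss,
        lifetime_g=lg,
        lifetime_s=ls,
        intensity=intensity,
        valid=valid,
        voxel_um=stack.voxel_um,
        rep_frequency=stack.rep_frequency,
    )


def single_exponential_position(
    tau_ns: float, rep_frequency: float, harmonic: int = 1
) -> PhasorPoint:
    """Universal-semicircle position of a single-exponential decay.

    g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²) with ω = 2π·h·rep_frequency.
    """
    if tau_ns < 0:
        raise ValueError("lifetime must be non-negative")
    omega = 2.0 * np.pi * harmonic * rep_frequency * 1e-9  # rad/ns
    wt = omega * tau_ns
    d = 1.0 + wt * wt
    return PhasorPoint(1.0 / d, wt / d)


def universal_circle_projection(
    p: PhasorPoint, rep_frequency: float, harmonic: int = 1
) -> float:
    """Phase lifetime τ_phase = (s/g)/ω in ns, used for pseudocoloring.

    Returns the :data:`LONG_LIFETIME` sentinel when g ≤ 0 (phase beyond
    the quarter period, outside the single-exponential range).
    """
    if p.g <= 0:
        return LONG_LIFETIME
    omega = 2.0 * np.pi * harmonic * rep_frequency * 1e-9
    return (p.s / p.g) / omega
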