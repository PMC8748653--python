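"""Analytic optical-crowding model and Monte-Carlo verification.

With N puncta of individual (PSF) volume v_i placed uniformly in a total
volume V_T, the expected fraction that are optically isolated is

    n/N = (1 − v_i/V_T)^(N−1),

the product over the other N−1 puncta of the probability of not landing in
the exclusion volume.  The observed count n under-reports the true N; the
true count is recovered by numerically inverting the relation (the smaller
positive root — the larger root lies near 1/(v_i/V_T) and is unphysical at
realistic densities).  The headline loss estimate is reported relative to
the detected count, 100·(N−n)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

__all__ = [
    "CrowdingModel",
    "isolated_fraction",
    "estimate_true_count",
    "overlap_interval",
    "crowding_simulation",
]


@dataclass
class CrowdingModel:
    """Crowding bookkeeping: detected n, inferred N, volumes, losses."""

    n: float  # detected isolated puncta
    N: float  # inferred true count
    v_i: float  # per-punctum (PSF) volume, µm³
    V_T: float  # total scanned volume, µm³

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.N):
            raise ValueError("need 0 <= n <= N")
        if not (0 < self.v_i < self.V_T):
            raise ValueError("need 0 < v_i < V_T")

    @property
    def loss_vs_detected(self) -> float:
        """100·(N−n)/n — loss relative to detected counts (headline)."""
        return 100.0 * (self.N - self.n) / self.n if self.n else 0.0

    @property
    def loss_vs_true(self) -> float:
        """100·(N−n)/N — loss relative to the inferred true count."""
        return 100.0 * (self.N - self.n) / self.N if self.N else 0.0


def isolated_fraction(N: float, v_i: float, V_T: float) -> float:
    """(1 − v_i/V_T)^(N−1): expected fraction of non-overlapped puncta."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if v_i < 0 or v_i >= V_T:
        raise ValueError("need 0 <= v_i < V_T")
    return float((1.0 - v_i / V_T) ** (N - 1.0))


def estimate_true_count(n: float, v_i: float, V_T: float, rtol: float = 1e-8) -> float:
    """Invert N·(1 − v_i/V_T)^(N−1) = n for the smaller positive root.

    Bracketed root finding on [n, N*] where N* = 1/ln(1/(1−v_i/V_T)) is the
    maximiser of the left-hand side (so the small root lies below it).
    Raises when n exceeds that maximum — a density beyond model validity.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return 0.0
    if v_i <= 0 or v_i >= V_T:
        raise ValueError("need 0 < v_i < V_T")
    q = 1.0 - v_i / V_T
    n_star = -1.0 / np.log(q)  # argmax of N q^(N-1)

    def f(N: float) -> float:
        return N * q ** (N - 1.0) - n

    if f(n_star) < 0:
        raise ValueError(
            f"detected count n={n} exceeds the model maximum "
            f"{n_star * q ** (n_star - 1):.1f}; density beyond model validity"
        )
    if n >= n_star:
        return float(n_star)
    return float(brentq(f, n, n_star, rtol=rtol))


def overlap_interval(
    n: float, V_T: float, v_i_min: float, v_i_max: float
) -> tuple[float, float]:
    """Percent of puncta lost to crowding at the two PSF-volume endpoints.

    Returns 100·(N−n)/n at v_i_min and v_i_max, each rounded to 1 decimal.
    """
    if not (0 < v_i_min <= v_i_max < V_T):
        raise ValueError("need 0 < v_i_min <= v_i_max < V_T")
    out = []
    for v in (v_i_min, v_i_max):
        N = estimate_true_count(n, v, V_T)
        out.append(round(100.0 * (N - n) / n, 1))
    return out[0], out[1]


def crowding_simulation(
    densities,
    iterations: int,
    psf_volume: float,
    volume: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Monte-Carlo check of the isolated-fraction formula.

    For each total count N, points are placed uniformly in a cube of
    volume ``volume`` with periodic (toroidal) boundaries; a point counts
    as isolated when no other point lies within the radius of the sphere
    of volume ``psf_volume`` (the exclusion volume of the model).  Reports
    the mean observed isolated fraction over the iterations next to the
    model prediction.
    """
    if iterations < 1:
        raise ValueError("need at least one iteration")
    side = volume ** (1.0 / 3.0)
    r_excl = (3.0 * psf_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    rows = []
    for N in densities:
        N = int(N)
        fracs = []
        for _ in range(iterations):
            pts = rng.uniform(0.0, side, size=(N, 3))
            if N == 1:
                fracs.append(1.0)
                continue
            tree = cKDTree(pts, boxsize=side)
            pairs = tree.query_pairs(r_excl, output_type="ndarray")
            crowded = np.zeros(N, dtype=bool)
            if len(pairs):
                crowded[pairs.ravel()] = True
            fracs.append(1.0 - crowded.mean())
        fracs = np.asarray(fracs)
        rows.append(
            {
                "N": N,
                "observed_isolated_fraction": fracs.mean(),
                "observed_se": fracs.std(ddof=1) / np.sqrt(iterations)
                if iterations > 1
                else np.nan,
                "predicted_isolated_fraction": isolated_fraction(
                    max(N, 1), psf_volume, volume
                ),
            }
        )
    return pd.DataFrame(rows)
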