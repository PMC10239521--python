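"""Circular descriptive statistics and the two-sample Watson-Williams test.

Angles are compass bearings in degrees throughout: 0 = north, increasing
clockwise, reduced mod 360 on input.  The circular mean of a sample is the
bearing of the vector sum of unit vectors at the sample angles; the mean
resultant length r-bar in [0, 1] measures angular concentration (1 = all
angles identical, 0 = complete cancellation).

The Watson-Williams test compares the mean directions of two independent
circular samples via an F statistic with a concentration-based correction
factor; it assumes both samples are roughly von Mises with a common, not too
small concentration (a warning is emitted when the pooled r-bar drops below
0.45).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "circular_mean",
    "kappa_estimate",
    "watson_williams",
    "paired_direction_test",
    "WatsonWilliamsResult",
]


def _as_angles(angles_deg) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty circular sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite angle in circular sample")
    return a % 360.0


def circular_mean(angles_deg) -> tuple[float, float]:
    """Mean bearing and mean resultant length of a circular sample.

    Returns (mean_deg in [0, 360), r_bar in [0, 1]).  When the resultant all
    but cancels (r_bar < 1e-12) the mean is undefined and NaN is returned.
    """
    a = np.radians(_as_angles(angles_deg))
    # compass convention: sin -> east component, cos -> north component
    east = np.sin(a).sum()
    north = np.cos(a).sum()
    n = a.size
    rbar = math.hypot(east, north) / n
    if rbar < 1e-12:
        return float("nan"), 0.0
    deg = math.degrees(math.atan2(east, north)) % 360.0
    return (0.0 if deg >= 360.0 else deg), rbar


def kappa_estimate(rbar: float) -> float:
    """Maximum-likelihood-style estimate of the von Mises concentration kappa
    from the mean resultant length, via the standard three-regime
    approximation."""
    r = float(rbar)
    if r < 0:
        raise ValueError("rbar must be non-negative")
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    r = min(r, 1.0 - 1e-12)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


@dataclass(frozen=True)
class WatsonWilliamsResult:
    F: float
    df1: int
    df2: int
    p: float
    K: float
    mean_dir_1: float
    mean_dir_2: float
    n1: int
    n2: int

    @property
    def N(self) -> int:
        return self.n1 + self.n2


def watson_williams(sample1, sample2) -> WatsonWilliamsResult:
    """Two-sample Watson-Williams test for equality of mean directions.

    With per-sample resultant lengths R1, R2 and pooled resultant R,

        F = K * (N - 2) * (R1 + R2 - R) / (N - (R1 + R2)),

    where K = 1 + 3/(8*kappa) corrects for finite concentration and kappa is
    estimated from the pooled mean resultant length (R1 + R2)/N.  p is the
    upper tail of F(1, N-2).
    """
    a1 = np.radians(_as_angles(sample1))
    a2 = np.radians(_as_angles(sample2))
    n1, n2 = a1.size, a2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two angles")
    N = n1 + n2

    def _resultant(a):
        return math.hypot(np.sin(a).sum(), np.cos(a).sum())

    R1, R2 = _resultant(a1), _resultant(a2)
    R = _resultant(np.concatenate([a1, a2]))
    rbar_w = (R1 + R2) / N
    if rbar_w < 0.45:
        warnings.warn(
            f"pooled mean resultant length {rbar_w:.3f} < 0.45; "
            "Watson-Williams assumptions are stressed"
        )
    kappa = kappa_estimate(rbar_w)
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else float("inf")

    denom = N - (R1 + R2)
    numer = R1 + R2 - R
    if denom <= 1e-12 or numer <= 1e-10 * N:
        # degenerate (all angles identical) or resultants exactly additive
        F = 0.0
        p = 1.0
    else:
        F = K * (N - 2) * numer / denom
        p = float(stats.f.sf(F, 1, N - 2))

    m1, _ = circular_mean(np.degrees(a1))
    m2, _ = circular_mean(np.degrees(a2))
    return WatsonWilliamsResult(
        F=float(F), df1=1, df2=N - 2, p=p, K=float(K),
        mean_dir_1=m1, mean_dir_2=m2, n1=n1, n2=n2,
    )


def paired_direction_test(
    species_dirs: dict, temp_dirs: dict
) -> tuple[WatsonWilliamsResult, int]:
    """Watson-Williams test on province-matched direction estimates.

    ``species_dirs`` and ``temp_dirs`` map province id -> direction (deg).
    Only provinces present in both with finite directions enter; the number
    of provinces dropped is returned alongside the result.  Each matched
    province contributes one angle to each group, so df2 = 2*n_matched - 2.
    """
    keys1 = {k for k, v in species_dirs.items() if v is not None and np.isfinite(v)}
    keys2 = {k for k, v in temp_dirs.items() if v is not None and np.isfinite(v)}
    matched = sorted(keys1 & keys2)
    dropped = len(set(species_dirs) | set(temp_dirs)) - len(matched)
    if len(matched) < 2:
        raise ValueError("fewer than two provinces with both direction estimates")
    s = [species_dirs[k] for k in matched]
    t = [temp_dirs[k] for k in matched]
    return watson_williams(s, t), dropped
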