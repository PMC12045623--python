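"""Minimal circular statistics: means, resultants, Watson–Williams test.

Angles are degrees unless noted.  The Watson–Williams test is the
circular analogue of one-way ANOVA for equality of mean directions
across groups, assuming von Mises samples with common, reasonably high
concentration; the implementation follows the classical F-statistic
with the kappa-dependent correction factor.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def circ_mean_deg(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean, degrees in [0, 360)."""
    a = np.deg2rad(np.asarray(angles, float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, float)
    c = np.sum(w * np.cos(a))
    s = np.sum(w * np.sin(a))
    return float(np.mod(np.rad2deg(np.arctan2(s, c)), 360.0))


def circ_resultant(angles: np.ndarray) -> float:
    """Mean resultant length in [0, 1]."""
    a = np.deg2rad(np.asarray(angles, float))
    return float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))


def circ_dist_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed smallest angular difference a-b, degrees in (-180, 180]."""
    d = np.mod(np.asarray(a, float) - np.asarray(b, float) + 180.0, 360.0) - 180.0
    return np.where(d == -180.0, 180.0, d)


def _kappa_from_rbar(rbar: float) -> float:
    # Fisher's approximation of the von Mises concentration
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(*groups: np.ndarray) -> tuple[float, float]:
    """Watson–Williams test for equal mean directions.

    Parameters are arrays of angles in degrees, one per group.  Returns
    ``(F, p)``.  Degenerate inputs (all samples essentially at one
    angle per group) are resolved by the direction of the limit: equal
    group means give p=1, distinct means give p=0.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    k = len(groups)
    n_i = np.array([len(g) for g in groups])
    n = int(n_i.sum())
    r_i = np.array([circ_resultant(g) * len(g) for g in groups])  # group resultant lengths
    all_angles = np.concatenate(groups)
    r_tot = circ_resultant(all_angles) * n

    sum_ri = r_i.sum()
    within = n - sum_ri
    between = sum_ri - r_tot
    if within < 1e-12:
        # perfectly concentrated groups: compare means directly
        means = [circ_mean_deg(g) for g in groups]
        spread = np.max(np.abs(circ_dist_deg(np.asarray(means), means[0])))
        return (np.inf, 0.0) if spread > 1e-6 else (0.0, 1.0)
    kappa = _kappa_from_rbar(min(sum_ri / n, 1 - 1e-12))
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    f = correction * ((n - k) * between) / ((k - 1) * within)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p
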