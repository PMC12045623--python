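"""Single-neuron tuning analysis.

A unit's reach-direction tuning in the peri-movement window (MO +/- 100
ms) is summarized per target-motion condition by three indices:
preferred direction (PD; the angle of the rate-weighted vector sum over
the eight reach sectors), tuning depth (max - min of sector means), and
offset (grand mean rate).  Target-motion modulation is then classified
statistically: PD, tuning amplitude and offset are re-estimated on
disjoint trial splits, and each moving-target condition is compared
with the static condition by a Watson–Williams test (PD shift) or a
Wilcoxon rank-sum test (gain, addition) with small practical-effect
floors.  Tuning is also described parametrically by nonlinear
tuning-model fits (simple cosine, gain, additive, PD-shift, and full
models) compared via adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .circular import circ_dist_deg, circ_mean_deg, watson_williams
from .synth import PopulationActivity
from .task import N_SECTORS, sector_center

MO_WINDOW_MS = (-100.0, 100.0)

TUNING_MODELS = ("simple", "gain", "additive", "pd_shift", "full")
_N_PARAMS = {"simple": 3, "gain": 5, "additive": 5, "pd_shift": 5, "full": 8}


@dataclass(frozen=True)
class TuningIndices:
    """PD / depth / offset of one unit in one target-motion condition."""

    pd: float  # degrees, NaN if undefined
    depth: float
    offset: float
    pd_defined: bool = True


@dataclass(frozen=True)
class ModulationLabel:
    """Statistical modulation flags of one unit (flags may co-occur)."""

    pd_shift: bool
    gain: bool
    addition: bool
    direction_tuned: bool

    @property
    def none(self) -> bool:
        return not (self.pd_shift or self.gain or self.addition or self.direction_tuned)


@dataclass
class TuningFit:
    model_kind: str
    params: dict[str, float]
    r2: float
    r2_adj: float
    n_trials: int
    n_params: int
    converged: bool = True


# ---------------------------------------------------------------------------
# PSTH


def psth(
    activity: PopulationActivity,
    neuron: int,
    velocity: float,
    sector: int,
    smooth_sd_ms: float = 20.0,
    n_boot: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Condition-averaged smoothed rate and bootstrap SE for one cell.

    Averages trials of one (velocity, sector) cell, smooths with a
    Gaussian kernel (sd 20 ms), and estimates the SE from 10 bootstrap
    resamples of trials.
    """
    tt = activity.trial_table
    idx = np.flatnonzero((tt["target_velocity"] == velocity) & (tt["sector"] == sector))
    if idx.size == 0:
        raise ValueError(f"no trials for velocity={velocity}, sector={sector}")
    trials = activity.rates[neuron, idx]  # n_trials x T
    sd_bins = smooth_sd_ms / activity.bin_width

    def smooth(x):
        return ndimage.gaussian_filter1d(x, sd_bins, mode="nearest")

    mean = smooth(trials.mean(axis=0))
    rng = np.random.default_rng(seed)
    boots = np.stack(
        [smooth(trials[rng.integers(0, idx.size, idx.size)].mean(axis=0)) for _ in range(n_boot)]
    )
    se = boots.std(axis=0, ddof=0)
    return mean, se


# ---------------------------------------------------------------------------
# tuning indices


def tuning_indices(mo_rates: np.ndarray, sectors: np.ndarray) -> TuningIndices:
    """Indices from per-trial MO-window rates of one condition.

    ``mo_rates``: trial rates; ``sectors``: 1..8 per trial.  All eight
    sectors must be populated.
    """
    mo_rates = np.asarray(mo_rates, float)
    sectors = np.asarray(sectors, int)
    means = np.empty(N_SECTORS)
    for k in range(1, N_SECTORS + 1):
        sel = sectors == k
        if not sel.any():
            raise ValueError(f"sector {k} has no trials")
        means[k - 1] = mo_rates[sel].mean()
    centers = np.array([sector_center(k) for k in range(1, N_SECTORS + 1)])
    c = np.sum(means * np.cos(np.deg2rad(centers)))
    s = np.sum(means * np.sin(np.deg2rad(centers)))
    resultant = np.hypot(c, s)
    if resultant < 1e-9 * max(means.max(), 1e-12):
        pd_, defined = np.nan, False
    else:
        pd_, defined = float(np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)), True
    return TuningIndices(
        pd=pd_, depth=float(means.max() - means.min()), offset=float(mo_rates.mean()),
        pd_defined=defined,
    )


def sector_means(mo_rates: np.ndarray, sectors: np.ndarray) -> np.ndarray:
    """Mean rate per reach sector (length 8)."""
    mo_rates = np.asarray(mo_rates, float)
    sectors = np.asarray(sectors, int)
    return np.array([mo_rates[sectors == k].mean() for k in range(1, N_SECTORS + 1)])


# ---------------------------------------------------------------------------
# modulation classification


def _split_pds(
    mo_rates: np.ndarray,
    sectors: np.ndarray,
    rng: np.random.Generator,
    max_splits: int = 5,
) -> np.ndarray:
    """Independent PD estimates from disjoint trial splits.

    Trials within each sector are partitioned round-robin into as many
    splits as the thinnest sector allows (capped at ``max_splits``);
    each split yields one PD from its own sector means.  Unlike
    bootstrap replicates, the splits are independent samples, so the
    Watson–Williams group size is not inflated.
    """
    idx_by_sector = [np.flatnonzero(sectors == k) for k in range(1, N_SECTORS + 1)]
    n_splits = min(min(ix.size for ix in idx_by_sector), max_splits)
    centers = np.array([sector_center(k) for k in range(1, N_SECTORS + 1)])
    assign = []
    for ix in idx_by_sector:
        perm = rng.permutation(ix)
        assign.append([perm[j::n_splits] for j in range(n_splits)])
    pds = np.empty(n_splits)
    for j in range(n_splits):
        means = np.array([mo_rates[assign[k][j]].mean() for k in range(N_SECTORS)])
        c = np.sum(means * np.cos(np.deg2rad(centers)))
        s = np.sum(means * np.sin(np.deg2rad(centers)))
        pds[j] = np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)
    return pds


def _split_cosine(
    mo_rates: np.ndarray,
    sectors: np.ndarray,
    theta: np.ndarray | None,
    rng: np.random.Generator,
    max_splits: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent (amplitude, offset) estimates from disjoint splits.

    Each split's estimates come from the linear cosine model
    a·cosθ + b·sinθ + c: amplitude sqrt(a²+b²), offset c.  Both are
    exact for cosine-tuned units whatever the trial angle distribution
    (raw sector statistics are not: they pick up angle-sampling terms
    proportional to the tuning amplitude).
    """
    if theta is None:
        theta = np.array([sector_center(k) for k in sectors])
    th = np.deg2rad(np.asarray(theta, float))
    idx_by_sector = [np.flatnonzero(sectors == k) for k in range(1, N_SECTORS + 1)]
    n_splits = min(min(ix.size for ix in idx_by_sector), max_splits)
    assign = [[] for _ in range(n_splits)]
    for ix in idx_by_sector:
        perm = rng.permutation(ix)
        for j in range(n_splits):
            assign[j].extend(perm[j::n_splits])
    amps = np.empty(n_splits)
    offs = np.empty(n_splits)
    for j, ix in enumerate(assign):
        ix = np.asarray(ix)
        A = np.column_stack([np.cos(th[ix]), np.sin(th[ix]), np.ones(ix.size)])
        coef, *_ = np.linalg.lstsq(A, mo_rates[ix], rcond=None)
        amps[j] = np.hypot(coef[0], coef[1])
        offs[j] = coef[2]
    return amps, offs


def classify_modulation(
    mo_rates: np.ndarray,
    sectors: np.ndarray,
    velocities: np.ndarray,
    theta: np.ndarray | None = None,
    static_velocity: float = 0.0,
    alpha: float = 0.05,
    min_shift_deg: float = 5.0,
    min_offset_frac: float = 0.02,
    min_gain_frac: float = 0.02,
    seed: int = 0,
) -> ModulationLabel:
    """Classify a unit's target-motion modulation of direction tuning.

    For each moving-target condition against the static condition:

    * *PD shift* — Watson–Williams test on independent PD estimates
      from disjoint trial splits, plus a practical floor of
      ``min_shift_deg`` on the PD difference;
    * *gain* — Wilcoxon rank-sum on split-wise tuning-amplitude
      estimates (sqrt(a²+b²) of a linear cosine fit a·cosθ+b·sinθ+c),
      with a practical floor of ``min_gain_frac`` on the relative
      amplitude change;
    * *addition* — Wilcoxon rank-sum on split-wise offset estimates
      (the cosine-fit intercept c, which isolates the offset from
      direction tuning regardless of the angle sampling), with a floor
      of ``min_offset_frac`` on the relative offset change.

    A flag is set if any moving condition rejects at ``alpha``.
    ``direction_tuned`` is a Kruskal–Wallis test of rates across sectors
    within any single condition; PD-shift and gain flags require it
    (modulation of a tuning curve presupposes a tuning curve).
    """
    mo_rates = np.asarray(mo_rates, float)
    sectors = np.asarray(sectors, int)
    velocities = np.asarray(velocities, float)
    theta = None if theta is None else np.asarray(theta, float)
    rng = np.random.default_rng(seed)

    vels = np.unique(velocities)
    if static_velocity not in vels or vels.size < 2:
        raise ValueError("need the static condition and at least one moving condition")

    sel_static = velocities == static_velocity
    static_pds = _split_pds(mo_rates[sel_static], sectors[sel_static], rng)
    static_pd = circ_mean_deg(static_pds)

    direction_tuned = False
    for v in vels:
        sel = velocities == v
        groups = [mo_rates[sel & (sectors == k)] for k in range(1, N_SECTORS + 1)]
        groups = [g for g in groups if g.size > 0]
        if len(groups) >= 2 and np.ptp(np.concatenate(groups)) > 0:
            try:
                if stats.kruskal(*groups).pvalue < alpha:
                    direction_tuned = True
                    break
            except ValueError:  # all identical values
                pass

    def _ranksum_with_floor(vals, static_vals, floor_scale, floor_frac):
        change = abs(float(np.mean(vals)) - float(np.mean(static_vals)))
        if change < floor_frac * max(abs(floor_scale), 1e-12):
            return False
        try:
            p = float(stats.mannwhitneyu(vals, static_vals, alternative="two-sided").pvalue)
        except ValueError:
            return False
        return p < alpha

    static_amps, static_offsets = _split_cosine(
        mo_rates[sel_static], sectors[sel_static],
        theta[sel_static] if theta is not None else None, rng,
    )
    static_amp = float(np.mean(static_amps))
    static_offset = float(np.mean(static_offsets))
    pd_shift = gain = addition = False
    for v in vels[vels != static_velocity]:
        sel = velocities == v
        amps, offs = _split_cosine(
            mo_rates[sel], sectors[sel], theta[sel] if theta is not None else None, rng
        )
        if direction_tuned and _ranksum_with_floor(amps, static_amps, static_amp, min_gain_frac):
            gain = True
        if _ranksum_with_floor(offs, static_offsets, static_offset, min_offset_frac):
            addition = True
        if direction_tuned:
            pds = _split_pds(mo_rates[sel], sectors[sel], rng)
            _, p_ww = watson_williams(pds, static_pds)
            shift_size = abs(circ_dist_deg(circ_mean_deg(pds), static_pd))
            if p_ww < alpha and shift_size >= min_shift_deg:
                pd_shift = True

    return ModulationLabel(pd_shift=pd_shift, gain=gain, addition=addition,
                           direction_tuned=direction_tuned)


def classify_population(
    activity: PopulationActivity,
    window_ms: tuple[float, float] = MO_WINDOW_MS,
    active_threshold: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Classify every (active) unit of a session; returns a flag table."""
    X = activity.window_mean(*window_ms)  # trials x neurons
    tt = activity.trial_table
    sectors = tt["sector"].to_numpy()
    velocities = tt["target_velocity"].to_numpy()
    theta = (
        tt["reach_endpoint_angle"].to_numpy()
        if "reach_endpoint_angle" in tt.columns
        else None
    )
    rows = []
    for i in range(activity.n_neurons):
        mean_rate = float(activity.rates[i].mean())
        active = mean_rate > active_threshold
        if active:
            lab = classify_modulation(
                X[:, i], sectors, velocities, theta=theta, seed=seed + i, **kwargs
            )
            rows.append(
                dict(neuron=i, active=True, pd_shift=lab.pd_shift, gain=lab.gain,
                     addition=lab.addition, direction_tuned=lab.direction_tuned,
                     none=lab.none, mean_rate=mean_rate)
            )
        else:
            rows.append(dict(neuron=i, active=False, pd_shift=False, gain=False,
                             addition=False, direction_tuned=False, none=False,
                             mean_rate=mean_rate))
    return pd.DataFrame(rows)


def modulation_fractions(flags: pd.DataFrame) -> dict[str, float]:
    """Fractions of gain / PD-shift / addition / none among active units."""
    act = flags[flags["active"]]
    n = max(len(act), 1)
    return {
        "gain": act["gain"].sum() / n,
        "pd_shift": act["pd_shift"].sum() / n,
        "addition": act["addition"].sum() / n,
        "none": act["none"].sum() / n,
        "n_active": len(act),
    }


# ---------------------------------------------------------------------------
# tuning-model fits


def _sig(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _model_predict(kind: str, p: np.ndarray, theta: np.ndarray, vel: np.ndarray) -> np.ndarray:
    th = np.deg2rad(theta)
    if kind == "simple":
        a1, pd_, c1 = p
        return a1 * np.cos(th - np.deg2rad(pd_)) + c1
    if kind == "gain":
        a1, a2, c2, pd_, c1 = p
        return (a1 * _sig(a2 * vel) + c2) * np.cos(th - np.deg2rad(pd_)) + c1
    if kind == "additive":
        a1, a2, a3, pd_, c1 = p
        return a1 * np.cos(th - np.deg2rad(pd_)) + a3 * _sig(a2 * vel) + c1
    if kind == "pd_shift":
        a1, a2, a5, pd_, c1 = p
        return a1 * np.cos(th - np.deg2rad(pd_) - np.deg2rad(a5 * _sig(a2 * vel))) + c1
    if kind == "full":
        a1, a2, a3p, a3, a4, a5, pd_, c1 = p
        s = _sig(a2 * vel)
        cosd = np.cos(th - np.deg2rad(pd_))
        return (
            a1 * cosd + a3p * s + a3 * s * cosd
            + a4 * np.cos(th - np.deg2rad(pd_) - np.deg2rad(a5 * s)) + c1
        )
    raise ValueError(f"unknown model kind {kind!r}")


_PARAM_NAMES = {
    "simple": ("a1", "theta_pd", "c1"),
    "gain": ("a1", "a2", "c2", "theta_pd", "c1"),
    "additive": ("a1", "a2", "a3", "theta_pd", "c1"),
    "pd_shift": ("a1", "a2", "a5", "theta_pd", "c1"),
    "full": ("a1", "a2", "a3_prime", "a3", "a4", "a5", "theta_pd", "c1"),
}


def fit_tuning_model(
    mo_rates: np.ndarray,
    theta: np.ndarray,
    vel: np.ndarray,
    model_kind: str,
    vel_scale: float = 120.0,
) -> TuningFit:
    """Nonlinear least-squares fit of one tuning model to single trials.

    ``vel`` is the signed target velocity in deg/s and is mapped to the
    symmetric code vel/``vel_scale`` inside the sigmoids (pass
    ``vel_scale=1`` with a pre-centered code for abstract units).
    Multi-start over an 8-point PD grid and two sigmoid-slope signs;
    ties broken by lowest residual, then smallest |a2|.
    """
    if model_kind not in TUNING_MODELS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    y = np.asarray(mo_rates, float)
    theta = np.asarray(theta, float)
    v = np.asarray(vel, float) / vel_scale
    n, p_n = y.size, _N_PARAMS[model_kind]
    if n < p_n + 2:
        raise ValueError(f"need at least {p_n + 2} trials for {model_kind}")

    amp0 = max(np.ptp(y) / 2.0, 1e-3)
    c0 = float(y.mean())
    starts = []
    for pd0 in np.arange(0.0, 360.0, 45.0):
        for a20 in (1.0, -1.0):
            if model_kind == "simple":
                starts.append([amp0, pd0, c0])
            elif model_kind == "gain":
                starts.append([amp0, a20, amp0 / 2, pd0, c0])
            elif model_kind == "additive":
                starts.append([amp0, a20, amp0 / 2, pd0, c0])
            elif model_kind == "pd_shift":
                starts.append([amp0, a20, 45.0, pd0, c0])
            else:
                starts.append([amp0, a20, amp0 / 4, amp0 / 4, amp0 / 4, 45.0, pd0, c0])
        if model_kind == "simple":
            break  # slope-sign start irrelevant

    def resid(p):
        return _model_predict(model_kind, p, theta, v) - y

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        cost = 2 * sol.cost
        a2_mag = abs(sol.x[1]) if model_kind != "simple" else 0.0
        key = (round(cost, 10), a2_mag)
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        return TuningFit(model_kind, {}, np.nan, np.nan, n, p_n, converged=False)

    sol = best[1]
    ss_res = float(2 * sol.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_n - 1)
    params = dict(zip(_PARAM_NAMES[model_kind], sol.x))
    params = _canonicalize(model_kind, params)
    return TuningFit(model_kind, params, r2, r2_adj, n, p_n)


def _canonicalize(kind: str, params: dict[str, float]) -> dict[str, float]:
    """Resolve the (-A, theta_pd+180) cosine degeneracy toward positive
    amplitude at the mid-velocity, and wrap theta_pd into [0, 360)."""
    p = dict(params)
    if kind == "gain":
        amp_mid = p["a1"] / 2.0 + p["c2"]
        if amp_mid < 0:
            p["a1"], p["c2"] = -p["a1"], -p["c2"]
            p["theta_pd"] += 180.0
    elif kind in ("simple", "additive", "pd_shift", "full"):
        if p["a1"] < 0:
            p["a1"] = -p["a1"]
            if kind == "full":  # every cos(theta - pd - ...) term flips with pd
                p["a3"] = -p["a3"]
                p["a4"] = -p["a4"]
            p["theta_pd"] += 180.0
    p["theta_pd"] = float(np.mod(p["theta_pd"], 360.0))
    return p


def compare_models(fits_by_model: dict[str, np.ndarray]) -> pd.DataFrame:
    """Population-level model comparison on per-neuron adjusted R².

    Returns one row per model with mean/sd adjusted R² and the one-tailed
    rank-sum p-value that the best-ranked model exceeds it.
    """
    if len(fits_by_model) < 2:
        raise ValueError("need at least two model kinds")
    order = sorted(fits_by_model, key=lambda m: -np.nanmean(fits_by_model[m]))
    top = np.asarray(fits_by_model[order[0]], float)
    rows = []
    for m in order:
        vals = np.asarray(fits_by_model[m], float)
        p = 0.5 if m == order[0] else float(
            stats.ranksums(top[~np.isnan(top)], vals[~np.isnan(vals)],
                           alternative="greater").pvalue
        )
        rows.append(dict(model=m, mean_r2_adj=np.nanmean(vals), sd_r2_adj=np.nanstd(vals),
                         p_vs_best=p))
    return pd.DataFrame(rows)
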