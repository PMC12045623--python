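"""Model-neuron populations and synthetic recording sessions.

Three representational single-neuron models combine a Gaussian temporal
profile, cosine tuning to reach direction, and a sigmoidal modulation of
the tuning by target velocity:

* ``gain``      — velocity scales the cosine amplitude,
* ``pd_shift``  — velocity rotates the preferred direction (up to 90 deg),
* ``additive``  — velocity shifts the direction-independent offset.

Model populations use an abstract velocity code ``vel = 1..5`` and a
64-direction grid (320 trials).  The noisy-session generator maps the
same mechanisms onto real task units (deg/s, spikes/s) and adds
Poisson-like trial noise, with ground-truth labels kept for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import (
    STANDARD_VELOCITIES,
    TrialCondition,
    assign_sector,
    make_trial_table,
)

MODEL_KINDS = ("gain", "pd_shift", "additive")

#: time axis of model neurons: bins 1..200, movement onset at bin 100
N_TIME_BINS = 200
MO_BIN = 100
TEMPORAL_SIGMA = 30.0  # bins
#: bins averaged for the movement-onset window (inclusive)
MO_WINDOW = (50, 150)

N_MODEL_DIRECTIONS = 64
MODEL_VELOCITIES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class ModelNeuronParams:
    """Parameters of one model neuron.

    ``g_n`` (gain / additive kinds) lies in [0, 1]; ``s_n`` (PD-shift
    kind) in [0, 1.5]; ``t_mu`` is the peak-time bin, drawn N(100, 10).
    """

    kind: str
    theta_pd: float
    g_n: float = 0.5
    s_n: float = 0.75
    t_mu: float = float(MO_BIN)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class PopulationActivity:
    """Firing-rate tensor (neurons x trials x time bins) with labels."""

    rates: np.ndarray
    bin_width: float
    alignment: str
    trial_table: pd.DataFrame
    bin_centers: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rates.ndim != 3:
            raise ValueError("rates must be neurons x trials x bins")
        if self.rates.shape[1] != len(self.trial_table):
            raise ValueError("trial dimension does not match trial table")
        if self.bin_centers is None:
            t = np.arange(self.rates.shape[2])
            self.bin_centers = (t - t.mean()) * self.bin_width

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    def window_mean(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Trials x neurons mean rate over bins centered in [start, end] ms."""
        mask = (self.bin_centers >= start_ms) & (self.bin_centers <= end_ms)
        if not mask.any():
            raise ValueError("window contains no bins")
        return self.rates[:, :, mask].mean(axis=2).T

    def bin_index_mean(self, first_bin: int, last_bin: int) -> np.ndarray:
        """Trials x neurons mean over 1-based bin indices (inclusive)."""
        return self.rates[:, :, first_bin - 1 : last_bin].mean(axis=2).T

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("rates", data=self.rates)
            f.create_dataset("bin_centers", data=self.bin_centers)
            f.attrs["bin_width"] = self.bin_width
            f.attrs["alignment"] = self.alignment
        self.trial_table.to_csv(str(path) + ".trials.csv", index=False)

    @classmethod
    def from_hdf5(cls, path) -> "PopulationActivity":
        import h5py

        with h5py.File(path, "r") as f:
            rates = f["rates"][:]
            centers = f["bin_centers"][:]
            bw = float(f.attrs["bin_width"])
            alignment = str(f.attrs["alignment"])
        table = pd.read_csv(str(path) + ".trials.csv")
        return cls(rates, bw, alignment, table, bin_centers=centers)


# ---------------------------------------------------------------------------
# model-neuron rate equations (abstract units: vel = 1..5, rate in [0, 3])


def _temporal(t: np.ndarray | float, t_mu: float) -> np.ndarray:
    return np.exp(-((np.asarray(t, float) - t_mu) ** 2) / (2.0 * TEMPORAL_SIGMA**2))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gain_neuron_rate(params: ModelNeuronParams, t, vel, theta) -> np.ndarray:
    """Gain model: velocity multiplies the cosine-tuning amplitude."""
    cos = np.cos(np.deg2rad(np.asarray(theta, float) - params.theta_pd))
    gain = _sigmoid(params.g_n * (np.asarray(vel, float) - 3.0))
    return _temporal(t, params.t_mu) * (gain * cos + 1.0)


def pd_shift_neuron_rate(params: ModelNeuronParams, t, vel, theta) -> np.ndarray:
    """PD-shift model: velocity rotates the preferred direction by up to 90 deg."""
    shift = 90.0 * _sigmoid(params.s_n * (np.asarray(vel, float) - 3.0))
    cos = np.cos(np.deg2rad(np.asarray(theta, float) - params.theta_pd - shift))
    return _temporal(t, params.t_mu) * (cos + 1.0)


def additive_neuron_rate(params: ModelNeuronParams, t, vel, theta) -> np.ndarray:
    """Additive model: velocity shifts the direction-independent offset."""
    cos = np.cos(np.deg2rad(np.asarray(theta, float) - params.theta_pd))
    offset = _sigmoid(params.g_n * (np.asarray(vel, float) - 3.0))
    return _temporal(t, params.t_mu) * (cos + offset + 1.0)


_RATE_FUNCS = {
    "gain": gain_neuron_rate,
    "pd_shift": pd_shift_neuron_rate,
    "additive": additive_neuron_rate,
}


def model_neuron_rate(params: ModelNeuronParams, t, vel, theta) -> np.ndarray:
    return _RATE_FUNCS[params.kind](params, t, vel, theta)


def _model_trial_grid() -> tuple[np.ndarray, np.ndarray]:
    """The 5 x 64 abstract trial grid: (vel, theta) per trial, vel-major."""
    thetas = 360.0 * np.arange(1, N_MODEL_DIRECTIONS + 1) / N_MODEL_DIRECTIONS
    vel = np.repeat(MODEL_VELOCITIES, N_MODEL_DIRECTIONS).astype(float)
    theta = np.tile(thetas, len(MODEL_VELOCITIES))
    return vel, theta


def draw_model_params(kind: str, n: int, rng: np.random.Generator) -> list[ModelNeuronParams]:
    """Per-neuron parameters: PDs on a uniform deterministic grid,
    g_n ~ U[0,1], s_n ~ U[0,1.5], t_mu ~ N(100,10)."""
    pds = 360.0 * np.arange(n) / n
    g = rng.uniform(0.0, 1.0, n)
    s = rng.uniform(0.0, 1.5, n)
    t_mu = rng.normal(MO_BIN, 10.0, n)
    return [
        ModelNeuronParams(kind=kind, theta_pd=pds[i], g_n=g[i], s_n=s[i], t_mu=t_mu[i])
        for i in range(n)
    ]


def build_model_population(
    kind_mix: dict[str, int],
    seed: int | np.random.Generator = 0,
) -> PopulationActivity:
    """Simulate a model population on the 5-velocity x 64-direction grid.

    ``kind_mix`` maps model kind to neuron count, e.g. ``{"gain": 300}``
    for a pure group or ``{"gain": 100, "pd_shift": 100, "additive": 100}``
    for the mixed group.  Returns an ``n x 320 x 200`` rate tensor with
    the abstract velocity code stored in the trial table (mapped onto the
    standard deg/s values for sector/velocity labels).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_total = sum(kind_mix.values())
    if n_total < 1:
        raise ValueError("need at least one neuron")
    vel, theta = _model_trial_grid()
    t = np.arange(1, N_TIME_BINS + 1, dtype=float)

    params: list[ModelNeuronParams] = []
    for kind, n in kind_mix.items():
        params.extend(draw_model_params(kind, n, rng))

    rates = np.empty((n_total, vel.size, N_TIME_BINS))
    for i, p in enumerate(params):
        rates[i] = _RATE_FUNCS[p.kind](p, t[None, :], vel[:, None], theta[:, None])

    vel_map = dict(zip(MODEL_VELOCITIES, STANDARD_VELOCITIES))
    table = pd.DataFrame(
        {
            "target_velocity": [vel_map[int(v)] for v in vel],
            "vel_code": vel,
            "reach_endpoint_angle": np.mod(theta, 360.0),
            "sector": [assign_sector(a) for a in theta],
        }
    )
    pop = PopulationActivity(
        rates=rates,
        bin_width=10.0,
        alignment="MO",
        trial_table=table,
        bin_centers=(t - MO_BIN) * 10.0,
        meta={"params": params, "kind_mix": dict(kind_mix)},
    )
    return pop


def mo_state_matrix(pop: PopulationActivity) -> np.ndarray:
    """Trials x neurons matrix averaged over the MO window (bins 50-150)."""
    return pop.bin_index_mean(*MO_WINDOW)


# ---------------------------------------------------------------------------
# noisy synthetic sessions in task units


@dataclass(frozen=True)
class ModulationSpec:
    """Ground-truth tuning of one synthetic unit in task units.

    ``amp`` is the cosine amplitude (spikes/s), ``baseline`` the offset
    rate, ``slope`` the sigmoid steepness on the velocity code
    (vel / 120 deg/s), and ``mod`` the modulation magnitude: extra gain
    amplitude (spikes/s), additive offset range (spikes/s), or maximal
    PD shift (degrees) depending on ``kind``.
    """

    kind: str
    theta_pd: float
    amp: float = 10.0
    baseline: float = 20.0
    slope: float = 1.5
    mod: float = 10.0

    def mean_rate(self, theta, vel_deg_s) -> np.ndarray:
        vc = np.asarray(vel_deg_s, float) / 120.0
        sig = _sigmoid(self.slope * vc)
        th = np.asarray(theta, float)
        if self.kind == "gain":
            fr = (self.mod * sig + self.amp) * np.cos(np.deg2rad(th - self.theta_pd)) + self.baseline
        elif self.kind == "additive":
            fr = self.amp * np.cos(np.deg2rad(th - self.theta_pd)) + self.mod * sig + self.baseline
        elif self.kind == "pd_shift":
            fr = (
                self.amp * np.cos(np.deg2rad(th - self.theta_pd - self.mod * sig))
                + self.baseline
            )
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        return np.maximum(fr, 0.0)


def default_population_spec(
    n_per_kind: int, rng: np.random.Generator, rate_scale: float = 1.0
) -> list[ModulationSpec]:
    """A mixed ground-truth population with uniform-grid PDs per kind."""
    specs = []
    for kind in MODEL_KINDS:
        pds = 360.0 * np.arange(n_per_kind) / max(n_per_kind, 1)
        for pd_ in pds:
            amp = rng.uniform(8.0, 15.0)
            mod = rng.uniform(40.0, 80.0) if kind == "pd_shift" else rng.uniform(8.0, 15.0)
            # baseline exceeds the largest possible tuning excursion so
            # rates never rectify at zero (rectification would itself
            # induce spurious mixed selectivity in a "pure" unit)
            head = amp + (0.0 if kind == "pd_shift" else mod)
            baseline = head + rng.uniform(5.0, 15.0)
            specs.append(
                ModulationSpec(
                    kind=kind,
                    theta_pd=float(pd_),
                    amp=rate_scale * amp,
                    baseline=rate_scale * baseline,
                    slope=rng.uniform(1.0, 2.5),
                    mod=mod if kind == "pd_shift" else rate_scale * mod,
                )
            )
    return specs


SESSION_BIN_MS = 50.0
SESSION_N_BINS = 40  # MO-1000 .. MO+1000


def generate_noisy_session(
    ground_truth: list[ModulationSpec],
    trials_per_cell: int,
    noise: float = 1.0,
    seed: int | np.random.Generator = 0,
    velocities: tuple[float, ...] = STANDARD_VELOCITIES,
) -> PopulationActivity:
    """Emulate a recorded session from known single-unit ground truth.

    Builds ``trials_per_cell`` trials in every (velocity, sector) cell
    with endpoint angles jittered uniformly inside the sector and delays
    drawn U[400, 800] ms.  Per-trial rates are the tuning-model mean
    scaled by a Gaussian temporal profile (sd 300 ms, peak jittered
    around MO), with Poisson-count noise per 50 ms bin whose variance is
    ``noise`` times the Poisson variance (``noise=0`` -> noiseless).
    """
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    conditions: list[TrialCondition] = []
    for v in velocities:
        for sector in range(1, 9):
            lo = (sector - 1) * 45.0
            for _ in range(trials_per_cell):
                endpoint = lo + rng.uniform(0.0, 45.0)
                delay = rng.uniform(400.0, 800.0)
                t_go = delay
                t_mo = t_go + 200.0
                t_touch = t_mo + 300.0
                theta0 = np.mod(endpoint - v * t_touch / 1000.0, 360.0)
                conditions.append(
                    TrialCondition(
                        target_velocity=v,
                        initial_target_angle=theta0,
                        reach_endpoint_angle=endpoint,
                        sector=sector,
                        t_target_on=0.0,
                        t_go=t_go,
                        t_move_onset=t_mo,
                        t_touch=t_touch,
                    )
                )
    rng.shuffle(conditions)
    table = make_trial_table(conditions)

    n = len(ground_truth)
    k = len(conditions)
    centers = (np.arange(SESSION_N_BINS) - (SESSION_N_BINS - 1) / 2.0) * SESSION_BIN_MS
    theta = table["reach_endpoint_angle"].to_numpy()
    vel = table["target_velocity"].to_numpy()

    peak_jitter = rng.normal(0.0, 100.0, size=(n, 1))
    profile = np.exp(-((centers[None, None, :] - peak_jitter[:, :, None]) ** 2) / (2 * 300.0**2))

    mean_tuning = np.stack([spec.mean_rate(theta, vel) for spec in ground_truth])  # n x k
    mean_rates = mean_tuning[:, :, None] * profile  # n x k x T

    if noise == 0:
        rates = mean_rates
    else:
        dt_s = SESSION_BIN_MS / 1000.0
        lam = mean_rates * dt_s / noise
        counts = rng.poisson(lam)
        rates = counts * noise / dt_s

    return PopulationActivity(
        rates=rates,
        bin_width=SESSION_BIN_MS,
        alignment="MO",
        trial_table=table,
        bin_centers=centers,
        meta={"ground_truth": list(ground_truth), "noise": noise},
    )
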