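"""Task-trained recurrent network for flexible manual interception.

A rate network of 200 rectified-tanh units with time constant 50 ms
receives five input channels — motor intention (the 2D interception
point, present only from MO-50 ms to MO), the moving target's 2D
location throughout the trial, and a GO step signal — and must output
2D hand velocity after movement onset so that the integrated hand
trajectory intercepts the target (path radius 0.15 a.u.).

Dynamics (Euler-integrated, dt = 10 ms):

    tau * dx/dt = -x + J r + B u,      r = tanh(x) for x > 0 else 0,
    z = W r.

The loss is the mean squared output error plus an activity penalty
alpha * sum_t sum_n r^2 (alpha = 1e-7), minimized with Adam (lr =
0.001) by backpropagation through time.  J is initialized
N(0, (g/N)^2) with g = 1.5 (a ``g_over_sqrt_n`` switch gives the
conventional 1/sqrt(N) scaling); B and W start at zero.

Trained models are then analyzed exactly like recorded populations:
node modulation classification, neural-state geometry, ablation and
connection-scaling perturbations, connectivity statistics, and latent
comparison with data via CCA and Procrustes analysis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _procrustes
from scipy.stats import pearsonr
from sklearn.cross_decomposition import CCA
from sklearn.decomposition import PCA

from . import tuning as tuning_mod
from .geometry import geometry_summary, neural_states
from .synth import PopulationActivity
from .task import (
    STANDARD_VELOCITIES,
    TARGET_RADIUS_AU,
    TrialCondition,
    assign_sector,
    bell_speed_profile,
    make_trial_table,
    target_angle_at,
)

VARIANTS = ("main", "GM", "GT", "sparse")

#: fixed trial phases, ms (delay is drawn per trial)
REACTION_TIME_MS = 200.0
MOVEMENT_TIME_MS = 300.0
INTENTION_LEAD_MS = 50.0

#: window extracted around MO for population-style analyses, ms
ALIGN_WINDOW_MS = (-500.0, 300.0)


@dataclass(frozen=True)
class RNNParams:
    n_units: int = 200
    tau: float = 50.0
    g: float = 1.5
    alpha: float = 1e-7
    lr: float = 0.001
    dt: float = 10.0
    sparsity: float = 0.0
    scale_mode: str = "g_over_n"  # or "g_over_sqrt_n"

    def __post_init__(self) -> None:
        if self.dt > self.tau / 2:
            raise ValueError("dt must be <= tau/2 for stable Euler integration")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.scale_mode not in ("g_over_n", "g_over_sqrt_n"):
            raise ValueError("scale_mode must be 'g_over_n' or 'g_over_sqrt_n'")


@dataclass
class RNNTrial:
    inputs: np.ndarray  # T x 5
    target_output: np.ndarray  # T x 2
    loss_mask: np.ndarray  # T (1 inside trial, 0 in padding)
    condition: TrialCondition
    mo_step: int
    end_step: int


@dataclass
class TrainedRNN:
    J: np.ndarray
    B: np.ndarray  # N x 5
    W: np.ndarray  # 2 x N
    params: RNNParams
    variant: str = "main"
    seed: int = 0
    loss_log: np.ndarray = field(default_factory=lambda: np.empty(0))

    def copy(self) -> "TrainedRNN":
        return copy.deepcopy(self)

    def to_hdf5(self, path) -> None:
        """Checkpoint weights, parameters, seed and training log."""
        import dataclasses

        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("J", data=self.J)
            f.create_dataset("B", data=self.B)
            f.create_dataset("W", data=self.W)
            f.create_dataset("loss_log", data=self.loss_log)
            f.attrs["variant"] = self.variant
            f.attrs["seed"] = self.seed
            for k, v in dataclasses.asdict(self.params).items():
                f.attrs[f"param_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "TrainedRNN":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {
                k[len("param_"):]: f.attrs[k] for k in f.attrs if k.startswith("param_")
            }
            kw = {
                k: (str(v) if k == "scale_mode" else type(RNNParams.__dataclass_fields__[k].default)(v))
                for k, v in kw.items()
            }
            return cls(
                J=f["J"][:], B=f["B"][:], W=f["W"][:],
                params=RNNParams(**kw),
                variant=str(f.attrs["variant"]), seed=int(f.attrs["seed"]),
                loss_log=f["loss_log"][:],
            )


def rectified_tanh(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, np.tanh(x), 0.0)


def _dphi(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0 - np.tanh(x) ** 2, 0.0)


def step(x: np.ndarray, u: np.ndarray, J: np.ndarray, B: np.ndarray,
         params: RNNParams) -> np.ndarray:
    """One Euler step of the rate dynamics; returns the next x."""
    a = params.dt / params.tau
    r = rectified_tanh(x)
    return x + a * (-x + r @ J.T + u @ B.T)


# ---------------------------------------------------------------------------
# trial construction


_VARIANT_CHANNELS = {
    "main": (0, 1, 2, 3, 4),
    "GM": (0, 1, 4),  # intention + GO
    "GT": (2, 3, 4),  # target + GO
    "sparse": (0, 1, 2, 3, 4),
}


def make_condition(
    target_velocity: float,
    endpoint_angle: float,
    delay_ms: float,
) -> TrialCondition:
    """A trial timed TO=0, GO=delay, MO=GO+200 ms, Touch=MO+300 ms, with
    the initial target angle back-computed so the target is at
    ``endpoint_angle`` at touch (the interception point)."""
    t_go = delay_ms
    t_mo = t_go + REACTION_TIME_MS
    t_touch = t_mo + MOVEMENT_TIME_MS
    theta0 = np.mod(endpoint_angle - target_velocity * t_touch / 1000.0, 360.0)
    return TrialCondition(
        target_velocity=target_velocity,
        initial_target_angle=float(theta0),
        reach_endpoint_angle=float(np.mod(endpoint_angle, 360.0)),
        sector=assign_sector(endpoint_angle),
        t_target_on=0.0,
        t_go=t_go,
        t_move_onset=t_mo,
        t_touch=t_touch,
    )


def build_trial(
    condition: TrialCondition,
    params: RNNParams,
    variant: str = "main",
    n_steps: int | None = None,
) -> RNNTrial:
    """Input and target time series of one trial.

    The desired output is a minimum-jerk speed profile directed at the
    interception point (the target position at touch), nonzero only
    after MO; its integral equals the interception displacement.
    """
    dt = params.dt
    end_step = int(round(condition.t_touch / dt))
    T = end_step if n_steps is None else n_steps
    if T < end_step:
        raise ValueError("n_steps shorter than the trial")
    t_ms = (np.arange(T) + 1) * dt  # time at the end of each step

    t_clip = np.minimum(t_ms, condition.t_touch)  # target stops at touch
    angles = np.mod(
        condition.initial_target_angle
        + condition.target_velocity * (t_clip - condition.t_target_on) / 1000.0,
        360.0,
    )
    target_xy = TARGET_RADIUS_AU * np.column_stack(
        [np.cos(np.deg2rad(angles)), np.sin(np.deg2rad(angles))]
    )
    icp_angle = target_angle_at(condition, condition.t_touch)
    icp = TARGET_RADIUS_AU * np.array(
        [np.cos(np.deg2rad(icp_angle)), np.sin(np.deg2rad(icp_angle))]
    )

    go_step = np.where(t_ms >= condition.t_go, 1.0, 0.0)
    mo_step = int(round(condition.t_move_onset / dt))
    intention = np.zeros((T, 2))
    in_lead = (t_ms > condition.t_move_onset - INTENTION_LEAD_MS) & (
        t_ms <= condition.t_move_onset
    )
    intention[in_lead] = icp

    inputs = np.zeros((T, 5))
    inputs[:, 0:2] = intention
    inputs[:, 2:4] = target_xy
    inputs[:, 4] = go_step
    keep = _VARIANT_CHANNELS[variant]
    drop = [c for c in range(5) if c not in keep]
    inputs[:, drop] = 0.0

    target = np.zeros((T, 2))
    n_move = end_step - mo_step
    speed = bell_speed_profile(MOVEMENT_TIME_MS / 1000.0, TARGET_RADIUS_AU, n_move)
    direction = icp / np.linalg.norm(icp)
    target[mo_step:end_step] = speed[:, None] * direction[None, :]

    loss_mask = np.zeros(T)
    loss_mask[:end_step] = 1.0
    return RNNTrial(inputs, target, loss_mask, condition, mo_step, end_step)


def random_conditions(n: int, rng: np.random.Generator) -> list[TrialCondition]:
    """Random training/validation conditions: uniform velocity from the
    standard set, uniform endpoint angle, delay U[400, 800] ms."""
    vels = rng.choice(STANDARD_VELOCITIES, n)
    angles = rng.uniform(0.0, 360.0, n)
    delays = rng.uniform(400.0, 800.0, n)
    return [make_condition(v, a, d) for v, a, d in zip(vels, angles, delays)]


def grid_conditions(trials_per_cell: int, rng: np.random.Generator) -> list[TrialCondition]:
    """Balanced 5 x 8 grid with endpoint jitter inside each sector."""
    conds = []
    for v in STANDARD_VELOCITIES:
        for sector in range(1, 9):
            for _ in range(trials_per_cell):
                endpoint = (sector - 1) * 45.0 + rng.uniform(0.0, 45.0)
                conds.append(make_condition(v, endpoint, rng.uniform(400.0, 800.0)))
    return conds


def validation_conditions(n: int = 500, seed: int = 12345) -> list[TrialCondition]:
    """The fixed validation set shared by all models and perturbations."""
    return random_conditions(n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# simulation and training


def _batch_arrays(trials: list[RNNTrial]):
    T = max(tr.inputs.shape[0] for tr in trials)
    K = len(trials)
    U = np.zeros((T, K, 5))
    Y = np.zeros((T, K, 2))
    M = np.zeros((T, K))
    for k, tr in enumerate(trials):
        t = tr.inputs.shape[0]
        U[:t, k] = tr.inputs
        Y[:t, k] = tr.target_output
        M[:t, k] = tr.loss_mask
        if t < T:  # hold the last input during padding, mask the loss
            U[t:, k] = tr.inputs[-1]
    return U, Y, M


def simulate(model: TrainedRNN, trials: list[RNNTrial]) -> tuple[np.ndarray, np.ndarray]:
    """Run the network; returns rates (T x K x N) and outputs (T x K x 2)."""
    U, _, _ = _batch_arrays(trials)
    T, K, _ = U.shape
    p = model.params
    a = p.dt / p.tau
    x = np.zeros((K, p.n_units))
    R = np.empty((T, K, p.n_units))
    for t in range(T):
        x = x + a * (-x + rectified_tanh(x) @ model.J.T + U[t] @ model.B.T)
        R[t] = rectified_tanh(x)
    Z = R @ model.W.T
    return R, Z


def _forward_backward(J, B, W, U, Y, M, params: RNNParams):
    """Loss and gradients by backpropagation through time."""
    T, K, _ = U.shape
    N = params.n_units
    a = params.dt / params.tau
    X = np.empty((T + 1, K, N))
    X[0] = 0.0
    for t in range(T):
        r = rectified_tanh(X[t])
        X[t + 1] = X[t] + a * (-X[t] + r @ J.T + U[t] @ B.T)
    R_all = rectified_tanh(X)  # rates at every state (R_all[t+1] follows step t)
    PHI = _dphi(X)
    R = R_all[1:]
    Z = R @ W.T
    n_loss = max(M.sum(), 1.0)
    err = (Z - Y) * M[:, :, None]
    e = float((err**2).sum() / (n_loss * 2.0))
    r1 = float((R**2 * M[:, :, None]).sum() / K)
    loss = e + params.alpha * r1

    dZ = err / n_loss  # d e / d Z  (factor 2 cancels with square)
    gW = np.einsum("tko,tkn->on", dZ, R)
    # dL/dR[t] from the readout and the activity penalty, all steps at once
    dR_all = dZ @ W + (2.0 * params.alpha / K) * R * M[:, :, None]
    gJ = np.zeros_like(J)
    gB = np.zeros_like(B)
    D = np.zeros((K, N))  # dL/dX[t+1] accumulated from steps after t+1
    for t in range(T - 1, -1, -1):
        D = D + dR_all[t] * PHI[t + 1]
        gJ += D.T @ R_all[t]
        gB += D.T @ U[t]
        D = D * (1 - a) + a * (D @ J) * PHI[t]
    return loss, e, a * gJ, a * gB, gW


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def update(self, grads):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def init_weights(params: RNNParams, seed: int, sparsity: float = 0.0):
    """Initial weights: J ~ N(0, sigma^2), W zero, B small Gaussian.

    With a rectified-tanh nonlinearity, zero initial state and an
    all-zero B, network activity is identically zero and every gradient
    vanishes, so B must start nonzero for training to move at all; it
    is drawn N(0, 1/sqrt(n_inputs)).
    """
    rng = np.random.default_rng(seed)
    n = params.n_units
    sigma = params.g / n if params.scale_mode == "g_over_n" else params.g / np.sqrt(n)
    J = rng.normal(0.0, sigma, (n, n))
    if sparsity > 0:
        mask = rng.random((n, n)) < sparsity
        J = J * mask
    B = rng.normal(0.0, 1.0 / np.sqrt(5.0), (n, 5))
    W = np.zeros((2, n))
    return J, B, W


def train(
    params: RNNParams = RNNParams(),
    n_steps: int = 3000,
    batch_size: int = 32,
    seed: int = 0,
    variant: str = "main",
    clip_norm: float = 1.0,
) -> TrainedRNN:
    """Train a network on randomly drawn interception trials.

    First-order Adam optimization of the output MSE plus activity
    penalty; gradients are clipped at global norm ``clip_norm``.
    Raises on divergence (NaN loss).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    sparsity = 0.1 if variant == "sparse" else params.sparsity
    J, B, W = init_weights(params, seed, sparsity)
    rng = np.random.default_rng(seed + 1)
    opt = _Adam([J.shape, B.shape, W.shape], params.lr)
    log = np.empty(n_steps)
    for it in range(n_steps):
        conds = random_conditions(batch_size, rng)
        trials = [build_trial(c, params, variant) for c in conds]
        U, Y, M = _batch_arrays(trials)
        loss, e, gJ, gB, gW = _forward_backward(J, B, W, U, Y, M, params)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at step {it}")
        gnorm = np.sqrt(sum((g**2).sum() for g in (gJ, gB, gW)))
        if gnorm > clip_norm:
            gJ, gB, gW = (g * clip_norm / gnorm for g in (gJ, gB, gW))
        dJ, dB, dW = opt.update([gJ, gB, gW])
        J -= dJ
        B -= dB
        W -= dW
        log[it] = loss
    return TrainedRNN(J=J, B=B, W=W, params=params, variant=variant, seed=seed, loss_log=log)


def validate(
    model: TrainedRNN, conditions: list[TrialCondition] | None = None
) -> tuple[float, float]:
    """Mean and sd of the endpoint-to-target distance on a trial set.

    The endpoint is the integral of the output velocity from MO to the
    end of the movement window; the target is the interception point.
    """
    if conditions is None:
        conditions = validation_conditions()
    trials = [build_trial(c, model.params, model.variant) for c in conditions]
    _, Z = simulate(model, trials)
    dt_s = model.params.dt / 1000.0
    dists = np.empty(len(trials))
    for k, tr in enumerate(trials):
        endpoint = Z[tr.mo_step : tr.end_step, k].sum(axis=0) * dt_s
        icp_angle = target_angle_at(tr.condition, tr.condition.t_touch)
        icp = TARGET_RADIUS_AU * np.array(
            [np.cos(np.deg2rad(icp_angle)), np.sin(np.deg2rad(icp_angle))]
        )
        dists[k] = np.linalg.norm(endpoint - icp)
    return float(dists.mean()), float(dists.std())


# ---------------------------------------------------------------------------
# population-style analyses of node activity


def node_population(
    model: TrainedRNN,
    trials_per_cell: int = 5,
    seed: int = 7,
) -> PopulationActivity:
    """Simulate a balanced condition grid and package node rates as a
    population aligned to MO (window MO-500 .. MO+300 ms)."""
    rng = np.random.default_rng(seed)
    conds = grid_conditions(trials_per_cell, rng)
    trials = [build_trial(c, model.params, model.variant) for c in conds]
    R, _ = simulate(model, trials)
    dt = model.params.dt
    n_pre = int(round(-ALIGN_WINDOW_MS[0] / dt))
    n_post = int(round(ALIGN_WINDOW_MS[1] / dt))
    K = len(trials)
    N = model.params.n_units
    rates = np.empty((N, K, n_pre + n_post))
    for k, tr in enumerate(trials):
        rates[:, k, :] = R[tr.mo_step - n_pre : tr.mo_step + n_post, k, :].T
    centers = (np.arange(n_pre + n_post) - n_pre + 0.5) * dt
    table = make_trial_table(conds)
    return PopulationActivity(rates=rates, bin_width=dt, alignment="MO",
                              trial_table=table, bin_centers=centers)


def classify_nodes(
    model: TrainedRNN,
    activity: PopulationActivity | None = None,
    active_threshold: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify node modulation with the same procedure as for neurons.

    Nodes whose temporal-mean rate is below ``active_threshold`` are
    excluded from the fractions (counted as inactive).
    """
    if activity is None:
        activity = node_population(model)
    return tuning_mod.classify_population(
        activity, active_threshold=active_threshold, seed=seed
    )


def node_geometry(
    model: TrainedRNN,
    activity: PopulationActivity | None = None,
    n_pcs: int = 3,
) -> dict:
    """Neural-state geometry of node activity at MO (ellipses, tilt
    angles, tilt-vs-velocity fit)."""
    if activity is None:
        activity = node_population(model)
    ss = neural_states(activity, window_ms=(-100.0, 100.0), n_pcs=n_pcs)
    return geometry_summary(ss)


# ---------------------------------------------------------------------------
# perturbations and connectivity


def ablate(model: TrainedRNN, nodes: np.ndarray) -> TrainedRNN:
    """Zero all connections touching ``nodes``; returns a new model."""
    nodes = np.asarray(nodes, int)
    if nodes.size == 0:
        raise ValueError("node subset is empty")
    out = model.copy()
    out.J[nodes, :] = 0.0
    out.J[:, nodes] = 0.0
    out.B[nodes, :] = 0.0
    out.W[:, nodes] = 0.0
    return out


def scale_connection(
    model: TrainedRNN, from_nodes: np.ndarray, to_nodes: np.ndarray, factor: float = 1.5
) -> TrainedRNN:
    """Multiply recurrent weights from one node class to another."""
    out = model.copy()
    out.J[np.ix_(np.asarray(to_nodes, int), np.asarray(from_nodes, int))] *= factor
    return out


def connectivity_summary(model: TrainedRNN, flags: pd.DataFrame) -> dict:
    """Mean |J| between modulation classes and a Kruskal–Wallis omnibus.

    ``flags`` is the classify_nodes table; classes are the gain /
    pd_shift / addition flag sets (mixtures contribute to each flag
    they carry).  Self-connections are excluded.
    """
    classes = {"S": "pd_shift", "G": "gain", "A": "addition"}
    members = {k: np.flatnonzero(flags[col] & flags["active"]) for k, col in classes.items()}
    absJ = np.abs(model.J)
    mat = pd.DataFrame(index=list(classes), columns=list(classes), dtype=float)
    groups = []
    for to_k, to_ix in members.items():
        for fr_k, fr_ix in members.items():
            if to_ix.size == 0 or fr_ix.size == 0:
                mat.loc[to_k, fr_k] = np.nan
                continue
            block = absJ[np.ix_(to_ix, fr_ix)]
            if to_k == fr_k:
                vals = block[~np.eye(to_ix.size, dtype=bool)]
            else:
                vals = block.ravel()
            mat.loc[to_k, fr_k] = vals.mean()
            groups.append(vals)
    if len(groups) >= 2 and np.ptp(np.concatenate(groups)) > 0:
        kw = stats.kruskal(*groups)
        kw_p = float(kw.pvalue)
    else:
        kw_p = 1.0
    return {"mean_abs_weight": mat, "kruskal_p": kw_p, "members": members}


# ---------------------------------------------------------------------------
# latent comparison


def model_latents(
    model: TrainedRNN,
    trials_per_cell: int = 3,
    n_bins: int = 40,
    seed: int = 11,
) -> np.ndarray:
    """Condition-averaged node activity between MO-200 and MO+120 ms,
    averaged into ``n_bins`` bins; rows are (condition x bin)."""
    activity = node_population(model, trials_per_cell=trials_per_cell, seed=seed)
    centers = activity.bin_centers
    mask = (centers >= -200.0) & (centers <= 120.0)
    sub = activity.rates[:, :, mask]  # N x K x t
    edges = np.linspace(0, sub.shape[2], n_bins + 1).astype(int)
    binned = np.stack(
        [sub[:, :, a:b].mean(axis=2) for a, b in zip(edges[:-1], edges[1:])], axis=2
    )  # N x K x n_bins
    tt = activity.trial_table
    rows = []
    for v in sorted(tt["target_velocity"].unique()):
        for s in range(1, 9):
            sel = ((tt["target_velocity"] == v) & (tt["sector"] == s)).to_numpy()
            rows.append(binned[:, sel, :].mean(axis=1).T)  # n_bins x N
    return np.vstack(rows)


def compare_latent(
    data_matrix: np.ndarray, model_matrix: np.ndarray, n_pcs: int = 30, n_cc: int = 10
) -> dict:
    """CCA correlations and Procrustes disparity between two latent sets.

    Both matrices are (bins x features); each is reduced to its first
    ``n_pcs`` PCs, the first ``n_cc`` canonical pairs are correlated,
    and the Procrustes disparity is computed between the PC score sets.
    """
    A = np.asarray(data_matrix, float)
    Bm = np.asarray(model_matrix, float)
    if A.shape[0] != Bm.shape[0]:
        raise ValueError("bin counts differ")
    n_pcs = min(n_pcs, A.shape[0] - 1, A.shape[1], Bm.shape[1])
    Sa = PCA(n_components=n_pcs).fit_transform(A)
    Sb = PCA(n_components=n_pcs).fit_transform(Bm)
    n_cc = min(n_cc, n_pcs)
    cca = CCA(n_components=n_cc, max_iter=2000)
    Ua, Ub = cca.fit_transform(Sa, Sb)
    rs = np.array([pearsonr(Ua[:, i], Ub[:, i])[0] for i in range(n_cc)])
    _, _, disparity = _procrustes(Sa, Sb)
    return {"canonical_r": rs, "procrustes_disparity": float(disparity)}


def build_variant(
    kind: str,
    params: RNNParams = RNNParams(),
    seed: int = 0,
    n_steps: int = 3000,
    batch_size: int = 32,
) -> TrainedRNN:
    """Train an alternative model: GM (no target input), GT (no
    intention input), or sparse (10% nonzero initial J)."""
    if kind not in ("GM", "GT", "sparse"):
        raise ValueError(f"unknown variant kind {kind!r}")
    return train(params, n_steps=n_steps, batch_size=batch_size, seed=seed, variant=kind)
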