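"""Population neural-state geometry.

Single-trial activity averaged in a 100 ms window is z-scored per
neuron and projected onto principal components.  Within each
target-motion condition the three-dimensional neural states form a
ring; each ring is fitted as a planar ellipse (total-least-squares
plane, then a direct ellipse-specific conic fit in the plane) and the
rings of moving-target conditions are compared with the static-target
ring by three metrics:

* tilting angle — signed angle between plane normals (CCW positive),
* rotation angle — circular mean PC1–PC2 angular offset of matched
  reach-sector centroids,
* state shift — RMS distance between arc-length-matched points on the
  two ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.decomposition import PCA

from .circular import circ_dist_deg, circ_mean_deg
from .synth import PopulationActivity
from .task import N_SECTORS


def soft_normalize(rates: np.ndarray, constant: float = 5.0, axis=None) -> np.ndarray:
    """Soft-normalize firing rates: FR / (range(FR) + constant).

    The range is taken per neuron (axis 0 of a neurons x ... array by
    default via ``axis`` over the remaining dimensions).
    """
    rates = np.asarray(rates, float)
    if axis is None:
        axis = tuple(range(1, rates.ndim))
    rng_ = rates.max(axis=axis, keepdims=True) - rates.min(axis=axis, keepdims=True)
    return rates / (rng_ + constant)


@dataclass
class NeuralStateSet:
    """Single-trial PC coordinates with condition labels."""

    states: np.ndarray  # trials x P
    explained_variance: np.ndarray  # per PC, percent
    labels: pd.DataFrame
    window_ms: tuple[float, float]
    dropped_neurons: list[int] = field(default_factory=list)


def neural_states(
    activity: PopulationActivity,
    window_ms: tuple[float, float] = (-100.0, 100.0),
    n_pcs: int = 3,
    bin_window: tuple[int, int] | None = None,
) -> NeuralStateSet:
    """Window-average, z-score per neuron, and project onto PCs.

    ``bin_window`` (1-based inclusive bin indices) overrides the ms
    window; zero-variance neurons are dropped and reported.
    """
    if bin_window is not None:
        X = activity.bin_index_mean(*bin_window)
    else:
        X = activity.window_mean(*window_ms)  # trials x neurons
    sd = X.std(axis=0)
    dropped = list(np.flatnonzero(sd == 0))
    keep = sd > 0
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_pcs = min(n_pcs, Xz.shape[1], Xz.shape[0])
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(Xz)
    return NeuralStateSet(
        states=scores,
        explained_variance=pca.explained_variance_ratio_ * 100.0,
        labels=activity.trial_table.reset_index(drop=True),
        window_ms=window_ms,
        dropped_neurons=dropped,
    )


# ---------------------------------------------------------------------------
# 3D ellipse fitting


@dataclass
class EllipseFit3D:
    center: np.ndarray  # 3
    normal: np.ndarray  # unit 3-vector
    u: np.ndarray  # in-plane basis vector along major axis
    v: np.ndarray  # in-plane basis vector along minor axis
    semi_major: float
    semi_minor: float
    r2_fit: float

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Points on the ellipse at parametric angles ``t`` (radians)."""
        t = np.atleast_1d(t)
        return (
            self.center[None, :]
            + self.semi_major * np.cos(t)[:, None] * self.u[None, :]
            + self.semi_minor * np.sin(t)[:, None] * self.v[None, :]
        )

    def sample_arclength(self, k: int, phase_dir: np.ndarray | None = None) -> np.ndarray:
        """``k`` points at uniform arc length, starting where the ellipse
        crosses the half-plane through ``phase_dir`` (default: major axis),
        proceeding in the +normal (CCW) sense."""
        t_dense = np.linspace(0.0, 2 * np.pi, 2048, endpoint=False)
        pts = self.sample(t_dense)
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
        total = arc[-1] + seg[-1]
        if phase_dir is not None:
            d = np.asarray(phase_dir, float) - np.dot(phase_dir, self.normal) * self.normal
            if np.linalg.norm(d) > 1e-12:
                ang = np.arctan2(
                    np.dot(d, self.v) / self.semi_minor, np.dot(d, self.u) / self.semi_major
                )
                i0 = int(np.argmin(np.abs(np.angle(np.exp(1j * (t_dense - ang))))))
            else:
                i0 = 0
        else:
            i0 = 0
        start = arc[i0]
        targets = np.mod(start + total * np.arange(k) / k, total)
        idx = np.searchsorted(arc, targets, side="right") - 1
        return pts[idx]


def _fit_ellipse_2d(x: np.ndarray, y: np.ndarray):
    """Direct ellipse-specific least-squares conic fit (Halir–Flusser).

    Returns center (2,), semi-axes (major, minor), and the major-axis
    angle in radians.  Raises if the conic is not an ellipse.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    D1 = np.column_stack([x**2, x * y, y**2])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate point set for ellipse fit") from err
    M = S1 + S2 @ T
    C = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    M = np.linalg.solve(C, M)
    eigval, eigvec = np.linalg.eig(M)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.flatnonzero((cond > 0) & np.isreal(eigval))
    if ok.size == 0:
        raise ValueError("no ellipse solution (points may be hyperbolic/collinear)")
    a1 = np.real(eigvec[:, ok[0]])
    coeffs = np.concatenate([a1, (T @ a1)])  # A,B,C,D,E,F for Ax²+Bxy+Cy²+Dx+Ey+F
    A, B, Cc, D, E, F = coeffs
    # conic -> geometric parameters via the quadratic-form eigenbasis
    Q = np.array([[A, B / 2.0], [B / 2.0, Cc]])
    L = np.array([D, E])
    try:
        xc = -0.5 * np.linalg.solve(Q, L)
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate ellipse") from err
    k = -(xc @ Q @ xc + L @ xc + F)  # y'Qy = k on the ellipse
    lam, V = np.linalg.eigh(Q)
    if not (np.all(lam * np.sign(k) > 0) and k != 0):
        raise ValueError("degenerate ellipse")
    axes = np.sqrt(k / lam)  # semi-axis along each eigenvector
    order = np.argsort(-axes)
    a_len, b_len = float(axes[order[0]]), float(axes[order[1]])
    major = V[:, order[0]]
    phi = float(np.arctan2(major[1], major[0]))
    return xc, (a_len, b_len), phi


def fit_ellipse_condition(points: np.ndarray) -> EllipseFit3D:
    """Fit a 3D ellipse to one condition's neural states (trials x 3).

    Plane by total least squares (smallest-variance PCA direction),
    then a direct ellipse-constrained conic fit in the plane.  The fit
    quality is r2 = 1 - sum(d_i^2)/sum(|p_i - centroid|^2) with d_i the
    3D distance from each point to the nearest point on the ellipse.
    """
    P = np.asarray(points, float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("points must be trials x 3")
    if P.shape[0] < 8:
        raise ValueError("need at least 8 points")
    centroid = P.mean(axis=0)
    Q = P - centroid
    _, sv, Vt = np.linalg.svd(Q, full_matrices=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-30):
        raise ValueError("points are collinear")
    e1, e2, n = Vt[0], Vt[1], Vt[2]
    xy = Q @ np.column_stack([e1, e2])
    c2d, (a_len, b_len), phi = _fit_ellipse_2d(xy[:, 0], xy[:, 1])
    u2 = np.array([np.cos(phi), np.sin(phi)])
    v2 = np.array([-np.sin(phi), np.cos(phi)])
    center = centroid + c2d[0] * e1 + c2d[1] * e2
    u3 = u2[0] * e1 + u2[1] * e2
    v3 = v2[0] * e1 + v2[1] * e2
    normal = np.cross(u3, v3)
    normal /= np.linalg.norm(normal)
    fit = EllipseFit3D(center=center, normal=normal, u=u3, v=v3,
                       semi_major=a_len, semi_minor=b_len, r2_fit=np.nan)
    d = _distance_to_ellipse(P, fit)
    ss_tot = np.sum(np.linalg.norm(P - centroid, axis=1) ** 2)
    fit.r2_fit = float(1.0 - np.sum(d**2) / ss_tot) if ss_tot > 0 else np.nan
    return fit


def _distance_to_ellipse(points: np.ndarray, e: EllipseFit3D, n_dense: int = 1024) -> np.ndarray:
    """3D distance from each point to the nearest point on the ellipse
    (dense parametric sampling)."""
    samples = e.sample(np.linspace(0, 2 * np.pi, n_dense, endpoint=False))
    d2 = ((points[:, None, :] - samples[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))


# ---------------------------------------------------------------------------
# ellipse comparison metrics


def tilting_angle(e: EllipseFit3D, ref: EllipseFit3D, sign_axis: np.ndarray | None = None) -> float:
    """Signed angle between ellipse-plane normals, degrees in (-90, 90].

    The unsigned angle between normals is folded into [0, 90]; the sign
    is the side of ``sign_axis`` (a direction in the reference plane) on
    which the tilted normal leans.  Without a sign axis the magnitude is
    returned.
    """
    n1 = e.normal / np.linalg.norm(e.normal)
    n0 = ref.normal / np.linalg.norm(ref.normal)
    if np.dot(n1, n0) < 0:
        n1 = -n1
    cosang = np.clip(np.dot(n1, n0), -1.0, 1.0)
    ang = np.rad2deg(np.arccos(cosang))
    if ang > 90.0:
        ang = 180.0 - ang
    if sign_axis is None:
        return float(ang)
    lean = n1 - np.dot(n1, n0) * n0
    s = np.sign(np.dot(lean, sign_axis)) or 1.0
    return float(s * ang)


def rotation_angle(states: np.ndarray, sectors: np.ndarray,
                   ref_states: np.ndarray, ref_sectors: np.ndarray) -> float:
    """Circular-mean PC1–PC2 angular offset of matched sector centroids.

    Sectors missing from either condition are skipped.
    """
    diffs = []
    c = states[:, :2].mean(axis=0)
    c0 = ref_states[:, :2].mean(axis=0)
    for k in range(1, N_SECTORS + 1):
        a = states[sectors == k, :2]
        b = ref_states[ref_sectors == k, :2]
        if a.shape[0] == 0 or b.shape[0] == 0:
            continue
        va = a.mean(axis=0) - c
        vb = b.mean(axis=0) - c0
        diffs.append(np.rad2deg(np.arctan2(va[1], va[0]) - np.arctan2(vb[1], vb[0])))
    if not diffs:
        raise ValueError("no common sectors")
    m = circ_mean_deg(np.asarray(diffs))
    return float(circ_dist_deg(m, 0.0))


def state_shift(e: EllipseFit3D, ref: EllipseFit3D, k: int = 64,
                phase_dir: np.ndarray | None = None) -> float:
    """RMS 3D distance between arc-length-matched points on two ellipses."""
    if phase_dir is None:
        phase_dir = ref.u
    p1 = e.sample_arclength(k, phase_dir)
    p0 = ref.sample_arclength(k, phase_dir)
    return float(np.sqrt(np.mean(np.sum((p1 - p0) ** 2, axis=1))))


def fit_tilt_vs_velocity(angles: np.ndarray, velocities: np.ndarray):
    """OLS fit tilt = slope * velocity + intercept; returns (slope,
    intercept, r2)."""
    angles = np.asarray(angles, float)
    velocities = np.asarray(velocities, float)
    if angles.size < 3:
        raise ValueError("need at least 3 conditions")
    A = np.column_stack([velocities, np.ones_like(velocities)])
    coef, *_ = np.linalg.lstsq(A, angles, rcond=None)
    pred = A @ coef
    ss_res = np.sum((angles - pred) ** 2)
    ss_tot = np.sum((angles - angles.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(coef[0]), float(coef[1]), float(r2)


def align_static_plane(states: np.ndarray, static_fit: EllipseFit3D) -> np.ndarray:
    """Rigidly rotate all states so the static ellipse normal is +z.

    A proper rotation about the state-cloud origin; pairwise distances
    and all tilt/rotation/shift metrics are preserved.
    """
    n = static_fit.normal / np.linalg.norm(static_fit.normal)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = np.dot(n, z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return states @ R.T


# ---------------------------------------------------------------------------
# per-session summary


def geometry_summary(
    state_set: NeuralStateSet,
    static_velocity: float = 0.0,
    velocity_column: str = "target_velocity",
) -> dict:
    """Ellipse fits and tilt/rotation/shift per condition plus the
    tilt-vs-velocity regression.

    The tilt sign axis is the velocity-sign-weighted mean in-plane lean
    of the moving-condition normals, so CCW target motion reads
    positive by construction and CW negative.
    """
    labels = state_set.labels
    vels = np.sort(labels[velocity_column].unique())
    if static_velocity not in vels:
        raise ValueError("static condition missing")
    S = state_set.states[:, :3]
    fits: dict[float, EllipseFit3D] = {}
    for v in vels:
        fits[v] = fit_ellipse_condition(S[labels[velocity_column] == v])
    ref = fits[static_velocity]
    n0 = ref.normal
    # sign axis: velocity-sign-weighted lean of moving normals in the ref plane
    lean_sum = np.zeros(3)
    for v in vels:
        if v == static_velocity:
            continue
        n1 = fits[v].normal.copy()
        if np.dot(n1, n0) < 0:
            n1 = -n1
        lean_sum += np.sign(v - static_velocity) * (n1 - np.dot(n1, n0) * n0)
    sign_axis = lean_sum if np.linalg.norm(lean_sum) > 1e-12 else ref.u

    sec = labels["sector"].to_numpy()
    ref_mask = (labels[velocity_column] == static_velocity).to_numpy()
    rows = []
    for v in vels:
        mask = (labels[velocity_column] == v).to_numpy()
        rows.append(
            dict(
                velocity=float(v),
                tilt_deg=tilting_angle(fits[v], ref, sign_axis),
                rotation_deg=rotation_angle(S[mask], sec[mask], S[ref_mask], sec[ref_mask]),
                state_shift=state_shift(fits[v], ref),
                r2_fit=fits[v].r2_fit,
            )
        )
    table = pd.DataFrame(rows)
    slope, intercept, r2 = fit_tilt_vs_velocity(
        table["tilt_deg"].to_numpy(), table["velocity"].to_numpy()
    )
    return {
        "per_condition": table,
        "fits": fits,
        "tilt_slope": slope,
        "tilt_intercept": intercept,
        "tilt_r2": r2,
        "sign_axis": sign_axis,
        "explained_variance": state_set.explained_variance,
    }


def fit_pc_tuning(
    pc_scores: np.ndarray,
    theta: np.ndarray,
    vel: np.ndarray,
    vel_scale: float = 120.0,
) -> pd.DataFrame:
    """R² of each PC against a direction model and a velocity model.

    Direction: PC = a1*cos(theta) + a2*sin(theta) + c (linear LS).
    Velocity:  PC = a1 / (1 + exp(-a2*vel)) + c (nonlinear LS).
    """
    scores = np.atleast_2d(np.asarray(pc_scores, float))
    if scores.shape[0] == len(np.asarray(theta)):
        scores = scores.T  # -> PCs x trials
    th = np.deg2rad(np.asarray(theta, float))
    v = np.asarray(vel, float) / vel_scale
    if scores.shape[1] < 10:
        raise ValueError("need at least 10 trials")
    rows = []
    A = np.column_stack([np.cos(th), np.sin(th), np.ones_like(th)])
    for i, y in enumerate(scores):
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2_dir = 1.0 - np.sum((y - A @ coef) ** 2) / ss_tot if ss_tot > 0 else np.nan

        def sig_model(p):
            return p[0] / (1.0 + np.exp(-p[1] * v)) + p[2] - y

        best = np.inf
        for a20 in (1.0, -1.0, 4.0):
            try:
                sol = optimize.least_squares(sig_model, [np.ptp(y), a20, y.mean()], method="lm")
                best = min(best, 2 * sol.cost)
            except Exception:
                continue
        r2_vel = 1.0 - best / ss_tot if ss_tot > 0 and np.isfinite(best) else np.nan
        rows.append(dict(pc=i + 1, r2_direction=float(r2_dir), r2_velocity=float(r2_vel),
                         a1=float(coef[0]), a2=float(coef[1]), c=float(coef[2])))
    return pd.DataFrame(rows)
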