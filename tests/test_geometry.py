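import copy

import numpy as np
import pytest

from neurorbit import geometry as G
from neurorbit import synth
from neurorbit.geometry import neural_states


def rotation_matrix(ax, ay, az):
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def tilted_ellipse_points(a=3.0, b=1.5, n=60, angles=(0.3, 0.2, 0.9), center=(1, 2, 3), seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t), np.zeros(n)])
    R = rotation_matrix(*angles)
    return pts @ R.T + np.asarray(center, float), R


class TestSoftNormalize:
    def test_zero_range(self):
        out = G.soft_normalize(np.full((1, 10), 10.0))
        assert np.allclose(out, 2.0)

    def test_range_plus_five(self):
        x = np.linspace(0, 15, 16)[None, :]
        assert np.allclose(G.soft_normalize(x), x / 20.0)

    def test_output_bounded_below_one(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 200, (5, 100))
        out = G.soft_normalize(x)
        assert out.max() < 1.0


class TestNeuralStates:
    def test_rank_two_data(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 30))
        coef = rng.normal(size=(100, 2))
        pop = synth.build_model_population({"gain": 1}, seed=0)  # labels only
        X = coef @ basis
        X = X - X.min() + 1.0  # shift positive; constant offset is centered away
        act = synth.PopulationActivity(
            rates=X.T[:, :, None], bin_width=1.0, alignment="MO",
            trial_table=pop.trial_table.iloc[:100].reset_index(drop=True),
        )
        ss = neural_states(act, bin_window=(1, 1), n_pcs=5)
        assert ss.explained_variance[:2].sum() > 99.9

    def test_scores_uncorrelated(self):
        pop = synth.build_model_population({"gain": 50}, seed=2)
        ss = neural_states(pop, bin_window=synth.MO_WINDOW, n_pcs=3)
        cov = np.cov(ss.states.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.diag(cov).max()


class TestEllipseFit:
    def test_exact_planar_ellipse(self):
        pts, R = tilted_ellipse_points()
        fit = G.fit_ellipse_condition(pts)
        assert fit.r2_fit > 0.9999
        assert fit.semi_major == pytest.approx(3.0, rel=1e-6)
        assert fit.semi_minor == pytest.approx(1.5, rel=1e-6)
        assert abs(np.dot(fit.normal, R[:, 2])) == pytest.approx(1.0, abs=1e-9)

    def test_circle(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([2 * np.cos(t), 2 * np.sin(t), np.zeros(40)])
        fit = G.fit_ellipse_condition(pts)
        assert fit.semi_major == pytest.approx(2.0, rel=1e-9)
        assert fit.semi_minor == pytest.approx(2.0, rel=1e-9)
        assert abs(fit.normal[2]) == pytest.approx(1.0)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.zeros(20), np.zeros(20)])
        with pytest.raises(ValueError):
            G.fit_ellipse_condition(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            G.fit_ellipse_condition(np.zeros((5, 3)))


class TestEllipseMetrics:
    def test_tilt_identity_and_fold(self):
        pts, _ = tilted_ellipse_points()
        e = G.fit_ellipse_condition(pts)
        assert G.tilting_angle(e, e) == 0.0
        flipped = copy.deepcopy(e)
        flipped.normal = -e.normal
        assert G.tilting_angle(flipped, e) == pytest.approx(0.0, abs=1e-9)

    def test_tilt_thirty_degrees(self):
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        flat = np.column_stack([3 * np.cos(t), 1.5 * np.sin(t), np.zeros(50)])
        R = rotation_matrix(np.deg2rad(30.0), 0, 0)
        e = G.fit_ellipse_condition(flat @ R.T)
        ref = G.fit_ellipse_condition(flat)
        assert G.tilting_angle(e, ref) == pytest.approx(30.0, abs=1e-6)

    def test_rotation_angle_constructed(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 360, 160)
        sectors = (theta // 45).astype(int) + 1
        base = np.column_stack(
            [np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta)), np.zeros(160)]
        )
        ang = np.deg2rad(20.0)
        Rz = rotation_matrix(0, 0, ang)
        rotated = base @ Rz.T
        out = G.rotation_angle(rotated, sectors, base, sectors)
        assert out == pytest.approx(20.0, abs=1e-6)

    def test_state_shift_translation_along_normal(self):
        pts, _ = tilted_ellipse_points()
        e = G.fit_ellipse_condition(pts)
        moved = copy.deepcopy(e)
        moved.center = e.center + 0.8 * e.normal
        assert G.state_shift(moved, e) == pytest.approx(0.8, abs=1e-3)
        assert G.state_shift(e, e) == pytest.approx(0.0, abs=1e-9)


class TestTiltRegression:
    def test_exact_line(self):
        vels = np.array([-240.0, -120.0, 0.0, 120.0, 240.0])
        slope, intercept, r2 = G.fit_tilt_vs_velocity(0.2 * vels, vels)
        assert slope == pytest.approx(0.2)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_flat_tilt_flagged(self):
        vels = np.array([-120.0, 0.0, 120.0])
        slope, _, r2 = G.fit_tilt_vs_velocity(np.zeros(3), vels)
        assert slope == 0.0
        assert np.isnan(r2)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            G.fit_tilt_vs_velocity(np.zeros(2), np.zeros(2))


class TestAlignStaticPlane:
    def test_invariances(self):
        pop = synth.build_model_population({"gain": 60}, seed=5)
        ss = neural_states(pop, bin_window=synth.MO_WINDOW, n_pcs=3)
        gs = G.geometry_summary(ss, velocity_column="vel_code", static_velocity=3.0)
        static = gs["fits"][3.0]
        aligned = G.align_static_plane(ss.states[:, :3], static)
        # pairwise distances preserved
        rng = np.random.default_rng(0)
        i, j = rng.integers(0, len(aligned), 2 * 20).reshape(2, 20)
        d0 = np.linalg.norm(ss.states[i, :3] - ss.states[j, :3], axis=1)
        d1 = np.linalg.norm(aligned[i] - aligned[j], axis=1)
        assert np.allclose(d0, d1)
        # static normal maps to +-z
        sel = (ss.labels["vel_code"] == 3.0).to_numpy()
        new_static = G.fit_ellipse_condition(aligned[sel])
        assert abs(new_static.normal[2]) == pytest.approx(1.0, abs=1e-6)
        # tilt angles unchanged
        ss2 = copy.deepcopy(ss)
        ss2.states = aligned
        gs2 = G.geometry_summary(ss2, velocity_column="vel_code", static_velocity=3.0)
        assert np.allclose(
            np.abs(gs["per_condition"]["tilt_deg"]),
            np.abs(gs2["per_condition"]["tilt_deg"]),
            atol=1e-6,
        )


class TestPCTuning:
    def test_direction_model_exact(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 360, 50)
        vel = rng.choice([-240, -120, 0, 120, 240], 50)
        pc = 2.0 * np.cos(np.deg2rad(theta)) + 1.0
        out = G.fit_pc_tuning(pc, theta, vel)
        assert out["r2_direction"].iloc[0] == pytest.approx(1.0)
        assert out["a1"].iloc[0] == pytest.approx(2.0)
        assert out["c"].iloc[0] == pytest.approx(1.0)

    def test_direction_model_blind_to_velocity_signal(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, 360, 200)
        vel = np.tile([-240, -120, 0, 120, 240], 40)
        pc = 3.0 / (1 + np.exp(-vel / 120.0)) + rng.normal(0, 0.01, 200)
        out = G.fit_pc_tuning(pc, theta, vel)
        assert out["r2_direction"].iloc[0] < 0.1
        assert out["r2_velocity"].iloc[0] > 0.95
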