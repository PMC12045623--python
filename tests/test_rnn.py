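import numpy as np
import pytest

from neurorbit import rnn
from neurorbit.task import TARGET_RADIUS_AU, target_angle_at

TINY = rnn.RNNParams(n_units=24, dt=10.0)


@pytest.fixture(scope="module")
def tiny_model():
    """A small quickly trained network for contract tests."""
    return rnn.train(TINY, n_steps=250, batch_size=16, seed=0)


class TestDynamics:
    def test_zero_fixed_point(self):
        x = np.zeros((1, 4))
        J = np.zeros((4, 4))
        B = np.zeros((4, 5))
        p = rnn.RNNParams(n_units=4)
        out = rnn.step(x, np.zeros((1, 5)), J, B, p)
        assert np.allclose(out, 0.0)

    def test_low_pass_closed_form_with_no_recurrence(self):
        """With J=0 each unit is a first-order low-pass filter of B u:
        x(t) = u0 (1 - exp(-t/tau)), matched within Euler error O(dt)."""
        p = rnn.RNNParams(n_units=1, dt=5.0, tau=50.0)
        J = np.zeros((1, 1))
        B = np.array([[1.0, 0, 0, 0, 0]])
        u = np.array([[0.8, 0, 0, 0, 0]])
        x = np.zeros((1, 1))
        ts, xs = [], []
        for k in range(60):
            x = rnn.step(x, u, J, B, p)
            ts.append((k + 1) * p.dt)
            xs.append(x[0, 0])
        expected = 0.8 * (1.0 - np.exp(-np.asarray(ts) / p.tau))
        assert np.max(np.abs(np.asarray(xs) - expected)) < 0.8 * p.dt / p.tau

    def test_rectified_tanh_range(self):
        x = np.linspace(-5, 8, 400)
        r = rnn.rectified_tanh(x)
        assert r.min() == 0.0 and r.max() < 1.0
        assert rnn.rectified_tanh(np.array([-5.0, 0.0]))[0] == 0.0


class TestTrialConstruction:
    def test_static_target_intention_equals_onset_position(self):
        c = rnn.make_condition(0.0, endpoint_angle=30.0, delay_ms=500.0)
        tr = rnn.build_trial(c, TINY)
        icp = tr.inputs[tr.mo_step - 1, 0:2]
        onset = TARGET_RADIUS_AU * np.array(
            [np.cos(np.deg2rad(c.initial_target_angle)),
             np.sin(np.deg2rad(c.initial_target_angle))]
        )
        assert np.allclose(icp, onset)

    def test_output_integrates_to_interception_displacement(self):
        c = rnn.make_condition(240.0, endpoint_angle=100.0, delay_ms=640.0)
        tr = rnn.build_trial(c, TINY)
        disp = tr.target_output.sum(axis=0) * TINY.dt / 1000.0
        icp_angle = target_angle_at(c, c.t_touch)
        icp = TARGET_RADIUS_AU * np.array(
            [np.cos(np.deg2rad(icp_angle)), np.sin(np.deg2rad(icp_angle))]
        )
        assert np.allclose(disp, icp, atol=2e-4)

    def test_fast_target_leads_mo_position(self):
        """At 240 deg/s the interception point leads the MO target
        position by the rotation over the 300 ms movement."""
        c = rnn.make_condition(240.0, endpoint_angle=0.0, delay_ms=500.0)
        lead = target_angle_at(c, c.t_touch) - target_angle_at(c, c.t_move_onset)
        assert np.mod(lead, 360.0) == pytest.approx(240.0 * 0.3, abs=1e-9)

    def test_intention_window_is_50ms_before_mo(self):
        c = rnn.make_condition(120.0, 45.0, 600.0)
        tr = rnn.build_trial(c, TINY)
        active = np.abs(tr.inputs[:, 0:2]).sum(axis=1) > 0
        assert active.sum() == int(rnn.INTENTION_LEAD_MS / TINY.dt)
        assert active[tr.mo_step - 1] and not active[tr.mo_step]

    def test_go_channel_step(self):
        c = rnn.make_condition(0.0, 10.0, 480.0)
        tr = rnn.build_trial(c, TINY)
        go = tr.inputs[:, 4]
        assert set(np.unique(go)) == {0.0, 1.0}
        assert np.all(np.diff(go) >= 0)


class TestTrainingContracts:
    def test_untrained_readout_outputs_zero(self):
        J, B, W = rnn.init_weights(TINY, seed=0)
        model = rnn.TrainedRNN(J=J, B=B, W=W, params=TINY)
        trials = [rnn.build_trial(c, TINY) for c in rnn.random_conditions(3, np.random.default_rng(0))]
        _, Z = rnn.simulate(model, trials)
        assert np.allclose(Z, 0.0)
        mean, _ = rnn.validate(model, rnn.validation_conditions(20))
        assert mean == pytest.approx(TARGET_RADIUS_AU, abs=1e-6)

    def test_loss_decreases(self, tiny_model):
        log = tiny_model.loss_log
        assert np.mean(log[-25:]) < 0.6 * np.mean(log[:25])

    def test_penalty_term_is_alpha_times_squared_rates(self):
        p = rnn.RNNParams(n_units=5, alpha=1e-3)
        rng = np.random.default_rng(0)
        J = rng.normal(0, 0.2, (5, 5))
        B = rng.normal(0, 0.2, (5, 5))
        W = rng.normal(0, 0.2, (2, 5))
        T, K = 7, 2
        U = rng.normal(0, 1, (T, K, 5))
        Y = np.zeros((T, K, 2))
        M = np.ones((T, K))
        loss, e, *_ = rnn._forward_backward(J, B, W, U, Y, M, p)
        # recompute rates independently through the public step function
        x = np.zeros((K, 5))
        r1 = 0.0
        for t in range(T):
            x = rnn.step(x, U[t], J, B, p)
            r1 += (rnn.rectified_tanh(x) ** 2).sum()
        assert loss - e == pytest.approx(p.alpha * r1 / K, rel=1e-10)

    def test_determinism_given_seed(self):
        a = rnn.train(TINY, n_steps=20, batch_size=4, seed=3)
        b = rnn.train(TINY, n_steps=20, batch_size=4, seed=3)
        assert np.array_equal(a.J, b.J) and np.array_equal(a.W, b.W)

    def test_tiny_model_learns_task(self, tiny_model):
        mean, _ = rnn.validate(tiny_model, rnn.validation_conditions(50))
        assert mean < TARGET_RADIUS_AU / 2


class TestPerturbations:
    def test_ablate_all_silences_output(self, tiny_model):
        pert = rnn.ablate(tiny_model, np.arange(TINY.n_units))
        trials = [rnn.build_trial(c, TINY) for c in rnn.random_conditions(2, np.random.default_rng(1))]
        _, Z = rnn.simulate(pert, trials)
        assert np.allclose(Z, 0.0)

    def test_ablate_empty_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            rnn.ablate(tiny_model, np.array([], dtype=int))

    def test_ablation_leaves_original_untouched(self, tiny_model):
        J0 = tiny_model.J.copy()
        rnn.ablate(tiny_model, np.array([0, 1]))
        assert np.array_equal(tiny_model.J, J0)

    def test_scale_connection_identity_and_roundtrip(self, tiny_model):
        sub = np.array([0, 2, 4])
        same = rnn.scale_connection(tiny_model, sub, sub, factor=1.0)
        assert np.allclose(same.J, tiny_model.J)
        up = rnn.scale_connection(tiny_model, sub, sub, factor=1.5)
        back = rnn.scale_connection(up, sub, sub, factor=1 / 1.5)
        assert np.allclose(back.J, tiny_model.J)


class TestLatentComparison:
    def test_identical_matrices(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(40, 25))
        out = rnn.compare_latent(A, A.copy(), n_pcs=10, n_cc=5)
        assert np.all(out["canonical_r"] > 0.999)
        assert out["procrustes_disparity"] < 1e-12

    def test_disparity_rotation_invariant(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(40, 10))
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        a = rnn.compare_latent(A, A @ Q, n_pcs=8, n_cc=4)
        assert a["procrustes_disparity"] < 1e-10

    def test_independent_noise_low_correlation(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(60, 30))
        B = rng.normal(size=(60, 30))
        out = rnn.compare_latent(A, B, n_pcs=5, n_cc=3)
        perm_r = []
        for _ in range(20):
            out_p = rnn.compare_latent(A, B[rng.permutation(60)], n_pcs=5, n_cc=3)
            perm_r.append(out_p["canonical_r"][0])
        # observed leading correlation sits inside the permutation null
        assert out["canonical_r"][0] < np.max(perm_r) + 0.05

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rnn.compare_latent(np.zeros((10, 4)), np.zeros((12, 4)))


def test_variant_channel_masks():
    c = rnn.make_condition(120.0, 45.0, 600.0)
    gm = rnn.build_trial(c, TINY, variant="GM")
    gt = rnn.build_trial(c, TINY, variant="GT")
    assert np.allclose(gm.inputs[:, 2:4], 0.0) and np.abs(gm.inputs[:, 0:2]).sum() > 0
    assert np.allclose(gt.inputs[:, 0:2], 0.0) and np.abs(gt.inputs[:, 2:4]).sum() > 0


def test_sparse_variant_initialization():
    J, _, _ = rnn.init_weights(TINY, seed=0, sparsity=0.1)
    frac = np.mean(J != 0)
    assert 0.05 < frac < 0.15


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    path = tmp_path / "model.h5"
    tiny_model.to_hdf5(path)
    back = rnn.TrainedRNN.from_hdf5(path)
    assert np.array_equal(back.J, tiny_model.J)
    assert np.array_equal(back.W, tiny_model.W)
    assert back.params == tiny_model.params
    assert back.variant == tiny_model.variant and back.seed == tiny_model.seed


def test_connectivity_summary_uniform_weights(tiny_model):
    import pandas as pd

    model = tiny_model.copy()
    model.J = np.ones_like(model.J) * 0.3
    n = model.params.n_units
    flags = pd.DataFrame(
        dict(
            neuron=np.arange(n), active=True,
            gain=np.arange(n) % 3 == 0,
            pd_shift=np.arange(n) % 3 == 1,
            addition=np.arange(n) % 3 == 2,
        )
    )
    out = rnn.connectivity_summary(model, flags)
    mat = out["mean_abs_weight"].to_numpy(dtype=float)
    assert np.allclose(mat, 0.3)
    assert mat.min() >= 0.0
    assert out["kruskal_p"] > 0.99
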