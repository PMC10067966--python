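import numpy as np
import pytest

from latentnav.decoding import (
    DEFAULT_ETA_GRID,
    DecoderFit,
    LinearPopulationDecoder,
    decoder_angle,
    error_analysis,
    per_trial_decoding_error,
    select_timescale,
    smooth_rates,
    surrogate_angle_null,
)
from latentnav.neural import SessionData
from latentnav.task import Trial


def _fake_session(counts, signals, dt=0.006, trial_len=100, targets=None,
                  responses=None):
    """Session scaffold from a counts matrix split into equal trials."""
    N, T = counts.shape
    n_trials = T // trial_len
    slices = [(k * trial_len, (k + 1) * trial_len) for k in range(n_trials)]
    trials = []
    for k in range(n_trials):
        tp = (2.0, 0.0) if targets is None else tuple(targets[k])
        rp = tp if responses is None else tuple(responses[k])
        trials.append(Trial(
            trial_id=k, target_polar=tp,
            linear_velocity=np.zeros(2), angular_velocity=np.zeros(2),
            position=np.zeros((2, 2)), heading=np.zeros(2),
            cmd_linear=np.zeros(2), cmd_angular=np.zeros(2),
            events={"target_on": 0.0, "stop_time": trial_len * dt,
                    "target_off": 0.3, "movement_onset": 0.1,
                    "feedback_time": trial_len * dt},
            response_polar=rp, rewarded=True))
    return SessionData(dt=dt, trials=trials, trial_slices=slices,
                       counts=counts, spike_times=[], signals=signals,
                       events={})


class TestSmoothing:
    def test_impulse_response_is_causal_exponential(self):
        counts = np.zeros(500)
        counts[100] = 1
        dt, eta = 0.006, 0.05
        r = smooth_rates(counts, dt, eta)
        assert np.all(r[:100] == 0)
        decay = r[101:140] / r[100]
        expected = np.exp(-np.arange(1, 40) * dt / eta)
        np.testing.assert_allclose(decay, expected, rtol=1e-9)

    def test_steady_train_converges_to_rate(self):
        dt = 0.005
        counts = np.full(4000, 0.1)  # 20 Hz equivalent drive
        r = smooth_rates(counts, dt, 0.1)
        assert r[-1] == pytest.approx(20.0, rel=1e-6)

    def test_halving_eta_doubles_decay(self):
        counts = np.zeros(200)
        counts[10] = 1
        r1 = smooth_rates(counts, 0.006, 0.08)
        r2 = smooth_rates(counts, 0.006, 0.04)
        assert (r2[30] / r2[10]) == pytest.approx((r1[30] / r1[10]) ** 2, rel=1e-9)

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            smooth_rates(np.zeros(10), 0.006, 0.0)


class TestOls:
    def test_identity_design(self):
        dec = LinearPopulationDecoder().fit(np.eye(2), np.array([3.0, 5.0]))
        np.testing.assert_allclose(dec.coef_, [3, 5])

    def test_single_neuron_closed_form(self):
        dec = LinearPopulationDecoder().fit(np.array([[1.0], [2.0]]),
                                            np.array([2.0, 4.0]))
        assert dec.coef_[0] == pytest.approx(2.0)

    def test_exact_identifiability(self, rng):
        R = rng.normal(size=(200, 5))
        w = rng.normal(size=5)
        dec = LinearPopulationDecoder().fit(R, R @ w)
        np.testing.assert_allclose(dec.coef_, w, atol=1e-8)

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            LinearPopulationDecoder().fit(np.zeros((10, 3)), np.zeros(10))


class TestTimescaleSelection:
    def _self_consistent_session(self, eta_gen=0.1, seed=0):
        rng = np.random.default_rng(seed)
        N, trial_len, n_trials = 12, 150, 40
        T = trial_len * n_trials
        counts = rng.poisson(0.12, size=(N, T))
        sess = _fake_session(counts, {}, trial_len=trial_len)
        R = smooth_rates(counts, sess.dt, eta_gen, sess.trial_slices).T
        w = rng.normal(size=N)
        x = R @ w + 0.3 * np.std(R @ w) * rng.standard_normal(T)
        sess.signals["synthetic_target"] = x
        return sess

    def test_recovers_generative_timescale(self):
        sess = self._self_consistent_session(eta_gen=0.1)
        fit = select_timescale(sess, "synthetic_target", seed=0)
        grid = np.asarray(DEFAULT_ETA_GRID)
        k_gen = np.argmin(np.abs(np.log(grid) - np.log(0.1)))
        k_sel = np.argmin(np.abs(grid - fit.eta))
        assert abs(k_sel - k_gen) <= 1

    def test_eta_within_grid_and_deterministic(self):
        sess = self._self_consistent_session()
        f1 = select_timescale(sess, "synthetic_target", seed=3)
        f2 = select_timescale(sess, "synthetic_target", seed=3)
        assert 0.025 <= f1.eta <= 0.250
        assert f1.eta == f2.eta
        np.testing.assert_array_equal(f1.split["test"], f2.split["test"])

    def test_split_fractions(self):
        sess = self._self_consistent_session()
        f = select_timescale(sess, "synthetic_target", seed=0)
        n = sess.n_trials
        assert len(f.split["train"]) == round(0.8 * n)
        parts = np.concatenate([f.split["train"], f.split["val"], f.split["test"]])
        assert sorted(parts) == list(range(n))


class TestErrorAnalysis:
    def _offset_session(self, seed=0, permute=False):
        """Decoded value is a constant c; behavioral error is c - x_k by
        construction, so decoding error equals behavioral error exactly."""
        rng = np.random.default_rng(seed)
        N, trial_len, n_trials = 4, 80, 100
        T = trial_len * n_trials
        counts = np.zeros((N, T), dtype=np.int64)
        c = 2.0
        x_k = rng.uniform(1.0, 3.0, n_trials)
        sig = np.repeat(x_k, trial_len)
        signals = {v: sig.copy() for v in
                   ("dist_to_target", "linear_velocity", "angle_to_target",
                    "angular_velocity")}
        beh = c - x_k
        targets = np.column_stack([np.full(n_trials, 2.0), np.zeros(n_trials)])
        resp_err = rng.permutation(beh) if permute else beh
        responses = np.column_stack([2.0 + resp_err, np.zeros(n_trials)])
        sess = _fake_session(counts, signals, trial_len=trial_len,
                             targets=targets, responses=responses)
        fits = {v: DecoderFit(variable=v, weights=np.zeros(N), eta=0.05,
                              split={}, performance=np.nan, intercept=c)
                for v in signals}
        return sess, fits

    def test_perfect_correspondence(self):
        sess, fits = self._offset_session()
        res = error_analysis(sess, fits)
        assert res.r_decode_vs_behavior == pytest.approx(1.0)
        assert res.undershoot_overshoot_auc == pytest.approx(1.0)

    def test_permuted_null(self):
        sess, fits = self._offset_session(permute=True)
        res = error_analysis(sess, fits)
        assert abs(res.r_decode_vs_behavior) < 0.25
        assert abs(res.undershoot_overshoot_auc - 0.5) < 0.15

    def test_sensory_error_propagates_to_latent(self):
        # neurons encode a NOISY velocity observation and its integral; both
        # decoders inherit the same observation noise, so their per-trial
        # errors correlate positively
        rng = np.random.default_rng(4)
        trial_len, n_trials, dt = 120, 60, 0.006
        T = trial_len * n_trials
        v = np.tile(np.linspace(1, 2, trial_len), n_trials)
        obs_noise = np.repeat(rng.normal(0, 0.25, n_trials), trial_len)
        v_obs = v + obs_noise
        d_obs = np.concatenate([
            np.cumsum(v_obs[a:a + trial_len]) * dt for a in
            range(0, T, trial_len)])
        counts = np.vstack([
            rng.poisson(np.clip(0.05 * (1 + 0.5 * v_obs), 0, 5)) for _ in range(8)
        ] + [
            rng.poisson(np.clip(0.05 * (1 + 0.5 * d_obs), 0, 5)) for _ in range(8)
        ])
        d_true = np.concatenate([
            np.cumsum(v[a:a + trial_len]) * dt for a in range(0, T, trial_len)])
        signals = {"linear_velocity": v, "dist_to_target": d_true,
                   "angle_to_target": v.copy(), "angular_velocity": d_true.copy()}
        sess = _fake_session(counts, signals, trial_len=trial_len)
        fv = select_timescale(sess, "linear_velocity", seed=1)
        fd = select_timescale(sess, "dist_to_target", seed=1)
        ev = per_trial_decoding_error(sess, fv)
        ed = per_trial_decoding_error(sess, fd)
        assert np.corrcoef(ev, ed)[0, 1] > 0.3


class TestSurrogateModes:
    def test_identical_decoders_give_unit_correlation(self, rng):
        w = rng.normal(size=10)
        act = rng.normal(size=(500, 10))
        slices = [(k * 50, (k + 1) * 50) for k in range(10)]
        null = surrogate_angle_null(w, w.copy(), act, slices, 20, rng)
        np.testing.assert_allclose(null, 1.0, atol=1e-10)

    def test_isotropic_null_mean_matches_cos_phi(self, rng):
        # Monte-Carlo oracle: for isotropic activity the expected correlation
        # between projections separated by phi is cos(phi)
        a = np.zeros(40); a[0] = 1.0
        b = np.zeros(40); b[0] = np.cos(np.pi / 3); b[1] = np.sin(np.pi / 3)
        assert decoder_angle(a, b) == pytest.approx(np.pi / 3)
        act = rng.normal(size=(4000, 40))
        slices = [(k * 2, (k + 1) * 2) for k in range(2000)]
        null = surrogate_angle_null(a, b, act, slices, 100, rng)
        assert null.mean() == pytest.approx(np.cos(np.pi / 3), abs=0.05)

    def test_zero_vector_rejected(self, rng):
        with pytest.raises(ValueError):
            surrogate_angle_null(np.zeros(5), np.ones(5), np.zeros((10, 5)),
                                 [(0, 10)], 3, rng)
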