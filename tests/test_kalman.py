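import numpy as np
import pytest

from _oracles import ols_normal_equations, textbook_filter
from emgtrace.kalman import KalmanTrace, kf_step


def _simulate_linear_gaussian(rng, n_trials=50, n_per=200, noise=0.05):
    """Ground-truth A*, H* with Gaussian noise; returns trials + truth."""
    A_true = np.array([[0.9, 0.1], [-0.05, 0.85]])
    H_true = rng.normal(scale=0.5, size=(2, 7))
    deltas, feats = [], []
    for _ in range(n_trials):
        s = rng.normal(size=2)
        S, Z = [], []
        for _ in range(n_per):
            z = rng.normal(size=7)
            s = A_true @ s + rng.normal(scale=noise, size=2)
            # make the measurement model hold: overwrite part of s from z
            s = 0.5 * s + 0.5 * (H_true @ z) + rng.normal(scale=noise, size=2)
            S.append(s.copy())
            Z.append(z)
        deltas.append(np.asarray(S))
        feats.append(np.asarray(Z))
    return deltas, feats, A_true, H_true


class TestFitting:
    def test_ols_matches_normal_equations(self, rng):
        S = rng.normal(size=(300, 2))
        Z = rng.normal(size=(300, 7))
        res = KalmanTrace([S], [Z]).fit()
        B = ols_normal_equations(Z, S)  # (7, 2)
        np.testing.assert_allclose(res.H, B.T, atol=1e-8)
        A_ref = ols_normal_equations(S[:-1], S[1:]).T
        np.testing.assert_allclose(res.A, A_ref, atol=1e-8)

    def test_parameter_recovery_on_simulated_data(self, rng):
        """A, H recovered within Frobenius distance 0.05 at n = 10^4."""
        A_true = np.array([[0.8, 0.15], [-0.1, 0.75]])
        H_true = rng.normal(scale=0.4, size=(2, 7))
        s = np.zeros(2)
        S, Z = [], []
        for _ in range(10000):
            z = rng.normal(size=7)
            s = H_true @ z + rng.normal(scale=0.01, size=2)
            S.append(s)
            Z.append(z)
        S, Z = np.asarray(S), np.asarray(Z)
        # AR structure: build states whose next value follows A_true
        S_ar = [np.zeros(2)]
        for _ in range(9999):
            S_ar.append(A_true @ S_ar[-1] + rng.normal(scale=0.01, size=2))
        S_ar = np.asarray(S_ar)
        res_h = KalmanTrace([S], [Z]).fit()
        assert np.linalg.norm(res_h.H - H_true) < 0.05
        res_a = KalmanTrace([S_ar], [rng.normal(size=(10000, 7))]).fit()
        assert np.linalg.norm(res_a.A - A_true) < 0.05

    def test_noise_free_linear_data_zero_residuals(self, rng):
        H_true = rng.normal(size=(2, 7))
        Z = rng.normal(size=(500, 7))
        S = Z @ H_true.T
        res = KalmanTrace([S], [Z]).fit()
        assert np.abs(res.R).max() < 1e-16

    def test_rank_deficiency_names_channel(self, rng):
        Z = rng.normal(size=(100, 7))
        Z[:, 4] = 2.0 * Z[:, 1]  # d5 dependent
        S = rng.normal(size=(100, 2))
        with pytest.raises(ValueError, match="rank-deficient"):
            KalmanTrace([S], [Z]).fit()


class TestFilter:
    def _fitted(self, rng):
        deltas, feats, _, _ = _simulate_linear_gaussian(rng, n_trials=10, n_per=100)
        return KalmanTrace(deltas, feats).fit()

    def test_trust_measurement_limit(self, rng):
        res = self._fitted(rng)
        res.R = np.zeros((2, 2))
        z = rng.normal(size=7)
        s, _ = res.step(np.array([5.0, -3.0]), np.eye(2), z)
        np.testing.assert_allclose(s, res.H @ z, atol=1e-8)

    def test_trust_model_limit(self, rng):
        res = self._fitted(rng)
        res.R = 1e12 * np.eye(2)
        res.Q = np.zeros((2, 2))
        s_prev = np.array([5.0, -3.0])
        s, _ = res.step(s_prev, 1e-6 * np.eye(2), rng.normal(size=7))
        np.testing.assert_allclose(s, res.A @ s_prev, atol=1e-4)

    def test_matches_textbook_filter(self, rng):
        res = self._fitted(rng)
        Z = rng.normal(size=(50, 7))
        ours = res.filter(Z)
        ref = textbook_filter(res.A, res.Q, res.H, res.R, res.s0, res.P0, Z)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_covariance_stays_symmetric_psd(self, rng):
        res = self._fitted(rng)
        s, P = res.s0.copy(), res.P0.copy()
        for z in rng.normal(size=(200, 7)):
            s, P = res.step(s, P, z)
            np.testing.assert_allclose(P, P.T, atol=1e-12)
            assert np.linalg.eigvalsh(P).min() > -1e-10

    def test_singular_innovation_suggests_ridge(self):
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            kf_step(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)),
                    np.zeros((2, 7)), np.zeros(2), np.zeros((2, 2)), np.zeros(7))

    def test_reconstruct_constant_when_silent(self, rng):
        res = self._fitted(rng)
        res.A = np.zeros((2, 2))
        res.H = np.zeros((2, 7))
        res.s0 = np.zeros(2)
        out = res.reconstruct(np.zeros((10, 7)), start_point=(3.0, 4.0))
        np.testing.assert_allclose(out, np.tile([3.0, 4.0], (11, 1)))

    def test_filter_smooths_raw_regression(self, rng):
        """Filtered deltas vary less than the raw H z predictor on noisy data."""
        deltas, feats, _, _ = _simulate_linear_gaussian(
            rng, n_trials=20, n_per=100, noise=0.5)
        res = KalmanTrace(deltas, feats).fit()
        Z = feats[0]
        raw = Z @ res.H.T
        filt = res.filter(Z)
        assert np.var(np.diff(filt, axis=0)) < np.var(np.diff(raw, axis=0))
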