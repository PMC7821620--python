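"""Preprocessing, delay embedding, ridge fitting, FDR, ROI resampling."""

import numpy as np
import pytest

from genrefmri import encoding, synth
from genrefmri.encoding import (
    RidgeEncoder, delay_embed, preprocess_bold, fit_ridge, select_lambda,
    evaluate, roi_from_resampling, fit_with_nuisance,
    predict_excluding_nuisance, EncodingModel, pearson_by_column,
)


class TestPreprocess:
    def test_constant_input_zeroed_and_flagged(self):
        R = np.full((200, 3), 5.0)
        out, flagged = preprocess_bold(R)
        assert np.all(out == 0)
        assert np.all(flagged)

    def test_slow_ramp_removed(self):
        t = np.arange(400)
        ramp = t / 400.0
        fast = np.sin(2 * np.pi * t / 7.0)
        R = (ramp + fast)[:, None]
        out, _ = preprocess_bold(R, tr=1.5, window=240.0)
        corr = np.corrcoef(out[:, 0], ramp)[0, 1]
        assert abs(corr) < 0.1

    def test_zscore_moments(self):
        rng = np.random.default_rng(0)
        R = rng.normal(2.0, 3.0, size=(300, 5))
        out, flagged = preprocess_bold(R)
        assert not flagged.any()
        assert np.abs(out.mean(axis=0)).max() < 1e-10
        assert np.abs(out.std(axis=0) - 1).max() < 1e-10

    def test_per_run_independence(self):
        rng = np.random.default_rng(1)
        R = rng.normal(size=(200, 2))
        bounds = [(0, 100), (100, 200)]
        out, _ = preprocess_bold(R, run_boundaries=bounds)
        for a, b in bounds:
            assert abs(out[a:b, 0].mean()) < 1e-10
            assert abs(out[a:b, 0].std() - 1) < 1e-10


class TestDelayEmbed:
    def test_padding_and_shape(self):
        F = np.arange(20, dtype=float).reshape(10, 2)
        d = delay_embed(F)
        assert d.values.shape == (10, 10)
        assert np.all(d.values[0] == 0)  # no lag defined at row 0

    def test_impulse_traces_through_lags(self):
        F = np.zeros((10, 1))
        F[0, 0] = 1.0
        d = delay_embed(F)
        for k in range(1, 6):
            col = d.values[:, k - 1]
            assert col[k] == 1.0
            assert col.sum() == 1.0

    def test_no_leakage_across_runs(self):
        F = np.ones((20, 1))
        d = delay_embed(F, run_boundaries=[(0, 10), (10, 20)])
        # first rows of the second run must be zero-padded, not carry run 1
        for k in range(1, 6):
            assert np.all(d.values[10 : 10 + k, k - 1] == 0)

    def test_block_matches_shifted_features(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(30, 3))
        d = delay_embed(F)
        for k in range(1, 6):
            assert np.array_equal(d.block(k)[k:], F[:-k])

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            delay_embed(np.ones((4, 1)))


class TestRidge:
    def test_matches_normal_equations_on_random_systems(self):
        """SVD ridge equals brute-force normal equations on 50 systems."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            F = rng.normal(size=(60, 8))
            R = rng.normal(size=(60, 4))
            lam = 10.0 ** rng.uniform(-2, 4)
            W = RidgeEncoder(alpha=lam).fit(F, R).W_
            W_ref = np.linalg.solve(F.T @ F + lam * np.eye(8), F.T @ R)
            assert np.abs(W - W_ref).max() < 1e-8

    def test_orthonormal_design_at_zero_lambda(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        R = rng.normal(size=(8, 2))
        W = RidgeEncoder(alpha=0.0).fit(Q, R).W_
        assert np.allclose(W, Q.T @ R, atol=1e-10)

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(40, 6))
        R = rng.normal(size=(40, 3))
        norms = [
            np.linalg.norm(RidgeEncoder(alpha=lam).fit(F, R).W_)
            for lam in (0.01, 1.0, 100.0, 1e4, 1e6)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_singular_at_zero_lambda_rejected(self):
        F = np.ones((10, 3))
        with pytest.raises(np.linalg.LinAlgError):
            RidgeEncoder(alpha=0.0).fit(F, np.ones((10, 1)))

    def test_per_voxel_alpha(self):
        rng = np.random.default_rng(3)
        F = rng.normal(size=(30, 4))
        R = rng.normal(size=(30, 2))
        W = RidgeEncoder(alpha=np.array([0.5, 50.0])).fit(F, R).W_
        for j, lam in enumerate([0.5, 50.0]):
            ref = np.linalg.solve(F.T @ F + lam * np.eye(4), F.T @ R[:, j])
            assert np.allclose(W[:, j], ref, atol=1e-8)

    def test_noiseless_weight_recovery(self):
        rng = np.random.default_rng(4)
        F = rng.normal(size=(200, 30))
        W_true = rng.normal(size=(30, 6))
        R = F @ W_true
        W = RidgeEncoder(alpha=1e-6).fit(F, R).W_
        for v in range(6):
            assert np.corrcoef(W[:, v], W_true[:, v])[0, 1] > 0.999


class TestSelectLambda:
    def test_noiseless_prefers_small_lambda(self):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(200, 10))
        W = rng.normal(size=(10, 4))
        Fd = encoding.DelayedFeatureMatrix(F, 2, [(0, 200)])
        lam, _ = select_lambda(Fd, F @ W, grid=(0.01, 1e6), seed=0)
        assert np.all(lam == 0.01)

    def test_pure_noise_still_selects_from_grid(self):
        rng = np.random.default_rng(6)
        F = rng.normal(size=(100, 10))
        R = rng.normal(size=(100, 3))
        lam, _ = select_lambda(F, R, grid=(1.0, 10.0), seed=0)
        assert set(np.atleast_1d(lam)) <= {1.0, 10.0}

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        F = rng.normal(size=(100, 10))
        R = rng.normal(size=(100, 3))
        l1, _ = select_lambda(F, R, grid=(0.1, 10.0), seed=3)
        l2, _ = select_lambda(F, R, grid=(0.1, 10.0), seed=3)
        assert np.array_equal(l1, l2)


class TestEvaluate:
    def _model(self, N, V, lam=1.0):
        rng = np.random.default_rng(0)
        return EncodingModel(rng.normal(size=(5 * N, V)), lam, N)

    def test_perfect_prediction(self):
        rng = np.random.default_rng(1)
        model = self._model(2, 3)
        F = rng.normal(size=(50, 10))
        R = F @ model.W
        amap = evaluate(model, F, R)
        assert np.allclose(amap.r, 1.0)
        assert amap.q_significant.all()

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(2)
        model = self._model(2, 3)
        F = rng.normal(size=(50, 10))
        amap = evaluate(model, F, -(F @ model.W))
        assert np.allclose(amap.r, -1.0)
        assert not amap.q_significant.any()

    def test_bh_against_exhaustive_oracle(self):
        """BH on a hand-set p vector matches the largest-k rule."""
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.01, 0.02, 0.04, 0.5])
        sig = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        # oracle: largest k with p_(k) <= k q / m, all smaller p significant
        m, q = len(p), 0.05
        ps = np.sort(p)
        ks = [k for k in range(1, m + 1) if ps[k - 1] <= k * q / m]
        kmax = max(ks)
        oracle = p <= ps[kmax - 1]
        assert np.array_equal(sig, oracle)
        assert sig.tolist() == [True, True, True, True, False]

    def test_zero_variance_prediction_insignificant(self):
        model = EncodingModel(np.zeros((10, 2)), 1.0, 2)
        rng = np.random.default_rng(3)
        F = rng.normal(size=(30, 10))
        amap = evaluate(model, F, rng.normal(size=(30, 2)))
        assert np.all(amap.p == 1.0)
        assert not amap.q_significant.any()


class TestROI:
    def test_high_snr_voxels_always_selected_and_noise_never(self):
        rng = np.random.default_rng(8)
        T, D, V = 400, 4, 20
        F = rng.normal(size=(T, D))
        Fd = delay_embed(F)
        W = rng.normal(size=(5 * D, V // 2))
        R = np.hstack([
            Fd.values @ W + 0.01 * rng.normal(size=(T, V // 2)),
            rng.normal(size=(T, V // 2)),
        ])
        roi = roi_from_resampling(Fd, R, lam=1.0, n_resamples=20, seed=0)
        assert np.all(roi.selection_frequency[: V // 2] == 1.0)
        assert np.all(roi.mask[: V // 2])
        assert not roi.mask[V // 2 :].any()

    def test_impossible_threshold_empty(self):
        rng = np.random.default_rng(9)
        F = rng.normal(size=(100, 2))
        Fd = delay_embed(F)
        R = rng.normal(size=(100, 4))
        roi = roi_from_resampling(Fd, R, lam=1.0, n_resamples=5,
                                  freq_threshold=1.1, seed=0)
        assert not roi.mask.any()


class TestNuisance:
    def _delayed(self, T, N, seed):
        rng = np.random.default_rng(seed)
        return delay_embed(rng.normal(size=(T, N)))

    def test_zero_nuisance_equals_plain_fit(self):
        rng = np.random.default_rng(10)
        Fm = self._delayed(100, 3, 1)
        Fn = delay_embed(np.zeros((100, 2)))
        R = rng.normal(size=(100, 4))
        plain = fit_ridge(Fm, R, 1.0)
        nuis = fit_with_nuisance(Fm, Fn, R, 1.0)
        p1 = plain.predict(Fm)
        p2 = predict_excluding_nuisance(nuis, Fm)
        assert np.abs(p1 - p2).max() < 1e-10

    def test_nuisance_driven_response_decodes_to_nothing(self):
        rng = np.random.default_rng(11)
        Fm = self._delayed(300, 3, 2)
        Fn = self._delayed(300, 2, 3)
        W_n = rng.normal(size=(10, 4))
        R = Fn.values @ W_n + 0.1 * rng.normal(size=(300, 4))
        model = fit_with_nuisance(Fm, Fn, R, 1.0)
        Fm_test = self._delayed(200, 3, 4)
        Fn_test = self._delayed(200, 2, 5)
        R_test = Fn_test.values @ W_n
        pred = predict_excluding_nuisance(model, Fm_test)
        r = pearson_by_column(pred, R_test)
        assert np.abs(r).max() < 0.25

    def test_main_driven_response_survives_exclusion(self):
        rng = np.random.default_rng(12)
        Fm = self._delayed(300, 3, 6)
        Fn = self._delayed(300, 2, 7)
        W_m = rng.normal(size=(15, 4))
        R = Fm.values @ W_m + 0.05 * rng.normal(size=(300, 4))
        plain = fit_ridge(Fm, R, 1.0)
        nuis = fit_with_nuisance(Fm, Fn, R, 1.0)
        Fm_test = self._delayed(200, 3, 8)
        R_test = Fm_test.values @ W_m
        r_plain = pearson_by_column(plain.predict(Fm_test), R_test)
        r_excl = pearson_by_column(
            predict_excluding_nuisance(nuis, Fm_test), R_test
        )
        assert np.abs(r_plain - r_excl).max() < 0.05
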