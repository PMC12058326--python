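"""Backward-TRF core: lagged designs, ridge fits, cross-validation."""

import numpy as np
import pytest

from kinetrf import (EnvelopeSeries, KinematicSeries, LagWindow,
                     build_lagged_design, crossvalidate, fit_ridge, make_folds,
                     predict_envelope, score_pearson, summarize_weights,
                     tune_lambda)
from kinetrf.decoder import _FoldBlocks


def series(values, rate=30.0):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] < values.shape[1]:
        values = values.T
    meta = [(f"S{c}", "y") for c in range(values.shape[1])]
    return KinematicSeries(values, meta, rate, 1, "velocity")


def ridge_oracle(x, y, lam):
    """Independent oracle: least squares on the ridge-augmented system."""
    n, p = x.shape
    aug_x = np.vstack([x, np.sqrt(lam) * np.eye(p)])
    aug_y = np.concatenate([y, np.zeros(p)])
    return np.linalg.lstsq(aug_x, aug_y, rcond=None)[0]


class TestLagWindow:
    def test_default_window_lag_count(self):
        w = LagWindow(rate_hz=30.0)
        assert w.n_lags == 37
        assert w.lags_samples[0] == -30 and w.lags_samples[-1] == 6

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            LagWindow(200.0, -1000.0)


class TestBuildLaggedDesign:
    def test_zero_lag_identity(self, rng):
        v = rng.normal(size=(40, 1))
        w = LagWindow(0.0, 1.0, rate_hz=30.0)  # single lag 0
        np.testing.assert_array_equal(build_lagged_design(series(v), w), v)

    def test_impulse_produces_shifted_copies(self):
        v = np.zeros((20, 1))
        v[10] = 1.0
        w = LagWindow(-1000 / 30, 1000 / 30, rate_hz=30.0)  # lags -1, 0, +1
        d = build_lagged_design(series(v), w)
        assert d.shape == (20, 3)
        assert d[11, 0] == 1.0 and d[10, 1] == 1.0 and d[9, 2] == 1.0
        assert d.sum() == 3.0

    def test_matches_brute_force_indexing(self, rng):
        v = rng.normal(size=(60, 3))
        w = LagWindow(rate_hz=30.0)
        d = build_lagged_design(series(v), w)
        lags = w.lags_samples
        for t in rng.integers(0, 60, size=8):
            for c in range(3):
                for li, lag in enumerate(lags):
                    expected = v[t + lag, c] if 0 <= t + lag < 60 else 0.0
                    assert d[t, c * w.n_lags + li] == expected

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            build_lagged_design(series(rng.normal(size=(10, 1))),
                                LagWindow(rate_hz=30.0))


class TestFitRidge:
    def test_exact_linear_fit_at_zero_lambda(self, rng):
        x = rng.normal(size=(80, 5))
        beta = rng.normal(size=5)
        y = x @ beta + 2.0
        model = fit_ridge(x, y, 0.0)
        pred = ((x - model.x_mean) / model.x_sd) @ model.flat_weights \
            + model.intercept
        np.testing.assert_allclose(pred, y, atol=1e-8)
        assert score_pearson(pred, y) == pytest.approx(1.0)

    def test_infinite_lambda_shrinks_to_mean(self, rng):
        x = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        model = fit_ridge(x, y, 1e12)
        assert np.abs(model.flat_weights).max() < 1e-6
        assert model.intercept == pytest.approx(y.mean())

    @pytest.mark.parametrize("lam", [0.0, 1.0, 100.0])
    def test_matches_normal_equation_oracle(self, lam, rng):
        x = rng.normal(size=(50, 8))
        y = rng.normal(size=50)
        xz = (x - x.mean(0)) / x.std(0)
        model = fit_ridge(x, y, lam)
        np.testing.assert_allclose(model.flat_weights,
                                   ridge_oracle(xz, y - y.mean(), lam),
                                   atol=1e-8)

    def test_monotone_shrinkage(self, rng):
        x = rng.normal(size=(60, 10))
        y = rng.normal(size=60)
        norms = [np.linalg.norm(fit_ridge(x, y, lam).flat_weights)
                 for lam in (0.0, 1.0, 10.0, 100.0, 1000.0)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_singular_system_warns_and_solves(self, rng):
        x = rng.normal(size=(20, 5))
        x = np.column_stack([x, x[:, 0]])  # exact collinearity
        with pytest.warns(RuntimeWarning, match="singular"):
            model = fit_ridge(x, rng.normal(size=20), 0.0)
        assert np.isfinite(model.flat_weights).all()


class TestPredictScore:
    def test_predict_matches_design_product_oracle(self, rng):
        v = rng.normal(size=(90, 2))
        kin = series(v)
        w = LagWindow(rate_hz=30.0)
        design = build_lagged_design(kin, w)
        y = rng.normal(size=90)
        model = fit_ridge(design, y, 1.0, channel_meta=kin.channel_meta,
                          window=w)
        pred = predict_envelope(model, kin)
        oracle = ((design - model.x_mean) / model.x_sd) @ model.flat_weights \
            + model.intercept
        np.testing.assert_allclose(pred.values, oracle, atol=1e-12)

    def test_zero_input_predicts_intercept(self, rng):
        v = rng.normal(size=(90, 2))
        kin = series(v)
        w = LagWindow(rate_hz=30.0)
        y = rng.normal(size=90) + 5.0
        model = fit_ridge(build_lagged_design(kin, w), y, 10.0,
                          channel_meta=kin.channel_meta, window=w)
        zeros = kin.copy_with(values=np.zeros_like(v))
        pred = predict_envelope(model, zeros)
        spread = pred.values.max() - pred.values.min()
        assert spread < 1e-9 * max(1.0, abs(model.intercept))

    def test_channel_mismatch_rejected(self, rng):
        kin = series(rng.normal(size=(90, 2)))
        w = LagWindow(rate_hz=30.0)
        model = fit_ridge(build_lagged_design(kin, w), rng.normal(size=90),
                          1.0, channel_meta=kin.channel_meta, window=w)
        other = KinematicSeries(rng.normal(size=(90, 2)),
                                [("A", "x"), ("B", "x")], 30.0, 1, "velocity")
        with pytest.raises(ValueError, match="channel"):
            predict_envelope(model, other)

    def test_pearson_identities(self):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.9])
        assert score_pearson(x, x) == pytest.approx(1.0)
        assert score_pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_printed_toy_value(self):
        # closed-form formula oracle for {(1,2),(2,4),(3,5)}
        assert score_pearson([1, 2, 3], [2, 4, 5]) == pytest.approx(0.9820,
                                                                    abs=5e-5)

    def test_pearson_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            score_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            score_pearson([1.0, 2.0], [1.0, 2.0])


class TestFolds:
    def test_fold_count_is_floor_duration_over_15(self):
        folds = make_folds(30 * 95, 30.0, 15.0)  # 95 s -> 6 folds
        assert len(folds) == 6
        assert folds[0][0] == 0 and folds[-1][1] == 30 * 95
        assert all(b - a >= 10 * 30 for a, b in folds)
        for (a1, b1), (a2, b2) in zip(folds, folds[1:]):
            assert b1 == a2

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            make_folds(100, 30.0, 15.0)


def linear_coupled(rng, n=2400, n_ch=4, noise=0.0, lag=4):
    """Envelope = lagged sum of channels (coupling inside the window)."""
    v = rng.normal(size=(n, n_ch)).cumsum(axis=0)
    v -= v.mean(axis=0)
    y = np.roll(v.sum(axis=1), lag)  # motion precedes envelope by `lag`
    y[:lag] = 0.0
    if noise:
        y = y + rng.normal(0, noise * y.std(), n)
    return series(v), EnvelopeSeries(y, 30.0)


class TestTuneAndCrossvalidate:
    def test_grid_of_one_returns_it(self, rng):
        kin, env = linear_coupled(rng)
        _, _, info = crossvalidate([kin], [env], LagWindow(rate_hz=30.0),
                                   (7.5,), 15.0)
        assert info["lambda"] == 7.5

    def test_noiseless_data_selects_small_lambda(self, rng):
        kin, env = linear_coupled(rng)
        blocks = _FoldBlocks([kin], [env], LagWindow(rate_hz=30.0), 15.0)
        lam, scores = tune_lambda(blocks, (1e-2, 1e2, 1e6), {0: 0})
        assert lam == 1e-2
        assert scores[1e-2] > scores[1e6]

    def test_heavy_noise_selects_larger_lambda(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            kin, env = linear_coupled(rng, n=1350, noise=6.0)
            blocks = _FoldBlocks([kin], [env], LagWindow(rate_hz=30.0), 15.0)
            lam, _ = tune_lambda(blocks, (1e-3, 1e1, 1e5), {0: 0})
            hits += lam > 1e-3
        assert hits >= 8

    def test_empty_grid_rejected(self, rng):
        kin, env = linear_coupled(rng)
        blocks = _FoldBlocks([kin], [env], LagWindow(rate_hz=30.0), 15.0)
        with pytest.raises(ValueError):
            tune_lambda(blocks, (), {0: 0})

    def test_noiseless_recovery_cross_validated(self, rng):
        kin, env = linear_coupled(rng, n=3600)
        table, _, _ = crossvalidate([kin], [env], LagWindow(rate_hz=30.0),
                                    (1e-2, 1.0), 15.0)
        assert table["r"].mean() >= 0.99

    def test_independent_envelope_scores_near_zero(self):
        rs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            kin, _ = linear_coupled(rng, n=2700)
            env = EnvelopeSeries(rng.normal(size=2700), 30.0)
            table, _, _ = crossvalidate([kin], [env], LagWindow(rate_hz=30.0),
                                        (1e2,), 15.0)
            rs.append(table["r"].mean())
        mean, sem = np.mean(rs), np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(mean) <= max(0.05, 3 * sem)

    def test_scale_equivariance_of_predictions(self, rng):
        kin, env = linear_coupled(rng, n=1800)
        t1, _, _ = crossvalidate([kin], [env], LagWindow(rate_hz=30.0),
                                 (1.0,), 15.0)
        scaled = kin.copy_with(values=kin.values * np.array([100.0, 1, 1, 0.01]))
        t2, _, _ = crossvalidate([scaled], [env], LagWindow(rate_hz=30.0),
                                 (1.0,), 15.0)
        np.testing.assert_allclose(t1["r"], t2["r"], atol=1e-6)


class TestSummarizeWeights:
    def test_zero_and_single_weight(self):
        kin = series(np.zeros((40, 2)))
        w = LagWindow(rate_hz=30.0)
        model = fit_ridge(np.zeros((40, 2 * w.n_lags)) + 1e-9,
                          np.zeros(40), 1.0, channel_meta=kin.channel_meta,
                          window=w)
        model.weights[:] = 0.0
        assert (summarize_weights(model)["importance"] == 0).all()
        model.weights[1, 5] = -3.0
        tab = summarize_weights(model)
        assert tab["importance"][1] == pytest.approx(3.0 / w.n_lags)
        assert tab["importance"][0] == 0.0

    def test_matches_mean_abs_oracle(self, rng):
        kin = series(rng.normal(size=(40, 3)))
        w = LagWindow(rate_hz=30.0)
        model = fit_ridge(rng.normal(size=(40, 3 * w.n_lags)),
                          rng.normal(size=40), 1.0,
                          channel_meta=kin.channel_meta, window=w)
        tab = summarize_weights(model)
        np.testing.assert_allclose(tab["importance"],
                                   np.abs(model.weights).mean(axis=1))
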