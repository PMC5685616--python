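"""Maximum-entropy model: feature expansion, the penalized fit against
closed-form and grid-search oracles, and prediction behaviour."""

import numpy as np
import pytest

from sdmshift.errors import ConfigError
from sdmshift.grid import PredictorStack, RasterGrid
from sdmshift.maxent import (
    FeatureDef,
    build_features,
    evaluate_features,
    fit_maxent,
    predict_logistic,
    predict_raw,
    sample_background,
)


def _stack(X, kinds=None):
    p = X.shape[1]
    kinds = kinds or ["continuous"] * p
    layers = [
        RasterGrid(X[:, j][None, :], np.zeros((1, X.shape[0]), bool), 0.0, 1.0,
                   1.0, "planar")
        for j in range(p)
    ]
    return PredictorStack(layers=layers, names=[f"x{j}" for j in range(p)],
                          kinds=kinds)


class TestFeatureCounts:
    def test_lqpt_two_continuous(self):
        rng = np.random.default_rng(0)
        stack = _stack(rng.normal(size=(200, 2)))
        feats = build_features(stack, classes="LQPT", n_knots=3)
        kinds = [f.kind for f in feats]
        assert kinds.count("linear") == 2
        assert kinds.count("quadratic") == 2
        assert kinds.count("product") == 1
        assert kinds.count("threshold") == 6
        assert len(feats) == 11

    def test_categorical_layer_adds_one_indicator_per_class(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(size=300),
                             rng.integers(1, 12, 300).astype(float)])
        stack = _stack(X, kinds=["continuous", "categorical"])
        feats = build_features(stack, classes="LQPT", n_knots=3)
        assert sum(f.kind == "category" for f in feats) == 11

    def test_linear_only(self):
        rng = np.random.default_rng(2)
        stack = _stack(rng.normal(size=(100, 4)))
        feats = build_features(stack, classes="L")
        assert len(feats) == 4 and all(f.kind == "linear" for f in feats)

    def test_empty_stack_rejected(self):
        with pytest.raises((ConfigError, IndexError)):
            build_features(PredictorStack(layers=[], names=[], kinds=[]))


class TestFitOracles:
    def test_single_binary_feature_closed_form(self):
        rng = np.random.default_rng(3)
        b, p, N, m = 0.3, 0.7, 5000, 300
        Xb = (rng.random((N, 1)) < b).astype(float)
        Xp = (rng.random((m, 1)) < p).astype(float)
        feats = [FeatureDef("category", 0, category=1.0)]
        model = fit_maxent(Xp, Xb, feats, beta0=0.0, max_iter=2000, tol=1e-12)
        phat, bhat = Xp.mean(), Xb.mean()
        lam_star = np.log(phat * (1 - bhat) / (bhat * (1 - phat)))
        assert model.lam[0] == pytest.approx(lam_star, abs=1e-4)

    def test_single_binary_feature_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        Xb = (rng.random((2000, 1)) < 0.4).astype(float)
        Xp = (rng.random((150, 1)) < 0.8).astype(float)
        feats = [FeatureDef("category", 0, category=1.0)]
        model = fit_maxent(Xp, Xb, feats, beta0=0.0, max_iter=2000, tol=1e-12)
        a = Xp.mean()
        f = Xb[:, 0]

        def objective(lam):
            z = lam * f
            return a * lam - (np.log(np.exp(z).sum()))

        coarse = np.linspace(-6, 6, 2401)
        lam_grid = coarse[int(np.argmax([objective(g) for g in coarse]))]
        # refine around the coarse optimum
        fine = np.linspace(lam_grid - 0.01, lam_grid + 0.01, 2001)
        vals = [objective(g) for g in fine]
        lam_star = fine[int(np.argmax(vals))]
        assert model.lam[0] == pytest.approx(lam_star, abs=1e-4)

    def test_matched_means_give_uniform_model(self):
        rng = np.random.default_rng(5)
        Xb = rng.normal(size=(1000, 2))
        feats = [FeatureDef("linear", 0), FeatureDef("linear", 1)]
        model = fit_maxent(Xb, Xb, feats, beta0=1.0)
        assert np.allclose(model.lam, 0.0)
        q = model.raw_at(Xb)
        assert np.allclose(q, 1.0 / 1000)
        p = model.logistic_at(Xb)
        assert np.allclose(p, 0.5, atol=1e-6)

    def test_raw_normalizes_over_background(self):
        rng = np.random.default_rng(6)
        Xb = rng.normal(size=(800, 3))
        Xp = Xb[rng.choice(800, 60, replace=False)] + 0.5
        stack = _stack(Xb.T.reshape(3, 1, 800).transpose(1, 2, 0)[0])
        feats = [FeatureDef("linear", j) for j in range(3)] + [
            FeatureDef("quadratic", j) for j in range(3)
        ]
        model = fit_maxent(Xp, Xb, feats, beta0=1.0)
        assert model.raw_at(Xb).sum() == pytest.approx(1.0, abs=1e-8)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(7)
        Xb = rng.normal(size=(1500, 2))
        Xp = Xb[Xb[:, 0] > 0.8][:100]
        feats = [FeatureDef("linear", 0), FeatureDef("linear", 1),
                 FeatureDef("quadratic", 0)]
        model = fit_maxent(Xp, Xb, feats, beta0=0.5)
        h = model.objective_history
        assert len(h) > 1
        assert all(h[i + 1] <= h[i] + 1e-10 for i in range(len(h) - 1))

    def test_self_consistency_moment_matching(self):
        # at an unpenalized optimum the model-expected feature means over
        # the background equal the presence-sample feature means
        rng = np.random.default_rng(8)
        Xb = rng.normal(size=(2000, 2))
        w = np.exp(0.8 * Xb[:, 0] - 0.4 * Xb[:, 1])
        idx = rng.choice(2000, 200, replace=False, p=w / w.sum())
        Xp = Xb[idx]
        feats = [FeatureDef("linear", 0), FeatureDef("linear", 1)]
        model = fit_maxent(Xp, Xb, feats, beta0=0.0, max_iter=3000, tol=1e-14)
        G = model.scaled_features(Xb)
        q = model.raw_at(Xb)
        expected = q @ G
        observed = model.scaled_features(Xp).mean(axis=0)
        assert np.allclose(expected, observed, atol=1e-3)

    def test_constant_features_warn_and_give_uniform(self):
        Xb = np.ones((100, 1))
        Xp = np.ones((10, 1))
        with pytest.warns(UserWarning):
            model = fit_maxent(Xp, Xb, [FeatureDef("linear", 0)], beta0=1.0)
        assert np.allclose(model.lam, 0.0)
        assert np.allclose(model.raw_at(Xb), 0.01)


class TestPrediction:
    def test_monotone_in_single_positive_linear_weight(self):
        rng = np.random.default_rng(9)
        Xb = rng.normal(size=(1000, 1))
        Xp = Xb[Xb[:, 0] > 1.0][:50]
        model = fit_maxent(Xp, Xb, [FeatureDef("linear", 0)], beta0=0.1)
        assert model.lam[0] > 0
        xs = np.sort(rng.uniform(Xb.min(), Xb.max(), 50))[:, None]
        q = model.raw_at(xs)
        assert np.all(np.diff(q) >= -1e-15)

    def test_clamped_prediction_equals_training_max(self):
        rng = np.random.default_rng(10)
        Xb = rng.uniform(0, 1, size=(500, 1))
        Xp = Xb[Xb[:, 0] > 0.7][:40]
        feats = [FeatureDef("linear", 0), FeatureDef("quadratic", 0)]
        model = fit_maxent(Xp, Xb, feats, beta0=0.5)
        beyond = np.array([[5.0]])
        at_max = np.array([[Xb.max()]])
        assert model.logistic_at(beyond, clamp=True) == pytest.approx(
            model.logistic_at(at_max, clamp=False)
        )
        assert model.logistic_at(beyond, clamp=False) != pytest.approx(
            model.logistic_at(at_max, clamp=False)
        )

    def test_logistic_monotone_in_raw(self):
        rng = np.random.default_rng(11)
        Xb = rng.normal(size=(500, 1))
        Xp = Xb[Xb[:, 0] > 0.5][:40]
        model = fit_maxent(Xp, Xb, [FeatureDef("linear", 0)], beta0=0.2)
        q = model.raw_at(Xb)
        p = model.logistic_at(Xb, clamp=False)
        order = np.argsort(q)
        assert np.all(np.diff(p[order]) >= -1e-15)

    def test_grid_prediction_and_missing_predictor(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(300, 2))
        stack = _stack(X)
        bg = sample_background(stack, n=200, seed=0)
        feats = build_features(stack, classes="LQ", n_knots=2,
                               background_values=stack.values_at(bg))
        pres = bg[:30]
        from sdmshift.maxent import fit_on_cells

        model = fit_on_cells(stack, pres, bg, feats, beta0=1.0)
        raster = predict_raw(model, stack)
        assert raster.values.shape == stack.grid.shape
        logi = predict_logistic(model, stack)
        land = ~logi.mask
        assert np.all((logi.values[land] > 0) & (logi.values[land] < 1))
        one_layer = _stack(X[:, :1])
        with pytest.raises(ConfigError):
            predict_raw(model, one_layer)
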