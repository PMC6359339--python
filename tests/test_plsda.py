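"""PLS-DA correctness against closed-form oracles, VIP identities and
waveband selection behavior."""

import numpy as np
import pytest

from seedspec.hypercube import WavelengthAxis
from seedspec.plsda import (
    VIPResult,
    fit_plsda,
    pixel_accuracy,
    predict_pixels,
    refit_on_bands,
    select_latent_variables,
    select_wavebands,
    vip_scores,
)
from seedspec.segment import SpectraTable


def _table(X, y, axis=None):
    X = np.asarray(X, dtype=float)
    axis = axis or WavelengthAxis(np.linspace(1000, 1800, X.shape[1]))
    return SpectraTable(X, np.asarray(y), np.arange(1, len(y) + 1), axis)


class TestFitPLSDA:
    def test_univariate_exact(self):
        # y = 0/1 depends linearly on the single predictor: slope recovered
        x = np.array([0.0, 0.5, 0.0, 0.5, 0.1, 0.4])
        y = np.array([0, 1, 0, 1, 0, 1])
        m = fit_plsda(_table(x[:, None], y), 1)
        scores, _ = predict_pixels(m, x[:, None])
        # single-component PLS1 on one predictor == simple linear regression
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert m.beta[0] == pytest.approx(slope, abs=1e-10)
        assert m.b0 == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)

    def test_full_rank_equals_least_squares(self, rng):
        # oracle: normal equations on centered data
        worst = 0.0
        for _ in range(10):
            X = rng.normal(size=(50, 5))
            y = (rng.normal(size=50) > 0).astype(float)
            y[:2] = [0, 1]
            m = fit_plsda(_table(X, y), 5)
            Xc, yc = X - X.mean(0), y - y.mean()
            beta_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
            worst = max(worst, np.abs(m.beta - beta_ols).max())
        assert worst < 1e-8

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(40, 8))
        y = np.repeat([0, 1], 20)
        perm = rng.permutation(40)
        m1 = fit_plsda(_table(X, y), 3)
        m2 = fit_plsda(_table(X[perm], y[perm]), 3)
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-10)

    def test_factor_beta_equivalence_on_training(self, rng):
        X = rng.normal(size=(60, 12))
        y = np.repeat([0.0, 1.0], 30)
        X[:, 4] += 2 * y
        m = fit_plsda(_table(X, y), 4)
        beta_scores, _ = predict_pixels(m, X)
        factor_scores = (X - m.x_mean) @ m.W @ np.linalg.inv(m.P.T @ m.W) @ m.q \
            + m.y_mean
        np.testing.assert_allclose(beta_scores, factor_scores, atol=1e-8)

    def test_agrees_with_reference_implementation(self, rng):
        # independent route: scikit-learn's PLSRegression (also NIPALS-based)
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(80, 15))
        y = np.repeat([0.0, 1.0], 40)
        X[:, 5] += 1.5 * y
        for n_lv in (1, 3, 5):
            m = fit_plsda(_table(X, y), n_lv)
            ref = PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(m.beta, ref.coef_.ravel(), atol=1e-8)

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_plsda(_table(X, np.ones(10)), 1)


class TestSelectLatentVariables:
    def test_curve_and_choice_on_one_direction(self, labelled_table):
        m = select_latent_variables(labelled_table, max_lv=6, n_folds=4, seed=0)
        assert m.rmsecv_curve.shape == (6,)
        assert np.all(np.isfinite(m.rmsecv_curve)) and np.all(m.rmsecv_curve >= 0)
        # one informative direction -> small A wins
        assert m.n_lv <= 3
        assert m.rmsecv_curve[m.n_lv - 1] <= m.rmsecv_curve[0]

    def test_deterministic(self, labelled_table):
        a = select_latent_variables(labelled_table, max_lv=5, n_folds=4, seed=3)
        b = select_latent_variables(labelled_table, max_lv=5, n_folds=4, seed=3)
        assert a.n_lv == b.n_lv
        np.testing.assert_array_equal(a.rmsecv_curve, b.rmsecv_curve)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_max_lv_clipped_with_warning(self, labelled_table):
        with pytest.warns(RuntimeWarning, match="clipped"):
            m = select_latent_variables(labelled_table, max_lv=500, n_folds=4,
                                        seed=0)
        assert m.n_lv <= 12


class TestPredictAndAccuracy:
    def test_boundary_score_is_nonviable(self):
        x = np.array([[0.0, 0.5], [0.5, 1.0]])
        y = np.array([0, 1])
        m = fit_plsda(_table(np.vstack([x, x + 0.01]), np.r_[y, y]), 1)
        m.beta = np.zeros(2)
        m.b0 = 0.5
        _, cls = predict_pixels(m, x)
        assert np.all(cls == 0)  # exactly 0.5 -> class 0 (strict >)
        m.b0 = 0.7
        _, cls = predict_pixels(m, x)
        assert np.all(cls == 1)

    def test_band_mismatch_raises(self, labelled_table):
        m = fit_plsda(labelled_table, 2)
        with pytest.raises(ValueError, match="bands"):
            predict_pixels(m, np.zeros((3, 5)))

    def test_separable_training_accuracy(self, labelled_table):
        m = fit_plsda(labelled_table, 2)
        _, cls = predict_pixels(m, labelled_table.X)
        acc = pixel_accuracy(cls, labelled_table.y)
        assert acc.loc[acc.group == "total", "accuracy_pct"].item() >= 99.0

    def test_accuracy_table(self):
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = truth.copy()
        pred[[0, 4, 5]] = 1 - pred[[0, 4, 5]]  # 7 of 10 correct
        acc = pixel_accuracy(pred, truth)
        by = dict(zip(acc.group, acc.accuracy_pct))
        assert by["total"] == pytest.approx(70.0)
        assert by["viable"] == pytest.approx(75.0)
        assert by["nonviable"] == pytest.approx(400 / 6)

    def test_all_ones_prediction(self):
        truth = np.repeat([1, 0], 5)
        acc = pixel_accuracy(np.ones(10, dtype=int), truth)
        by = dict(zip(acc.group, acc.accuracy_pct))
        assert (by["viable"], by["nonviable"], by["total"]) == (100.0, 0.0, 50.0)


class TestVIP:
    def test_normalization_identity(self, rng):
        for _ in range(5):
            X = rng.normal(size=(50, 15))
            y = np.repeat([0.0, 1.0], 25)
            X[:, rng.integers(15)] += y
            m = fit_plsda(_table(X, y), 4)
            v = vip_scores(m)
            assert (v.scores**2).sum() == pytest.approx(15, abs=1e-10)

    def test_uniform_single_component_gives_unit_scores(self):
        # all bands identical -> w has equal loadings -> VIP == 1 everywhere
        rng = np.random.default_rng(5)
        base = rng.normal(size=50)
        X = np.tile(base[:, None], (1, 6))
        y = (base > 0).astype(float)
        m = fit_plsda(_table(X, y), 1)
        v = vip_scores(m)
        np.testing.assert_allclose(v.scores, 1.0, atol=1e-10)

    def test_two_band_toy_hand_computed(self):
        # only band 1 carries signal; verify against the formula by hand
        rng = np.random.default_rng(11)
        n = 200
        y = np.repeat([0.0, 1.0], n // 2)
        X = np.c_[y * 2 + rng.normal(0, 0.01, n), rng.normal(0, 0.01, n)]
        m = fit_plsda(_table(X, y), 1)
        v = vip_scores(m)
        w = m.W[:, 0]
        expected = np.sqrt(2 * w**2)  # single component: VIP_j = sqrt(p w_j^2)
        np.testing.assert_allclose(v.scores, expected, atol=1e-12)
        assert v.scores[0] > 1 > v.scores[1]


class TestSelectWavebands:
    def _vip(self, scores, axis=None):
        scores = np.asarray(scores, dtype=float)
        axis = axis or WavelengthAxis(np.linspace(1000, 1800, scores.size))
        return VIPResult(scores, axis)

    def test_flat_curve_empty(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            sel = select_wavebands(self._vip(np.ones(10)))
        assert sel.size == 0

    def test_single_triangular_peak(self):
        s = np.array([0.2, 0.5, 2.0, 0.5, 0.2])
        axis = WavelengthAxis([1000.0, 1100.0, 1200.0, 1300.0, 1400.0])
        sel = select_wavebands(self._vip(s, axis))
        np.testing.assert_array_equal(sel, [1200.0])

    def test_endpoints_included_when_above_one(self):
        s = np.array([1.5, 0.5, 0.4, 0.5, 1.2])
        axis = WavelengthAxis([1000.0, 1100.0, 1200.0, 1300.0, 1400.0])
        sel = select_wavebands(self._vip(s, axis))
        np.testing.assert_array_equal(sel, [1000.0, 1400.0])

    def test_min_separation_keeps_higher_peak(self):
        s = np.array([0.1, 1.5, 0.9, 1.6, 0.1, 0.1])
        sel = select_wavebands(self._vip(s), min_separation=3)
        assert sel.size == 1  # the 1.6 peak wins

    def test_max_bands_caps_by_score(self):
        s = np.array([0.1, 1.2, 0.1, 1.8, 0.1, 1.5, 0.1])
        axis = WavelengthAxis(np.linspace(1000, 1600, 7))
        sel = select_wavebands(self._vip(s, axis), max_bands=2)
        np.testing.assert_array_equal(sel, [1300.0, 1500.0])


class TestRefitOnBands:
    def test_identity_subset(self, labelled_table):
        full = select_latent_variables(labelled_table, max_lv=4, n_folds=4, seed=0)
        re = refit_on_bands(labelled_table, labelled_table.axis.values,
                            max_lv=4, n_folds=4, seed=0)
        assert re.n_lv == full.n_lv
        np.testing.assert_allclose(re.beta, full.beta, atol=1e-12)

    def test_single_band(self, labelled_table):
        nm = labelled_table.axis.values[3]
        m = refit_on_bands(labelled_table, [nm], max_lv=4, n_folds=4, seed=0)
        assert m.n_lv == 1
        assert len(m.wavelengths) == 1

    def test_off_axis_band_raises(self, labelled_table):
        with pytest.raises(KeyError):
            refit_on_bands(labelled_table, [1234.5], max_lv=2, n_folds=4, seed=0)
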