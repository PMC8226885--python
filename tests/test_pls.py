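import numpy as np
import pytest

from nirselect.dataset import SpectraSet
from nirselect.pls import (
    MccvConfig,
    PLS1Regression,
    fit_pls,
    mccv_evaluate,
    pls1_beta,
    predict,
    rpd_band,
)
from tests.conftest import make_planted


def krylov_pls1_beta(X, y, k):
    """Deflation-free PLS1 oracle.

    The k-component PLS1 coefficient is the least-squares solution
    restricted to the Krylov subspace K_k = span{s, As, ..., A^{k-1}s}
    with s = Xc'yc and A = Xc'Xc.  Built independently of the NIPALS
    implementation: orthonormalise the Krylov basis by QR, solve the
    projected least-squares problem by SVD.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    s = Xc.T @ yc
    V = np.empty((X.shape[1], k))
    v = s
    for j in range(k):
        V[:, j] = v
        v = Xc.T @ (Xc @ v)
    Q, _ = np.linalg.qr(V)
    coef, *_ = np.linalg.lstsq(Xc @ Q, yc, rcond=None)
    return Q @ coef


class TestPLS1Core:
    def test_univariate_proportionality(self):
        x = np.linspace(1, 2, 10)
        s = SpectraSet(np.column_stack([x, np.zeros(10)]), [1.0, 2.0], y=2 * x)
        model = fit_pls(s, 1)
        assert abs(model.beta[0] - 2.0) < 1e-10
        np.testing.assert_allclose(predict(model, s), 2 * x, atol=1e-10)

    def test_full_rank_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = X @ np.array([1.0, 2, -1, 0.5, 0]) + 0.1 * rng.normal(size=20)
        beta, xm, ym = pls1_beta(X, y, 5)
        ols = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_krylov_svd_oracle_wide_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 50))
        y = rng.normal(size=10)
        beta, _, _ = pls1_beta(X, y, 3)
        oracle = krylov_pls1_beta(X, y, 3)
        np.testing.assert_allclose(beta, oracle, atol=1e-8)

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_matches_sklearn_pls(self, k):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + 0.2 * rng.normal(size=30)
        beta, _, _ = pls1_beta(X, y, k)
        ref = sklearn_pls.PLSRegression(n_components=k, scale=False).fit(X, y)
        np.testing.assert_allclose(beta, np.ravel(ref.coef_), atol=1e-8)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant y"):
            pls1_beta(np.random.default_rng(0).normal(size=(8, 3)), np.ones(8), 2)


class TestPredict:
    def test_mean_spectrum_predicts_mean_y(self, small_spectra):
        model = fit_pls(small_spectra, 3)
        at_mean = SpectraSet(
            np.vstack([model.x_mean, model.x_mean]), small_spectra.wavelengths
        )
        np.testing.assert_allclose(predict(model, at_mean), model.y_mean, atol=1e-10)

    def test_channel_mismatch_raises(self, small_spectra):
        model = fit_pls(small_spectra, 2)
        other = SpectraSet(np.ones((2, 5)) * np.arange(5), np.arange(5.0))
        with pytest.raises(ValueError, match="channel mismatch"):
            predict(model, other)

    def test_zero_channel_does_not_change_predictions(self, small_spectra):
        model = fit_pls(small_spectra, 3)
        base = predict(model, small_spectra)
        padded = SpectraSet(
            np.hstack([small_spectra.X, np.zeros((small_spectra.n_samples, 1))]),
            np.append(small_spectra.wavelengths, 9999.0),
            y=small_spectra.y,
        )
        model2 = fit_pls(padded, 3)
        np.testing.assert_allclose(predict(model2, padded), base, atol=1e-8)


class TestEstimatorAPI:
    def test_fit_predict_and_get_params(self, small_spectra):
        est = PLS1Regression(n_components=3)
        est.fit(small_spectra.X, small_spectra.y)
        assert est.coef_.shape == (small_spectra.n_channels,)
        assert est.get_params()["n_components"] == 3
        r2 = est.score(small_spectra.X, small_spectra.y)
        assert r2 > 0.9

    def test_pipeline_composition_with_selector(self):
        from sklearn.pipeline import Pipeline
        from nirselect.vscaa import VSCAASelector

        s = make_planted(1, n=60, p=20, informative=(3, 11), noise=0.2)
        pipe = Pipeline(
            [
                ("select", VSCAASelector(n_loops=5, variable_spaces=20,
                                         n_sample_spaces=10, seed=0)),
                ("pls", PLS1Regression(n_components=2)),
            ]
        )
        pipe.fit(s.X, s.y)
        assert pipe.score(s.X, s.y) > 0.5


class TestMccv:
    def test_noise_free_model_is_perfect(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        y = X @ np.array([1.0, -2, 0.5, 0, 0, 1])
        s = SpectraSet(X, np.arange(6.0), y=y)
        rep = mccv_evaluate(s, MccvConfig(n_repeats=20, seed=0), n_components=6)
        assert rep.RMSECV < 1e-8 and rep.Rc > 1 - 1e-8
        assert rep.RMSEP < 1e-8

    def test_same_seed_identical_report(self, planted_spectra):
        s = planted_spectra(5, n=60, p=15)
        r1 = mccv_evaluate(s, MccvConfig(n_repeats=10, seed=3))
        r2 = mccv_evaluate(s, MccvConfig(n_repeats=10, seed=3))
        assert r1.to_dict() == r2.to_dict()

    def test_rmsecv_rederivable_from_stored_splits(self, planted_spectra):
        s = planted_spectra(6, n=60, p=15)
        rep = mccv_evaluate(s, MccvConfig(n_repeats=10, seed=1))
        k = rep.n_components
        sq, cnt = 0.0, 0
        for split in rep.meta["per_split"]:
            pred = split["pred"][:, k - 1]
            meas = s.y[split["val_idx"]]
            sq += np.sum((pred - meas) ** 2)
            cnt += len(meas)
        np.testing.assert_allclose(np.sqrt(sq / cnt), rep.RMSECV, rtol=0, atol=1e-12)

    def test_calibration_size_must_leave_holdout(self, planted_spectra):
        s = planted_spectra(0, n=30, p=8)
        with pytest.raises(ValueError):
            mccv_evaluate(s, MccvConfig(calibration_size=30, seed=0))


class TestRpdBand:
    @pytest.mark.parametrize(
        "rpd,label",
        [
            (2.857, "excellent"),
            (2.5, "very good"),
            (2.0, "very good"),
            (1.9, "good"),
            (1.5, "fair"),
            (1.1, "poor"),
            (0.5, "very poor"),
        ],
    )
    def test_bands(self, rpd, label):
        assert rpd_band(rpd) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rpd_band(-0.1)
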