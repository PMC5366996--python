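"""NIPALS PLS1, PCA screening, LOO-CV and model-comparison contracts.

scikit-learn's PLSRegression and a hand-rolled per-fold loop serve as
independent oracles; they never stand in for the implementation.
"""

import numpy as np
import pytest
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression

import mirpls as m
from mirpls.exceptions import DegenerateDataError, GridError, RankError


def beer_lambert_rank1(rng, n=12, p=40):
    """Noiseless single-component mixtures: X = conc x band shape."""
    band = np.exp(-((np.arange(p) - 18.0) ** 2) / 40.0)
    conc = rng.uniform(2, 10, size=n)
    return conc[:, None] * band[None, :], conc


class TestFitPls:
    def test_rank1_system_fits_exactly(self, rng):
        X, y = beer_lambert_rank1(rng)
        model = m.fit_pls(X, y, 1)
        np.testing.assert_allclose(model.fitted_values, y, atol=1e-8)

    def test_full_rank_equals_minimum_norm_least_squares(self, rng):
        X = rng.normal(size=(10, 20))
        y = rng.normal(size=10)
        model = m.fit_pls(X, y, 9)  # rank of centred X
        Xc = X - X.mean(axis=0)
        oracle = Xc @ (np.linalg.pinv(Xc) @ (y - y.mean())) + y.mean()
        np.testing.assert_allclose(model.predict_pretreated(X), oracle, atol=1e-6)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 25))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        a = m.fit_pls(X, y, 4).coefficients
        b = m.fit_pls(X[perm], y[perm], 4).coefficients
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        T = m.fit_pls(X, y, 6).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.diag(gram).max()

    def test_matches_established_library(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        model = m.fit_pls(X, y, 5)
        sk = PLSRegression(n_components=5, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(
            model.predict_pretreated(X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_excess_latent_variables_rejected(self, rng):
        X, y = beer_lambert_rank1(rng, n=6)
        with pytest.raises(RankError):
            m.fit_pls(X, y, 2)  # rank-1 data cannot yield a second LV

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            m.fit_pls(rng.normal(size=(5, 8)), np.full(5, 3.0), 2)


class TestPredict:
    def test_training_set_reproduces_fitted_values(self, averaged_sim):
        sset, design = averaged_sim
        y = design["ethanol"].to_numpy()
        model = m.calibrate(sset, y, "sub_min+2nd_derivative", 6)
        np.testing.assert_allclose(m.predict(model, sset), model.fitted_values, atol=1e-10)

    def test_duplicated_spectrum_predicts_identically(self, averaged_sim):
        sset, design = averaged_sim
        model = m.calibrate(sset, design["ethanol"].to_numpy(), "sub_min+2nd_derivative", 6)
        dup = m.SpectrumSet(
            grid=sset.grid,
            absorbance=np.vstack([sset.absorbance[0], sset.absorbance[0]]),
            sample_ids=["a", "b"],
        )
        pred = m.predict(model, dup)
        assert pred[0] == pred[1]

    def test_grid_mismatch_rejected(self, averaged_sim):
        sset, design = averaged_sim
        model = m.calibrate(sset, design["ethanol"].to_numpy(), "sub_min+2nd_derivative", 6)
        other = m.SpectrumSet(
            grid=m.WavenumberGrid.from_range(850, 1200, 2.0),
            absorbance=np.zeros((1, 176)),
            sample_ids=["x"],
        )
        with pytest.raises(GridError):
            m.predict(model, other)

    def test_zero_ethanol_spectrum_predicts_near_zero(self, averaged_sim):
        sset, design = averaged_sim
        model = m.calibrate(sset, design["ethanol"].to_numpy(), "sub_min+2nd_derivative", 6)
        # water blank: zero-concentration mixture + instrument noise only
        config = m.SimConfig(seed=7)
        blank_rng = np.random.default_rng(99)
        blank = m.SpectrumSet(
            grid=sset.grid,
            absorbance=blank_rng.normal(0, config.noise_sigma, size=(5, 351)),
            sample_ids=[f"blank{i}" for i in range(5)],
        )
        pred = m.predict(model, blank)
        assert np.abs(pred).max() < 0.5  # unbiased extrapolation to 0 % w/w


def naive_loo_rmsecv(X, y, n_lv, spacing):
    """Independent fold loop: scipy pre-treatment + sklearn PLS per fold."""
    preds = []
    for i in range(len(y)):
        tr = np.delete(X, i, axis=0)
        sub = tr - tr.min(axis=1, keepdims=True)
        d2 = savgol_filter(sub, 9, 3, deriv=2, delta=spacing, axis=1, mode="interp")
        sk = PLSRegression(n_components=n_lv, scale=False).fit(
            d2, np.delete(y, i)[:, None]
        )
        xi = X[i : i + 1] - X[i : i + 1].min()
        xi = savgol_filter(xi, 9, 3, deriv=2, delta=spacing, axis=1, mode="interp")
        preds.append(sk.predict(xi).ravel()[0])
    return float(np.sqrt(np.mean((np.asarray(preds) - y) ** 2)))


class TestLooCv:
    def test_noiseless_rank1_has_vanishing_rmsecv(self, rng):
        X, y = beer_lambert_rank1(rng)
        assert m.loo_cv(X, y, None, 1).rmsecv < 1e-6

    def test_one_submodel_per_standard(self, averaged_sim):
        sset, design = averaged_sim
        cv = m.loo_cv(sset.absorbance, design["ethanol"].to_numpy(),
                      "sub_min+2nd_derivative", 6, spacing=1.0)
        assert cv.cv_predictions.shape == (25,)

    def test_equals_independent_fold_loop(self, averaged_sim):
        sset, design = averaged_sim
        y = design["ethanol"].to_numpy()
        ours = m.loo_cv(sset.absorbance, y, "sub_min+2nd_derivative", 6, spacing=1.0)
        oracle = naive_loo_rmsecv(sset.absorbance, y, 6, spacing=1.0)
        np.testing.assert_allclose(ours.rmsecv, oracle, rtol=1e-8)


class TestSelectNLv:
    def test_two_factor_data_selects_two(self, rng):
        p = 50
        f1 = np.exp(-((np.arange(p) - 15.0) ** 2) / 30)
        f2 = np.exp(-((np.arange(p) - 35.0) ** 2) / 40)
        c1 = rng.uniform(1, 5, 30)
        c2 = rng.uniform(1, 5, 30)
        X = np.outer(c1, f1) + np.outer(c2, f2) + rng.normal(0, 1e-5, (30, p))
        chosen, curve = m.select_n_lv(X, c1, None, 6)
        assert chosen == 2
        assert len(curve) == 6

    def test_parsimony_prefers_elbow_over_max(self, rng):
        X, y = beer_lambert_rank1(rng, n=15, p=30)
        X = X + rng.normal(0, 1e-9, X.shape)  # give higher LVs something to chew
        chosen, _ = m.select_n_lv(X, y, None, 4)
        assert chosen == 1

    def test_max_lv_one_returns_one(self, rng):
        X, y = beer_lambert_rank1(rng)
        chosen, curve = m.select_n_lv(X, y, None, 1)
        assert chosen == 1 and len(curve) == 1


class TestPcaScreen:
    def test_constructed_outlier_is_the_only_flag(self, rng):
        direction = np.ones(6) / np.sqrt(6)
        X = np.outer(np.linspace(-1, 1, 10), direction)
        X = np.vstack([X, 40.0 * direction])  # far along the same axis
        X = X + rng.normal(0, 1e-9, X.shape)
        _, t2, flags, _ = m.pca_screen(X, 1, alpha=0.05)
        assert list(np.flatnonzero(flags)) == [10]
        assert t2[10] > t2[:10].max()

    def test_duplicate_data_has_zero_second_component(self):
        X = np.vstack([np.outer(np.arange(4.0), np.ones(5))] )
        _, _, _, evr = m.pca_screen(X + 0.0, 1, 0.05)
        assert np.all(evr[1:] <= 1e-12)

    def test_explained_variance_sums_to_one(self, rng):
        _, _, _, evr = m.pca_screen(rng.normal(size=(8, 12)), 3, 0.05)
        assert evr.sum() == pytest.approx(1.0)
        assert np.all(evr >= 0)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(RankError):
            m.pca_screen(rng.normal(size=(5, 8)), 5, 0.05)


def _split(sset, y, start):
    idx = np.arange(sset.n_samples)[start::2]
    sub = m.SpectrumSet(
        grid=sset.grid,
        absorbance=sset.absorbance[idx],
        sample_ids=[sset.sample_ids[i] for i in idx],
    )
    return sub, y[idx]


class TestComparePretreatments:
    def test_ranking_contract_on_default_simulation(self, averaged_sim):
        sset, design = averaged_sim
        y = design["ethanol"].to_numpy()
        cal, y_cal = _split(sset, y, 0)
        val, y_val = _split(sset, y, 1)
        names = ["raw", "sub_min+mean_centering", "sub_min+2nd_derivative"]
        table = m.compare_pretreatments(cal, y_cal, val, y_val, names, max_lv=8)
        assert set(table["pipeline"]) == set(names)
        ok = table[~table["failed"]]
        assert ok.iloc[0]["rmsep"] <= ok["rmsep"].min() + 1e-9 or (
            ok.iloc[0]["r2_pred"] >= ok["r2_pred"].max() - 1e-12
        )

    def test_single_pipeline_single_row(self, averaged_sim):
        sset, design = averaged_sim
        y = design["ethanol"].to_numpy()
        cal, y_cal = _split(sset, y, 0)
        val, y_val = _split(sset, y, 1)
        table = m.compare_pretreatments(cal, y_cal, val, y_val, ["raw"], max_lv=6)
        assert len(table) == 1 and table.iloc[0]["pipeline"] == "raw"

    def test_derivative_beats_normalization_under_baseline_drift(self):
        """With smooth per-measurement baseline drift injected, a
        derivative pre-treatment should outrank min-max normalization
        (which cannot remove additive curvature) in the majority of runs."""
        wins = 0
        names = [
            "sub_min+2nd_derivative",
            "sub_min+normalization+mean_centering",
            "sub_min+normalization",
        ]
        for seed in range(10):
            sset, design = m.simulate_dataset(
                m.SimConfig(seed=seed, baseline_amplitude=0.02)
            )
            avg = m.average_replicates(sset)
            y = design.loc[avg.sample_ids, "ethanol"].to_numpy()
            cal, y_cal = _split(avg, y, 0)
            val, y_val = _split(avg, y, 1)
            table = m.compare_pretreatments(cal, y_cal, val, y_val, names, max_lv=8)
            wins += "derivative" in table.iloc[0]["pipeline"]
        assert wins > 5

    def test_failing_pipeline_recorded_not_fatal(self, rng):
        grid = m.WavenumberGrid.from_range(1000, 1020, 1.0)
        flat = m.SpectrumSet(  # flat spectra break min-max normalization
            grid=grid, absorbance=np.ones((6, 21)) * np.arange(1, 7)[:, None],
            sample_ids=[f"s{i}" for i in range(6)],
        )
        y = np.arange(1.0, 7.0)
        table = m.compare_pretreatments(
            flat, y, flat, y, ["sub_min+normalization", "raw"], max_lv=2
        )
        failed = table.set_index("pipeline")["failed"]
        assert bool(failed["sub_min+normalization"]) and not bool(failed["raw"])


class TestModelSerialization:
    def test_json_roundtrip_predicts_identically(self, averaged_sim, tmp_path):
        sset, design = averaged_sim
        model = m.calibrate(
            sset, design["ethanol"].to_numpy(), "sub_min+2nd_derivative+mean_centering", 5
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = m.PLSModel.from_json(path)
        np.testing.assert_allclose(
            m.predict(back, sset), m.predict(model, sset), atol=1e-12
        )
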