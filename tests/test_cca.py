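"""Tests for the canonical correlation analysis."""

import numpy as np
import pandas as pd
import pytest

from strainpart.cca import (
    build_multicellular_features,
    fit_cca,
    predict_strain_correlations,
)
from strainpart.measure import MORPHOLOGY_FEATURES


class TestFitCCA:
    def test_perfect_linear_relation(self, rng):
        X = rng.normal(size=(40, 5))
        Y = X @ rng.normal(size=(5, 3))
        rho = fit_cca(X, Y).correlations
        assert np.all(rho > 1 - 1e-6)

    def test_one_dimensional_reduction_equals_pearson(self, rng):
        x = rng.normal(size=(60, 1))
        y = 0.6 * x + rng.normal(size=(60, 1))
        rho1 = fit_cca(x, y).correlations[0]
        assert rho1 == pytest.approx(abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1]), abs=1e-6)

    def test_matches_brute_force_oracle(self, rng, brute_force_rho1):
        for trial in range(3):
            X = rng.normal(size=(20, 5))
            Y = rng.normal(size=(20, 3))
            rho1 = fit_cca(X, Y).correlations[0]
            assert rho1 == pytest.approx(brute_force_rho1(X, Y, seed=trial), abs=1e-4)

    def test_correlations_sorted_in_unit_interval(self, rng):
        rho = fit_cca(rng.normal(size=(50, 8)), rng.normal(size=(50, 3))).correlations
        assert np.all(np.diff(rho) <= 1e-12)
        assert np.all((rho >= 0) & (rho <= 1))

    def test_affine_rescaling_invariance(self, rng):
        X = rng.normal(size=(60, 6))
        Y = rng.normal(size=(60, 3))
        base = fit_cca(X, Y).correlations
        scales = rng.uniform(0.1, 10, 6)
        shifts = rng.normal(0, 5, 6)
        again = fit_cca(X * scales + shifts, Y).correlations
        assert np.allclose(base, again, atol=1e-10)

    def test_variate_cross_correlations_diagonal(self, rng):
        X = rng.normal(size=(80, 6))
        Y = 0.5 * X[:, :3] + rng.normal(size=(80, 3))
        res = fit_cca(X, Y)
        m = res.correlations.size
        for i in range(m):
            for j in range(m):
                r = np.corrcoef(res.variates_x[:, i], res.variates_y[:, j])[0, 1]
                if i == j:
                    assert abs(r) == pytest.approx(res.correlations[i], abs=1e-8)
                else:
                    assert abs(r) < 1e-8

    def test_recovers_planted_canonical_correlation(self, rng):
        # latent z links one X-direction to one Y-direction with corr ~ target
        n, target = 500, 0.7
        z = rng.normal(size=n)
        X = rng.normal(size=(n, 5))
        Y = rng.normal(size=(n, 3))
        X[:, 0] = z + rng.normal(0, np.sqrt(1 / target - 1), n)
        Y[:, 0] = z + rng.normal(0, np.sqrt(1 / target - 1), n)
        planted = target  # corr(X0, Y0) = 1/(1 + sigma^2) with sigma^2 = 1/t - 1
        rho1 = fit_cca(X, Y).correlations[0]
        assert rho1 == pytest.approx(planted, abs=0.08)

    def test_rank_deficient_warns(self, rng):
        X = rng.normal(size=(30, 4))
        X = np.hstack([X, X[:, :1] * 2.0])  # exactly collinear column
        Y = rng.normal(size=(30, 3))
        with pytest.warns(RuntimeWarning):
            res = fit_cca(X, Y)
        assert np.all(res.correlations <= 1.0)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            fit_cca(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)))
        X = rng.normal(size=(10, 2))
        X[:, 1] = 5.0
        with pytest.raises(ValueError):
            fit_cca(X, rng.normal(size=(10, 2)))


def _morph_df(feats: np.ndarray, centroids: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(feats, columns=list(MORPHOLOGY_FEATURES))
    df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    df["touches_border"] = False
    df["centroid_row"] = centroids[:, 0]
    df["centroid_col"] = centroids[:, 1]
    return df


class TestMulticellularFeatures:
    def test_square_lattice_neighbours(self, rng):
        feats = rng.normal(size=(4, 19))
        cents = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        out = build_multicellular_features(_morph_df(feats, cents))
        assert out.X.shape == (4, 76)
        # cell 1 at (0,0): nearest are cells 2 and 3 (distance 1, tie -> lower
        # label first), then cell 4 (distance sqrt(2))
        np.testing.assert_allclose(out.X[0, :19], feats[0])
        np.testing.assert_allclose(out.X[0, 19:38], feats[1])
        np.testing.assert_allclose(out.X[0, 38:57], feats[2])
        np.testing.assert_allclose(out.X[0, 57:], feats[3])

    def test_feature_matrix_width_is_76(self, hetero_monolayer):
        out = build_multicellular_features(
            hetero_monolayer["morphology"], hetero_monolayer["strain_table"]
        )
        assert out.X.shape[1] == 76
        assert len(out.feature_names) == 76
        assert out.Y.shape == (out.X.shape[0], 3)

    def test_too_few_cells_rejected(self, rng):
        feats = rng.normal(size=(3, 19))
        cents = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            build_multicellular_features(_morph_df(feats, cents))


class TestPredictStrainCorrelations:
    def test_perfect_relation_all_ones(self, rng):
        X = rng.normal(size=(40, 5))
        Y = X @ rng.normal(size=(5, 3))
        res = fit_cca(X, Y, strain_names=("eps_n", "eps_c", "eps_cell"))
        pred = predict_strain_correlations(res, Y)
        # every strain lies exactly in the span of the morphology variates
        assert np.all(pred["r_fit"] > 1 - 1e-5)

    def test_permuted_strains_near_zero(self, rng):
        X = rng.normal(size=(200, 5))
        Y = 0.8 * X[:, :3] + 0.3 * rng.normal(size=(200, 3))
        res = fit_cca(X, Y)
        perm = rng.permutation(Y)
        pred = predict_strain_correlations(res, perm)
        assert np.all(np.abs(pred["best_r"]) < 0.25)
        assert np.all(np.abs(pred["r_fit"]) < 0.3)

    def test_neighbour_coupled_strains_favour_multicellular(self, rng):
        # a cell's strain depends on its neighbours' (stiffness-like) features:
        # the multicellular fit must predict eps_cell at least as well
        n = 240
        cents = np.column_stack([rng.uniform(0, 100, n), rng.uniform(0, 100, n)])
        feats = rng.normal(size=(n, 19))
        morph = _morph_df(feats, cents)
        mc = build_multicellular_features(morph)
        own = mc.X[:, 0]  # own feature 0
        nb_mean = mc.X[:, [19, 38, 57]].mean(axis=1)  # neighbours' feature 0
        eps_cell = 0.25 + 0.02 * own + 0.05 * nb_mean + rng.normal(0, 0.01, len(mc.X))
        eps_n = 0.5 * eps_cell + rng.normal(0, 0.01, len(mc.X))
        eps_c = 2 * eps_cell - eps_n
        strains = pd.DataFrame(
            {"cell_id": mc.cell_ids, "eps_n": eps_n, "eps_c": eps_c, "eps_cell": eps_cell}
        )
        Y = strains[["eps_n", "eps_c", "eps_cell"]].to_numpy()

        names = ("eps_n", "eps_c", "eps_cell")
        keep = morph["cell_id"].isin(mc.cell_ids)
        X_uni = morph.loc[keep, list(MORPHOLOGY_FEATURES)].to_numpy()
        uni = predict_strain_correlations(fit_cca(X_uni, Y, strain_names=names), Y)
        multi_in = build_multicellular_features(morph, strains)
        multi = predict_strain_correlations(
            fit_cca(multi_in.X, multi_in.Y, strain_names=names), multi_in.Y
        )
        r_uni = abs(uni.set_index("strain").loc["eps_cell", "r_fit"])
        r_multi = abs(multi.set_index("strain").loc["eps_cell", "r_fit"])
        assert r_multi >= r_uni
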