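"""Attribution battery: stratification, screens, rPCA, LMM, VPA, VIF, RF."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from terracarbon.stats import (
    classify_climate,
    fit_lmm,
    partial_correlation,
    rf_mccv,
    rotated_pca,
    screen_univariate,
    significance_stars,
    variation_partition,
    vif_prune,
)


class TestClassifyClimate:
    @pytest.mark.parametrize("ai,binary,zone", [
        (0.32, "arid", "semi-arid"),
        (0.55, "arid", "semi-humid"),
        (0.80, "arid", "humid"),
        (1.00, "humid", "humid"),   # boundary convention: AI = 1 -> humid
        (2.17, "humid", "humid"),
    ])
    def test_classification(self, ai, binary, zone):
        c = classify_climate(ai)
        assert (c.binary, c.zone) == (binary, zone)
        assert not c.extreme_arid

    def test_extreme_arid_flagged(self):
        assert classify_climate(0.15).extreme_arid

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_climate(0.0)


class TestScreenUnivariate:
    @staticmethod
    def _frame(n=40, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "group": ["a"] * (n // 2) + ["b"] * (n // 2),
            "x": rng.normal(0, 1, n),
            "spr": rng.normal(10, 2, n),
        })
        return df

    def test_identical_groups_give_null_t(self):
        df = self._frame()
        half = df["x"].to_numpy()[:20]
        df["x"] = np.concatenate([half, half])  # both groups identical
        out = screen_univariate(df, "group", ["x"])
        row = out.iloc[0]
        assert row["t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert row["t_p"] == pytest.approx(1.0)

    def test_perfect_correlation_three_stars(self):
        df = self._frame()
        df["spr"] = 2 * df["x"]
        out = screen_univariate(df, "group", ["x"], targets=("spr",))
        assert out.loc[0, "r_spr"] == pytest.approx(1.0)
        assert out.loc[0, "stars_spr"] == "***"

    def test_null_star_rates_calibrated(self):
        # 1000 independent null variables: star rates track their nominal
        # levels within 3 binomial SE
        rng = np.random.default_rng(4)
        n, p = 50, 1000
        df = pd.DataFrame(rng.normal(0, 1, (n, p)),
                          columns=[f"v{i}" for i in range(p)])
        df["group"] = ["a"] * 25 + ["b"] * 25
        df["spr"] = rng.normal(0, 1, n)
        out = screen_univariate(df, "group", [f"v{i}" for i in range(p)])
        stars = out["stars_spr"]
        for level, symbol in ((0.05, {"*", "**", "***"}),
                              (0.01, {"**", "***"}), (0.001, {"***"})):
            rate = stars.isin(symbol).mean()
            tol = 3 * np.sqrt(level * (1 - level) / p)
            assert abs(rate - level) < max(tol, 2 / p)

    def test_small_group_rejected(self):
        df = self._frame(n=4)
        with pytest.raises(ValueError, match="fewer than 3"):
            screen_univariate(df, "group", ["x"])

    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        x, y = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        assert partial_correlation(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_confounder_removed(self, rng):
        z = rng.normal(0, 1, 2000)
        x = z + rng.normal(0, 0.5, 2000)
        y = z.copy()
        assert abs(partial_correlation(x, y, z)) < 0.05

    def test_orthogonal_controls_leave_r_unchanged(self, rng):
        x, y = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        z = rng.normal(0, 1, 200)
        # orthogonalize z against x, y and the intercept exactly
        Q = np.column_stack([np.ones(200), x, y])
        z = z - Q @ np.linalg.lstsq(Q, z, rcond=None)[0]
        r0 = partial_correlation(x, y)
        assert partial_correlation(x, y, z) == pytest.approx(r0, abs=1e-9)

    def test_agrees_with_pingouin(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (150, 4)), columns=list("xyzw"))
        df["y"] += 0.5 * df["z"]
        df["x"] += 0.7 * df["z"]
        expected = pg.partial_corr(df, x="x", y="y", covar=["z", "w"])["r"].iloc[0]
        got = partial_correlation(df["x"], df["y"], df[["z", "w"]])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_collinear_controls_rejected(self, rng):
        x, y = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        z = rng.normal(0, 1, 50)
        with pytest.raises(np.linalg.LinAlgError):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


class TestRotatedPca:
    def test_block_structure_recovered(self, rng):
        # two independent latent factors, three indicators each
        n = 400
        f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        X = pd.DataFrame({
            "a1": f1 + 0.3 * rng.normal(0, 1, n),
            "a2": f1 + 0.3 * rng.normal(0, 1, n),
            "a3": f1 + 0.3 * rng.normal(0, 1, n),
            "b1": f2 + 0.3 * rng.normal(0, 1, n),
            "b2": f2 + 0.3 * rng.normal(0, 1, n),
            "b3": f2 + 0.3 * rng.normal(0, 1, n),
        })
        rc = rotated_pca(X)
        assert rc.loadings.shape[1] == 2
        for comp in rc.loadings.columns:
            on_a = rc.loadings.loc[["a1", "a2", "a3"], comp].abs() > 0.5
            on_b = rc.loadings.loc[["b1", "b2", "b3"], comp].abs() > 0.5
            assert on_a.all() != on_b.all()  # loads on exactly one block

    def test_isotropic_data_shows_no_structure(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (2000, 6)))
        rc = rotated_pca(X)
        assert rc.eigenvalues.max() < 1.25

    def test_rotation_is_orthogonal_and_variance_preserving(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (200, 8)))
        X.iloc[:, 1] += X.iloc[:, 0]
        X.iloc[:, 3] += X.iloc[:, 2]
        rc = rotated_pca(X)
        T = rc.rotation
        assert np.allclose(T.T @ T, np.eye(T.shape[1]), atol=1e-9)
        k = rc.loadings.shape[1]
        assert rc.variance_fractions.sum() == pytest.approx(
            rc.eigenvalues[:k].sum() / X.shape[1], abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rotated_pca(pd.DataFrame({"a": [1.0], "b": [2.0]}))


class TestLmm:
    @staticmethod
    def _data(n_sites=10, per_site=30, site_sd=1.0, noise=1.0, beta1=2.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sites):
            u = rng.normal(0, site_sd)
            x1 = rng.normal(0, 1, per_site)
            x2 = rng.normal(0, 1, per_site)
            depth = rng.uniform(0, 100, per_site)
            y = beta1 * x1 + u + rng.normal(0, noise, per_site)
            rows.append(pd.DataFrame({"site_id": f"S{s}", "y": y, "x1": x1,
                                      "x2": x2, "depth": depth}))
        return pd.concat(rows, ignore_index=True)

    def test_signal_predictor_selected_and_dominant(self):
        data = self._data()
        res = fit_lmm(data, "y", ["x1", "x2", "depth"])
        assert "x1" in res.selected
        assert abs(res.fixed_effects["x1"]) == max(
            abs(v) for v in res.fixed_effects.values())
        assert 0 <= res.r2m <= res.r2c <= 1

    def test_no_site_variance_collapses_r2c_to_r2m(self):
        data = self._data(site_sd=0.0, seed=1)
        res = fit_lmm(data, "y", ["x1", "x2"])
        assert res.r2c - res.r2m < 0.05

    def test_pure_noise_yields_no_explained_variance(self):
        data = self._data(beta1=0.0, site_sd=0.0, seed=2, n_sites=10, per_site=50)
        res = fit_lmm(data, "y", ["x1", "x2"])
        assert res.r2m < 0.05

    def test_too_few_sites_rejected(self):
        data = self._data(n_sites=2)
        with pytest.raises(ValueError):
            fit_lmm(data, "y", ["x1"])


class TestVariationPartition:
    @staticmethod
    def _blocks(rng, n=80):
        return {
            "g1": pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc")),
            "g2": pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=list("de")),
            "g3": pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=list("fg")),
        }

    def test_fractions_sum_to_one(self, rng):
        blocks = self._blocks(rng)
        y = rng.normal(0, 1, 80)
        res = variation_partition(y, blocks)
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_driver_gets_unique_fraction(self, rng):
        blocks = self._blocks(rng, n=200)
        # y driven by g1's first PC only
        from terracarbon.stats import _first_pc
        pc1, _ = _first_pc(blocks["g1"], "g1")
        y = pc1 + 0.1 * rng.normal(0, 1, 200)
        res = variation_partition(y, blocks)
        assert res.fractions["unique_g1"] == pytest.approx(
            res.adjusted_r2["1"], abs=0.02)
        assert abs(res.fractions["shared_g1_g2"]) < 0.02
        assert abs(res.fractions["shared_all"]) < 0.02

    def test_matches_brute_force_inclusion_exclusion(self):
        # independent oracle: statsmodels OLS adjusted R^2 for the 7 nested
        # regressions, combined by inclusion-exclusion
        for seed in range(12):
            rng = np.random.default_rng(seed)
            blocks = self._blocks(rng, n=60)
            y = (blocks["g1"]["a"].to_numpy() + 0.5 * blocks["g2"]["d"].to_numpy()
                 + rng.normal(0, 1, 60))
            res = variation_partition(y, blocks)

            from terracarbon.stats import _first_pc
            pcs = [_first_pc(blocks[k], k)[0] for k in ("g1", "g2", "g3")]

            def r2a(idx):
                X = sm.add_constant(np.column_stack([pcs[i] for i in idx]))
                return sm.OLS(y, X).fit().rsquared_adj

            A, B, C = r2a([0]), r2a([1]), r2a([2])
            AB, AC, BC = r2a([0, 1]), r2a([0, 2]), r2a([1, 2])
            ABC = r2a([0, 1, 2])
            g = A + B + C - AB - AC - BC + ABC
            expected = {
                "unique_g1": ABC - BC, "unique_g2": ABC - AC, "unique_g3": ABC - AB,
                "shared_g1_g2": A + B - AB - g,
                "shared_g1_g3": A + C - AC - g,
                "shared_g2_g3": B + C - BC - g,
                "shared_all": g, "residual": 1 - ABC,
            }
            for k, v in expected.items():
                assert res.fractions[k] == pytest.approx(v, abs=1e-9), (seed, k)

    def test_overlapping_blocks_rejected(self, rng):
        blocks = self._blocks(rng)
        blocks["g2"] = blocks["g2"].rename(columns={"d": "a"})
        with pytest.raises(ValueError, match="share"):
            variation_partition(rng.normal(0, 1, 80), blocks)

    def test_degenerate_block_named_in_error(self, rng):
        blocks = self._blocks(rng)
        blocks["g3"]["f"] = 1.0
        with pytest.raises(ValueError, match="g3"):
            variation_partition(rng.normal(0, 1, 80), blocks)


class TestVifPrune:
    def test_orthogonal_panel_untouched(self, rng):
        X = pd.DataFrame(np.linalg.qr(rng.normal(0, 1, (100, 4)))[0],
                         columns=list("abcd"))
        reduced, removed = vif_prune(X)
        assert removed == [] and list(reduced.columns) == list("abcd")

    def test_duplicate_column_removed_once(self, rng):
        a = rng.normal(0, 1, 100)
        X = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(0, 1, 100)})
        reduced, removed = vif_prune(X)
        assert len(removed) == 1
        assert removed[0][0] in ("a", "dup")
        assert reduced.shape[1] == 2

    def test_stepwise_sequence_matches_recomputed_vifs(self, rng):
        # three strongly correlated variables: the removal order must match
        # a brute-force recomputation with the statsmodels VIF
        n = 200
        base = rng.normal(0, 1, n)
        X = pd.DataFrame({f"v{i}": base + 0.22 * rng.normal(0, 1, n)
                          for i in range(3)})
        X["noise"] = rng.normal(0, 1, n)
        _, removed = vif_prune(X, threshold=5.0)

        work = X.copy()
        expected = []
        while work.shape[1] >= 2:
            Z = sm.add_constant(work.to_numpy())
            vifs = [variance_inflation_factor(Z, j + 1)
                    for j in range(work.shape[1])]
            worst = int(np.argmax(vifs))
            if vifs[worst] < 5.0:
                break
            expected.append(work.columns[worst])
            work = work.drop(columns=[work.columns[worst]])
        assert [name for name, _ in removed] == expected


class TestRfMccv:
    def test_null_response_has_no_skill(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (500, 5)),
                         columns=[f"v{i}" for i in range(5)])
        y = rng.normal(0, 1, 500)
        res = rf_mccv(y, X, n_rep=15, n_trees=60, seed=0)
        assert res.r2.mean() <= 0.05

    def test_signal_variable_top_ranked(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (400, 4)),
                         columns=["x1", "x2", "x3", "x4"])
        y = 3 * X["x1"].to_numpy() + 0.3 * rng.normal(0, 1, 400)
        res = rf_mccv(y, X, n_rep=20, n_trees=60, seed=1)
        top = res.importance_per_rep.argmax(axis=1)
        assert np.mean(top == 0) >= 0.95
        assert res.importance.loc[0, "variable"] == "x1"

    def test_seed_determinism(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (100, 3)))
        X.columns = ["a", "b", "c"]
        y = X["a"].to_numpy() + rng.normal(0, 1, 100)
        r1 = rf_mccv(y, X, n_rep=5, n_trees=30, seed=3)
        r2 = rf_mccv(y, X, n_rep=5, n_trees=30, seed=3)
        assert np.array_equal(r1.rmse, r2.rmse)
        assert np.array_equal(r1.importance_per_rep, r2.importance_per_rep)

    def test_small_sample_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (10, 2)))
        with pytest.raises(ValueError):
            rf_mccv(rng.normal(0, 1, 10), X, n_rep=5)
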