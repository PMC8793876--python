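import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from xylemcomp.compstats import (
    TraitTable,
    aicc_model_selection,
    anova_tukey,
    blomberg_k,
    compact_letters,
    independent_contrasts,
    pca,
    pearson_matrix,
    pic,
    resolve_polytomies,
    vif,
)
from xylemcomp.synthgen import SynthConfig, simulate_traits, simulate_tree
from xylemcomp.treeio import parse_newick, phylo_vcv


def star_newick(n, bl=1.0):
    return "(" + ",".join(f"t{i}:{bl}" for i in range(n)) + ");"


class TestTraitTable:
    def test_duplicate_species_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            TraitTable(df)

    def test_infinite_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.inf]}, index=["a", "b"])
        with pytest.raises(ValueError, match="non-finite"):
            TraitTable(df)

    def test_nan_allowed(self):
        TraitTable(pd.DataFrame({"x": [1.0, np.nan]}, index=["a", "b"]))


class TestPearson:
    def test_self_correlation(self, trait_table_factory, rng):
        tab = trait_table_factory({"x": rng.normal(size=10), "y": rng.normal(size=10)})
        r, p, n = pearson_matrix(tab)
        assert r.loc["x", "x"] == 1.0

    def test_perfect_anticorrelation(self, trait_table_factory, rng):
        x = rng.normal(size=12)
        tab = trait_table_factory({"x": x, "y": -x})
        r, _, _ = pearson_matrix(tab)
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_brute_force_oracle(self, trait_table_factory, rng):
        x, y = rng.normal(size=28), rng.normal(size=28)
        tab = trait_table_factory({"x": x, "y": y})
        r, _, _ = pearson_matrix(tab)
        expect = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r.loc["x", "y"] == pytest.approx(expect, abs=1e-12)

    def test_constant_trait_missing_with_reason(self, trait_table_factory, rng):
        tab = trait_table_factory({"x": rng.normal(size=8), "c": np.ones(8)})
        r, _, _ = pearson_matrix(tab)
        assert np.isnan(r.loc["x", "c"])
        assert ("x", "c") in r.attrs["missing_reasons"]

    def test_pairwise_complete_cases(self, trait_table_factory, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(0, 0.1, 10)
        y[0] = np.nan
        tab = trait_table_factory({"x": x, "y": y})
        r, _, n = pearson_matrix(tab)
        assert n.loc["x", "y"] == 9


class TestPic:
    def test_two_tip_contrast(self):
        tree = parse_newick("(A:1,B:1);")
        cs = independent_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert len(cs.contrasts) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2), abs=1e-12)

    def test_contrast_count(self, yule_tree, rng):
        vals = dict(zip(yule_tree.tip_labels(), rng.normal(size=28)))
        cs = independent_contrasts(yule_tree, vals)
        assert len(cs.contrasts) == 27

    @pytest.mark.parametrize("seed", range(10))
    def test_gls_whitening_oracle(self, seed, tree_factory):
        """Sum of squared contrasts equals the GLS quadratic form around the
        phylogenetic mean."""
        tree = tree_factory(n_tips=12, seed=seed)
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        order = tree.tip_labels()
        cs = independent_contrasts(tree, dict(zip(order, x)))
        V = phylo_vcv(tree).matrix
        Vinv = np.linalg.inv(V)
        ones = np.ones(len(x))
        a_hat = (ones @ Vinv @ x) / (ones @ Vinv @ ones)
        q = (x - a_hat) @ Vinv @ (x - a_hat)
        assert np.sum(cs.contrasts**2) == pytest.approx(q, rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_star_equals_pearson(self, seed, trait_table_factory):
        rng = np.random.default_rng(seed)
        n = 16
        tree = parse_newick(star_newick(n))
        x, y = rng.normal(size=n), rng.normal(size=n)
        tab = TraitTable(pd.DataFrame({"x": x, "y": y}, index=[f"t{i}" for i in range(n)]))
        with pytest.warns(UserWarning, match="polytomies"):
            r_pic, _, _, _ = pic(tree, tab, "x", "y")
        r_raw = np.corrcoef(x, y)[0, 1]
        assert r_pic == pytest.approx(r_raw, abs=1e-8)

    def test_species_mismatch_lists_offenders(self, yule_tree, trait_table_factory, rng):
        tab = trait_table_factory({"x": rng.normal(size=5), "y": rng.normal(size=5)})
        with pytest.raises(ValueError, match="mismatch"):
            pic(yule_tree, tab, "x", "y")

    def test_polytomy_strict_mode(self):
        tree = parse_newick(star_newick(5))
        with pytest.raises(ValueError, match="polytom"):
            resolve_polytomies(tree, strict=True)


class TestBlombergK:
    def test_affine_invariance(self, yule_tree):
        x = simulate_traits(yule_tree, seed=3)
        t1 = TraitTable(pd.DataFrame({"x": x}))
        t2 = TraitTable(pd.DataFrame({"x": 5.0 * x - 7.0}))
        k1 = blomberg_k(yule_tree, t1, "x", n_perm=10, seed=0).k
        k2 = blomberg_k(yule_tree, t2, "x", n_perm=10, seed=0).k
        assert k1 == pytest.approx(k2, rel=1e-8)

    def test_seeded_reproducibility(self, yule_tree):
        x = simulate_traits(yule_tree, seed=3)
        tab = TraitTable(pd.DataFrame({"x": x}))
        a = blomberg_k(yule_tree, tab, "x", n_perm=199, seed=11)
        b = blomberg_k(yule_tree, tab, "x", n_perm=199, seed=11)
        assert (a.k, a.p_value) == (b.k, b.p_value)

    def test_p_resolution(self, yule_tree):
        x = simulate_traits(yule_tree, seed=3)
        tab = TraitTable(pd.DataFrame({"x": x}))
        res = blomberg_k(yule_tree, tab, "x", n_perm=99, seed=1)
        assert 0 < res.p_value <= 1
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))

    def test_bm_calibration_small(self):
        """Reduced-size calibration; the full 500-replicate version runs in
        the acceptance suite."""
        ks = []
        for rep in range(60):
            tree = simulate_tree(SynthConfig(n_species=28, seed=1000 + rep))
            x = simulate_traits(tree, lam=0.0, seed=rep)
            ks.append(blomberg_k(tree, TraitTable(pd.DataFrame({"x": x})), "x", n_perm=19, seed=rep).k)
        assert 0.85 < np.mean(ks) < 1.15

    def test_white_noise_low_k(self):
        ks = []
        for rep in range(60):
            tree = simulate_tree(SynthConfig(n_species=28, seed=2000 + rep))
            x = simulate_traits(tree, lam=1.0, seed=rep)
            ks.append(blomberg_k(tree, TraitTable(pd.DataFrame({"x": x})), "x", n_perm=19, seed=rep).k)
        assert np.mean(ks) < 0.5


class TestAnovaTukey:
    def test_f_equals_t_squared_two_groups(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = anova_tukey(np.r_[a, b], ["a"] * 12 + ["b"] * 15)
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_all_equal_f_zero(self):
        res = anova_tukey([5.0] * 9, ["a", "b", "c"] * 3)
        assert res.f_statistic == 0.0
        assert len(set(res.letters.values())) == 1

    def test_shifted_group_distinct_letter(self, rng):
        y = np.r_[rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(8, 1, 10)]
        g = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = anova_tukey(y, g)
        assert res.letters["c"] not in (res.letters["a"], res.letters["b"])
        assert res.letters["a"] == res.letters["b"]

    def test_singleton_group_excluded(self, rng):
        y = np.r_[rng.normal(size=6), [1.0]]
        with pytest.warns(UserWarning, match="excluded"):
            res = anova_tukey(y, ["a"] * 3 + ["b"] * 3 + ["c"])
        assert res.excluded_groups == ["c"]

    def test_letters_consistent_with_pairwise(self, rng):
        y = np.r_[rng.normal(0, 1, 8), rng.normal(3, 1, 8), rng.normal(6, 1, 8)]
        res = anova_tukey(y, ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        for g1 in "abc":
            for g2 in "abc":
                if g1 < g2:
                    share = set(res.letters[g1]) & set(res.letters[g2])
                    sig = res.pairwise_p.loc[g1, g2] < 0.05
                    assert bool(share) == (not sig)

    def test_compact_letters_direct(self):
        letters = compact_letters(["a", "b", "c"], {("a", "c")})
        assert set(letters["a"]) & set(letters["c"]) == set()
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])


class TestPca:
    def test_perfectly_correlated_pair(self, trait_table_factory, rng):
        x = rng.normal(size=15)
        tab = trait_table_factory({"x": x, "y": 2 * x + 1})
        _, _, frac = pca(tab)
        assert frac["PC1"] == pytest.approx(1.0, abs=1e-12)

    def test_fraction_sums_to_one(self, trait_table_factory, rng):
        tab = trait_table_factory({c: rng.normal(size=20) for c in "abcde"})
        _, _, frac = pca(tab)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_eigen_oracle(self, trait_table_factory, rng):
        tab = trait_table_factory({c: rng.normal(size=25) for c in "abcd"})
        loadings, _, frac = pca(tab)
        C = np.corrcoef(tab.data.to_numpy(), rowvar=False)
        w = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(frac.to_numpy() * w.sum(), w, atol=1e-10)
        # loadings reconstruct C
        np.testing.assert_allclose(
            loadings.to_numpy() @ np.diag(frac.to_numpy() * w.sum()) @ loadings.to_numpy().T,
            C,
            atol=1e-10,
        )

    def test_constant_trait_dropped(self, trait_table_factory, rng):
        tab = trait_table_factory({"x": rng.normal(size=10), "c": np.ones(10), "y": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="constant"):
            loadings, _, _ = pca(tab)
        assert "c" not in loadings.index


class TestVif:
    def test_orthogonal_predictors(self, trait_table_factory):
        n = 8
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        tab = trait_table_factory({"x1": x1, "x2": x2})
        v = vif(tab, ["x1", "x2"])
        np.testing.assert_allclose(v.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_duplicate_infinite(self, trait_table_factory, rng):
        x = rng.normal(size=12)
        tab = trait_table_factory({"x1": x, "x2": x, "x3": rng.normal(size=12)})
        v = vif(tab, ["x1", "x2", "x3"])
        assert np.isinf(v["x1"]) and np.isinf(v["x2"])
        assert "x1" in v.attrs["flagged"]

    def test_brute_force_oracle(self, trait_table_factory, rng):
        tab = trait_table_factory({c: rng.normal(size=30) for c in "abc"})
        v = vif(tab, ["a", "b", "c"])
        for target in "abc":
            others = [c for c in "abc" if c != target]
            X = sm.add_constant(tab.data[others].to_numpy())
            r2 = sm.OLS(tab.data[target].to_numpy(), X).fit().rsquared
            assert v[target] == pytest.approx(1 / (1 - r2), rel=1e-10)


def manual_aicc(y, X_cols, data):
    """Independent AICc oracle via statsmodels."""
    n = len(data)
    X = sm.add_constant(data[X_cols].to_numpy()) if X_cols else np.ones((n, 1))
    fit = sm.OLS(data[y].to_numpy(), X).fit()
    k = len(X_cols) + 2
    return -2 * fit.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class TestAiccSelection:
    def test_single_candidate_two_models(self, trait_table_factory, rng):
        tab = trait_table_factory({"y": rng.normal(size=20), "x": rng.normal(size=20)})
        sel = aicc_model_selection(tab, "y", ["x"])
        assert len(sel.models) == 2
        assert sel.models["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_enumeration_p3(self, trait_table_factory, rng):
        data = {c: rng.normal(size=28) for c in "abc"}
        data["y"] = 0.5 * data["a"] + rng.normal(0, 1, 28)
        tab = trait_table_factory(data)
        sel = aicc_model_selection(tab, "y", ["a", "b", "c"], standardize=False)
        assert len(sel.models) == 8
        D = tab.data
        for _, row in sel.models.iterrows():
            expect = manual_aicc("y", list(row["predictors"]), D)
            assert row["AICc"] == pytest.approx(expect, rel=1e-10)

    def test_best_model_delta_zero_and_selected(self, trait_table_factory, rng):
        data = {c: rng.normal(size=25) for c in "ab"}
        data["y"] = data["a"] + rng.normal(0, 0.3, 25)
        tab = trait_table_factory(data)
        sel = aicc_model_selection(tab, "y", ["a", "b"])
        assert sel.models["delta"].iloc[0] == 0.0
        assert len(sel.selected) >= 1
        assert sel.models["predictors"].iloc[0] == ("a",)

    def test_planted_signal_importance(self, trait_table_factory, rng):
        x1, x2, x3 = (rng.normal(size=28) for _ in range(3))
        y = 0.6 * x1 + rng.normal(0, 0.5, 28)
        tab = trait_table_factory({"y": y, "x1": x1, "x2": x2, "x3": x3})
        sel = aicc_model_selection(tab, "y", ["x1", "x2", "x3"])
        assert "x1" in sel.models["predictors"].iloc[0]
        assert sel.importance["x1"] > sel.importance["x2"]
        assert sel.importance["x1"] > sel.importance["x3"]

    def test_importance_in_unit_interval(self, trait_table_factory, rng):
        tab = trait_table_factory({c: rng.normal(size=20) for c in "yab"})
        sel = aicc_model_selection(tab, "y", ["a", "b"])
        assert ((sel.importance >= 0) & (sel.importance <= 1)).all()

    def test_averaged_coefficient_zero_substitution(self, trait_table_factory, rng):
        data = {c: rng.normal(size=26) for c in "ab"}
        data["y"] = 0.8 * data["a"] + rng.normal(0, 0.4, 26)
        tab = trait_table_factory(data)
        sel = aicc_model_selection(tab, "y", ["a", "b"], delta_threshold=np.inf)
        w = sel.models["weight"].to_numpy()
        w = w / w.sum()
        beta_a = []
        for _, row in sel.models.iterrows():
            beta_a.append(row.get("a", 0.0) if "a" in row["predictors"] else 0.0)
        assert sel.averaged_coef["a"] == pytest.approx(np.sum(w * np.array(beta_a)), abs=1e-10)
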