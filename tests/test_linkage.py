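"""Linkage core: LOD formula, regression oracle, thresholds, forward
search, drop intervals and effect annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import growthmap as gm
from growthmap.linkage import annotate_peak, lod_from_r2, lod_scores


def regression_lod_oracle(X, y):
    """Independent oracle: per-marker least-squares fit, LOD from model R^2.

    R^2 = 1 - RSS/TSS from an explicit design-matrix solve, nothing shared
    with the correlation-based scan path.
    """
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        g = X[:, j]
        ok = ~np.isnan(g)
        gj, yj = g[ok], y[ok]
        n = len(gj)
        if n < 3 or np.ptp(gj) == 0 or np.ptp(yj) == 0:
            continue
        D = np.column_stack([np.ones(n), gj])
        beta, rss, *_ = np.linalg.lstsq(D, yj, rcond=None)
        rss = float(rss[0]) if len(rss) else float(((yj - D @ beta) ** 2).sum())
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss
        out[j] = -n * np.log(1.0 - min(r2, 1 - 1e-12)) / (2 * np.log(10))
    return out


_AFFINE_CASE = {}


def _affine_case():
    if not _AFFINE_CASE:
        rng = np.random.default_rng(41)
        X = rng.choice([-1.0, 1.0], size=(60, 10))
        y = rng.normal(size=60) + 0.5 * X[:, 3]
        _AFFINE_CASE["data"] = (X, y, lod_scores(X, y))
    return _AFFINE_CASE["data"]


class TestLodFormula:
    def test_r_zero_gives_zero(self):
        assert lod_from_r2(0.0, 100) == 0.0

    def test_printed_formula_value(self):
        # n=100, R=0.5: -100 ln(0.75) / (2 ln 10), equivalently
        # (n/2) log10(1/(1-R^2))
        expected = (100 / 2) * np.log10(1 / 0.75)
        assert lod_from_r2(0.25, 100) == pytest.approx(6.246936, abs=1e-6)
        assert lod_from_r2(0.25, 100) == pytest.approx(expected, abs=1e-12)

    def test_perfect_correlation_finite(self):
        assert np.isfinite(lod_from_r2(1.0, 50))

    def test_matches_regression_oracle(self, panel, planted_trait):
        _, sim = planted_trait
        X = panel.coded().to_numpy().T
        y = sim.values.to_numpy()
        np.testing.assert_allclose(
            lod_scores(X, y), regression_lod_oracle(X, y), atol=1e-10
        )

    def test_oracle_equivalence_with_missing_genotypes(self, panel, planted_trait):
        _, sim = planted_trait
        X = panel.coded().to_numpy().T.copy()
        rng = np.random.default_rng(40)
        X[rng.random(X.shape) < 0.05] = np.nan
        y = sim.values.to_numpy()
        np.testing.assert_allclose(
            lod_scores(X, y), regression_lod_oracle(X, y), atol=1e-10
        )

    def test_monomorphic_marker_and_constant_trait_zero(self):
        X = np.column_stack([np.ones(30), np.repeat([-1.0, 1.0], 15)])
        y = np.random.default_rng(0).normal(size=30)
        assert lod_scores(X, y)[0] == 0.0
        assert (lod_scores(X, np.ones(30)) == 0).all()

    @given(st.floats(min_value=0.1, max_value=10), st.floats(min_value=-5, max_value=5))
    def test_affine_trait_invariance(self, scale, shift):
        X, y, base = _affine_case()
        np.testing.assert_allclose(lod_scores(X, scale * y + shift), base, atol=1e-8)

    def test_allele_coding_swap_invariance(self, panel, planted_trait):
        _, sim = planted_trait
        X = panel.coded().to_numpy().T
        y = sim.values.to_numpy()
        np.testing.assert_allclose(lod_scores(-X, y), lod_scores(X, y), atol=1e-12)


class TestMergePheno:
    def test_disjoint_sets_rejected(self, panel):
        trait = pd.Series([1.0, 2.0] * 10, index=[f"other_{i}" for i in range(20)])
        with pytest.raises(ValueError):
            gm.merge_pheno(panel, trait)

    def test_identical_sets_unchanged(self, panel, planted_trait):
        _, sim = planted_trait
        g, t = gm.merge_pheno(panel, sim.values)
        assert list(g.strains) == list(panel.strains)
        assert t.equals(sim.values)

    def test_partial_overlap_intersects(self, panel, planted_trait):
        _, sim = planted_trait
        t = sim.values.iloc[: panel.n_strains - 9]
        g, tt = gm.merge_pheno(panel, t)
        assert g.n_strains == len(tt) == panel.n_strains - 9
        assert list(g.strains) == list(tt.index)


class TestPermutationThreshold:
    def test_constant_trait_zero_threshold(self, panel):
        y = pd.Series(np.ones(panel.n_strains), index=panel.strains)
        thr = gm.permutation_threshold(panel, y, n_permutations=50, seed=1)
        assert thr.value == 0.0

    def test_seed_reproducible(self, panel, planted_trait):
        _, sim = planted_trait
        a = gm.permutation_threshold(panel, sim.values, 200, seed=5)
        b = gm.permutation_threshold(panel, sim.values, 200, seed=5)
        assert a.value == b.value

    def test_few_permutations_warns(self, panel, planted_trait):
        _, sim = planted_trait
        with pytest.warns(UserWarning):
            gm.permutation_threshold(panel, sim.values, n_permutations=10, seed=0)

    def test_order_statistic_definition(self, panel, planted_trait):
        """Threshold equals the ceil(0.95 N)-th smallest null max LOD."""
        from growthmap.linkage import LinkageModel, _max_lod_null

        _, sim = planted_trait
        model = LinkageModel(panel, sim.values)
        rng = np.random.default_rng(9)
        null = _max_lod_null(model._X, model._y, 100, rng)
        thr = model.permutation_threshold(100, alpha=0.05, seed=9)
        assert thr.value == pytest.approx(np.sort(null)[94], abs=1e-12)


class TestLodDropInterval:
    def test_immediate_drop_single_marker(self):
        table = pd.DataFrame({"marker": ["m1", "m2", "m3"], "chrom": ["I"] * 3,
                              "bp": [10, 20, 30], "lod": [5.0, 3.0, 1.0]})
        prof = gm.LodProfile(table)
        assert gm.lod_drop_interval(prof, "m1") == (10, 10)

    def test_hand_checked_run(self, hand_profile):
        # peak lod 5 at m3, cutoff 3.5 -> run covers m3..m4 only
        assert gm.lod_drop_interval(hand_profile, "m3") == (300, 400)

    def test_flat_profile_whole_chromosome(self):
        table = pd.DataFrame({"marker": [f"m{i}" for i in range(4)],
                              "chrom": ["I"] * 4, "bp": [1, 2, 3, 4],
                              "lod": [2.0] * 4})
        prof = gm.LodProfile(table)
        assert gm.lod_drop_interval(prof, "m0") == (1, 4)

    def test_negative_drop_rejected(self, hand_profile):
        with pytest.raises(ValueError):
            gm.lod_drop_interval(hand_profile, "m3", drop=-1)

    def test_interval_confined_to_peak_chromosome(self, panel, planted_trait):
        marker, sim = planted_trait
        prof = gm.lod_profile(panel, sim.values)
        left, right = gm.lod_drop_interval(prof, prof.peak()["marker"])
        chrom = prof.peak()["chrom"]
        t = prof.table
        on = t[t["chrom"] == chrom]
        assert on["bp"].min() <= left <= right <= on["bp"].max()


class TestAnnotate:
    def test_equal_class_means_zero_effect(self, small_map):
        g = gm.simulate_riail_genotypes(small_map, 40, seed=50)
        y = pd.Series(np.zeros(40), index=g.strains)
        y[:] = 1.0
        var, eff = annotate_peak(g, y, "I_001")
        assert eff == 0.0 and var == 0.0

    def test_r2_to_variance_pct(self):
        """R ~ 0.294 corresponds to ~8.6% variance explained."""
        rng = np.random.default_rng(51)
        g = rng.choice([-1.0, 1.0], size=40_000)
        a = gm.effect_for_variance_fraction(0.086)
        y = a * g + rng.normal(size=g.size)
        geno = gm.GenotypeMatrix(
            pd.DataFrame([np.where(g > 0, "CB4856", "N2")], index=["m"],
                         columns=[f"s{i}" for i in range(g.size)]))
        var, eff = annotate_peak(geno, y, "m")
        assert var == pytest.approx(8.6, abs=0.8)
        assert eff == pytest.approx(2 * a, abs=0.05)

    def test_empty_allele_class_fails(self):
        geno = gm.GenotypeMatrix(
            pd.DataFrame([["N2"] * 6], index=["m"],
                         columns=[f"s{i}" for i in range(6)]))
        with pytest.raises(ValueError):
            annotate_peak(geno, np.arange(6.0), "m")


class TestForwardSearch:
    def test_planted_qtl_found_on_true_chromosome(self, panel, planted_trait):
        marker, sim = planted_trait
        res = gm.forward_search(panel, sim.values, n_permutations=300, seed=60)
        assert res.n_qtl >= 1
        assert res.qtl.iloc[0]["chromosome"] == "X"
        assert (res.qtl["lod"] > res.threshold.value).all()

    def test_two_qtl_recovered_separately(self, panel):
        a = gm.effect_for_variance_fraction(0.10)
        sim = gm.simulate_trait(
            panel, [gm.QtlSpec("II_010", a), gm.QtlSpec("V_010", a)], seed=61)
        res = gm.forward_search(panel, sim.values, n_permutations=300, seed=62)
        chroms = set(res.qtl["chromosome"])
        assert {"II", "V"} <= chroms

    def test_qtl_table_shape_and_summary(self, panel, planted_trait):
        _, sim = planted_trait
        res = gm.forward_search(panel, sim.values, n_permutations=200, seed=63)
        assert list(res.qtl.columns) == [
            "trait", "chromosome", "interval_left_bp", "interval_right_bp",
            "peak_bp", "peak_marker", "lod", "variance_explained_pct",
            "effect_size",
        ]
        assert (res.qtl["interval_left_bp"] <= res.qtl["peak_bp"]).all()
        assert (res.qtl["peak_bp"] <= res.qtl["interval_right_bp"]).all()
        text = res.summary()
        assert "QTL detected" in text and "Threshold" in text

    def test_fixed_threshold_short_circuits_permutations(self, panel, planted_trait):
        _, sim = planted_trait
        res = gm.forward_search(panel, sim.values, threshold=3.0)
        assert res.threshold.value == 3.0

    def test_max_qtl_caps_detections(self, panel, planted_trait):
        _, sim = planted_trait
        res = gm.forward_search(panel, sim.values, threshold=0.5, max_qtl=2)
        assert res.n_qtl == 2

    def test_plot_returns_axis(self, panel, planted_trait):
        import matplotlib

        matplotlib.use("Agg")
        _, sim = planted_trait
        res = gm.forward_search(panel, sim.values, threshold=3.0)
        ax = res.plot()
        assert ax.get_ylabel() == "LOD"
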