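"""Statistical core: Fisher-z integration, Z-test, outlier rule, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from batsig import (
    DEFAULT_MARKER_SETS,
    ExpressionMatrix,
    TissuePanelSimConfig,
    compare_set_correlations,
    correlation_matrix,
    detect_outliers,
    filter_genes_by_outliers,
    fisher_z,
    gene_set_correlation,
    generate_tissue_panel,
    hierarchical_cluster,
    inverse_fisher_z,
    pearson_r,
)
from batsig.concordance import CorrelationMatrix
from batsig.exceptions import (
    ConfigurationError,
    DomainError,
    EmptySetError,
    InsufficientDataError,
    MismatchedPanelsError,
)
from batsig.simulate import add_factor_free_gene


def _panel(values: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = [f"S{i+1}" for i in range(df.shape[1])]
    meta = pd.DataFrame({"tissue": ["t"] * df.shape[1]},
                        index=pd.Index(df.columns, name="sample_id"))
    return ExpressionMatrix(values=df, samples=meta)


class TestPearson:
    def test_exact_linear_dependence(self):
        r, n = pearson_r([1, 2, 3], [2, 4, 6])
        assert (r, n) == (1.0, 3)
        r, _ = pearson_r([1, 2, 3], [3, 2, 1])
        assert r == -1.0

    def test_hand_computed_example(self):
        r, n = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert n == 4

    def test_pairwise_complete_drops_missing(self):
        r, n = pearson_r([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_zero_variance_flags_undefined(self):
        r, n = pearson_r([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r) and n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1, 2], [3, 4])


class TestFisherZ:
    def test_zero_fixed_point_and_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_exact(self, r):
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_unit_r_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            fisher_z(1.5)


class TestGeneSetCorrelation:
    def test_identical_members_collapse_to_member_r(self):
        # anchor correlates 0.6-ish identically with two duplicated members
        rng = np.random.default_rng(0)
        a = rng.standard_normal(40)
        b = 0.6 * a + 0.8 * rng.standard_normal(40)
        m = _panel({"A": a - a.min() + 1, "M1": b - b.min() + 1, "M2": b - b.min() + 1})
        gsc = gene_set_correlation("A", ["M1", "M2"], m)
        r1, _ = pearson_r(m.values.loc["A"], m.values.loc["M1"])
        assert gsc.r_bar == pytest.approx(r1, abs=1e-12)

    def test_two_member_closed_form(self):
        # members with r = 0.0 and 0.5 at equal n: z̄ = 0.27465, r̄ = 0.26795
        z_bar = (fisher_z(0.0) + fisher_z(0.5)) / 2
        assert z_bar == pytest.approx(0.27465, abs=1e-4)
        assert inverse_fisher_z(z_bar) == pytest.approx(0.26795, abs=1e-4)

    def test_single_member_set_returns_that_r(self, tissue_panel):
        matrix, _ = tissue_panel
        gsc = gene_set_correlation("PRDM16", ["CITED1"], matrix)
        r, _ = pearson_r(matrix.values.loc["PRDM16"], matrix.values.loc["CITED1"])
        assert gsc.r_bar == pytest.approx(r, abs=1e-9)

    def test_adding_member_at_current_rbar_leaves_rbar_fixed(self):
        # set-monotonicity invariant, checked on the z scale it is defined on
        rng = np.random.default_rng(3)
        a = rng.standard_normal(60)
        members = {f"M{i}": 0.5 * a + rng.standard_normal(60) for i in range(3)}
        m = _panel({"A": a + 10, **{k: v + 10 for k, v in members.items()}})
        base = gene_set_correlation("A", list(members), m)
        # append a synthetic member whose r equals the current r̄ exactly
        extra = base.members.copy()
        extra.loc[len(extra)] = {
            "gene": "MX", "r": base.r_bar, "n": 60,
            "z": fisher_z(base.r_bar), "weight": 57,
        }
        w, z = extra["weight"].to_numpy(float), extra["z"].to_numpy(float)
        assert inverse_fisher_z(np.sum(w * z) / np.sum(w)) == pytest.approx(base.r_bar, abs=1e-12)

    def test_weighted_mean_with_unequal_n(self):
        # member 1 observed on 10 complete pairs, member 2 on 5: w = 7 vs 2
        rng = np.random.default_rng(8)
        a = rng.standard_normal(10)
        m1 = 0.7 * a + 0.5 * rng.standard_normal(10)
        m2 = 0.7 * a + 0.5 * rng.standard_normal(10)
        m2[5:] = np.nan
        m = _panel({"A": a + 10, "M1": m1 + 10, "M2": m2 + 10})
        gsc = gene_set_correlation("A", ["M1", "M2"], m)
        r1, n1 = pearson_r(m.values.loc["A"], m.values.loc["M1"])
        r2, n2 = pearson_r(m.values.loc["A"], m.values.loc["M2"])
        want = ((n1 - 3) * fisher_z(r1) + (n2 - 3) * fisher_z(r2)) / (n1 + n2 - 6)
        assert gsc.z_bar == pytest.approx(want, abs=1e-12)

    def test_anchor_removed_and_empty_set_rejected(self, tissue_panel):
        matrix, _ = tissue_panel
        with pytest.raises(EmptySetError):
            gene_set_correlation("PRDM16", ["PRDM16"], matrix)

    def test_se_modes(self, tissue_panel):
        matrix, _ = tissue_panel
        genes = list(DEFAULT_MARKER_SETS["beige"])
        cons = gene_set_correlation("PRDM16", genes, matrix, se_mode="conservative")
        indep = gene_set_correlation("PRDM16", genes, matrix, se_mode="independent")
        assert cons.se == pytest.approx(1 / np.sqrt(15 - 3))
        assert indep.se == pytest.approx(1 / np.sqrt(len(genes) * (15 - 3)))
        assert cons.se > indep.se


class TestCompareSetCorrelations:
    def test_closed_form_example(self):
        # r̄=0.9 vs 0.1 on a 13-sample panel, conservative SE = 1/sqrt(10)
        z = (fisher_z(0.9) - fisher_z(0.1)) / np.sqrt(2 / 10)
        assert z == pytest.approx(3.068, abs=1e-3)
        from scipy import stats as ss

        assert 2 * ss.norm.sf(z) == pytest.approx(0.00215, abs=5e-5)

    def test_equal_sets_give_z_zero_p_one(self, tissue_panel):
        matrix, _ = tissue_panel
        g = gene_set_correlation("PRDM16", ["CITED1", "TMEM26"], matrix, "s")
        v = compare_set_correlations(g, g)
        assert v.z_statistic == 0.0
        assert v.p_value == 1.0

    def test_antisymmetry_under_swap(self, tissue_panel):
        matrix, _ = tissue_panel
        a = gene_set_correlation("PRDM16", list(DEFAULT_MARKER_SETS["beige"]), matrix, "beige")
        b = gene_set_correlation("PRDM16", list(DEFAULT_MARKER_SETS["classical"]), matrix, "classical")
        v1, v2 = compare_set_correlations(a, b), compare_set_correlations(b, a)
        assert v1.z_statistic == pytest.approx(-v2.z_statistic)
        assert v1.p_value == pytest.approx(v2.p_value)
        assert v1.winner == v2.winner
        assert 0 <= v1.p_value <= 1

    def test_mismatched_panels_rejected(self, tissue_panel):
        matrix, _ = tissue_panel
        other, _ = generate_tissue_panel(TissuePanelSimConfig(n_tissues=10, seed=1))
        a = gene_set_correlation("PRDM16", ["CITED1"], matrix)
        b = gene_set_correlation("PRDM16", ["CITED1"], other)
        with pytest.raises(MismatchedPanelsError):
            compare_set_correlations(a, b)

    def test_beige_set_wins_on_factor_panel(self, tissue_panel):
        matrix, _ = tissue_panel
        a = gene_set_correlation("PRDM16", list(DEFAULT_MARKER_SETS["beige"]), matrix, "beige", log2=True)
        b = gene_set_correlation("PRDM16", list(DEFAULT_MARKER_SETS["classical"]), matrix, "classical", log2=True)
        v = compare_set_correlations(a, b)
        assert v.winner == "beige"
        assert v.p_value < 0.01

    def test_null_calibration_conservative(self):
        """Anchor independent of both sets: rejection rate ≤ α + MC error."""
        alpha, reps = 0.05, 2000
        rejections = 0
        beige = list(DEFAULT_MARKER_SETS["beige"])
        classical = list(DEFAULT_MARKER_SETS["classical"])
        for s in range(reps):
            panel, _ = generate_tissue_panel(
                TissuePanelSimConfig(n_tissues=15, beige_loading=0.9, noise_sd=0.3, seed=s)
            )
            panel = add_factor_free_gene(panel, "NULLA", noise_sd=0.3, seed=s)
            a = gene_set_correlation("NULLA", beige, panel, "beige", log2=True)
            b = gene_set_correlation("NULLA", classical, panel, "classical", log2=True)
            rejections += compare_set_correlations(a, b).p_value < alpha
        mc = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert rejections / reps <= alpha + mc


def _brute_force_outliers(values):
    """Literal whisker rule with hand-rolled type-7 quartiles."""
    v = sorted(values)
    n = len(v)

    def quant(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = quant(0.25), quant(0.75)
    iqr = q3 - q1
    return {i for i, x in enumerate(values) if x < q1 - 1.5 * iqr or x > q3 + 1.5 * iqr}


class TestOutliers:
    def test_single_extreme_point_flagged(self):
        e = detect_outliers([1, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        assert e.flagged == ("9",)  # positional id of the value 100
        assert e.q1 == pytest.approx(3.25)
        assert e.q3 == pytest.approx(7.75)
        assert e.whisker_high == 9.0

    def test_constant_vector_has_no_outliers(self):
        e = detect_outliers([5.0] * 6)
        assert e.flagged == ()
        assert e.iqr == 0.0

    def test_symmetric_data_unflagged(self):
        e = detect_outliers([-3, -2, -1, 0, 1, 2, 3])
        assert e.flagged == ()

    def test_insufficient_data_flag(self):
        e = detect_outliers([1.0, 2.0, 3.0])
        assert e.insufficient and e.flagged == ()

    def test_whisker_edges_are_data_points_within_fences(self):
        e = detect_outliers([1, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        assert e.lower_fence <= e.whisker_low <= e.whisker_high <= e.upper_fence
        assert e.whisker_low in (1.0,) and e.whisker_high in (9.0,)

    @given(st.lists(st.integers(min_value=0, max_value=10), min_size=4, max_size=8))
    @settings(max_examples=300, derandomize=True)
    def test_agrees_with_brute_force_rule(self, values):
        e = detect_outliers([float(x) for x in values])
        assert {int(i) for i in e.flagged} == _brute_force_outliers([float(x) for x in values])


class TestFilterGenes:
    def test_threshold_semantics(self):
        clean = list(np.linspace(9.0, 11.0, 10))
        wild = list(np.linspace(9.0, 11.0, 8)) + [500.0, 700.0]
        m = _panel({"CLEAN": clean, "WILD": wild})
        kept, report = filter_genes_by_outliers(m, max_outlier_fraction=0.15)
        assert "CLEAN" in kept.genes
        assert "WILD" not in kept.genes
        assert report.excluded_genes == ["WILD"]
        # a vacuous threshold excludes nothing
        kept_all, _ = filter_genes_by_outliers(m, max_outlier_fraction=1.0)
        assert kept_all.genes == ["CLEAN", "WILD"]


class TestCorrelationMatrix:
    def test_symmetric_with_unit_diagonal(self, tissue_panel):
        matrix, _ = tissue_panel
        cm = correlation_matrix(matrix)
        r = cm.r.to_numpy()
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)

    def test_duplicate_genes_correlate_perfectly(self):
        m = _panel({"X": [1, 2, 3, 4], "Y": [2, 4, 6, 8]})
        cm = correlation_matrix(m)
        assert cm.r.loc["X", "Y"] == pytest.approx(1.0)

    def test_independent_genes_stay_near_zero(self):
        rng = np.random.default_rng(12)
        m = _panel({f"G{i}": rng.lognormal(0, 0.5, 500) for i in range(4)})
        cm = correlation_matrix(m)
        off = cm.r.to_numpy()[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.15)


def _brute_force_upgma(dist: pd.DataFrame):
    """O(n^3) UPGMA over the original item-pair distances."""
    clusters = [frozenset([i]) for i in dist.index]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist.loc[a, b] for a in clusters[i] for b in clusters[j]])
                key = (d, sorted(clusters[i] | clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _), i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


class TestHierarchicalCluster:
    def _cm(self, dist: pd.DataFrame) -> CorrelationMatrix:
        r = 1.0 - dist
        np.fill_diagonal(r.values, 1.0)
        n = pd.DataFrame(10, index=dist.index, columns=dist.columns)
        return CorrelationMatrix(r=r, n=n)

    def test_three_item_hand_example(self):
        dist = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        dend = hierarchical_cluster(self._cm(dist))
        merges = dend.merges()
        assert merges[0] == (frozenset("AB"), pytest.approx(0.1))
        assert merges[1][0] == frozenset("ABC")
        assert merges[1][1] == pytest.approx(0.9)

    def test_duplicate_items_merge_at_zero(self):
        m = _panel({"X": [1, 2, 3, 4], "Y": [2, 4, 6, 8], "Z": [4, 3, 2, 1]})
        cm = correlation_matrix(m)
        dend = hierarchical_cluster(cm)
        first, h = dend.merges()[0]
        assert first == frozenset({"X", "Y"})
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_heights_non_decreasing_and_in_range(self, tissue_panel):
        matrix, _ = tissue_panel
        cm = correlation_matrix(matrix, log2=True)
        dend = hierarchical_cluster(cm)
        h = dend.heights
        assert np.all(np.diff(h) >= -1e-12)
        assert h.min() >= 0.0 and h.max() <= 2.0 + 1e-12

    def test_matches_brute_force_oracle_on_small_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            k = 6
            labels = [f"I{j}" for j in range(k)]
            d = rng.uniform(0.05, 1.9, size=(k, k))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dist = pd.DataFrame(d, index=labels, columns=labels)
            dend = hierarchical_cluster(self._cm(dist))
            oracle = _brute_force_upgma(dist)
            for (got_set, got_h), (want_set, want_h) in zip(dend.merges(), oracle):
                assert got_set == want_set
                assert got_h == pytest.approx(want_h, abs=1e-10)

    def test_newick_export_contains_all_leaves(self, tissue_panel):
        matrix, _ = tissue_panel
        cm = correlation_matrix(matrix, log2=True)
        nwk = hierarchical_cluster(cm).to_newick()
        assert nwk.endswith(";")
        for g in matrix.genes:
            assert g in nwk

    def test_missing_cells_rejected(self):
        r = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=["A", "B"], columns=["A", "B"])
        n = pd.DataFrame(5, index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(CorrelationMatrix(r=r, n=n))
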