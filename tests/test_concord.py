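"""Hit ratios, correlations against direct-formula oracles, call sets,
Venn intersections, the gene rule and the group-difference tests."""

import math

import numpy as np
import pandas as pd
import pytest

from cnvconcord import DataError, InsufficientDataError
from cnvconcord.arraynorm import process_signals
from cnvconcord.concord import (
    anova_tukey,
    build_call_sets,
    build_ratio_table,
    concordance_matrix,
    gene_calls,
    interplatform_hit_ratio,
    interspecies_hit_ratio,
    intersect_sets,
    kruskal_wallis,
    pearson,
    venn_sets,
)
from cnvconcord.hitcount import classify_multicopy, filter_universal
from cnvconcord.synthio import probe_truth


def make_table(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["a_long", "a_short", "b_long", "b_short"]
    ).rename_axis("probe_id")


@pytest.fixture(scope="module")
def collapsed_pipeline(collapsed_dataset):
    d = collapsed_dataset
    universal = filter_universal(d["hit_table"])
    _, multi = classify_multicopy(universal)
    _, acgh = process_signals(d["signals"])
    table = build_ratio_table(universal, acgh)
    return d, table, table.loc[table.index.intersection(multi)]


class TestHitRatios:
    def test_interspecies_ratio_arithmetic(self):
        t = make_table({"p1": [2, 2, 1, 1], "p2": [1, 1, 1, 1]})
        r = interspecies_hit_ratio(t, "longread")
        assert r.loc["p1"] == pytest.approx(1.0)
        assert r.loc["p2"] == pytest.approx(0.0)

    def test_interplatform_ratio_arithmetic(self):
        t = make_table({"p1": [3, 1, 1, 1], "p2": [1, 1, 1, 1]})
        r = interplatform_hit_ratio(t, "a")
        assert r.loc["p1"] == pytest.approx(math.log2(3))
        assert r.loc["p2"] == pytest.approx(0.0)

    def test_zero_count_is_a_contract_violation(self):
        t = make_table({"p1": [1, 1, 0, 1]})
        with pytest.raises(DataError):
            interspecies_hit_ratio(t, "longread")

    def test_longread_ratio_recovers_truth_without_collapse(self, noiseless_dataset):
        d = noiseless_dataset
        universal = filter_universal(d["hit_table"])
        pt = probe_truth(d["probeset"], d["truth"])
        r = interspecies_hit_ratio(universal, "longread")
        np.testing.assert_allclose(r, pt.loc[r.index, "true_log2_ratio"], atol=1e-12)

    def test_interplatform_positive_exactly_for_collapsed_families(self, collapsed_pipeline):
        d, table, _ = collapsed_pipeline
        truth, ps = d["truth"], d["probeset"]
        collapsed_genes = set(truth.loc[truth["collapsed_a"], "gene_id"])
        expected = {
            p for p, g in zip(ps["probe_id"], ps["gene_id"]) if g in collapsed_genes
        }
        positive = set(table.index[table["interplatform_a"] > 0])
        assert positive == expected
        uncollapsed = table.index.difference(expected)
        assert (table.loc[uncollapsed, "interplatform_a"] == 0).all()


class TestPearson:
    def test_perfect_linear_relationships(self, rng):
        x = rng.normal(0, 1, 50)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-30)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        res = pearson(x, y)
        # independent direct computation
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        t = r * math.sqrt((len(x) - 2) / (1 - r * r))
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == 198

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestConcordanceMatrix:
    def test_noiseless_no_collapse_all_pairs_perfect(self, noiseless_dataset):
        d = noiseless_dataset
        universal = filter_universal(d["hit_table"])
        _, multi = classify_multicopy(universal)
        _, acgh = process_signals(d["signals"])
        table = build_ratio_table(universal, acgh).loc[multi]
        res = concordance_matrix(table, mode="all_multicopy")
        for pair, cr in res.items():
            assert cr.r == pytest.approx(1.0, abs=1e-9), pair

    def test_collapse_degrades_shortread_correlation(self):
        # partial collapse, noiseless arrays: short-read ratios flatten to 0
        # at collapsed loci while long-read ratios track the truth
        from conftest import small_config, _build

        d = _build(small_config(noise_sd=0.0, collapse_probability=0.5, seed=42))
        universal = filter_universal(d["hit_table"])
        _, multi = classify_multicopy(universal)
        _, acgh = process_signals(d["signals"])
        table = build_ratio_table(universal, acgh).loc[multi]
        res = concordance_matrix(table, mode="all_multicopy")
        assert res[("acgh", "longread")].r > res[("acgh", "shortread")].r

    def test_nonneutral_pair_mode_drops_doubly_neutral_probes_only(self):
        table = pd.DataFrame(
            {
                "acgh": [0.05, 0.9, 1.2, -0.9, 0.1, 1.4, -1.0, 0.2],
                "hit_longread": [0.0, 1.0, 1.0, -1.0, 0.0, 1.6, -1.0, 1.0],
                "hit_shortread": [0.0, 0.0, 1.0, -1.0, 0.0, 0.0, -1.0, 0.0],
            },
            index=[f"p{i}" for i in range(8)],
        )
        table["interplatform_a"] = 0.0
        table["interplatform_b"] = 0.0
        full = concordance_matrix(table, mode="all_multicopy")
        sub = concordance_matrix(table, mode="nonneutral_pair")
        # p0 and p4 are neutral in every platform; they drop from all pairs
        assert sub[("acgh", "longread")].df == full[("acgh", "longread")].df - 2

    def test_insufficient_probes_raise(self):
        table = pd.DataFrame(
            {
                "acgh": [0.0, 0.0],
                "hit_longread": [0.0, 0.0],
                "hit_shortread": [0.0, 0.0],
                "interplatform_a": [0.0, 0.0],
                "interplatform_b": [0.0, 0.0],
            },
            index=["p1", "p2"],
        )
        with pytest.raises(InsufficientDataError):
            concordance_matrix(table, mode="nonneutral_pair")


class TestCallSetsAndIntersection:
    def test_hit_zero_and_subthreshold_acgh_in_neither_direction(self):
        table = pd.DataFrame(
            {
                "acgh": [0.5, 1.0, -1.0],
                "hit_longread": [0.0, 1.0, -1.0],
                "hit_shortread": [0.0, 0.0, 0.0],
                "interplatform_a": [0.0, 1.0, 0.0],
                "interplatform_b": [0.0, 0.0, 1.0],
            },
            index=["p1", "p2", "p3"],
        )
        sets = build_call_sets(table, 0.8)
        assert "p1" not in sets["acgh"]["a"] and "p1" not in sets["acgh"]["b"]
        assert "p1" not in sets["longread"]["a"] and "p1" not in sets["longread"]["b"]
        assert sets["acgh"]["a"] == {"p2"} and sets["acgh"]["b"] == {"p3"}
        assert sets["longread"]["a"] == {"p2"} and sets["longread"]["b"] == {"p3"}

    def test_identical_sets_fall_in_triple_intersection(self):
        sets = {p: {"a": {"x", "y"}, "b": set()} for p in ("acgh", "longread", "shortread")}
        counts = intersect_sets(sets)["a"]["probes"]
        assert counts["all"] == 2
        assert sum(counts.values()) == 2

    def test_disjoint_sets_fill_exclusive_regions_only(self):
        sets = {
            "acgh": {"a": {"x"}, "b": set()},
            "longread": {"a": {"y"}, "b": set()},
            "shortread": {"a": {"z"}, "b": set()},
        }
        counts = intersect_sets(sets)["a"]["probes"]
        assert counts["acgh_only"] == counts["longread_only"] == counts["shortread_only"] == 1
        assert counts["all"] == 0
        assert sum(counts.values()) == 3

    def test_region_counts_sum_to_union(self, collapsed_pipeline):
        _, _, multic = collapsed_pipeline
        sets = build_call_sets(multic, 0.8)
        for direction in ("a", "b"):
            union = (
                sets["acgh"][direction]
                | sets["longread"][direction]
                | sets["shortread"][direction]
            )
            counts = intersect_sets(sets)[direction]["probes"]
            assert sum(counts.values()) == len(union)

    def test_noiseless_platforms_call_identically_above_threshold(self, noiseless_dataset):
        d = noiseless_dataset
        universal = filter_universal(d["hit_table"])
        _, multi = classify_multicopy(universal)
        _, acgh = process_signals(d["signals"])
        table = build_ratio_table(universal, acgh).loc[multi]
        sets = build_call_sets(table, 0.8)
        pt = probe_truth(d["probeset"], d["truth"])
        expected_a = set(pt.index[pt["true_log2_ratio"] > 0.8]) & set(table.index)
        assert sets["acgh"]["a"] == expected_a
        # hit platforms flag every nonzero ratio, a superset of the aCGH calls
        assert sets["acgh"]["a"] <= sets["longread"]["a"]

    def test_collapsed_families_in_acgh_longread_but_not_shortread_sets(
        self, collapsed_pipeline
    ):
        d, _, multic = collapsed_pipeline
        truth, ps = d["truth"], d["probeset"]
        sets = build_call_sets(multic, 0.8)
        regions = venn_sets(sets, "a")
        strong_collapsed = set(
            truth.loc[
                truth["collapsed_a"]
                & ~truth["collapsed_b"]
                & (np.log2(truth["copies_a"] / truth["copies_b"]) > 0.8),
                "gene_id",
            ]
        )
        probes = {
            p
            for p, g in zip(ps["probe_id"], ps["gene_id"])
            if g in strong_collapsed and p in multic.index
        }
        # noiseless: those probes are gains for aCGH and long-read, shortread misses them
        assert probes <= (regions["acgh_longread"] | regions["all"])
        assert probes & regions["all"] == set()


class TestGeneRule:
    def test_single_gain_probe_lifts_gene(self):
        sets = {"acgh": {"a": {"g1_p0"}, "b": set()}}
        mapping = {"g1_p0": "g1", "g1_p1": "g1", "g1_p2": "g1"}
        genes = gene_calls(sets, mapping)
        assert genes["acgh"]["a"] == {"g1"}

    def test_all_neutral_probes_no_gene_call(self):
        sets = {"acgh": {"a": set(), "b": set()}}
        genes = gene_calls(sets, {"g1_p0": "g1"})
        assert genes["acgh"]["a"] == set()

    def test_intergenic_probes_never_contribute(self):
        sets = {"acgh": {"a": {"ig0001_0", "g1_p0"}, "b": set()}}
        genes = gene_calls(sets, {"g1_p0": "g1", "ig0001_0": ""})
        assert genes["acgh"]["a"] == {"g1"}

    def test_multi_gene_probe_rejected(self):
        sets = {"acgh": {"a": {"p"}, "b": set()}}
        with pytest.raises(DataError):
            gene_calls(sets, {"p": ["g1", "g2"]})

    def test_gene_level_venn_counts_bounded_by_probe_level(self, collapsed_pipeline):
        d, _, multic = collapsed_pipeline
        ps = d["probeset"]
        sets = build_call_sets(multic, 0.8)
        mapping = dict(zip(ps["probe_id"], ps["gene_id"]))
        out = intersect_sets(sets, probe_to_gene=mapping)
        for direction in ("a", "b"):
            probes = out[direction]["probes"]
            genes = out[direction]["genes"]
            assert sum(genes.values()) <= sum(probes.values())


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, df, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and df == 1 and p == 1.0

    def test_matches_hand_computed_rank_formula(self):
        groups = [[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]]
        h, df, p = kruskal_wallis(groups)
        # ranks 1..6, no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        n, rbar1, rbar2 = 6, 2.0, 5.0
        expected = 12 / (n * (n + 1)) * (3 * (rbar1 - 3.5) ** 2 + 3 * (rbar2 - 3.5) ** 2)
        assert h == pytest.approx(expected, abs=1e-12)
        assert df == 1

    def test_invariant_under_monotone_transform(self, rng):
        g1, g2 = rng.normal(0, 1, 30), rng.normal(1, 1, 25)
        h1, _, _ = kruskal_wallis([g1, g2])
        h2, _, _ = kruskal_wallis([np.exp(g1), np.exp(g2)])
        assert h1 == pytest.approx(h2, abs=1e-9)


class TestAnovaTukey:
    def test_equal_groups_degenerate_to_null(self):
        res = anova_tukey({"g1": [1.0, 1.0, 1.0], "g2": [1.0, 1.0, 1.0]})
        assert res["F"] == 0.0
        assert (res["tukey"]["p_adj"] == 1.0).all()

    def test_planted_shift_detected(self, rng):
        res = anova_tukey(
            {
                "base": rng.normal(0.0, 0.3, 100),
                "shifted": rng.normal(1.0, 0.3, 100),
            }
        )
        assert res["tukey"]["p_adj"].iloc[0] < 0.01

    def test_tukey_never_more_liberal_than_unadjusted_t(self, rng):
        from scipy import stats

        groups = {
            "g1": rng.normal(0, 1, 40),
            "g2": rng.normal(0.3, 1, 35),
            "g3": rng.normal(0.5, 1, 30),
        }
        res = anova_tukey(groups)
        names = list(groups)
        for row in res["tukey"].itertuples():
            t_p = stats.ttest_ind(groups[row.group1], groups[row.group2]).pvalue
            assert row.p_adj >= t_p - 1e-9
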