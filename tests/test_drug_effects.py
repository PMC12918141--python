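import math

import numpy as np
import pandas as pd
import pytest

from ubigen.drug_effects import (
    affected_genes_by_drug,
    affected_proportions,
    group_summaries,
    rank_by_bias,
    sector_effect_sizes,
    significant_pairs,
    weighted_mean_score,
)
from ubigen.formats_io import DrugStatsTable, ValidationError
from ubigen.ranking_classification import classify_sectors

from test_ranking_classification import scores_from, uniform_ranking


def stats_table(rows):
    """rows: (gene, drug, conc, p, lfc)"""
    return DrugStatsTable(
        pd.DataFrame(rows, columns=["gene_id", "drug_id", "concentration", "p_value", "log_fc"])
    )


class TestSignificantPairs:
    def test_boundary_is_inclusive(self):
        t = stats_table([("g1", "d1", "c", 0.05, 1.0), ("g2", "d1", "c", 0.051, 1.0)])
        kept = significant_pairs(t)
        assert set(kept.records["gene_id"]) == {"g1"}

    def test_empty_table_stays_empty(self):
        t = stats_table([])
        assert len(significant_pairs(t)) == 0

    def test_alpha_outside_unit_interval_rejected(self):
        t = stats_table([("g1", "d1", "c", 0.01, 1.0)])
        for alpha in (0, 1, -0.5):
            with pytest.raises(ValidationError):
                significant_pairs(t, alpha)


class TestAffectedProportions:
    universe = {f"g{i}" for i in range(10)}
    ubiq = {"g0", "g1", "g2", "g3"}

    def test_hand_counted_fixture(self):
        # drug affects 2 ubiquitous of 4 and 3 non-ubiquitous of 6
        rows = [(g, "d1", "c", 0.01, 1.0) for g in ("g0", "g1", "g4", "g5", "g6")]
        summaries = affected_proportions(stats_table(rows), self.ubiq, self.universe)
        s = summaries["d1"]
        assert s.prop_ubiq == pytest.approx(0.5)
        assert s.prop_nonubiq == pytest.approx(0.5)
        assert s.bias_ratio == pytest.approx(1.0)

    def test_ubiquitous_only_drug(self):
        rows = [(g, "d1", "c", 0.01, 1.0) for g in self.ubiq]
        s = affected_proportions(stats_table(rows), self.ubiq, self.universe)["d1"]
        assert (s.prop_ubiq, s.prop_nonubiq, s.bias_ratio) == (1.0, 0.0, 0.0)

    def test_drug_without_significant_records_has_omitted_ratio(self):
        sig = significant_pairs(
            stats_table([("g0", "d1", "c", 0.9, 1.0), ("g4", "d2", "c", 0.01, 1.0)])
        )
        # d1 keeps no records, so it is absent from the significant table;
        # a drug present but hitting nothing gets both proportions 0
        summaries = affected_proportions(sig, self.ubiq, self.universe)
        assert "d1" not in summaries
        empty = affected_proportions(stats_table([("g99", "d3", "c", 0.01, 1.0)]),
                                     self.ubiq, self.universe)["d3"]
        assert empty.prop_ubiq == empty.prop_nonubiq == 0.0
        assert empty.bias_ratio is None

    def test_any_significant_concentration_counts_once(self):
        rows = [("g0", "d1", "c1", 0.01, 1.0), ("g0", "d1", "c2", 0.02, 2.0)]
        s = affected_proportions(stats_table(rows), self.ubiq, self.universe)["d1"]
        assert s.n_affected_ubiq == 1

    def test_denominators_constant_across_drugs(self):
        rows = [("g0", "d1", "c", 0.01, 1.0), ("g4", "d2", "c", 0.01, 1.0)]
        summaries = affected_proportions(stats_table(rows), self.ubiq, self.universe)
        assert {s.n_ubiq_total for s in summaries.values()} == {4}
        assert {s.n_nonubiq_total for s in summaries.values()} == {6}

    def test_bias_ratio_below_one_iff_ubiquitous_biased(self, rng):
        for _ in range(20):
            n_u = int(rng.integers(0, 5))
            n_n = int(rng.integers(0, 7))
            rows = [(f"g{i}", "d", "c", 0.01, 1.0) for i in range(n_u)]
            rows += [(f"g{4 + i}", "d", "c", 0.01, 1.0) for i in range(n_n)]
            if not rows:
                continue
            s = affected_proportions(stats_table(rows), self.ubiq, self.universe)["d"]
            if s.bias_ratio is not None and math.isfinite(s.bias_ratio):
                assert (s.bias_ratio < 1) == (s.prop_ubiq > s.prop_nonubiq)

    def test_invalid_sets_rejected(self):
        t = stats_table([("g0", "d1", "c", 0.01, 1.0)])
        with pytest.raises(ValidationError):
            affected_proportions(t, {"gX"}, self.universe)  # not a subset
        with pytest.raises(ValidationError):
            affected_proportions(t, self.universe, self.universe)  # empty complement

    def test_filter_then_group_commutes(self):
        rows = [("g0", "d1", "c", 0.01, 2.0), ("g4", "d1", "c", 0.5, 9.0),
                ("g5", "d1", "c", 0.03, 1.0)]
        t = stats_table(rows)
        direct = affected_proportions(significant_pairs(t), self.ubiq, self.universe)["d1"]
        assert direct.n_affected_ubiq == 1 and direct.n_affected_nonubiq == 1
        # the non-significant g4 record contributes to neither count nor mean
        assert direct.mean_abs_lfc == pytest.approx(1.5)


class TestRankByBias:
    def make(self, ratios):
        from ubigen.drug_effects import DrugEffectSummary

        return {
            d: DrugEffectSummary(d, 0, 0, 0.1, 0.1 * (r if r is not None and math.isfinite(r) else 1),
                                 r, 0.0)
            for d, r in ratios.items()
        }

    def test_sorted_ends(self):
        summaries = self.make({"d1": 0.2, "d2": 1.0, "d3": 5.0})
        ubiq_biased, non_biased = rank_by_bias(summaries, top_n=1)
        assert (ubiq_biased, non_biased) == (["d1"], ["d3"])

    def test_infinite_ratio_sorts_above_finite(self):
        summaries = self.make({"d1": 0.5, "dinf": math.inf, "d3": 100.0})
        _, non_biased = rank_by_bias(summaries, top_n=2)
        assert non_biased == ["dinf", "d3"]

    def test_ties_broken_by_drug_id_and_undefined_excluded(self):
        summaries = self.make({"b": 1.0, "a": 1.0, "c": None})
        ubiq_biased, non_biased = rank_by_bias(summaries, top_n=3)
        assert ubiq_biased == ["a", "b"] == non_biased

    def test_single_drug_in_both_lists(self):
        summaries = self.make({"only": 2.0})
        assert rank_by_bias(summaries) == (["only"], ["only"])


class TestGroupSummaries:
    universe = {f"g{i}" for i in range(10)}
    ubiq = {"g0", "g1", "g2", "g3"}

    def drug_summaries(self):
        rows = [("g0", "d1", "c", 0.01, 1.0),  # d1: 1 ubiq, 0 non
                ("g0", "d2", "c", 0.01, 3.0), ("g1", "d2", "c", 0.01, 1.0),  # d2: 2 ubiq
                ("g4", "d3", "c", 0.01, 2.0)]  # d3: 1 non-ubiq
        return affected_proportions(stats_table(rows), self.ubiq, self.universe)

    def test_single_drug_group_identical(self):
        summaries = self.drug_summaries()
        groups, skipped = group_summaries(summaries, {"d1": "solo"})
        assert skipped == 2
        assert groups["solo"].prop_ubiq == summaries["d1"].prop_ubiq

    def test_mean_of_member_proportions(self):
        summaries = self.drug_summaries()
        groups, _ = group_summaries(summaries, {"d1": "g", "d2": "g"})
        # props 0.25 and 0.5 -> mean 0.375; mean |lfc| (1.0 and 2.0) -> 1.5
        assert groups["g"].prop_ubiq == pytest.approx(0.375)
        assert groups["g"].mean_abs_lfc == pytest.approx(1.5)

    def test_pooled_mode_uses_pooled_counts(self):
        summaries = self.drug_summaries()
        groups, _ = group_summaries(summaries, {"d1": "g", "d2": "g"}, pooled=True)
        # 3 affected ubiquitous gene-drug pairs over 2*4 slots
        assert groups["g"].prop_ubiq == pytest.approx(3 / 8)

    def test_empty_grouping_rejected(self):
        with pytest.raises(ValidationError):
            group_summaries(self.drug_summaries(), {})


class TestWeightedMeanScore:
    scores = scores_from({"g0": 0.9, "g1": 0.1, "g2": 0.5})

    def test_single_gene_returns_its_score(self):
        t = stats_table([("g0", "d1", "c", 0.01, 2.0)])
        assert weighted_mean_score(t, self.scores, "d1") == pytest.approx(0.9)

    def test_equal_weights_give_arithmetic_mean(self):
        t = stats_table([("g0", "d1", "c", 0.01, 2.0), ("g1", "d1", "c", 0.01, -2.0)])
        assert weighted_mean_score(t, self.scores, "d1") == pytest.approx(0.5)

    def test_weighted_case(self):
        t = stats_table([("g0", "d1", "c", 0.01, 3.0), ("g1", "d1", "c", 0.01, 1.0)])
        assert weighted_mean_score(t, self.scores, "d1") == pytest.approx(0.7)

    def test_max_collapse_across_concentrations(self):
        t = stats_table([("g0", "d1", "c1", 0.01, 1.0), ("g0", "d1", "c2", 0.01, -3.0),
                         ("g1", "d1", "c1", 0.01, 1.0)])
        # g0 weight max(1,3)=3, g1 weight 1 -> (3*0.9 + 0.1)/4
        assert weighted_mean_score(t, self.scores, "d1") == pytest.approx(0.7)

    def test_all_zero_lfc_warns_and_averages(self):
        t = stats_table([("g0", "d1", "c", 0.01, 0.0), ("g1", "d1", "c", 0.01, 0.0)])
        with pytest.warns(UserWarning, match="unweighted"):
            assert weighted_mean_score(t, self.scores, "d1") == pytest.approx(0.5)

    def test_no_scored_gene_rejected(self):
        t = stats_table([("absent", "d1", "c", 0.01, 1.0)])
        with pytest.raises(ValidationError):
            weighted_mean_score(t, self.scores, "d1")


class TestSectorEffectSizes:
    def make_sectors(self):
        a = uniform_ranking(40)
        b = scores_from({f"g{i:06d}": (41 - i) / 41 if i >= 2 else 0.01 for i in range(40)})
        return classify_sectors(a, b)  # g000000/1 -> "10", g000002/3 -> "01"

    def test_mean_within_sector(self):
        sec = self.make_sectors()
        t = stats_table([("g000000", "d1", "c", 0.01, 1.0), ("g000001", "d1", "c", 0.01, -3.0)])
        out = sector_effect_sizes(t, sec)
        assert out.loc["10", "mean_abs_lfc"] == pytest.approx(2.0)
        assert "00" not in out.index  # missing, not zero

    def test_grouped_by_drug_label(self):
        sec = self.make_sectors()
        t = stats_table([("g000000", "d1", "c", 0.01, 1.0), ("g000000", "d2", "c", 0.01, 5.0)])
        out = sector_effect_sizes(t, sec, grouping={"d1": "L", "d2": "N"})
        assert out.loc[("10", "L"), "mean_abs_lfc"] == 1.0
        assert out.loc[("10", "N"), "mean_abs_lfc"] == 5.0

    def test_planted_sector_10_has_largest_effects(self, paired, synth_scores):
        # generator knock-downs (sector-10 genes) receive the broad drugs'
        # large planted effects; construct a table where knocked genes get
        # bigger |lfc| and confirm recovery of the ordering
        from ubigen.scoring_core import compose_scores

        ta = compose_scores(paired.a)
        tb = compose_scores(paired.b)
        sec = classify_sectors(ta, tb, top_fraction=0.2)
        rng = np.random.default_rng(7)
        rows = []
        for g in sorted(sec.shared_genes)[::5]:
            big = g in paired.knocked_down
            rows.append((g, "d1", "c", 0.01, rng.normal(3.0 if big else 0.5, 0.1)))
        out = sector_effect_sizes(stats_table(rows), sec)
        if {"10", "00"} <= set(out.index):
            assert out.loc["10", "mean_abs_lfc"] > out.loc["00", "mean_abs_lfc"]
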