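import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idap.evidence_kg import Category, KGCandidate
from idap.evidence_literature import MentionCounts
from idap.evidence_oncokb import OncoKBDrugEvidence
from idap.evidence_trials import TrialSummary
from idap.integrate_rank import (
    BenchmarkResult,
    WeightConfig,
    benchmark_truthset,
    combined_score,
    merge_and_rank,
    weight_sensitivity,
    within_sample_percentile,
)


def kg_cand(drug, score):
    return KGCandidate(
        drug=drug,
        category=Category.REPURPOSING_PRIORITY,
        targeted_mutated_genes=frozenset({"G1"}),
        fda_approved=True,
        txgnn_score=score,
    )


def mentions_of(**totals):
    return MentionCounts(per_gene_drug={("G1", d): n for d, n in totals.items()})


def trial_summary(drug, n=2, nct="NCT00000001", phase="PHASE3"):
    return TrialSummary(drug, n, nct, phase, "title")


class TestPercentile:
    def test_single_value(self):
        assert within_sample_percentile([5]) == [1.0]

    def test_ties_share_percentile(self):
        assert within_sample_percentile([0, 10, 10, 40]) == [0.25, 0.75, 0.75, 1.0]

    def test_all_equal_gives_one(self):
        assert within_sample_percentile([3, 3, 3]) == [1.0, 1.0, 1.0]

    def test_empty(self):
        assert within_sample_percentile([]) == []

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_counting_oracle_and_range(self, values):
        n = len(values)
        got = within_sample_percentile(values)
        for v, p in zip(values, got):
            assert p == sum(1 for u in values if u <= v) / n
            assert 0 < p <= 1


class TestCombinedScore:
    def test_maximal_row(self):
        assert combined_score(1, 1, 1, 3, True, 1) == pytest.approx(1.75, abs=1e-15)

    def test_all_zero(self):
        assert combined_score(0, 0, 0, 0, False, 0) == 0.0

    def test_partial_row(self):
        # 0.5*0.5 + 0 + 0 + 0.20*0 + 0 + 0.05*1
        assert combined_score(0.5, 0, 0, 1, False, 1) == pytest.approx(0.30, abs=1e-15)

    def test_custom_weights_substitute(self):
        w = WeightConfig(w_tx=1.0, w_pm=0.0, w_ok=0.0)
        assert combined_score(0.25, 0.9, 0.9, 1, False, 0, w) == pytest.approx(0.25)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightConfig(w_tx=-0.1)


class TestMergeAndRank:
    def rank(self, weights=None, with_trials=True):
        oncokb = OncoKBDrugEvidence(scores={"AAA": 4.0}, best_level={"AAA": "LEVEL_1"})
        mentions = mentions_of(AAA=2, BBB=5)
        kg = [kg_cand("BBB", 100.0), kg_cand("CCC", 110.0)]
        trials = {"AAA": trial_summary("AAA")} if with_trials else {}
        return merge_and_rank(oncokb, mentions, kg, trials, weights)

    def test_universe_is_union_of_score_layers(self):
        ranked = self.rank()
        assert sorted(ranked["drug"]) == ["AAA", "BBB", "CCC"]

    def test_single_layer_membership(self):
        ranked = self.rank().set_index("drug")
        # AAA: mentions + oncokb, no kg
        assert ranked.loc["AAA", "support_count"] == 2
        assert ranked.loc["CCC", "support_count"] == 1
        assert ranked.loc["CCC", "clinical_flag"] == 0

    def test_trial_only_drugs_excluded(self):
        oncokb = OncoKBDrugEvidence()
        ranked = merge_and_rank(
            oncokb, mentions_of(AAA=1), [], {"ZZZ": trial_summary("ZZZ")}
        )
        assert list(ranked["drug"]) == ["AAA"]

    def test_ranks_are_permutation(self):
        ranked = self.rank()
        assert sorted(ranked["rank"]) == [1, 2, 3]

    def test_empty_universe(self):
        ranked = merge_and_rank(OncoKBDrugEvidence(), MentionCounts(), [], {})
        assert len(ranked) == 0 and "combined_score" in ranked.columns

    def test_alphabetical_tie_break_order_independent(self):
        # two drugs with identical evidence in every layer
        mentions = mentions_of(XX=3, YY=3)
        kg = [kg_cand("XX", 50.0), kg_cand("YY", 50.0)]
        ranked = merge_and_rank(OncoKBDrugEvidence(), mentions, kg, {})
        assert list(ranked["drug"]) == ["XX", "YY"]
        ranked_rev = merge_and_rank(OncoKBDrugEvidence(), mentions, kg[::-1], {})
        assert list(ranked_rev["drug"]) == ["XX", "YY"]

    def test_deterministic_repeat(self):
        a, b = self.rank(), self.rank()
        pd.testing.assert_frame_equal(a, b)

    def test_rank_invariant_under_monotone_transform(self):
        base = self.rank()
        for transform in (lambda x: 2 * x + 7, lambda x: x**3):
            oncokb = OncoKBDrugEvidence(scores={"AAA": 4.0}, best_level={})
            mentions = mentions_of(AAA=2, BBB=5)
            kg = [kg_cand("BBB", transform(100.0)), kg_cand("CCC", transform(110.0))]
            ranked = merge_and_rank(oncokb, mentions, kg, {"AAA": trial_summary("AAA")})
            assert list(ranked["drug"]) == list(base["drug"])
            pd.testing.assert_series_equal(ranked["combined_score"], base["combined_score"])

    def test_max_attainable_never_exceeded(self):
        rng = random.Random(3)
        for _ in range(20):
            drugs = [f"D{i}" for i in range(rng.randint(1, 8))]
            oncokb = OncoKBDrugEvidence(
                scores={d: float(rng.randint(0, 4)) for d in drugs}, best_level={}
            )
            mentions = MentionCounts(
                per_gene_drug={("G", d): rng.randint(0, 9) for d in drugs}
            )
            kg = [kg_cand(d, float(rng.randint(0, 120))) for d in drugs]
            trials = {d: trial_summary(d) for d in drugs if rng.random() < 0.5}
            ranked = merge_and_rank(oncokb, mentions, kg, trials)
            assert (ranked["combined_score"] <= 1.75 + 1e-12).all()


class TestWeightSensitivity:
    def layers(self):
        # txgnn and mention layers order drugs oppositely
        mentions = mentions_of(AA=9, BB=1)
        kg = [kg_cand("AA", 10.0), kg_cand("BB", 100.0)]
        return OncoKBDrugEvidence(), mentions, kg, {}

    def test_opposed_layers_flip_top1(self):
        oncokb, mentions, kg, trials = self.layers()
        configs = [WeightConfig(1, 0, 0), WeightConfig(0, 1, 0)]
        result = weight_sensitivity(oncokb, mentions, kg, trials, configs)
        tops = [r.top1 for r in result.rows]
        assert tops[0] != tops[1]
        assert not result.top1_stable

    def test_default_self_comparison_full_overlap(self):
        oncokb, mentions, kg, trials = self.layers()
        result = weight_sensitivity(
            oncokb, mentions, kg, trials, [WeightConfig(), WeightConfig()]
        )
        assert all(r.topk_overlap == 1.0 for r in result.rows)
        assert result.top1_stable

    def test_requires_two_configs(self):
        with pytest.raises(ValueError):
            weight_sensitivity(*self.layers(), configs=[WeightConfig()])


class TestBenchmark:
    def ranked(self, drugs):
        return pd.DataFrame({"drug": drugs, "rank": range(1, len(drugs) + 1)})

    def test_direct_scan(self):
        result = benchmark_truthset(self.ranked(["A", "B", "C"]), {"C"})
        assert result == BenchmarkResult(True, True, 3, True)

    def test_empty_truth_not_eligible(self):
        assert benchmark_truthset(self.ranked(["A"]), set()).eligible is False

    def test_empty_ranking_not_recovered(self):
        result = benchmark_truthset(self.ranked([]), {"X"})
        assert result.eligible and not result.recovered
        assert result.first_match_rank is None and not result.top10_hit

    def test_rank_beyond_ten_not_top10(self):
        drugs = [f"D{i:02d}" for i in range(12)] + ["TRUTH"]
        result = benchmark_truthset(self.ranked(drugs), {"TRUTH"})
        assert result.recovered and result.first_match_rank == 13
        assert not result.top10_hit
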