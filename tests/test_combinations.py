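"""Subset evaluation, attainment, burden ratios and greedy cover."""

import statistics
from itertools import chain, combinations as itercombos

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbcombo.combinations import (
    UniqueContribution,
    attainment,
    evaluate_all_subsets,
    evaluate_combination,
    greedy_cover,
    precision_improvement_ratio,
    results_reduction_distribution,
    results_reduction_ratio,
    select_candidates,
    stratified_attainment,
    unique_contributions,
)
from dbcombo.exceptions import (
    NoEvaluableReviewError,
    TargetUnreachableError,
    TooManyCandidatesError,
)
from dbcombo.model import Corpus
from dbcombo.synth import generate_corpus, truth_recount

from conftest import make_review, small_config


def nonempty_subsets(databases):
    dbs = sorted(databases)
    return [
        frozenset(c)
        for c in chain.from_iterable(itercombos(dbs, n) for n in range(1, len(dbs) + 1))
    ]


class TestUniqueContributions:
    def test_hand_enumerable(self):
        review = make_review(
            "r", ["A_DB", "B_DB"], [{"A_DB"}, {"A_DB", "B_DB"}, {"B_DB"}, {"B_DB"}]
        )
        summary = unique_contributions(Corpus(reviews=(review,)))
        by_db = {c.database: c.n_unique_refs for c in summary.per_database}
        assert by_db == {"A_DB": 1, "B_DB": 2}
        assert summary.total_unique == 3

    def test_everything_overlapping_gives_zero(self):
        review = make_review("r", ["A_DB", "B_DB"], [{"A_DB", "B_DB"}] * 4)
        summary = unique_contributions(Corpus(reviews=(review,)))
        assert summary.total_unique == 0

    def test_matches_truth_ledger_recount(self, small_synth):
        corpus, truth = small_synth
        summary = unique_contributions(corpus)
        for contribution in summary.per_database:
            d = contribution.database
            oracle = sum(
                sum(1 for m in t.include_membership if m == {d})
                for t in truth.reviews
                if d in t.searched
            )
            assert contribution.n_unique_refs == oracle
        assert summary.total_unique == sum(
            sum(1 for m in t.include_membership if len(m) == 1) for t in truth.reviews
        )

    def test_conservation_of_unique_counts(self, small_synth):
        corpus, _ = small_synth
        summary = unique_contributions(corpus)
        single_provenance = sum(
            sum(1 for inc in r.retrieved_includes if len(inc.retrieved_by) == 1)
            for r in corpus.reviews
        )
        assert sum(c.n_unique_refs for c in summary.per_database) == single_provenance


class TestSelectCandidates:
    BENCH = [
        UniqueContribution("EMBASE", 58, 29, 132),
        UniqueContribution("MEDLINE", 58, 27, 69),
        UniqueContribution("WOS", 58, 19, 37),
        UniqueContribution("GS", 58, 24, 37),
        UniqueContribution("CINAHL", 18, 1, 6),
        UniqueContribution("SCOPUS", 24, 3, 5),
        UniqueContribution("PSYCINFO", 11, 1, 2),
        UniqueContribution("SPORTDISCUS", 2, 2, 3),
    ]

    def test_benchmark_top_four(self):
        top = select_candidates(self.BENCH, k=4)
        assert top[:2] == ["EMBASE", "MEDLINE"]
        assert set(top[2:]) == {"WOS", "GS"}  # tied at 37 unique references
        assert top[2] == "GS"  # tie broken by reviews-with-unique (24 > 19)

    def test_k_beyond_size_gives_full_ordering(self):
        assert len(select_candidates(self.BENCH, k=50)) == len(self.BENCH)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 58)),
            min_size=1,
            max_size=8,
        )
    )
    def test_agrees_with_sort_oracle(self, rows):
        table = [
            UniqueContribution(f"DB{i}", 58, reviews, uniques)
            for i, (uniques, reviews) in enumerate(rows)
        ]
        oracle = sorted(
            table, key=lambda c: (-c.n_unique_refs, -c.n_reviews_with_unique, c.database)
        )
        assert select_candidates(table, k=len(table)) == [c.database for c in oracle]


class TestEvaluateCombination:
    def test_single_review_full_combo_is_perfect(self, tiny_corpus):
        perf = evaluate_combination(tiny_corpus, {"EMBASE", "MEDLINE"})
        assert perf.overall_recall == perf.median_recall == perf.min_recall == 1.0
        assert perf.pct_reviews_full_recall == 1.0

    def test_unsearched_combination_has_no_evaluable_review(self, tiny_corpus):
        with pytest.raises(NoEvaluableReviewError):
            evaluate_combination(tiny_corpus, {"EMBASE", "CINAHL"})

    def test_subset_count_and_order(self, small_synth):
        corpus, _ = small_synth
        rows = evaluate_all_subsets(corpus, ["EMBASE", "MEDLINE", "WOS", "GS"])
        assert len(rows) == 15
        sizes = [len(r.combo) for r in rows]
        assert sizes == sorted(sizes)
        for row in rows:
            assert row == evaluate_combination(corpus, row.combo)

    def test_candidate_cap(self, small_synth):
        corpus, _ = small_synth
        with pytest.raises(TooManyCandidatesError):
            evaluate_all_subsets(corpus, [f"D{i}" for i in range(13)])

    @pytest.mark.parametrize("seed", [3, 4])
    def test_equals_truth_recount_for_all_subsets(self, seed):
        corpus, truth = generate_corpus(small_config(seed=seed))
        for combo in nonempty_subsets({"EMBASE", "MEDLINE", "WOS", "GS", "COCHRANE_CENTRAL"}):
            oracle = truth_recount(truth, combo)
            perf = evaluate_combination(corpus, combo)
            assert perf.includes_retrieved == oracle.pooled.includes_retrieved
            assert perf.includes_total == oracle.pooled.includes_total
            assert perf.results_total_dedup == oracle.pooled.results_total
            per_review = [
                m.recall for m in oracle.per_review.values() if m.includes_total > 0
            ]
            assert perf.median_recall == pytest.approx(statistics.median(per_review))
            assert perf.min_recall == pytest.approx(min(per_review))

    def test_precision_nnr_reciprocity(self, small_synth):
        corpus, _ = small_synth
        for row in evaluate_all_subsets(corpus, ["EMBASE", "MEDLINE", "GS"]):
            assert row.precision * row.nnr == pytest.approx(1.0)

    def test_monotone_in_nested_combos(self, small_synth):
        corpus, _ = small_synth
        order = ["GS", "WOS", "MEDLINE", "EMBASE"]
        prev = None
        for size in range(1, 5):
            perf = evaluate_combination(corpus, frozenset(order[:size]))
            if prev is not None:
                assert perf.includes_retrieved >= prev.includes_retrieved
                assert perf.results_total_dedup >= prev.results_total_dedup
                assert perf.overall_recall >= prev.overall_recall - 1e-12
            prev = perf


class TestAttainment:
    def _recall_corpus(self, recalls):
        """One review per desired recall value: n includes, k found by A_DB."""
        reviews = []
        for i, target in enumerate(recalls):
            n = 20
            k = round(target * n)
            prov = [{"A_DB"}] * k + [{"B_DB"}] * (n - k)
            reviews.append(make_review(f"r{i}", ["A_DB", "B_DB"], prov))
        return Corpus(reviews=tuple(reviews))

    def test_hand_count(self):
        corpus = self._recall_corpus([1.0, 0.96, 0.90, 0.50])
        row = attainment(corpus, {"A_DB"}, thresholds=(1.0, 0.95, 0.90, 0.80))
        assert row.at(0.95) == pytest.approx(0.5)
        assert row.at(0.90) == pytest.approx(0.75)

    def test_threshold_one_equals_full_recall_share(self, small_synth):
        corpus, _ = small_synth
        combo = frozenset({"EMBASE", "MEDLINE"})
        row = attainment(corpus, combo)
        assert row.at(1.0) == pytest.approx(
            evaluate_combination(corpus, combo).pct_reviews_full_recall
        )

    def test_non_increasing_in_threshold(self, small_synth):
        corpus, _ = small_synth
        for combo in nonempty_subsets({"EMBASE", "GS", "WOS"}):
            row = attainment(corpus, combo)
            pct = list(row.pct_reviews_at_or_above)
            assert pct == sorted(pct)  # thresholds descend, shares ascend

    def test_strict_comparator_never_exceeds_inclusive(self):
        corpus = self._recall_corpus([1.0, 0.95, 0.90])
        inclusive = attainment(corpus, {"A_DB"}, thresholds=(0.95,))
        strict = attainment(corpus, {"A_DB"}, thresholds=(0.95,), strict=True)
        assert strict.at(0.95) <= inclusive.at(0.95)
        assert inclusive.at(0.95) == pytest.approx(2 / 3)
        assert strict.at(0.95) == pytest.approx(1 / 3)

    def test_matches_truth_recount(self, small_synth):
        corpus, truth = small_synth
        combo = frozenset({"EMBASE", "WOS"})
        oracle = truth_recount(truth, combo)
        recalls = [m.recall for m in oracle.per_review.values() if m.includes_total > 0]
        row = attainment(corpus, combo, thresholds=(0.9,))
        assert row.at(0.9) == pytest.approx(
            sum(1 for x in recalls if x >= 0.9) / len(recalls)
        )

    def test_single_group_equals_unstratified(self, small_synth):
        import dataclasses

        corpus, _ = small_synth
        # strip the key so everything lands in one group
        stripped = Corpus(
            reviews=tuple(dataclasses.replace(r, metadata={}) for r in corpus.reviews)
        )
        groups = stratified_attainment(stripped, {"EMBASE"}, "domain")
        assert set(groups) == {"unknown"}
        assert groups["unknown"] == attainment(stripped, {"EMBASE"})

    def test_planted_domain_effect_recovers_ordering(self):
        config = small_config(
            seed=21,
            n_reviews=40,
            noise_pool_mean=0.0,
            domain_effect={"therapy": 1.0, "etiology": 0.45},
        )
        corpus, _ = generate_corpus(config)
        groups = stratified_attainment(corpus, {"EMBASE", "MEDLINE"}, "domain", (0.9,))
        assert groups["therapy"].at(0.9) > groups["etiology"].at(0.9)


class TestBurdenRatios:
    def test_full_set_ratio_is_one(self, small_synth):
        corpus, _ = small_synth
        review = corpus.reviews[0]
        assert results_reduction_ratio(review, review.searched_databases) == 1.0
        assert precision_improvement_ratio(review, review.searched_databases) == pytest.approx(1.0)

    def test_half_results_all_includes_doubles_precision(self):
        # A_DB finds every include with half the records of the full search
        review = make_review(
            "r", ["A_DB", "B_DB"], [{"A_DB"}] * 5, n_noise_per_db={"A_DB": 45, "B_DB": 50}
        )
        assert precision_improvement_ratio(review, {"A_DB"}) == pytest.approx(2.0)
        assert results_reduction_ratio(review, {"A_DB"}) == pytest.approx(0.5)

    def test_reduction_matches_naive_union(self, small_synth):
        corpus, truth = small_synth
        combo = frozenset({"MEDLINE", "GS"})
        for review, rtruth in zip(corpus.reviews, truth.reviews):
            members = list(rtruth.include_membership) + list(rtruth.noise_membership)
            num = sum(1 for m in members if m & combo)
            den = sum(1 for m in members if m)
            assert results_reduction_ratio(review, combo) == pytest.approx(num / den)

    def test_distribution_summary_bounds(self, small_synth):
        corpus, _ = small_synth
        summary = results_reduction_distribution(corpus, {"EMBASE"})
        assert 0 <= summary["min"] <= summary["q1"] <= summary["median"]
        assert summary["median"] <= summary["q3"] <= summary["max"] <= 1.0


class TestGreedyCover:
    def _corpus(self):
        # A_DB alone reaches 0.9 everywhere; C_DB adds the remainder
        reviews = [
            make_review(f"r{i}", ["A_DB", "B_DB", "C_DB"],
                        [{"A_DB"}] * 9 + [{"C_DB"}])
            for i in range(4)
        ]
        return Corpus(reviews=tuple(reviews))

    def test_single_database_suffices(self):
        assert greedy_cover(self._corpus(), target_recall=0.9, target_share_of_reviews=1.0) == ["A_DB"]

    def test_full_recall_needs_both_contributors(self):
        chosen = greedy_cover(self._corpus(), target_recall=1.0, target_share_of_reviews=1.0)
        assert set(chosen) == {"A_DB", "C_DB"}

    def test_unreachable_target_raises(self, tiny_corpus):
        big = Corpus(
            reviews=tuple(
                make_review(f"r{i}", ["A_DB", "B_DB"], [{"A_DB"}, {"B_DB"}])
                for i in range(3)
            )
        )
        # per-review recall of any single database is 0.5; both give 1.0
        with pytest.raises(TargetUnreachableError):
            greedy_cover(big, target_recall=1.0, target_share_of_reviews=1.0, candidates=["A_DB"])

    @pytest.mark.parametrize("seed", [5, 6])
    def test_never_beats_exhaustive_optimum(self, seed):
        corpus, _ = generate_corpus(
            small_config(seed=seed, n_reviews=8, noise_pool_mean=0.0)
        )
        pool = ["EMBASE", "MEDLINE", "WOS", "GS", "COCHRANE_CENTRAL"]
        target = 0.95
        chosen = greedy_cover(corpus, target, target_share_of_reviews=0.5, candidates=pool)
        share_chosen = attainment(corpus, frozenset(chosen), (target,)).at(target)
        best = max(
            attainment(corpus, combo, (target,)).at(target)
            for combo in nonempty_subsets(pool)
        )
        assert share_chosen <= best + 1e-12
        assert share_chosen >= 0.5  # it did reach the requested share
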