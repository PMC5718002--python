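"""Exhaustive evaluation of database combinations over a review corpus.

Given a corpus with provenance attached, this module answers the
questions a search specialist deciding which databases to search
actually asks:

* Which databases contribute references no other database found
  (:func:`unique_contributions`), and which are therefore candidates
  for the core combination (:func:`select_candidates`)?
* How does every subset of the candidates perform — overall recall,
  per-review median and minimum recall, share of reviews at full
  recall, precision, number needed to read
  (:func:`evaluate_combination`, :func:`evaluate_all_subsets`)?
* For how many reviews does a combination reach a recall threshold
  (:func:`attainment`, :func:`stratified_attainment`)?
* What does a smaller combination buy in screening burden — fewer
  records (:func:`results_reduction_ratio`) and higher precision
  (:func:`precision_improvement_ratio`)?
* Which databases would a cost-aware greedy set cover pick to reach a
  target recall in a target share of reviews (:func:`greedy_cover`)?

A review enters a combination's statistics only when it searched every
member of that combination; evaluating an unsearched database as a
miss would bias recall downward.  Deduplicated result counts are
computed exactly from record membership whenever records are present;
a corpus carrying only per-database counts falls back to their sum,
flagged as not deduplicated.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from itertools import combinations as _itercombos
from typing import Iterable, Mapping, Sequence

from .exceptions import (
    EmptyDenominatorError,
    NoEvaluableReviewError,
    TargetUnreachableError,
    TooManyCandidatesError,
)
from .metrics import review_recall
from .model import Combo, Corpus, ReviewDataset, combo_name

__all__ = [
    "CombinationPerformance",
    "AttainmentRow",
    "UniqueContribution",
    "UniqueContributionSummary",
    "unique_contributions",
    "select_candidates",
    "evaluate_combination",
    "evaluate_all_subsets",
    "attainment",
    "stratified_attainment",
    "results_reduction_ratio",
    "results_reduction_distribution",
    "precision_improvement_ratio",
    "precision_improvement_distribution",
    "greedy_cover",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (1.00, 0.95, 0.90, 0.80)
MAX_CANDIDATES = 12
_FULL = 1.0 - 1e-12  # tolerance for "recall is exactly 1" on float division


@dataclass(frozen=True)
class CombinationPerformance:
    """One row of the combination performance table."""

    combo: Combo
    n_reviews_evaluated: int
    results_total_dedup: int
    includes_retrieved: int
    includes_total: int
    overall_recall: float
    median_recall: float
    min_recall: float
    pct_reviews_full_recall: float
    precision: float
    nnr: float
    dedup_exact: bool = True

    @property
    def name(self) -> str:
        return combo_name(self.combo)


@dataclass(frozen=True)
class AttainmentRow:
    """Share of reviews on which a combination reaches each recall threshold."""

    combo: Combo
    thresholds: tuple[float, ...]
    pct_reviews_at_or_above: tuple[float, ...]
    n_reviews: int

    def at(self, threshold: float) -> float:
        return self.pct_reviews_at_or_above[self.thresholds.index(threshold)]


@dataclass(frozen=True)
class UniqueContribution:
    database: str
    n_reviews_used: int
    n_reviews_with_unique: int
    n_unique_refs: int


@dataclass(frozen=True)
class UniqueContributionSummary:
    per_database: tuple[UniqueContribution, ...]
    total_unique: int
    retrieved_includes_total: int

    @property
    def unique_share(self) -> float:
        if self.retrieved_includes_total == 0:
            raise EmptyDenominatorError("no retrieved includes in corpus")
        return self.total_unique / self.retrieved_includes_total


# ---------------------------------------------------------------------------
# unique references and candidate selection


def unique_contributions(corpus: Corpus) -> UniqueContributionSummary:
    """Count includes whose provenance is exactly one database.

    These "unique references" measure what each database adds that no
    other searched database found — the basis for choosing candidate
    databases.
    """
    databases = sorted(corpus.all_databases)
    rows = []
    total_unique = 0
    retrieved_total = sum(len(r.retrieved_includes) for r in corpus.reviews)
    for d in databases:
        used = [r for r in corpus.reviews if d in r.searched_databases]
        n_with_unique = 0
        n_unique = 0
        for review in used:
            uniques_here = sum(
                1 for inc in review.retrieved_includes if inc.retrieved_by == {d}
            )
            n_unique += uniques_here
            if uniques_here:
                n_with_unique += 1
        total_unique += n_unique
        rows.append(UniqueContribution(d, len(used), n_with_unique, n_unique))
    return UniqueContributionSummary(tuple(rows), total_unique, retrieved_total)


def select_candidates(
    contributions: Sequence[UniqueContribution], k: int
) -> list[str]:
    """Top-k databases by unique-reference count.

    Ties break by the number of reviews with unique references, then by
    canonical name, so the ordering is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(
        contributions,
        key=lambda c: (-c.n_unique_refs, -c.n_reviews_with_unique, c.database),
    )
    return [c.database for c in ordered[:k]]


# ---------------------------------------------------------------------------
# combination performance


def _combo_results_dedup(review: ReviewDataset, combo: Combo) -> tuple[int, bool]:
    """Deduplicated record count of a combination on one review.

    Exact (count of distinct works any combo member retrieved) when the
    review carries records; otherwise the sum of per-database counts,
    flagged inexact.
    """
    if review.records:
        return sum(1 for rec in review.records if rec.retrieved_by & combo), True
    return sum(review.result_counts.get(d, 0) for d in combo), False


def _per_review_recalls(
    reviews: Sequence[ReviewDataset], combo: Combo
) -> list[float]:
    """Retrieved-basis recalls, skipping reviews with no retrieved includes."""
    return [
        review_recall(r, combo)
        for r in reviews
        if len(r.retrieved_includes) > 0
    ]


def evaluate_combination(corpus: Corpus, combo: Iterable[str]) -> CombinationPerformance:
    """Full performance of one database combination over the corpus.

    Only reviews that searched every member of the combination are
    evaluated.  Overall recall pools includes over those reviews;
    median, minimum and full-recall share summarise the per-review
    recall distribution.
    """
    c: Combo = frozenset(combo)
    if not c:
        raise ValueError("combination must be non-empty")
    evaluated = corpus.reviews_searching(c)
    if not evaluated:
        raise NoEvaluableReviewError(f"no review searched all of {combo_name(c)}")

    includes_total = sum(len(r.retrieved_includes) for r in evaluated)
    includes_retrieved = sum(
        sum(1 for inc in r.retrieved_includes if inc.retrieved_by & c)
        for r in evaluated
    )
    per_review = [_combo_results_dedup(r, c) for r in evaluated]
    results_total = sum(n for n, _ in per_review)
    dedup_exact = all(exact for _, exact in per_review)

    recalls = _per_review_recalls(evaluated, c)
    if not recalls or includes_total == 0:
        raise EmptyDenominatorError(
            f"no retrieved includes among reviews evaluable for {combo_name(c)}"
        )
    overall = includes_retrieved / includes_total
    return CombinationPerformance(
        combo=c,
        n_reviews_evaluated=len(evaluated),
        results_total_dedup=results_total,
        includes_retrieved=includes_retrieved,
        includes_total=includes_total,
        overall_recall=overall,
        median_recall=statistics.median(recalls),
        min_recall=min(recalls),
        pct_reviews_full_recall=sum(1 for x in recalls if x >= _FULL) / len(recalls),
        precision=includes_retrieved / results_total if results_total else 0.0,
        nnr=results_total / includes_retrieved if includes_retrieved else float("inf"),
        dedup_exact=dedup_exact,
    )


def evaluate_all_subsets(
    corpus: Corpus, candidates: Sequence[str]
) -> list[CombinationPerformance]:
    """Evaluate every non-empty subset of the candidate databases.

    2^n - 1 subsets, returned by size then lexicographically — the
    layout of the performance table.
    """
    cands = sorted(set(candidates))
    if len(cands) > MAX_CANDIDATES:
        raise TooManyCandidatesError(
            f"{len(cands)} candidates; exhaustive enumeration capped at {MAX_CANDIDATES}"
        )
    out = []
    for size in range(1, len(cands) + 1):
        for subset in _itercombos(cands, size):
            out.append(evaluate_combination(corpus, frozenset(subset)))
    return out


# ---------------------------------------------------------------------------
# attainment


def attainment(
    corpus: Corpus,
    combo: Iterable[str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    strict: bool = False,
) -> AttainmentRow:
    """Share of evaluated reviews whose recall reaches each threshold.

    ``strict=True`` switches the comparison from >= to >, except at
    threshold 1.0 where > is unsatisfiable and >= is always used.
    """
    c: Combo = frozenset(combo)
    ts = tuple(thresholds)
    if any(not 0 < t <= 1 for t in ts):
        raise ValueError("thresholds must lie in (0, 1]")
    if list(ts) != sorted(ts, reverse=True):
        raise ValueError("thresholds must be sorted descending")
    evaluated = corpus.reviews_searching(c)
    recalls = _per_review_recalls(evaluated, c)
    if not recalls:
        raise NoEvaluableReviewError(f"no evaluable review for {combo_name(c)}")
    pct = []
    for t in ts:
        if strict and t < 1.0:
            hits = sum(1 for x in recalls if x > t)
        else:
            hits = sum(1 for x in recalls if x >= t - 1e-12)
        pct.append(hits / len(recalls))
    return AttainmentRow(c, ts, tuple(pct), len(recalls))


def stratified_attainment(
    corpus: Corpus,
    combo: Iterable[str],
    group_key: str,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    strict: bool = False,
) -> dict[str, AttainmentRow]:
    """Attainment computed within each metadata group independently.

    Reviews lacking the key fall into group ``"unknown"``.  Groups with
    no evaluable review are omitted.
    """
    groups: dict[str, list[ReviewDataset]] = {}
    for review in corpus.reviews:
        groups.setdefault(str(review.metadata.get(group_key, "unknown")), []).append(review)
    out: dict[str, AttainmentRow] = {}
    for name, reviews in sorted(groups.items()):
        sub = Corpus(reviews=tuple(reviews), database_registry=corpus.database_registry)
        try:
            out[name] = attainment(sub, combo, thresholds, strict=strict)
        except NoEvaluableReviewError:
            continue
    return out


# ---------------------------------------------------------------------------
# burden ratios


def results_reduction_ratio(review: ReviewDataset, combo: Iterable[str]) -> float:
    """Fraction of the full search's deduplicated results a combination keeps.

    1.0 means no reduction (the combination retrieves as many records
    as searching every database the review searched).
    """
    c: Combo = frozenset(combo)
    combo_n, _ = _combo_results_dedup(review, c)
    total_n, _ = _combo_results_dedup(review, review.searched_databases)
    if total_n == 0:
        raise EmptyDenominatorError(f"review {review.review_id!r} retrieved no records")
    return combo_n / total_n


def results_reduction_distribution(
    corpus: Corpus, combo: Iterable[str]
) -> dict[str, float]:
    """Per-review results-reduction ratios summarised for box plots."""
    c: Combo = frozenset(combo)
    values = [results_reduction_ratio(r, c) for r in corpus.reviews_searching(c)]
    return _distribution_summary(values, combo_name(c))


def precision_improvement_ratio(review: ReviewDataset, combo: Iterable[str]) -> float:
    """Precision of the combination relative to searching everything.

    Values above 1 mean the combination is MORE precise than the
    review's full search (fewer irrelevant records per relevant one).
    """
    c: Combo = frozenset(combo)
    combo_results, _ = _combo_results_dedup(review, c)
    total_results, _ = _combo_results_dedup(review, review.searched_databases)
    combo_includes = sum(1 for inc in review.retrieved_includes if inc.retrieved_by & c)
    total_includes = len(review.retrieved_includes)
    if combo_results == 0 or total_results == 0 or total_includes == 0 or combo_includes == 0:
        raise EmptyDenominatorError(
            f"precision ratio undefined for {combo_name(c)} on review {review.review_id!r}"
        )
    return (combo_includes / combo_results) / (total_includes / total_results)


def precision_improvement_distribution(
    corpus: Corpus, combo: Iterable[str]
) -> dict[str, float]:
    c: Combo = frozenset(combo)
    values = []
    for review in corpus.reviews_searching(c):
        try:
            values.append(precision_improvement_ratio(review, c))
        except EmptyDenominatorError:
            continue
    return _distribution_summary(values, combo_name(c))


def _distribution_summary(values: list[float], name: str) -> dict[str, float]:
    if not values:
        raise NoEvaluableReviewError(f"no evaluable review for {name}")
    qs = statistics.quantiles(values, n=4, method="inclusive") if len(values) > 1 else [values[0]] * 3
    return {
        "n": float(len(values)),
        "min": min(values),
        "q1": qs[0],
        "median": statistics.median(values),
        "q3": qs[2],
        "max": max(values),
    }


# ---------------------------------------------------------------------------
# greedy set cover


def greedy_cover(
    corpus: Corpus,
    target_recall: float,
    target_share_of_reviews: float,
    costs: Mapping[str, float] | None = None,
    candidates: Sequence[str] | None = None,
) -> list[str]:
    """Greedy database selection toward a recall target.

    Adds, at each step, the database with the best marginal gain in the
    share of reviews reaching ``target_recall``, per unit cost.  When no
    single addition moves that share (a plateau: several databases are
    needed jointly), the mean per-review recall gain breaks the plateau,
    so progress toward the target continues.  Stops when
    ``target_share_of_reviews`` is reached or nothing improves either
    objective.  Ties break lexicographically.  Raises
    :class:`TargetUnreachableError` when even the full candidate set
    falls short.
    """
    if not 0 < target_recall <= 1:
        raise ValueError("target_recall must be in (0, 1]")
    if not 0 < target_share_of_reviews <= 1:
        raise ValueError("target_share_of_reviews must be in (0, 1]")
    pool = sorted(set(candidates) if candidates is not None else corpus.all_databases)
    cost = {d: (costs or {}).get(d, 1.0) for d in pool}

    def share(combo: frozenset[str]) -> float:
        if not combo:
            return 0.0
        try:
            row = attainment(corpus, combo, thresholds=(target_recall,))
        except NoEvaluableReviewError:
            return 0.0
        return row.pct_reviews_at_or_above[0]

    def mean_recall(combo: frozenset[str]) -> float:
        if not combo:
            return 0.0
        recalls = _per_review_recalls(corpus.reviews_searching(combo), combo)
        return sum(recalls) / len(recalls) if recalls else 0.0

    if share(frozenset(pool)) < target_share_of_reviews - 1e-12:
        raise TargetUnreachableError(
            f"full set {combo_name(pool)} reaches only "
            f"{share(frozenset(pool)):.3f} of reviews at recall {target_recall}"
        )
    chosen: list[str] = []
    current_share, current_mean = 0.0, 0.0
    remaining = list(pool)
    while current_share < target_share_of_reviews - 1e-12 and remaining:
        best_d, best_key = None, (0.0, 0.0)
        for d in remaining:  # lexicographic order makes ties deterministic
            combo = frozenset(chosen) | {d}
            key = (
                (share(combo) - current_share) / cost[d],
                (mean_recall(combo) - current_mean) / cost[d],
            )
            better_share = key[0] > best_key[0] + 1e-12
            tied_share = abs(key[0] - best_key[0]) <= 1e-12
            if better_share or (tied_share and key[1] > best_key[1] + 1e-12):
                best_d, best_key = d, key
        if best_d is None:
            break
        chosen.append(best_d)
        remaining.remove(best_d)
        current_share = share(frozenset(chosen))
        current_mean = mean_recall(frozenset(chosen))
    return chosen
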