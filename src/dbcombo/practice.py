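"""Do published reviews search enough databases?

A practice sample is a frequency table of the database combinations a
set of published systematic reviews report searching (reduced to the
key databases under evaluation).  Combining those frequencies with the
corpus-measured probability that each combination reaches a recall
threshold yields one number: the probability that a review drawn from
current practice retrieved an acceptable share (e.g. 95%) of the
relevant references it could have found.

    P(acceptable) = sum over combinations c of  w_c * P(recall >= t | c)

where w_c is the combination's frequency share in the sample and the
conditional probability is the attainment share measured on the corpus.
Reviews searching none of the key databases contribute probability 0.

Two weighting conventions are exposed: ``denominator="matched"``
divides by the summed frequency of reviews that searched at least one
key database (the default), ``denominator="total"`` divides by the full
sample size so that non-matching reviews dilute the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .combinations import attainment
from .exceptions import EmptyDenominatorError, MissingProbabilityError, NoEvaluableReviewError
from .model import Combo, Corpus, combo_name

__all__ = [
    "PracticeSample",
    "RecallProbabilityTable",
    "reduce_to_key_combo",
    "derive_probability_table",
    "probability_of_acceptable_recall",
]

Denominator = Literal["matched", "total"]


@dataclass(frozen=True)
class PracticeSample:
    """Frequencies of key-database combinations in published reviews.

    ``n_total`` counts the whole sample, including reviews that matched
    no key database (those appear in no entry).
    """

    entries: tuple[tuple[Combo, int], ...]
    n_total: int

    def __post_init__(self) -> None:
        entries = tuple((frozenset(c), int(f)) for c, f in self.entries)
        object.__setattr__(self, "entries", entries)
        if any(f < 0 for _, f in entries):
            raise ValueError("frequencies must be non-negative")
        if self.matched_total > self.n_total:
            raise ValueError("sum of frequencies exceeds n_total")

    @property
    def matched_total(self) -> int:
        return sum(f for _, f in self.entries)


@dataclass(frozen=True)
class RecallProbabilityTable:
    """P(recall >= threshold | combination), per combination and threshold."""

    probabilities: dict[Combo, dict[float, float]] = field(default_factory=dict)

    def lookup(self, combo: Combo, threshold: float) -> float:
        combo = frozenset(combo)
        if combo not in self.probabilities:
            raise MissingProbabilityError(combo)
        by_threshold = self.probabilities[combo]
        if threshold not in by_threshold:
            raise MissingProbabilityError(combo)
        return by_threshold[threshold]

    @property
    def thresholds(self) -> tuple[float, ...]:
        for by_threshold in self.probabilities.values():
            return tuple(sorted(by_threshold, reverse=True))
        return ()


def reduce_to_key_combo(searched: Iterable[str], key_set: Iterable[str]) -> Combo:
    """Project the databases a review searched onto the key set.

    The empty intersection is allowed: such reviews count toward the
    sample total but carry zero probability of acceptable recall via
    the key databases.
    """
    key = frozenset(key_set)
    if not key:
        raise ValueError("key_set must be non-empty")
    return frozenset(searched) & key


def derive_probability_table(
    corpus: Corpus,
    key_set: Iterable[str],
    thresholds: Sequence[float],
) -> RecallProbabilityTable:
    """Measure attainment on the corpus for every non-empty key subset."""
    from itertools import combinations as _itercombos

    key = sorted(frozenset(key_set))
    ts = tuple(sorted(thresholds, reverse=True))
    table: dict[Combo, dict[float, float]] = {}
    for size in range(1, len(key) + 1):
        for subset in _itercombos(key, size):
            combo = frozenset(subset)
            try:
                row = attainment(corpus, combo, thresholds=ts)
            except NoEvaluableReviewError:
                continue
            table[combo] = dict(zip(row.thresholds, row.pct_reviews_at_or_above))
    return RecallProbabilityTable(table)


def probability_of_acceptable_recall(
    sample: PracticeSample,
    probs: RecallProbabilityTable | Mapping[Combo, Mapping[float, float]],
    threshold: float,
    denominator: Denominator = "matched",
) -> float:
    """Weighted probability that a sampled review reached the recall threshold.

    Every non-empty combination in the sample must be present in the
    probability table; an absent one raises
    :class:`MissingProbabilityError` naming it — silently treating it
    as zero would understate practice.
    """
    if not isinstance(probs, RecallProbabilityTable):
        probs = RecallProbabilityTable(
            {frozenset(c): dict(t) for c, t in probs.items()}
        )
    denom = sample.matched_total if denominator == "matched" else sample.n_total
    if denom <= 0:
        raise EmptyDenominatorError("practice sample is empty")
    total = 0.0
    for combo, freq in sample.entries:
        if not combo or freq == 0:
            continue  # no key database searched: contributes probability 0
        total += (freq / denom) * probs.lookup(combo, threshold)
    return total


def sample_table_rows(
    sample: PracticeSample,
    probs: RecallProbabilityTable,
    thresholds: Sequence[float],
    denominator: Denominator = "matched",
) -> list[dict[str, object]]:
    """Per-combination rows of the practice table (for reporting).

    Columns: combination, frequency, frequency share, and for each
    threshold the conditional probability and its frequency-weighted
    product.  The weighted products sum to the headline probabilities.
    """
    denom = sample.matched_total if denominator == "matched" else sample.n_total
    if denom <= 0:
        raise EmptyDenominatorError("practice sample is empty")
    rows = []
    for combo, freq in sample.entries:
        row: dict[str, object] = {
            "combination": combo_name(combo),
            "frequency": freq,
            "frequency_share": freq / denom,
        }
        for t in thresholds:
            p = probs.lookup(combo, t) if combo else 0.0
            row[f"p_recall_{t:g}"] = p
            row[f"weighted_{t:g}"] = (freq / denom) * p
        rows.append(row)
    return rows
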