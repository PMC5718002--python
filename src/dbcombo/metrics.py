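"""Search performance measures: recall, precision, number needed to read.

For a database (or combination of databases) evaluated against a
review's included references:

    recall    = includes retrieved by the combination / includes retrieved by all databases
    precision = includes retrieved by the combination / total records retrieved by it
    NNR       = total records retrieved by it / includes retrieved by it

NNR (number needed to read) is the reciprocal of precision: the average
number of records a screener must read per relevant reference found.

Two recall denominators ("bases") exist and both are used in practice:

``retrieved``
    includes retrieved by at least one searched database — the default,
    and the denominator of all combination comparisons.  By definition
    the full searched set scores 1.0 on this basis.
``published``
    every include of the published review, also counting those found by
    hand searching, reference checking or contacting authors.  Always
    less than or equal to the retrieved-basis recall.

All functions return full-precision fractions; rounding happens only in
the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .exceptions import CombinationNotSearchedError, EmptyDenominatorError
from .model import Combo, ReviewDataset

__all__ = [
    "MetricInputs",
    "recall",
    "precision",
    "number_needed_to_read",
    "review_recall",
]

RecallBasis = Literal["retrieved", "published"]


@dataclass(frozen=True)
class MetricInputs:
    """The three counts every performance measure is built from."""

    includes_retrieved: int
    includes_total: int
    results_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.includes_retrieved <= self.includes_total:
            raise ValueError(
                f"includes_retrieved={self.includes_retrieved} outside "
                f"[0, includes_total={self.includes_total}]"
            )
        if self.includes_retrieved > self.results_total:
            raise ValueError("cannot retrieve more includes than total records")

    @property
    def recall(self) -> float:
        return recall(self.includes_retrieved, self.includes_total)

    @property
    def precision(self) -> float:
        return precision(self.includes_retrieved, self.results_total)

    @property
    def nnr(self) -> float:
        return number_needed_to_read(self.results_total, self.includes_retrieved)


def recall(includes_retrieved: int, includes_total: int) -> float:
    if includes_total <= 0:
        raise EmptyDenominatorError("recall undefined: no included references in denominator")
    return includes_retrieved / includes_total


def precision(includes_retrieved: int, results_total: int) -> float:
    if results_total <= 0:
        raise EmptyDenominatorError("precision undefined: no records retrieved")
    return includes_retrieved / results_total


def number_needed_to_read(results_total: int, includes_retrieved: int) -> float:
    """Records screened per relevant reference found; report rounded to integer."""
    if includes_retrieved <= 0:
        raise EmptyDenominatorError("NNR undefined: no included references retrieved")
    return results_total / includes_retrieved


def review_recall(
    review: ReviewDataset,
    combo: Iterable[str],
    basis: RecallBasis = "retrieved",
) -> float:
    """Recall of a database combination on one review.

    Numerator: includes whose provenance intersects ``combo``.
    Denominator: retrieved includes (default) or all includes
    (``basis="published"``), see module docstring.
    """
    c: Combo = frozenset(combo)
    if not c <= review.searched_databases:
        missing = sorted(c - review.searched_databases)
        raise CombinationNotSearchedError(
            f"review {review.review_id!r} did not search {missing}"
        )
    if basis == "published":
        denominator = len(review.includes)
    else:
        denominator = len(review.retrieved_includes)
    if denominator == 0:
        raise EmptyDenominatorError(
            f"review {review.review_id!r} has no includes on basis {basis!r}"
        )
    numerator = sum(1 for rec in review.retrieved_includes if rec.retrieved_by & c)
    return numerator / denominator
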