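"""Core domain types: reference records, review datasets, corpora.

A :class:`ReferenceRecord` is one bibliographic work together with its
*provenance* — the set of databases whose searches retrieved it.  A
:class:`ReviewDataset` bundles everything recorded for one systematic
review: which databases were searched, how many records each returned,
the deduplicated record clusters, and the review's included references
(the relevance gold standard).  A :class:`Corpus` is a collection of
reviews sharing one database registry.

Databases are carried as canonical-name strings (see
:mod:`dbcombo.labels`); sets of them are frozensets so they can key
dictionaries of combination results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable

from .exceptions import CorpusValidationError
from .labels import DatabaseLabel, default_registry

__all__ = ["ReferenceRecord", "ReviewDataset", "Corpus", "Combo", "combo_name"]

Combo = frozenset[str]

KNOWN_DOMAINS = {"therapy", "etiology", "epidemiology", "diagnosis", "management", "prognosis"}


def combo_name(combo: Iterable[str]) -> str:
    """Stable display name for a database combination, e.g. ``EMBASE-GS-MEDLINE``."""
    return "-".join(sorted(combo)) or "(none)"


@dataclass(frozen=True)
class ReferenceRecord:
    """One bibliographic record with database provenance.

    ``retrieved_by`` may be empty for an included reference found by
    other search methods (hand searching, reference checking, contacting
    authors); such includes are excluded from retrieved-basis recall
    denominators but count on the published basis.
    """

    record_id: str
    first_author_surname: str = ""
    year: int | None = None
    title: str = ""
    retrieved_by: Combo = field(default_factory=frozenset)
    is_included: bool = False
    second_author_surname: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "retrieved_by", frozenset(self.retrieved_by))
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise ValueError(f"record {self.record_id}: implausible year {self.year}")


@dataclass(frozen=True)
class ReviewDataset:
    """Everything recorded for one systematic review's search.

    ``records`` holds deduplicated clusters: one entry per distinct work,
    with ``retrieved_by`` listing every database that returned it.  The
    pre-deduplication count per database is in ``result_counts``, as
    recorded at the moment of searching.  ``includes`` are the review's
    included references with provenance attached (possibly empty for
    other-methods finds).
    """

    review_id: str
    searched_databases: Combo
    result_counts: dict[str, int] = field(default_factory=dict)
    records: tuple[ReferenceRecord, ...] = ()
    includes: tuple[ReferenceRecord, ...] = ()
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "searched_databases", frozenset(self.searched_databases))
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "includes", tuple(self.includes))

    # -- derived views -------------------------------------------------

    @property
    def retrieved_includes(self) -> tuple[ReferenceRecord, ...]:
        """Includes retrieved by at least one searched database."""
        return tuple(r for r in self.includes if r.retrieved_by)

    @property
    def other_methods_includes(self) -> tuple[ReferenceRecord, ...]:
        """Includes found only by non-database methods (empty provenance)."""
        return tuple(r for r in self.includes if not r.retrieved_by)

    def with_includes(self, includes: Iterable[ReferenceRecord]) -> "ReviewDataset":
        return replace(self, includes=tuple(includes))

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Enforce the dataset invariants; raise CorpusValidationError on breach."""
        rid = self.review_id
        for d in self.result_counts:
            if d not in self.searched_databases:
                raise CorpusValidationError(
                    rid, f"result_counts lists {d}, which is not in searched_databases"
                )
        for d, n in self.result_counts.items():
            if n < 0:
                raise CorpusValidationError(rid, f"negative result count for {d}")
        seen_ids: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen_ids:
                raise CorpusValidationError(rid, f"duplicate record_id {rec.record_id}")
            seen_ids.add(rec.record_id)
        for rec in list(self.records) + list(self.includes):
            extra = rec.retrieved_by - self.searched_databases
            if extra:
                raise CorpusValidationError(
                    rid,
                    f"record {rec.record_id} attributed to unsearched database(s) "
                    f"{sorted(extra)}",
                )
        if self.records and self.result_counts:
            for d, n in self.result_counts.items():
                attributed = sum(1 for rec in self.records if d in rec.retrieved_by)
                if attributed != n:
                    raise CorpusValidationError(
                        rid,
                        f"result_counts[{d}] = {n} but {attributed} records are "
                        f"attributed to it",
                    )
        dom = self.metadata.get("domain")
        if dom is not None and dom not in KNOWN_DOMAINS:
            raise CorpusValidationError(rid, f"unknown review domain {dom!r}")


@dataclass(frozen=True)
class Corpus:
    """A set of reviews under one database registry."""

    reviews: tuple[ReviewDataset, ...]
    database_registry: tuple[DatabaseLabel, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reviews", tuple(self.reviews))
        registry = tuple(self.database_registry) or tuple(default_registry())
        object.__setattr__(self, "database_registry", registry)

    def validate(self) -> None:
        ids = [r.review_id for r in self.reviews]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(dupes[0], "duplicate review_id in corpus")
        known = {lab.canonical_name for lab in self.database_registry}
        for review in self.reviews:
            review.validate()
            missing = review.searched_databases - known
            if missing:
                raise CorpusValidationError(
                    review.review_id,
                    f"searched database(s) {sorted(missing)} absent from registry",
                )

    @property
    def all_databases(self) -> Combo:
        out: set[str] = set()
        for r in self.reviews:
            out |= r.searched_databases
        return frozenset(out)

    def reviews_searching(self, combo: Iterable[str]) -> tuple[ReviewDataset, ...]:
        """Reviews whose searched set covers every member of ``combo``."""
        c = frozenset(combo)
        return tuple(r for r in self.reviews if c <= r.searched_databases)
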