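"""Locating included references inside a review's multi-database library.

A published review lists its included studies, but not which database
search found them.  Provenance is recovered by searching the review's
combined (pre-deduplication) library: first by a ``surname|year`` key —
first author surname plus publication year — then, when several distinct
works share that key, by second-author equality and title similarity.
Records of the *same* work retrieved from several databases all count:
their databases are unioned into the include's provenance.

An include matching nothing is attributed to other search methods
(hand searching, reference checking, author contact) and excluded from
retrieved-basis recall denominators downstream.  Ambiguity that title
similarity cannot break is never resolved silently: the include is
flagged ``ambiguous-unresolved`` and excluded, so every attribution in
the analysis is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .exceptions import ConsistencyError
from .model import Combo, ReferenceRecord, ReviewDataset
from .normalize import normalize_text, title_tokens, token_jaccard

__all__ = [
    "MatchResult",
    "build_match_key",
    "match_included",
    "match_review",
    "attach_provenance",
    "deduplicate_records",
]

NO_SURNAME_SENTINEL = "<no-surname>"
DEFAULT_TITLE_THRESHOLD = 0.6


@dataclass(frozen=True)
class MatchResult:
    """Outcome of locating one included reference in the library."""

    included_ref: ReferenceRecord
    matched_record_ids: frozenset[str]
    provenance: Combo
    status: str  # matched | unmatched | ambiguous-resolved | ambiguous-unresolved

    def __post_init__(self) -> None:
        if self.status in ("unmatched", "ambiguous-unresolved"):
            assert not self.provenance
        else:
            assert self.provenance or self.matched_record_ids


def build_match_key(ref: ReferenceRecord) -> str:
    """``surname|year`` lookup key in normal form.

    A missing surname produces a sentinel key that never collides with a
    real surname, forcing the title stage of matching.
    """
    if not ref.first_author_surname and not ref.title:
        raise ValueError(f"record {ref.record_id}: neither surname nor title present")
    surname = normalize_text(ref.first_author_surname) or NO_SURNAME_SENTINEL
    year = ref.year if ref.year is not None else "?"
    return f"{surname}|{year}"


def _group_works(candidates: Sequence[ReferenceRecord]) -> dict[str, list[ReferenceRecord]]:
    """Group library records into distinct works by normalized title."""
    works: dict[str, list[ReferenceRecord]] = {}
    for rec in candidates:
        works.setdefault(normalize_text(rec.title), []).append(rec)
    return works


def _result(include: ReferenceRecord, records: Iterable[ReferenceRecord], status: str) -> MatchResult:
    recs = list(records)
    provenance: set[str] = set()
    for r in recs:
        provenance |= r.retrieved_by
    return MatchResult(
        included_ref=include,
        matched_record_ids=frozenset(r.record_id for r in recs),
        provenance=frozenset(provenance),
        status=status,
    )


def match_included(
    included: ReferenceRecord,
    library: Sequence[ReferenceRecord],
    title_threshold: float = DEFAULT_TITLE_THRESHOLD,
) -> MatchResult:
    """Locate one included reference in a review's combined library.

    Stage 1 selects records sharing the ``surname|year`` key.  When the
    survivors form more than one distinct work, stage 2a keeps works
    whose second-author surname equals the include's (when both sides
    have one), and stage 2b keeps works whose normalized title-token
    Jaccard similarity with the include is at least ``title_threshold``,
    picking the strictly most similar work.  A similarity tie between
    distinct works is flagged ``ambiguous-unresolved`` and excluded.
    """
    if not 0 < title_threshold <= 1:
        raise ValueError("title_threshold must be in (0, 1]")
    key = build_match_key(included)
    if key.startswith(NO_SURNAME_SENTINEL):
        candidates = list(library)  # no usable key: title matching over everything
    else:
        candidates = [r for r in library if build_match_key(r) == key]
    if not candidates:
        return _result(included, (), "unmatched")

    works = _group_works(candidates)
    if len(works) == 1:
        return _result(included, candidates, "matched")

    # stage 2a: second-author surname, cheap and strict, when data exist
    inc_second = normalize_text(included.second_author_surname)
    if inc_second:
        surviving = {
            title: recs
            for title, recs in works.items()
            if any(normalize_text(r.second_author_surname) == inc_second for r in recs)
        }
        if len(surviving) == 1:
            return _result(included, next(iter(surviving.values())), "ambiguous-resolved")
        if surviving:
            works = surviving

    # stage 2b: title-token similarity
    inc_tokens = title_tokens(included.title)
    scored = {
        title: token_jaccard(inc_tokens, title_tokens(recs[0].title))
        for title, recs in works.items()
    }
    passing = {t: s for t, s in scored.items() if s >= title_threshold}
    if not passing:
        return _result(included, (), "unmatched")
    best = max(passing.values())
    best_titles = [t for t, s in passing.items() if s == best]
    if len(best_titles) > 1:
        return _result(included, (), "ambiguous-unresolved")
    return _result(included, works[best_titles[0]], "ambiguous-resolved")


def match_review(
    review: ReviewDataset, title_threshold: float = DEFAULT_TITLE_THRESHOLD
) -> list[MatchResult]:
    """Match every include of a review against its own record library."""
    return [
        match_included(inc, review.records, title_threshold=title_threshold)
        for inc in review.includes
    ]


def attach_provenance(review: ReviewDataset, results: Sequence[MatchResult]) -> ReviewDataset:
    """Write match provenance back onto the review's includes.

    Requires one result per include, in order.  Matched record ids must
    exist in the review's record set (when records are present).
    """
    if len(results) != len(review.includes):
        raise ConsistencyError(
            f"review {review.review_id!r}: {len(results)} match results "
            f"for {len(review.includes)} includes"
        )
    known_ids = {r.record_id for r in review.records}
    new_includes = []
    for include, res in zip(review.includes, results):
        if known_ids and not res.matched_record_ids <= known_ids:
            stray = sorted(res.matched_record_ids - known_ids)
            raise ConsistencyError(
                f"review {review.review_id!r}: matched record id(s) {stray} "
                f"not present in the review's records"
            )
        new_includes.append(replace(include, retrieved_by=res.provenance, is_included=True))
    return review.with_includes(new_includes)


def deduplicate_records(records: Sequence[ReferenceRecord]) -> list[ReferenceRecord]:
    """Cluster pre-deduplication records into one record per distinct work.

    Identity is exact equality of the ``surname|year`` key plus the
    normalized title; provenance is unioned over the cluster.  Order of
    first appearance is preserved and the first record's fields win.
    """
    clusters: dict[tuple[str, str], ReferenceRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (build_match_key(rec), normalize_text(rec.title))
        if key in clusters:
            kept = clusters[key]
            clusters[key] = replace(
                kept,
                retrieved_by=kept.retrieved_by | rec.retrieved_by,
                is_included=kept.is_included or rec.is_included,
            )
        else:
            clusters[key] = rec
            order.append(key)
    return [clusters[k] for k in order]
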