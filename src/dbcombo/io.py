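"""Readers and writers for reference lists, corpus manifests and corpora.

Interchange formats are deliberately open: RIS (the standard export of
reference managers, including EndNote) and CSV for reference lists, a
YAML or JSON manifest for a corpus, JSON for a fully materialised
corpus.  Proprietary reference-manager binary formats are out of scope.

RIS handling covers the tags this analysis needs — ``TY``/``AU``/``PY``
(or ``Y1``)/``TI`` (or ``T1``)/``ID``/``ER`` — which is the subset
reference managers reliably populate.  Database provenance is not an
RIS concept, so it travels beside the file: a whole RIS export carries
one database (the source it was exported from), while CSV carries a
per-row ``database`` or semicolon-joined ``databases`` column.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Iterable

import yaml

from .exceptions import CorpusValidationError, MissingFieldError, ParseError
from .labels import DatabaseLabel, canonicalize_database, default_registry
from .model import Corpus, ReferenceRecord, ReviewDataset

__all__ = [
    "read_reference_list",
    "write_reference_list",
    "load_corpus",
    "corpus_to_json",
    "corpus_from_json",
]

_RIS_TITLE_TAGS = ("TI", "T1")
_RIS_YEAR_TAGS = ("PY", "Y1")


def _surname(author_field: str) -> str:
    """Surname from an ``AU`` value: the part before the first comma."""
    return author_field.split(",", 1)[0].strip()


# ---------------------------------------------------------------------------
# RIS


def _read_ris(path: Path, database: str | None) -> list[ReferenceRecord]:
    records: list[ReferenceRecord] = []
    current: dict[str, list[str]] = {}
    start_line = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if len(line) >= 5 and line[2:5] == "  -":
                tag, value = line[:2], line[5:].strip()
            elif current:
                # continuation line of the previous tag value
                continue
            else:
                raise ParseError(f"malformed RIS line {line!r}", line=lineno)
            if tag == "TY":
                current = {"TY": [value]}
                start_line = lineno
            elif tag == "ER":
                records.append(_finish_ris_record(current, len(records), path, start_line, database))
                current = {}
            elif current:
                current.setdefault(tag, []).append(value)
            else:
                raise ParseError("RIS tag outside a TY..ER block", line=lineno)
    if current:
        raise ParseError("RIS file ended inside a record (missing ER)", line=start_line)
    return records


def _finish_ris_record(
    fields: dict[str, list[str]],
    index: int,
    path: Path,
    line: int,
    database: str | None,
) -> ReferenceRecord:
    authors = fields.get("AU", []) + fields.get("A1", [])
    title = next((fields[t][0] for t in _RIS_TITLE_TAGS if fields.get(t)), "")
    if not authors and not title:
        raise MissingFieldError(f"{path.name} record near line {line}: no author and no title")
    year = None
    for t in _RIS_YEAR_TAGS:
        if fields.get(t):
            # PY may look like "2015" or "2015/03/01"
            head = fields[t][0].split("/", 1)[0].strip()
            if head:
                try:
                    year = int(head)
                except ValueError as exc:
                    raise ParseError(f"unparseable year {fields[t][0]!r}", line=line) from exc
            break
    record_id = fields.get("ID", [f"{path.stem}:{index}"])[0]
    return ReferenceRecord(
        record_id=record_id,
        first_author_surname=_surname(authors[0]) if authors else "",
        second_author_surname=_surname(authors[1]) if len(authors) > 1 else "",
        year=year,
        title=title,
        retrieved_by=frozenset({database} if database else ()),
    )


def _write_ris(records: Iterable[ReferenceRecord], path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write("TY  - JOUR\n")
            fh.write(f"ID  - {rec.record_id}\n")
            if rec.first_author_surname:
                fh.write(f"AU  - {rec.first_author_surname}\n")
            if rec.second_author_surname:
                fh.write(f"AU  - {rec.second_author_surname}\n")
            if rec.year is not None:
                fh.write(f"PY  - {rec.year}\n")
            if rec.title:
                fh.write(f"TI  - {rec.title}\n")
            fh.write("ER  - \n")


# ---------------------------------------------------------------------------
# CSV

_CSV_FIELDS = ["record_id", "first_author_surname", "year", "title", "databases", "is_included"]


def _read_csv(path: Path, database: str | None) -> list[ReferenceRecord]:
    records: list[ReferenceRecord] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            try:
                provenance: frozenset[str]
                if row.get("databases"):
                    provenance = frozenset(
                        d.strip() for d in row["databases"].split(";") if d.strip()
                    )
                elif row.get("database"):
                    provenance = frozenset({row["database"].strip()})
                elif database:
                    provenance = frozenset({database})
                else:
                    provenance = frozenset()
                surname = (row.get("first_author_surname") or "").strip()
                title = (row.get("title") or "").strip()
                if not surname and not title:
                    raise MissingFieldError(f"{path.name} line {lineno}: no author and no title")
                records.append(
                    ReferenceRecord(
                        record_id=(row.get("record_id") or f"{path.stem}:{lineno - 2}").strip(),
                        first_author_surname=surname,
                        second_author_surname=(row.get("second_author_surname") or "").strip(),
                        year=int(row["year"]) if (row.get("year") or "").strip() else None,
                        title=title,
                        retrieved_by=provenance,
                        is_included=(row.get("is_included") or "").strip().lower()
                        in {"1", "true", "yes"},
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path.name}: {exc}", line=lineno) from exc
    return records


def _write_csv(records: Iterable[ReferenceRecord], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for rec in records:
            writer.writerow(
                {
                    "record_id": rec.record_id,
                    "first_author_surname": rec.first_author_surname,
                    "year": rec.year if rec.year is not None else "",
                    "title": rec.title,
                    "databases": ";".join(sorted(rec.retrieved_by)),
                    "is_included": "true" if rec.is_included else "",
                }
            )


# ---------------------------------------------------------------------------
# Public API


def read_reference_list(
    path: str | Path,
    format: str | None = None,
    database: str | None = None,
    registry: list[DatabaseLabel] | None = None,
) -> list[ReferenceRecord]:
    """Read a reference list from RIS or CSV.

    ``database`` assigns whole-file provenance (the database the file was
    exported from); CSV rows may instead carry their own ``database`` /
    ``databases`` column.  All provenance strings are canonicalized
    against ``registry`` (the default registry when omitted).
    """
    p = Path(path)
    fmt = (format or p.suffix.lstrip(".")).lower()
    reg = registry if registry is not None else default_registry()
    db = canonicalize_database(database, reg) if database else None
    if fmt == "ris":
        records = _read_ris(p, db)
    elif fmt == "csv":
        records = _read_csv(p, db)
    else:
        raise ParseError(f"unsupported reference list format {fmt!r}")
    return [
        rec
        if not rec.retrieved_by
        else ReferenceRecord(
            record_id=rec.record_id,
            first_author_surname=rec.first_author_surname,
            second_author_surname=rec.second_author_surname,
            year=rec.year,
            title=rec.title,
            retrieved_by=frozenset(canonicalize_database(d, reg) for d in rec.retrieved_by),
            is_included=rec.is_included,
        )
        for rec in records
    ]


def write_reference_list(
    records: Iterable[ReferenceRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records to RIS or CSV (format inferred from suffix when omitted)."""
    p = Path(path)
    fmt = (format or p.suffix.lstrip(".")).lower()
    if fmt == "ris":
        _write_ris(records, p)
    elif fmt == "csv":
        _write_csv(records, p)
    else:
        raise ParseError(f"unsupported reference list format {fmt!r}")


# ---------------------------------------------------------------------------
# Corpus manifest and JSON round-trip


def load_corpus(config_path: str | Path) -> Corpus:
    """Load and validate a corpus from a YAML/JSON manifest.

    Manifest schema (paths relative to the manifest file)::

        reviews:
          - review_id: r01
            searched_databases: [EMBASE, MEDLINE, WOS, GS]
            result_counts: {EMBASE: 1500, MEDLINE: 980}      # optional
            metadata: {domain: therapy}                       # optional
            records_file: r01_records.csv     # dedup clusters, OR:
            database_exports:                 # pre-dedup per-database files
              - {path: r01_embase.ris, format: ris, database: EMBASE}
            includes_file: r01_includes.csv   # optional

    Per-database exports are clustered into deduplicated records (same
    work retrieved by several databases becomes one record whose
    provenance is the union).  Every dataset invariant is enforced; a
    violation raises :class:`CorpusValidationError` naming the review.
    """
    cfg_path = Path(config_path)
    with cfg_path.open(encoding="utf-8") as fh:
        manifest = (
            json.load(fh) if cfg_path.suffix.lower() == ".json" else yaml.safe_load(fh)
        )
    if not isinstance(manifest, dict) or "reviews" not in manifest:
        raise CorpusValidationError("<manifest>", "manifest must contain a 'reviews' list")
    registry = default_registry()
    base = cfg_path.parent
    reviews = []
    for spec in manifest["reviews"]:
        rid = str(spec.get("review_id", ""))
        if not rid:
            raise CorpusValidationError("<manifest>", "review entry without review_id")
        searched = frozenset(
            canonicalize_database(d, registry) for d in spec.get("searched_databases", [])
        )
        records: list[ReferenceRecord] = []
        if spec.get("records_file"):
            records = read_reference_list(base / spec["records_file"], registry=registry)
        elif spec.get("database_exports"):
            from .matching import deduplicate_records  # local import: avoid cycle

            raw: list[ReferenceRecord] = []
            for exp in spec["database_exports"]:
                raw.extend(
                    read_reference_list(
                        base / exp["path"],
                        format=exp.get("format"),
                        database=exp["database"],
                        registry=registry,
                    )
                )
            records = deduplicate_records(raw)
        includes: list[ReferenceRecord] = []
        if spec.get("includes_file"):
            includes = [
                ReferenceRecord(
                    record_id=r.record_id,
                    first_author_surname=r.first_author_surname,
                    second_author_surname=r.second_author_surname,
                    year=r.year,
                    title=r.title,
                    retrieved_by=r.retrieved_by,
                    is_included=True,
                )
                for r in read_reference_list(base / spec["includes_file"], registry=registry)
            ]
        review = ReviewDataset(
            review_id=rid,
            searched_databases=searched,
            result_counts={
                canonicalize_database(d, registry): int(n)
                for d, n in (spec.get("result_counts") or {}).items()
            },
            records=tuple(records),
            includes=tuple(includes),
            metadata=dict(spec.get("metadata") or {}),
        )
        reviews.append(review)
    corpus = Corpus(reviews=tuple(reviews), database_registry=tuple(registry))
    corpus.validate()
    return corpus


def _record_to_dict(rec: ReferenceRecord) -> dict[str, Any]:
    return {
        "record_id": rec.record_id,
        "first_author_surname": rec.first_author_surname,
        "second_author_surname": rec.second_author_surname,
        "year": rec.year,
        "title": rec.title,
        "retrieved_by": sorted(rec.retrieved_by),
        "is_included": rec.is_included,
    }


def _record_from_dict(d: dict[str, Any]) -> ReferenceRecord:
    return ReferenceRecord(
        record_id=d["record_id"],
        first_author_surname=d.get("first_author_surname", ""),
        second_author_surname=d.get("second_author_surname", ""),
        year=d.get("year"),
        title=d.get("title", ""),
        retrieved_by=frozenset(d.get("retrieved_by", ())),
        is_included=bool(d.get("is_included", False)),
    )


def corpus_to_json(corpus: Corpus, path: str | Path | None = None) -> str:
    """Serialise a corpus to canonical JSON (sorted keys, stable order)."""
    payload = {
        "registry": [
            {"canonical_name": lab.canonical_name, "aliases": list(lab.aliases)}
            for lab in corpus.database_registry
        ],
        "reviews": [
            {
                "review_id": r.review_id,
                "searched_databases": sorted(r.searched_databases),
                "result_counts": {d: r.result_counts[d] for d in sorted(r.result_counts)},
                "metadata": r.metadata,
                "records": [_record_to_dict(rec) for rec in r.records],
                "includes": [_record_to_dict(rec) for rec in r.includes],
            }
            for r in corpus.reviews
        ],
    }
    text = json.dumps(payload, sort_keys=True, indent=None, separators=(",", ":"))
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def corpus_from_json(source: str | Path) -> Corpus:
    """Inverse of :func:`corpus_to_json`; accepts a path or a JSON string."""
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif not source.lstrip().startswith(("{", "[")):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    payload = json.loads(text)
    registry = tuple(
        DatabaseLabel(d["canonical_name"], tuple(d.get("aliases", ())))
        for d in payload.get("registry", ())
    )
    reviews = tuple(
        ReviewDataset(
            review_id=r["review_id"],
            searched_databases=frozenset(r["searched_databases"]),
            result_counts=dict(r.get("result_counts", {})),
            metadata=dict(r.get("metadata", {})),
            records=tuple(_record_from_dict(d) for d in r.get("records", ())),
            includes=tuple(_record_from_dict(d) for d in r.get("includes", ())),
        )
        for r in payload["reviews"]
    )
    corpus = Corpus(reviews=reviews, database_registry=registry)
    corpus.validate()
    return corpus
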