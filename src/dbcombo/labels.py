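"""Canonical database labels and alias resolution.

Bibliographic databases go by many names: the same source appears as
"Embase.com", "EMBASE" or "Embase Classic" depending on the vendor
interface that produced the export.  Analyses must treat these as one
database.  The registry maps raw source strings onto short canonical
tokens, many-to-one and case-insensitively.

The alias table also expresses deliberate merges.  MEDLINE searched via
Ovid and the PubMed "as supplied by publisher" subset (which exists to
catch e-publications not yet indexed in MEDLINE) are counted as a single
database labelled ``MEDLINE``: they are one bibliographic source reached
through two interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import UnknownDatabaseError

__all__ = [
    "DatabaseLabel",
    "default_registry",
    "canonicalize_database",
    "registry_index",
]


@dataclass(frozen=True)
class DatabaseLabel:
    """A canonical database identity plus the raw strings that map to it.

    Parameters
    ----------
    canonical_name:
        Short uppercase token, unique within a registry (e.g. ``EMBASE``).
    aliases:
        Raw source strings resolving to this label.  Matching is
        case-insensitive and whitespace-trimmed; the canonical name is
        always an implicit alias of itself.
    """

    canonical_name: str
    aliases: tuple[str, ...] = field(default_factory=tuple)

    def matches(self, raw: str) -> bool:
        token = raw.strip().casefold()
        if token == self.canonical_name.casefold():
            return True
        return any(token == a.strip().casefold() for a in self.aliases)


def default_registry() -> list[DatabaseLabel]:
    """The registry used throughout: nine canonical databases.

    The MEDLINE entry folds in the Ovid interface and PubMed's
    publisher-supplied subset; Google Scholar is ``GS``; Web of Science
    Core Collection is ``WOS``.
    """
    return [
        DatabaseLabel(
            "EMBASE",
            ("Embase", "Embase.com", "Embase Classic", "EMBASE (Embase.com)"),
        ),
        DatabaseLabel(
            "MEDLINE",
            (
                "MEDLINE (Ovid)",
                "Ovid MEDLINE",
                "Ovid MEDLINE(R)",
                "PubMed",
                "PubMed publisher [sb]",
                "PubMed (as supplied by publisher)",
                "publisher [sb]",
            ),
        ),
        DatabaseLabel(
            "WOS",
            ("Web of Science", "Web of Science Core Collection", "WoS", "ISI Web of Science"),
        ),
        DatabaseLabel("GS", ("Google Scholar", "scholar.google.com")),
        DatabaseLabel(
            "COCHRANE_CENTRAL",
            ("Cochrane CENTRAL", "CENTRAL", "Cochrane Central Register of Controlled Trials"),
        ),
        DatabaseLabel("CINAHL", ("CINAHL (EBSCOhost)", "Cinahl")),
        DatabaseLabel("PSYCINFO", ("PsycINFO", "PsycINFO (Ovid)", "PsycInfo")),
        DatabaseLabel("SCOPUS", ("Scopus", "SCOPUS (Elsevier)")),
        DatabaseLabel("SPORTDISCUS", ("SportDiscus", "SPORTDiscus (EBSCOhost)")),
    ]


def registry_index(registry: list[DatabaseLabel]) -> dict[str, str]:
    """Flat alias -> canonical_name lookup (casefolded keys)."""
    index: dict[str, str] = {}
    for label in registry:
        index[label.canonical_name.casefold()] = label.canonical_name
        for alias in label.aliases:
            index[alias.strip().casefold()] = label.canonical_name
    return index


def canonicalize_database(raw_label: str, registry: list[DatabaseLabel]) -> str:
    """Resolve a raw source string to its canonical database name.

    Unknown labels raise :class:`UnknownDatabaseError` rather than
    silently minting a new database — a typo in an export must never
    split one database into two.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    token = raw_label.strip().casefold()
    for label in registry:
        if label.matches(token):
            return label.canonical_name
    raise UnknownDatabaseError(f"unknown database label: {raw_label!r}")
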