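"""Text normalization for cross-database record identity.

Exports of the same work from different databases differ in case,
diacritics, punctuation and whitespace.  All identity comparisons
(author keys, title tokens) go through one normal form: casefold, strip
diacritics (NFKD decomposition, drop combining marks), drop punctuation,
collapse whitespace.
"""

from __future__ import annotations

import re
import unicodedata

__all__ = ["normalize_text", "title_tokens", "token_jaccard"]

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Canonical text form: casefolded, unaccented, unpunctuated, single-spaced."""
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    no_punct = _PUNCT.sub(" ", stripped.casefold())
    return _WS.sub(" ", no_punct).strip()


def title_tokens(title: str) -> frozenset[str]:
    """Normalized word set of a title."""
    norm = normalize_text(title)
    return frozenset(norm.split()) if norm else frozenset()


def token_jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    """Jaccard similarity of two token sets; empty-vs-empty counts as 0."""
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)
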