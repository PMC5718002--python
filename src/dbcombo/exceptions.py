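"""Exception hierarchy.

Every error raised by the library derives from :class:`DbComboError`, so
callers can catch one type at a CLI boundary.
"""


class DbComboError(Exception):
    """Base class for all dbcombo errors."""


class UnknownDatabaseError(DbComboError):
    """A raw database label matched no alias in the registry."""


class ParseError(DbComboError):
    """A reference file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line is not None else ""))


class MissingFieldError(DbComboError):
    """A record lacks both an author and a title and cannot be matched."""


class CorpusValidationError(DbComboError):
    """A review violates a dataset invariant; names the review and the invariant."""

    def __init__(self, review_id: str, invariant: str):
        self.review_id = review_id
        self.invariant = invariant
        super().__init__(f"review {review_id!r}: {invariant}")


class ConsistencyError(DbComboError):
    """A matched record id is not present in the review's record set."""


class EmptyDenominatorError(DbComboError):
    """A performance ratio was requested with a zero denominator."""


class CombinationNotSearchedError(DbComboError):
    """A combination includes a database the review did not search."""


class NoEvaluableReviewError(DbComboError):
    """No review in the corpus searched every member of the combination."""


class TooManyCandidatesError(DbComboError):
    """Exhaustive subset enumeration was requested above the candidate cap."""


class TargetUnreachableError(DbComboError):
    """Even the full database set cannot reach the requested recall target."""


class MissingProbabilityError(DbComboError):
    """A practice-sample combination has no entry in the probability table."""

    def __init__(self, combo):
        self.combo = frozenset(combo)
        super().__init__(
            "no recall probability for combination "
            + "-".join(sorted(self.combo))
        )


class ConfigError(DbComboError):
    """A synthetic-corpus configuration is invalid."""
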