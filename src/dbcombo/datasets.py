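"""Published benchmark counts for the 58-review prospective evaluation.

A prospective study at one academic medical library recorded, for 58
systematic reviews, the records every database search returned and
which of the reviews' included references each database had retrieved.
Its aggregate counts are reproduced here as input data: per-database
unique-reference counts, per-combination deduplicated result and
include counts for the four key databases (Embase, MEDLINE, Web of
Science, Google Scholar), and a 200-review practice sample with the
measured per-combination recall probabilities.

Everything downstream of these numbers (recall, precision, NNR, the
practice-sample probability of acceptable recall) is recomputed by the
package; nothing here stores a derived performance figure except the
practice sample's probability columns, which are measured corpus
attainment shares and serve as *inputs* to the practice model.
"""

from __future__ import annotations

from .combinations import UniqueContribution
from .practice import PracticeSample, RecallProbabilityTable

__all__ = [
    "INCLUDES_PUBLISHED_TOTAL",
    "INCLUDES_OTHER_METHODS",
    "INCLUDES_RETRIEVED_TOTAL",
    "UNIQUE_REFERENCES_TOTAL",
    "N_REVIEWS",
    "KEY_DATABASES",
    "benchmark_combination_counts",
    "benchmark_unique_contributions",
    "benchmark_practice_sample",
    "benchmark_probability_table",
]

N_REVIEWS = 58
#: Includes listed by the published reviews, includes found only by
#: non-database methods, and the difference: the retrieved-basis
#: denominator used by every combination comparison.
INCLUDES_PUBLISHED_TOTAL = 1830
INCLUDES_OTHER_METHODS = 84
INCLUDES_RETRIEVED_TOTAL = 1746
#: Retrieved includes found by exactly one database.
UNIQUE_REFERENCES_TOTAL = 292

KEY_DATABASES = ("EMBASE", "GS", "MEDLINE", "WOS")

#: combination -> (deduplicated records retrieved, includes retrieved),
#: pooled over all 58 reviews (every review searched all four).
_COMBINATION_COUNTS: dict[frozenset[str], tuple[int, int]] = {
    frozenset({"EMBASE"}): (85_521, 1500),
    frozenset({"MEDLINE"}): (56_340, 1375),
    frozenset({"WOS"}): (48_561, 1189),
    frozenset({"GS"}): (10_342, 601),
    frozenset({"EMBASE", "MEDLINE"}): (100_444, 1621),
    frozenset({"EMBASE", "WOS"}): (104_444, 1585),
    frozenset({"EMBASE", "GS"}): (91_411, 1570),
    frozenset({"MEDLINE", "WOS"}): (75_263, 1481),
    frozenset({"MEDLINE", "GS"}): (62_230, 1459),
    frozenset({"WOS", "GS"}): (54_451, 1320),
    frozenset({"EMBASE", "MEDLINE", "GS"}): (106_334, 1674),
    frozenset({"EMBASE", "MEDLINE", "WOS"}): (119_367, 1674),
    frozenset({"EMBASE", "WOS", "GS"}): (110_334, 1638),
    frozenset({"MEDLINE", "WOS", "GS"}): (81_153, 1528),
    frozenset({"EMBASE", "MEDLINE", "WOS", "GS"}): (125_257, 1716),
}

#: (database, reviews that searched it, reviews where it had unique
#: references, unique references) — the candidate-selection input.
_UNIQUE_CONTRIBUTIONS = (
    ("EMBASE", 58, 29, 132),
    ("MEDLINE", 58, 27, 69),
    ("WOS", 58, 19, 37),
    ("GS", 58, 24, 37),
    ("CINAHL", 18, 1, 6),
    ("SCOPUS", 24, 3, 5),
    ("PSYCINFO", 11, 1, 2),
    ("SPORTDISCUS", 2, 2, 3),
)

#: 200 recent published reviews: which key-database combinations they
#: searched.  Two reviews searched none of the key databases, so the
#: matched frequencies sum to 198 of an n_total of 200.
_PRACTICE_FREQUENCIES: tuple[tuple[frozenset[str], int], ...] = (
    (frozenset({"EMBASE", "MEDLINE"}), 73),
    (frozenset({"MEDLINE"}), 41),
    (frozenset({"EMBASE", "MEDLINE", "WOS"}), 40),
    (frozenset({"MEDLINE", "WOS"}), 21),
    (frozenset({"MEDLINE", "GS"}), 7),
    (frozenset({"MEDLINE", "WOS", "GS"}), 7),
    (frozenset({"EMBASE", "MEDLINE", "GS"}), 5),
    (frozenset({"EMBASE"}), 2),
    (frozenset({"EMBASE", "WOS"}), 1),
    (frozenset({"WOS"}), 1),
)

#: Measured attainment shares for the sampled combinations:
#: P(recall >= 0.95) and P(recall = 1.0) per combination, as printed in
#: the study's practice table (percent / 100).
_PRACTICE_PROBABILITIES: dict[frozenset[str], dict[float, float]] = {
    frozenset({"EMBASE", "MEDLINE"}): {0.95: 0.47, 1.0: 0.24},
    frozenset({"MEDLINE"}): {0.95: 0.16, 1.0: 0.09},
    frozenset({"EMBASE", "MEDLINE", "WOS"}): {0.95: 0.64, 1.0: 0.36},
    frozenset({"MEDLINE", "WOS"}): {0.95: 0.21, 1.0: 0.16},
    frozenset({"MEDLINE", "GS"}): {0.95: 0.26, 1.0: 0.16},
    frozenset({"MEDLINE", "WOS", "GS"}): {0.95: 0.37, 1.0: 0.29},
    frozenset({"EMBASE", "MEDLINE", "GS"}): {0.95: 0.76, 1.0: 0.41},
    frozenset({"EMBASE"}): {0.95: 0.19, 1.0: 0.14},
    frozenset({"EMBASE", "WOS"}): {0.95: 0.40, 1.0: 0.28},
    frozenset({"WOS"}): {0.95: 0.07, 1.0: 0.07},
}


def benchmark_combination_counts() -> dict[frozenset[str], tuple[int, int]]:
    """Per-combination (results, includes) counts; denominator 1746."""
    return dict(_COMBINATION_COUNTS)


def benchmark_unique_contributions() -> list[UniqueContribution]:
    return [UniqueContribution(*row) for row in _UNIQUE_CONTRIBUTIONS]


def benchmark_practice_sample() -> PracticeSample:
    return PracticeSample(entries=_PRACTICE_FREQUENCIES, n_total=200)


def benchmark_probability_table() -> RecallProbabilityTable:
    return RecallProbabilityTable(
        {combo: dict(ps) for combo, ps in _PRACTICE_PROBABILITIES.items()}
    )
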