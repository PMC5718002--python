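# dbcombo

Which bibliographic databases does a systematic review actually need to
search?

Systematic reviews are expected to find *every* study meeting their
criteria, so searchers query many databases — Embase, MEDLINE, Web of
Science, Google Scholar, Cochrane CENTRAL, subject databases — at a
heavy cost in search translation and screening burden. `dbcombo` is a
toolkit for information specialists and meta-researchers who have (or
simulate) per-review retrieval data: which databases were searched,
what each returned, and which of the review's included references each
database retrieved. From that it evaluates every database combination
and asks whether published reviews search enough.

## Measures

For a combination *C* of databases evaluated on reviews with included
references (the relevance gold standard):

- **recall(C)** = included references retrieved by *C* / included
  references retrieved by *any* searched database,
- **precision(C)** = included references retrieved by *C* / all
  (deduplicated) records retrieved by *C*,
- **NNR(C)** = 1 / precision(C), the number of records screened per
  relevant reference found.

Recall is reported pooled over all reviews and per review (median,
minimum, share of reviews at 100%), plus *attainment*: the share of
reviews for which *C* reaches a recall threshold (e.g. 95%).
The practice model combines a frequency table of the combinations
published reviews report searching with measured attainment, giving the
probability that a review drawn from current practice achieved
acceptable recall:
P(acceptable) = Σ_C w_C · P(recall ≥ t | C).

An included reference retrieved by exactly one database is a *unique
reference*; unique counts identify the candidate databases worth
evaluating exhaustively.

## Worked example

The package ships the pooled benchmark counts of a prospective
58-review evaluation (per-combination deduplicated results and
includes, denominator 1746 retrieved includes) and a 200-review
practice sample:

```python
from dbcombo import format_percent, number_needed_to_read, precision, recall
from dbcombo.datasets import (
    INCLUDES_RETRIEVED_TOTAL,
    benchmark_combination_counts,
    benchmark_practice_sample,
    benchmark_probability_table,
)
from dbcombo.practice import probability_of_acceptable_recall

counts = benchmark_combination_counts()
for name, combo in [("Embase alone", frozenset({"EMBASE"})),
                    ("EM+ML+WoS+GS", frozenset({"EMBASE", "MEDLINE", "WOS", "GS"}))]:
    results, includes = counts[combo]
    print(name,
          format_percent(recall(includes, INCLUDES_RETRIEVED_TOTAL)),
          format_percent(precision(includes, results)),
          round(number_needed_to_read(results, includes)))

p95 = probability_of_acceptable_recall(
    benchmark_practice_sample(), benchmark_probability_table(), 0.95)
print("P(recall >= 95%) in published practice:", format_percent(p95, 0))
```

prints

```
Embase alone 85.9% 1.8% 57
EM+ML+WoS+GS 98.3% 1.4% 73
P(recall >= 95%) in published practice: 40%
```

Read: Embase alone finds 85.9% of the relevant references at one hit
per 57 records screened; adding MEDLINE, Web of Science and Google
Scholar lifts recall to 98.3% at 73 records per hit — and only ~40% of
published reviews search a combination good enough for 95% recall.

The same pipeline runs end-to-end on generated data from the shell:

```
dbcombo synth --seed 42 --out corpus/
dbcombo ingest --manifest corpus/manifest.yaml --out corpus.json
dbcombo match --corpus corpus.json --out matched.json --audit audit.csv
dbcombo analyze --corpus matched.json --out reports/
```

`reports/` then contains the unique-contribution, subset-performance,
attainment and burden-ratio tables as CSV.

## Synthetic corpora

No raw multi-database retrieval data are publicly deposited, so
`dbcombo.synth` generates corpora with the recorded structure: 58
reviews, ~31 includes each, per-database retrieval probabilities set to
the observed single-database recalls, strong positive overlap (~17% of
includes unique to one database), ~4.6% of includes found outside the
databases, study-scale irrelevant volumes (NNR ≈ 17–73) and a
relevance-ranked Google-Scholar-like source truncated at 200 records.
Every membership draw is returned in a ground-truth ledger so any
analysis output can be recomputed by brute force (`truth_recount`) —
the test suite holds the pipeline to exact agreement with that oracle.
See `docs/methods.md` for the generative model and its limitations.

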