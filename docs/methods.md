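# Methods

## The evaluation model

The unit of analysis is a systematic review with recorded searches: the
set of databases searched, the records each returned (deduplicated into
one record per distinct work, with the set of databases that retrieved
it — its *provenance*), and the review's included references. Includes
retrieved by no database are attributed to other search methods (hand
searching, reference checking, author contact); they are excluded from
the default recall denominator, because a database combination cannot
be blamed for missing a reference no database search found. Both
denominators are available: `basis="retrieved"` (default) and
`basis="published"` (all includes).

A combination *C* is evaluated only on reviews that searched every
member of *C* — scoring an unsearched database as a miss would bias
recall downward. Over the evaluated reviews the package reports pooled
(overall) recall, the per-review median and minimum, the share of
reviews at full recall, precision and number needed to read, plus
attainment curves at arbitrary thresholds and two burden ratios
per review:

- *results reduction*: deduplicated records of *C* / deduplicated
  records of the full searched set (1.0 = no reduction);
- *precision improvement*: precision of *C* / precision of the full
  searched set. Values above 1 mean *C* is more precise than searching
  everything. (The two possible orientations of this ratio are easy to
  confuse; this package fixes this one and states it everywhere the
  ratio appears.)

Candidate databases for exhaustive evaluation are chosen by unique
contribution: the number of includes whose provenance is exactly that
database. Exhaustive evaluation enumerates all 2^n − 1 subsets (capped
at n = 12). A greedy set-cover variant adds databases by marginal gain
in the share of reviews reaching a target recall, per unit cost; when
no single database moves that share, the mean per-review recall breaks
the plateau. Greedy selection is a heuristic: on small corpora the
tests compare it against exhaustive enumeration.

### Practice assessment

Given a frequency table of the key-database combinations that a sample
of published reviews searched, and the corpus-measured attainment
P(recall ≥ t | C), the probability that a sampled review reached
acceptable recall is the frequency-weighted sum of the per-combination
attainment. Reviews searching none of the key databases contribute
probability zero. Two weighting conventions are exposed: dividing by
the summed matched frequency (default, matching how such tables are
conventionally printed) or by the full sample size. On the shipped
benchmark inputs the model yields 40% at the 95% threshold and 23% at
full recall; the per-row weighted products in the emitted table
reproduce the printed benchmark rows to within rounding. In the
published benchmark table the final column is headed as a product of
the two probability columns but its values are the frequency share
times the full-recall probability; the package computes and labels the
latter, treating the header as a typo.

## Reference matching

Included references are located in a review's combined
pre-deduplication library by a two-stage procedure mirroring manual
practice: first a normalized `surname|year` key (first-author surname,
publication year); when several distinct works share the key, exact
second-author surname equality (cheap and strict) and then title-token
Jaccard similarity with threshold 0.6 decide. The threshold is a
numeric surrogate for a human's "distinct part of the title" judgement;
0.6 tolerates truncations and subtitle loss while separating different
works that share an author and year. All records of the winning work —
one per database that retrieved it — contribute provenance. A
similarity tie between distinct works is flagged `ambiguous-unresolved`
and excluded with a warning rather than guessed, so every attribution
is auditable from the match log.

Text identity uses one normal form everywhere: casefold, NFKD
decomposition with combining marks stripped, punctuation dropped,
whitespace collapsed. On clean synthetic corpora matching recovers the
ground-truth membership exactly; under injected title perturbations the
error rate is measured, not assumed (case and diacritic perturbations
are absorbed completely by normalization; truncation is the failure
mode, reported by the perturbation tests).

DOI/PMID matching is deliberately absent: the procedure targets
exports where identifier coverage is unreliable, and author-year-title
matching is the auditable common denominator.

## The synthetic corpus generator

The generator emulates the recorded structure of a 58-review,
multi-database prospective evaluation. Defaults (all overridable):

| parameter | default | meaning |
| --- | --- | --- |
| `n_reviews` | 58 | corpus size |
| `includes_per_review_mean` | 31.6 | Poisson mean; only the total (1830/58) is constrained by the emulated conditions |
| `retrieval_marginals` | EMBASE .859, MEDLINE .788, WOS .681, GS .344, CENTRAL .25, CINAHL .20, SCOPUS .45, PSYCINFO .15, SPORTDISCUS .30 | P(include retrieved by d \| retrieved by ≥1), per database; the four key values are the observed single-database recalls, the rest are plausible fill-ins for databases whose recall was not reported |
| `overlap_strength` | 0.85 | amplitude of the shared latent state (below) |
| `other_methods_rate` | 0.046 | share of includes retrieved by no database |
| `search_probabilities` | core five 1.0; CINAHL 18/58, SCOPUS 24/58, PSYCINFO 11/58, SPORTDISCUS 2/58 | P(a review searches d), matching observed usage |
| `noise_pool_mean`, `noise_pool_dispersion` | 2130, 12 | negative-binomial candidate pool of irrelevant works per review (overdispersed across reviews) |
| `noise_marginals` | EMBASE .60, MEDLINE .385, WOS .33, GS .08, ... | P(an irrelevant candidate is returned by d) |
| `gs_rank_cap` / `gs_low_yield_cap` | 200 / 100 | Google-Scholar truncation; the tighter cap applies to reviews whose non-GS volume falls in the bottom `gs_low_yield_quantile` (0.1) of the corpus |

**Overlap model.** Each include draws a fair-coin latent "mainstream"
state. Conditional on the state, databases retrieve it independently
with probability p ± `overlap_strength` · min(p, 1 − p) (elevated for
mainstream, lowered otherwise). The symmetric placement preserves the
marginal exactly while the shared state induces positive correlation
whose covariance grows as the square of `overlap_strength` — so
pairwise overlap is provably monotone in the parameter, and at the
default the corpus lands at roughly 17% of retrieved includes unique
to a single database with most found by two or more. An asymmetric
variant (elevate mainstream only) was rejected because it inflates the
realized marginal above the configured value and loses monotonicity at
high strength.

**Conditioning on retrieval.** The configured marginals are
retrieved-basis quantities (that is what observed single-database
recalls are), so the generator solves a small per-review fixed point
q = p · P(retrieved | q) and rejection-samples membership vectors
conditional on non-emptiness. Pooled single-database recalls then
recover the configured marginals without bias; the suite checks them
to three binomial standard errors on 1700+ includes.

**Irrelevant volume.** Each review draws a candidate pool of irrelevant
works; each candidate is returned by each searched database
independently (conditional on being returned at all), giving
per-database volumes and between-database overlap of irrelevant records
in one mechanism. Defaults are sized so per-database volumes and
single-database NNRs match the emulated conditions (≈57, 41, 41, 17)
and the four-database NNR lands near 70.

**Google Scholar.** GS-retrieved records are relevance-ranked (includes
draw high scores, irrelevant works low, small overlap) and truncated to
the cap; truncation therefore sheds noise almost always, as a
relevance-sorted engine's first pages would.

**What the generator does not emulate**, and what passing tests
therefore do not show about real data: topic structure (domain effects
exist only as an optional planted multiplier, `domain_effect`),
search-strategy quality, database indexing lag, messy metadata beyond
the explicit title-perturbation operator, and niche-database-only
retrieval. On the last point: a single shared latent concentrates the
non-core retrieval mass into the other-methods category, so the
synthetic four-database combination misses fewer retrieved includes
(recall ≈ 99.8%, full recall in ≈ 95% of reviews) than the emulated
evaluation observed (98.3% / 74%), where niche databases occasionally
held the only copy of an include. Calibration priorities were the
single-database recalls, the unique share, the other-methods rate and
the NNR range; a second latent dimension for subject-specific retrieval
would be needed to also reproduce the four-database miss rate.

## Numerical choices

- All metrics are exact fractions internally; rounding happens once, at
  report time: one decimal for performance percentages, whole percents
  for practice tables, nearest integer for NNR, all round-half-up.
- Median of per-review recalls: midpoint average for even counts.
- Attainment comparison is ≥ by default; a strict `>` comparator is
  available (at threshold 1.0 strict comparison is unsatisfiable, so ≥
  is always used there).
- Full recall is tested as ≥ 1 − 1e−12 to absorb float division.
- Deduplicated result counts are exact record-membership unions when
  records are present; a counts-only corpus falls back to summed
  per-database counts, flagged `dedup_exact=False`. The exact mode is
  an improvement over working from counts recorded at search time,
  which cannot be re-deduplicated per subset.
- Candidate ordering and greedy ties break by unique-reference count,
  then reviews-with-unique, then canonical name — fully deterministic.
- The empty combination retrieves nothing by convention (recall 0);
  empty denominators raise `EmptyDenominatorError` rather than
  returning NaN.

## Benchmark data discrepancies

The shipped benchmark counts contain two internal inconsistencies of
their source, carried as-is rather than repaired: the per-database
unique-reference counts sum to 291 while the corpus-level unique total
is reported as 292 (shares are computed from whichever count the
operation actually uses); and one three-database row prints NNR 70
while its own counts give 119367/1674 = 71.3 (the package reports the
computed value; the row's printed precision of 1.4% is consistent with
71).

## Known limitations

- Reference matching has no identifier stage; heavily truncated titles
  plus author-year collisions can produce unresolved ambiguity, which
  is flagged and excluded rather than guessed.
- The counts-only fallback cannot deduplicate across databases, so its
  precision/NNR overstate the screening burden of multi-database
  combinations relative to the exact mode.
- Attainment shares on small strata are coarse (steps of 1/n); the
  stratified output reports n per group so users can judge.
- The greedy cover optimizes attainment share, not pooled recall; it
  can stop early on plateaus its secondary objective cannot break
  (e.g. all remaining databases useless alone and jointly).
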