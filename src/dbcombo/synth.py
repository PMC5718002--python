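"""Synthetic review corpora with realistic database-overlap structure.

No raw data from multi-database review searches are publicly deposited,
so every stage of the pipeline is exercised against generated corpora
that emulate the recorded structure of such data:

* ~58 reviews, each searching a core of Embase, MEDLINE, Web of
  Science, Google Scholar and Cochrane CENTRAL, plus subject databases
  (CINAHL, PsycINFO, Scopus, SportDiscus) with review-level
  probabilities;
* ~31 included references per review on average (1830 over 58
  reviews), of which a configurable share (default 4.6%) was found only
  by non-database methods;
* per-database marginal retrieval probabilities for includes set to the
  observed single-database recalls (Embase 0.859, MEDLINE 0.788, Web of
  Science 0.681, Google Scholar 0.344), with strong positive pairwise
  overlap so that most retrieved includes are found by two or more
  databases and roughly 17% are unique to one;
* large per-database volumes of irrelevant records, overdispersed
  across reviews and overlapping between databases, sized so the number
  needed to read falls in the observed 17-73 range;
* a relevance-ranked Google-Scholar-like database truncated to its
  first 200 records, or 100 for low-yield reviews.

Overlap model.  Each include draws a latent "mainstream" indicator
(fair coin).  Mainstream includes are retrieved by every searched
database with an elevated probability, non-mainstream with a lowered
one; the two are placed symmetrically around the configured marginal
(elevation amplitude = ``overlap_strength`` x min(p, 1-p)), so the
marginal is preserved exactly while the shared latent state induces
positive correlation between databases that grows monotonically with
``overlap_strength``.  Because the observed single-database recalls are
*conditional on retrieval by at least one database*, the generator
solves a small fixed point per review (q = p x P(retrieved | q)) and
rejection-samples membership vectors conditional on non-emptiness, so
pooled retrieved-basis recalls recover the configured marginals without
bias.

The ground truth (every membership vector drawn) is returned beside the
corpus as a :class:`SyntheticTruth` ledger, sufficient to recompute any
analysis output by brute force (:func:`truth_recount`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ConfigError
from .labels import default_registry
from .metrics import MetricInputs
from .model import Combo, Corpus, ReferenceRecord, ReviewDataset

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_corpus",
    "truth_recount",
    "TruthCounts",
    "perturb_titles",
    "default_config",
]

CORE_DATABASES = ("EMBASE", "MEDLINE", "WOS", "GS", "COCHRANE_CENTRAL")

_DEFAULT_SEARCH_PROBS = {
    "EMBASE": 1.0,
    "MEDLINE": 1.0,
    "WOS": 1.0,
    "GS": 1.0,
    "COCHRANE_CENTRAL": 1.0,
    "CINAHL": 18 / 58,
    "SCOPUS": 24 / 58,
    "PSYCINFO": 11 / 58,
    "SPORTDISCUS": 2 / 58,
}

#: Retrieved-basis marginal retrieval probability of an include, per
#: database.  The four key databases carry the observed single-database
#: recalls; the rest are plausible values for databases whose recall
#: was not reported.
_DEFAULT_MARGINALS = {
    "EMBASE": 0.859,
    "MEDLINE": 0.788,
    "WOS": 0.681,
    "GS": 0.344,
    "COCHRANE_CENTRAL": 0.25,
    "CINAHL": 0.20,
    "SCOPUS": 0.45,
    "PSYCINFO": 0.15,
    "SPORTDISCUS": 0.30,
}

#: Probability that an irrelevant candidate work is returned by each
#: database's search, sized so expected per-review volumes mirror the
#: recorded ones (Embase ~1475/review ... Google Scholar under its rank
#: cap) and the four-database union is ~60% of the summed counts.
_DEFAULT_NOISE_MARGINALS = {
    "EMBASE": 0.60,
    "MEDLINE": 0.385,
    "WOS": 0.33,
    "GS": 0.08,
    "COCHRANE_CENTRAL": 0.21,
    "CINAHL": 0.10,
    "SCOPUS": 0.30,
    "PSYCINFO": 0.08,
    "SPORTDISCUS": 0.05,
}

_DOMAIN_WEIGHTS = {
    "therapy": 19,
    "etiology": 13,
    "epidemiology": 6,
    "diagnosis": 6,
    "management": 5,
    "prognosis": 5,
    "unknown": 4,
}

_SURNAMES = [f"Author{i:03d}" for i in range(160)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_reviews: int = 58
    seed: int = 0
    search_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEARCH_PROBS)
    )
    includes_per_review_mean: float = 1830 / 58
    retrieval_marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS)
    )
    overlap_strength: float = 0.85
    other_methods_rate: float = 0.046
    noise_pool_mean: float = 2130.0
    noise_pool_dispersion: float = 12.0  # negative-binomial shape across reviews
    noise_marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_MARGINALS)
    )
    gs_rank_cap: int = 200
    gs_low_yield_cap: int = 100
    gs_low_yield_quantile: float = 0.1
    domain_effect: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        def _check_probs(name: str, mapping: Mapping[str, float]) -> None:
            for d, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{d}] = {p} outside [0, 1]")

        if self.n_reviews < 1:
            raise ConfigError("n_reviews must be positive")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer (mandatory for reproducibility)")
        _check_probs("search_probabilities", self.search_probabilities)
        _check_probs("retrieval_marginals", self.retrieval_marginals)
        _check_probs("noise_marginals", self.noise_marginals)
        if not 0.0 <= self.overlap_strength <= 1.0:
            raise ConfigError("overlap_strength must lie in [0, 1]")
        if not 0.0 <= self.other_methods_rate < 1.0:
            raise ConfigError("other_methods_rate must lie in [0, 1)")
        if self.gs_rank_cap <= 0 or self.gs_low_yield_cap <= 0:
            raise ConfigError("rank caps must be positive")
        if self.includes_per_review_mean <= 0 or self.noise_pool_mean < 0:
            raise ConfigError("means must be non-negative")
        if self.noise_pool_dispersion <= 0:
            raise ConfigError("noise_pool_dispersion must be positive")
        unknown = set(self.retrieval_marginals) - set(self.search_probabilities)
        if unknown:
            raise ConfigError(f"marginals given for unsearchable databases {sorted(unknown)}")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study-condition configuration, optionally overridden."""
    return replace(SyntheticConfig(seed=seed), **overrides)


@dataclass(frozen=True)
class ReviewTruth:
    """Ground truth for one generated review."""

    review_id: str
    searched: Combo
    include_membership: tuple[Combo, ...]  # empty set = other-methods include
    noise_membership: tuple[Combo, ...]
    domain: str


@dataclass(frozen=True)
class SyntheticTruth:
    """Ledger of every membership draw; the brute-force oracle's input."""

    config: SyntheticConfig
    reviews: tuple[ReviewTruth, ...]

    def by_id(self, review_id: str) -> ReviewTruth:
        for r in self.reviews:
            if r.review_id == review_id:
                return r
        raise KeyError(review_id)


# ---------------------------------------------------------------------------
# membership sampling


def _conditional_marginal_fixed_point(
    p: np.ndarray, s: float, max_iter: int = 60
) -> np.ndarray:
    """Latent marginals q with q_d / P(non-empty | q) = p_d.

    Solves q = p * P(non-empty | q) by fixed-point iteration, where
    non-emptiness probability is evaluated under the two-point overlap
    mixture.  Values are clipped to [0, 1]; with realistic marginals the
    retrieval probability is near 1 and convergence takes a handful of
    iterations.
    """
    q = p.copy()
    for _ in range(max_iter):
        amp = s * np.minimum(q, 1.0 - q)
        p_none = 0.5 * np.prod(1.0 - np.clip(q + amp, 0, 1)) + 0.5 * np.prod(
            1.0 - np.clip(q - amp, 0, 1)
        )
        q_new = np.clip(p * (1.0 - p_none), 0.0, 1.0)
        if np.max(np.abs(q_new - q)) < 1e-12:
            return q_new
        q = q_new
    return q


def _draw_membership(
    rng: np.random.Generator, q: np.ndarray, s: float
) -> np.ndarray:
    """One membership vector from the overlap mixture, conditioned non-empty."""
    amp = s * np.minimum(q, 1.0 - q)
    for _ in range(10_000):
        probs = np.clip(q + amp, 0, 1) if rng.random() < 0.5 else np.clip(q - amp, 0, 1)
        vec = rng.random(q.size) < probs
        if vec.any():
            return vec
    raise ConfigError("retrieval marginals too small to condition on retrieval")


def _draw_noise_pool(
    rng: np.random.Generator, n: int, probs: np.ndarray
) -> np.ndarray:
    """(n, d) irrelevant-work membership matrix, rows conditioned non-empty."""
    if n == 0:
        return np.zeros((0, probs.size), dtype=bool)
    mat = rng.random((n, probs.size)) < probs
    empty = ~mat.any(axis=1)
    while empty.any():
        mat[empty] = rng.random((int(empty.sum()), probs.size)) < probs
        empty = ~mat.any(axis=1)
    return mat


# ---------------------------------------------------------------------------
# corpus generation


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, SyntheticTruth]:
    """Generate a corpus and its ground-truth ledger; reproducible by seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    databases = sorted(config.search_probabilities)

    domains = list(_DOMAIN_WEIGHTS)
    domain_p = np.array(list(_DOMAIN_WEIGHTS.values()), dtype=float)
    domain_p /= domain_p.sum()

    # -- pass 1: draw everything except the Google-Scholar rank cap -------
    drafts = []
    uid = 0
    for i in range(config.n_reviews):
        rid = f"sr{i + 1:03d}"
        searched = sorted(
            d for d in databases if rng.random() < config.search_probabilities[d]
        ) or ["MEDLINE"]
        domain = domains[int(rng.choice(len(domains), p=domain_p))]
        effect = float(config.domain_effect.get(domain, 1.0))
        p = np.clip(
            np.array([config.retrieval_marginals.get(d, 0.0) for d in searched]) * effect,
            0.0,
            1.0,
        )
        n_includes = max(1, int(rng.poisson(config.includes_per_review_mean)))
        q = _conditional_marginal_fixed_point(p, config.overlap_strength)
        include_membership: list[frozenset[str]] = []
        for _ in range(n_includes):
            if rng.random() < config.other_methods_rate or not q.any():
                include_membership.append(frozenset())
            else:
                vec = _draw_membership(rng, q, config.overlap_strength)
                include_membership.append(
                    frozenset(d for d, hit in zip(searched, vec) if hit)
                )
        n_noise = int(
            rng.negative_binomial(
                config.noise_pool_dispersion,
                config.noise_pool_dispersion
                / (config.noise_pool_dispersion + config.noise_pool_mean),
            )
        ) if config.noise_pool_mean > 0 else 0
        noise_probs = np.array([config.noise_marginals.get(d, 0.0) for d in searched])
        if noise_probs.sum() == 0:
            n_noise = 0
        noise = _draw_noise_pool(rng, n_noise, noise_probs)
        noise_membership = [
            frozenset(d for d, hit in zip(searched, row) if hit) for row in noise
        ]
        drafts.append(
            {
                "rid": rid,
                "searched": searched,
                "domain": domain,
                "include_membership": include_membership,
                "noise_membership": noise_membership,
            }
        )

    # -- low-yield rule: reviews whose non-GS volume is in the bottom
    # quantile get the tighter Google-Scholar cap ---------------------------
    non_gs_totals = np.array(
        [
            sum(
                1
                for m in d["include_membership"] + d["noise_membership"]
                if m - {"GS"}
            )
            for d in drafts
        ],
        dtype=float,
    )
    cutoff = np.quantile(non_gs_totals, config.gs_low_yield_quantile)

    reviews: list[ReviewDataset] = []
    truths: list[ReviewTruth] = []
    for draft, non_gs_total in zip(drafts, non_gs_totals):
        cap = config.gs_low_yield_cap if non_gs_total <= cutoff else config.gs_rank_cap
        include_membership, noise_membership = _apply_gs_cap(
            rng, draft["include_membership"], draft["noise_membership"], cap
        )
        searched = draft["searched"]
        rid = draft["rid"]

        include_records = []
        for j, member in enumerate(include_membership):
            include_records.append(
                ReferenceRecord(
                    record_id=f"{rid}-inc{j:03d}",
                    first_author_surname=_SURNAMES[uid % len(_SURNAMES)],
                    second_author_surname=_SURNAMES[(uid * 7 + 3) % len(_SURNAMES)],
                    year=2000 + uid % 16,
                    title=f"Synthetic trial {uid:05d} of exposure {uid % 97} on outcome {uid % 53}",
                    retrieved_by=member,
                    is_included=True,
                )
            )
            uid += 1
        noise_records = []
        for j, member in enumerate(noise_membership):
            noise_records.append(
                ReferenceRecord(
                    record_id=f"{rid}-bg{j:05d}",
                    first_author_surname=_SURNAMES[(uid * 3 + 1) % len(_SURNAMES)],
                    year=1990 + uid % 32,
                    title=f"Background report {uid:06d} unrelated topic {uid % 211}",
                    retrieved_by=member,
                    is_included=False,
                )
            )
            uid += 1

        records = tuple(
            [r for r in include_records if r.retrieved_by] + noise_records
        )
        result_counts = {
            d: sum(1 for r in records if d in r.retrieved_by) for d in searched
        }
        metadata = {} if draft["domain"] == "unknown" else {"domain": draft["domain"]}
        reviews.append(
            ReviewDataset(
                review_id=rid,
                searched_databases=frozenset(searched),
                result_counts=result_counts,
                records=records,
                includes=tuple(include_records),
                metadata=metadata,
            )
        )
        truths.append(
            ReviewTruth(
                review_id=rid,
                searched=frozenset(searched),
                include_membership=tuple(include_membership),
                noise_membership=tuple(noise_membership),
                domain=draft["domain"],
            )
        )

    corpus = Corpus(reviews=tuple(reviews), database_registry=tuple(default_registry()))
    corpus.validate()
    return corpus, SyntheticTruth(config=config, reviews=tuple(truths))


def _apply_gs_cap(
    rng: np.random.Generator,
    include_membership: list[frozenset[str]],
    noise_membership: list[frozenset[str]],
    cap: int,
) -> tuple[list[frozenset[str]], list[frozenset[str]]]:
    """Truncate the Google-Scholar result list to its first ``cap`` records.

    Records are relevance-ranked: includes draw high scores, irrelevant
    works low ones, so truncation mostly sheds noise — mirroring a
    relevance-sorted engine whose first pages contain most of the
    relevant hits.
    """
    gs_inc = [i for i, m in enumerate(include_membership) if "GS" in m]
    gs_noise = [i for i, m in enumerate(noise_membership) if "GS" in m]
    n_gs = len(gs_inc) + len(gs_noise)
    if n_gs <= cap:
        return include_membership, noise_membership
    scored: list[tuple[float, str, int]] = []
    for i in gs_inc:
        scored.append((float(rng.uniform(0.75, 1.00)), "inc", i))
    for i in gs_noise:
        scored.append((float(rng.uniform(0.00, 0.78)), "bg", i))
    scored.sort(key=lambda t: -t[0])
    keep = {(kind, i) for _, kind, i in scored[:cap]}
    new_inc = [
        m - {"GS"} if ("GS" in m and ("inc", i) not in keep) else m
        for i, m in enumerate(include_membership)
    ]
    new_noise_all = [
        m - {"GS"} if ("GS" in m and ("bg", i) not in keep) else m
        for i, m in enumerate(noise_membership)
    ]
    # an irrelevant work retrieved only by the truncated tail vanishes
    new_noise = [m for m in new_noise_all if m]
    return new_inc, new_noise


# ---------------------------------------------------------------------------
# brute-force oracle


@dataclass(frozen=True)
class TruthCounts:
    """Naive recount of the truth ledger for one combination."""

    per_review: dict[str, MetricInputs]
    pooled: MetricInputs


def truth_recount(truth: SyntheticTruth, combo: Iterable[str]) -> TruthCounts:
    """Recount retrieval for a combination straight from membership vectors.

    Deliberately naive — plain set operations per record — so it can
    serve as an independent oracle for the analysis pipeline.  Reviews
    that did not search every combination member are excluded.  The
    empty combination retrieves nothing by convention (recall 0).
    """
    c = frozenset(combo)
    per_review: dict[str, MetricInputs] = {}
    pooled_ret, pooled_tot, pooled_res = 0, 0, 0
    for review in truth.reviews:
        if not c <= review.searched:
            continue
        retrieved_includes = [m for m in review.include_membership if m]
        includes_total = len(retrieved_includes)
        includes_retrieved = sum(1 for m in retrieved_includes if m & c)
        results_total = sum(1 for m in retrieved_includes if m & c) + sum(
            1 for m in review.noise_membership if m & c
        )
        per_review[review.review_id] = MetricInputs(
            includes_retrieved=includes_retrieved,
            includes_total=includes_total,
            results_total=results_total,
        )
        pooled_ret += includes_retrieved
        pooled_tot += includes_total
        pooled_res += results_total
    pooled = MetricInputs(
        includes_retrieved=pooled_ret,
        includes_total=pooled_tot,
        results_total=pooled_res,
    )
    return TruthCounts(per_review=per_review, pooled=pooled)


# ---------------------------------------------------------------------------
# title perturbation (matcher stress input)

_DIACRITIC_MAP = str.maketrans({"a": "á", "e": "é", "i": "í", "o": "ö", "u": "ü"})


_PERTURBATIONS = ("case", "truncate", "diacritics")


def perturb_titles(
    corpus: Corpus,
    rate: float,
    seed: int,
    kinds: tuple[str, ...] = _PERTURBATIONS,
) -> Corpus:
    """Randomly perturb record titles (case, truncation, diacritics).

    Only the library records change; includes keep their published
    titles, so the corpus stresses the matcher exactly where real
    exports are messy.  Ground truth is untouched.  ``kinds`` restricts
    the perturbations applied (e.g. ``("case",)`` for case changes
    only, which normalization must absorb completely).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if not kinds or any(k not in _PERTURBATIONS for k in kinds):
        raise ValueError(f"kinds must be a non-empty subset of {_PERTURBATIONS}")
    rng = np.random.default_rng(seed)
    new_reviews = []
    for review in corpus.reviews:
        new_records = []
        for rec in review.records:
            if rec.title and rng.random() < rate:
                kind = kinds[int(rng.integers(len(kinds)))]
                if kind == "case":
                    title = rec.title.upper()
                elif kind == "truncate":
                    title = rec.title[: max(1, int(len(rec.title) * 0.6))]
                else:
                    title = rec.title.translate(_DIACRITIC_MAP)
                rec = replace(rec, title=title)
            new_records.append(rec)
        new_reviews.append(replace(review, records=tuple(new_records)))
    return Corpus(reviews=tuple(new_reviews), database_registry=corpus.database_registry)
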