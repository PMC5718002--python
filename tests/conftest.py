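import pytest

from dbcombo.model import Corpus, ReferenceRecord, ReviewDataset
from dbcombo.synth import default_config, generate_corpus


def make_review(review_id, searched, include_provenances, n_noise_per_db=0, metadata=None):
    """Hand-build a review: includes with given provenance sets, optional
    database-specific noise records."""
    searched = frozenset(searched)
    includes = [
        ReferenceRecord(
            record_id=f"{review_id}-i{j}",
            first_author_surname=f"Inc{j}",
            year=2010,
            title=f"Included study {review_id} number {j}",
            retrieved_by=frozenset(prov),
            is_included=True,
        )
        for j, prov in enumerate(include_provenances)
    ]
    records = [r for r in includes if r.retrieved_by]
    k = 0
    noise_plan = (
        n_noise_per_db
        if isinstance(n_noise_per_db, dict)
        else {d: n_noise_per_db for d in searched}
    )
    for d in sorted(searched):
        for _ in range(noise_plan.get(d, 0)):
            records.append(
                ReferenceRecord(
                    record_id=f"{review_id}-n{k}",
                    first_author_surname=f"Bg{k}",
                    year=2005,
                    title=f"Background {review_id} item {k}",
                    retrieved_by=frozenset({d}),
                )
            )
            k += 1
    counts = {d: sum(1 for r in records if d in r.retrieved_by) for d in searched}
    return ReviewDataset(
        review_id=review_id,
        searched_databases=searched,
        result_counts=counts,
        records=tuple(records),
        includes=tuple(includes),
        metadata=metadata or {},
    )


@pytest.fixture
def tiny_review():
    """Three retrieved includes with provenance {A}, {A,B}, {B}."""
    return make_review(
        "tiny",
        ["EMBASE", "MEDLINE"],
        [{"EMBASE"}, {"EMBASE", "MEDLINE"}, {"MEDLINE"}],
    )


@pytest.fixture
def tiny_corpus(tiny_review):
    corpus = Corpus(reviews=(tiny_review,))
    corpus.validate()
    return corpus


def small_config(seed, **overrides):
    """A fast-to-generate configuration with the same structure as the
    default study conditions but less irrelevant-record volume."""
    params = dict(
        n_reviews=12,
        includes_per_review_mean=20.0,
        noise_pool_mean=120.0,
        seed=seed,
    )
    params.update(overrides)
    return default_config(**params)


@pytest.fixture(scope="session")
def small_synth():
    """A small seeded synthetic corpus plus its truth ledger."""
    return generate_corpus(small_config(seed=11))
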