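import numpy as np
import pytest

import tripletlab as tl


@pytest.fixture(scope="session")
def table4():
    return tl.load_table4_counts()


@pytest.fixture(scope="session")
def table7():
    return tl.load_fixture("table7")


@pytest.fixture(scope="session")
def table8():
    return tl.load_fixture("table8")


@pytest.fixture(scope="session")
def table7_truth(table7):
    return dict(zip(table7["triplet_id"].astype(int), table7["correct_label"]))


@pytest.fixture(scope="session")
def table7_counts(table7):
    return tl.vote_counts_from_ratios(table7, n=29)


def simulated_matrix(seed: int = 7, with_eda: bool = False):
    """A complete simulated annotation matrix under one seed."""
    cfg = tl.SimulationConfig(seed=seed)
    cohort = tl.generate_cohort(cfg)
    groups = tl.sample_and_group(cohort, seed=seed)
    triplets = tl.build_triplets(groups, cohort)
    results = tl.annotate_triplets(triplets)
    events = tl.simulate_annotators(triplets, [r.asba_u for r in results], cfg)
    if with_eda:
        series = tl.simulate_eda(events, cfg)
        events = tl.attach_eda_means(events, series)
    truth = {t.triplet_id: t.true_label for t in triplets}
    return tl.AnnotationMatrix(events, truth)


@pytest.fixture(scope="session")
def sim_matrix():
    return simulated_matrix(seed=7)


@pytest.fixture(scope="session")
def sim_matrix_eda():
    return simulated_matrix(seed=7, with_eda=True)


@pytest.fixture(scope="session")
def sim_cohort():
    return tl.generate_cohort(tl.SimulationConfig(seed=3))


def make_record(record_id="r0", stea=0, livfat=2.0, **overrides):
    """A cohort record with neutral defaults, overridable per field."""
    fields = dict(
        id=record_id,
        age=50.0,
        alat_s=0.5,
        alcohol_g_day=5.0,
        beta_blocker=0,
        crp_hs=1.0,
        diabetes=0,
        hypertonia=0,
        ldlch=3.5,
        sex="female",
        smoke_status="never",
        livfat_per=livfat,
        stea=stea,
    )
    fields.update(overrides)
    return tl.CohortRecord(**fields)


def brute_force_alpha(items: list[list[str]]) -> float:
    """Independent Krippendorff's alpha oracle by pair enumeration.

    ``items`` is a list of rating lists (nominal labels).  Observed
    disagreement averages the mismatch rate over all ordered within-item
    pairs weighted by 1/(m_u - 1); expected disagreement enumerates all
    ordered pairs of the pooled ratings.
    """
    big_n = sum(len(v) for v in items)
    d_o = 0.0
    for values in items:
        m = len(values)
        mismatches = sum(
            1 for i in range(m) for j in range(m) if i != j and values[i] != values[j]
        )
        d_o += mismatches / (m - 1)
    d_o /= big_n
    pooled = [v for values in items for v in values]
    mismatches = sum(
        1
        for i in range(big_n)
        for j in range(big_n)
        if i != j and pooled[i] != pooled[j]
    )
    d_e = mismatches / (big_n * (big_n - 1))
    return 1.0 - d_o / d_e
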