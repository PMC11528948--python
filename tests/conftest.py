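import pytest

from phenoconv.conversion import annotate_cohort
from phenoconv.simulate import MarginalSpec, reconstruct_marginal_cohort

# Printed-marginal reconstructions used across test modules: the 412-patient
# full sample (with its per-sex split), the 342-patient four-drug subsample,
# and the 49-patient aripiprazole group.
FULL_SAMPLE_SPEC = MarginalSpec(
    gpt_counts={"PM": 17, "IM": 167, "NM": 228},
    strong_counts={"IM": 38, "NM": 27},
    female_counts={"PM": 5, "IM": 41, "NM": 38},
    female_strong_counts={"IM": 10, "NM": 7},
)
SUBSAMPLE_SPEC = MarginalSpec(
    gpt_counts={"PM": 16, "IM": 130, "NM": 196},
    strong_counts={"IM": 29, "NM": 22},
)
ARIPIPRAZOLE_SPEC = MarginalSpec(
    gpt_counts={"PM": 3, "IM": 24, "NM": 22},
    strong_counts={"IM": 7, "NM": 4},
    main_drug="aripiprazole",
)


@pytest.fixture(scope="session")
def full_sample():
    return reconstruct_marginal_cohort(FULL_SAMPLE_SPEC)


@pytest.fixture(scope="session")
def full_sample_annotated(full_sample):
    annotated, events = annotate_cohort(full_sample)
    return annotated, events


@pytest.fixture(scope="session")
def subsample_annotated():
    annotated, events = annotate_cohort(reconstruct_marginal_cohort(SUBSAMPLE_SPEC))
    return annotated, events


@pytest.fixture(scope="session")
def aripiprazole_annotated():
    annotated, events = annotate_cohort(reconstruct_marginal_cohort(ARIPIPRAZOLE_SPEC))
    return annotated, events
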