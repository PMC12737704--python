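import numpy as np
import pytest

from screencut.cohorts import CohortDataset, ScaleSpec
from screencut.synthetic import generate_study_suite


@pytest.fixture(scope="session")
def scale():
    return ScaleSpec()


@pytest.fixture(scope="session")
def suite():
    """Default five-cohort synthetic study, fixed seed, shared across tests."""
    return generate_study_suite(seed=11)


@pytest.fixture
def tiny_cohort(scale):
    # perfect separation at c = 35
    return CohortDataset(
        dataset_id="tiny",
        participant_ids=np.array(["a", "b", "c", "d"], dtype=object),
        scores=np.array([40, 30, 35, 34]),
        outcomes=np.array([1, 0, 1, 0]),
        scale=scale,
    )


def random_cohort(rng, n=60, scale=None, dataset_id="rand"):
    """Small random integer-score cohort with both classes guaranteed."""
    scale = scale or ScaleSpec()
    n_pos = int(rng.integers(5, n - 5))
    scores = np.concatenate(
        [
            rng.integers(25, 60, n_pos),  # positives shifted upward
            rng.integers(13, 50, n - n_pos),
        ]
    )
    outcomes = np.concatenate([np.ones(n_pos, int), np.zeros(n - n_pos, int)])
    ids = np.array([f"r{i}" for i in range(n)], dtype=object)
    return CohortDataset(dataset_id, ids, scores, outcomes, scale)


# Summary statistics published for a five-cohort validation study of a
# 13-65 vaccine-hesitancy scale (fixed cut-off ">= 35"); used as *inputs*
# when checking the closed-form metric chains.
PUBLISHED_AUC = {
    "derivation": 0.960,
    "retest": 0.971,
    "validation_1": 0.891,
    "validation_2": 0.851,
    "validation_3": 0.760,
}
PUBLISHED_AT_35 = {
    # dataset: (prevalence, sensitivity, specificity)
    "derivation": (0.092, 0.935, 0.874),
    "retest": (0.092, 0.954, 0.870),
    "validation_1": (0.084, 0.878, 0.772),
    "validation_2": (0.181, 0.742, 0.819),
    "validation_3": (0.202, 0.733, 0.628),
}
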