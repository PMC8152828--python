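import numpy as np
import pytest

from painnet.connectivity import ConnectivityMatrix
from painnet.graphs import ThresholdedGraph
from painnet.pipeline import subject_condition_matrices
from painnet.roi import load_ground_truth_partition, load_roi_table
from painnet.synth import default_ground_truth, generate_cohort


@pytest.fixture(scope="session")
def roi34():
    return load_roi_table(include_audio_nodes=False)


@pytest.fixture(scope="session")
def roi36():
    return load_roi_table(include_audio_nodes=True)


@pytest.fixture(scope="session")
def truth34(roi34):
    return load_ground_truth_partition(roi34)


@pytest.fixture(scope="session")
def small_cohort(roi34, truth34):
    """4-subject, 2-session pain-only cohort (group-2 acquisition)."""
    gt = default_ground_truth(truth34)
    cohort, gt = generate_cohort(
        roi34, gt, n_subjects=4, n_sessions=2, preset="group2", seed=11
    )
    return cohort, gt


@pytest.fixture(scope="session")
def pain_mats(small_cohort):
    cohort, _ = small_cohort
    return subject_condition_matrices(cohort, "pain")


def clique_pair_graph(k: int = 4, weight: float = 1.0) -> ThresholdedGraph:
    """Two disconnected positive k-cliques (known optimum Q = 0.5)."""
    n = 2 * k
    A = np.zeros((n, n))
    A[:k, :k] = weight
    A[k:, k:] = weight
    np.fill_diagonal(A, 0.0)
    return ThresholdedGraph(A=A, density=1.0, node_labels=[f"n{i}" for i in range(n)])


def matrix_from(A: np.ndarray, labels=None) -> ConnectivityMatrix:
    A = np.asarray(A, float)
    labels = labels or [f"n{i}" for i in range(A.shape[0])]
    return ConnectivityMatrix(Z=A, node_labels=list(labels))
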