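import numpy as np
import pytest

from betam.core_metrics import IntensityMatrix, compute_beta, compute_m
from betam.synthetic_titration import default_design, simulate_titration

# replicate pairs of the default titration design (mixes run in duplicate)
REPLICATE_GROUPS = {
    "Mix1": ["Mix1_r1", "Mix1_r2"],
    "Mix2": ["Mix2_r1", "Mix2_r2"],
    "Mix5": ["Mix5_r1", "Mix5_r2"],
}
GROUP_A = ["Mix1_r1", "Mix1_r2"]  # pure sample A arrays
GROUP_B = ["Mix5_r1", "Mix5_r2"]  # pure sample B arrays


@pytest.fixture
def tiny_intensities() -> IntensityMatrix:
    """Three sites on two arrays with hand-checkable values."""
    return IntensityMatrix(
        site_ids=["cg1", "cg2", "cg3"],
        array_ids=["a1", "a2"],
        meth=np.array([[900.0, 0.0], [-50.0, 400.0], [1023.0, 2047.0]]),
        unmeth=np.array([[0.0, 500.0], [300.0, 400.0], [1023.0, 1023.0]]),
        detection_p=np.full((3, 2), 1e-6),
    )


@pytest.fixture(scope="session")
def platform_sim():
    """Full-platform-sized simulation at defaults: 27,578 sites, 8 arrays."""
    return simulate_titration(n_sites=27578, seed=2028)


@pytest.fixture(scope="session")
def eval_sim():
    """Evaluation-scale simulation: 10,000 sites, 30% truly differential."""
    return simulate_titration(n_sites=10000, diff_fraction=0.3, seed=515)


@pytest.fixture(scope="session")
def eval_matrices(eval_sim):
    x, truth = eval_sim
    return compute_beta(x), compute_m(x), truth
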