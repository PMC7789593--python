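import numpy as np
import pytest

from pgenmi.containers import DEPValueVector, EvidenceColumnKey, EvidenceMatrix
from pgenmi.model import PGenMiParams
from pgenmi.simulate import (
    SimulationSpec,
    simulate_dataset,
    simulate_genomic_fixture,
)


@pytest.fixture(scope="session")
def genomic_fixture():
    """Toy single-chromosome dataset with brute-force expected matrices."""
    return simulate_genomic_fixture(n_genes=12, n_tfs=3, seed=1)


@pytest.fixture(scope="session")
def informative_dataset():
    """Model-simulated data with one strongly informative evidence column
    (TF00) among five TFs; used by ranking/recovery/regulon tests."""
    k = 10
    w = np.zeros(k)
    w[0] = 3.0
    spec = SimulationSpec(
        n_genes=20_000,
        n_tfs=5,
        mark_changes=["H3K27ac-up", "H3K27ac-down"],
        evidence_density=0.05,
        true_params=PGenMiParams(w0=-2.0, w=w, alpha=0.2),
        seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def null_dataset():
    """Data with evidence carrying no signal (all true weights zero)."""
    spec = SimulationSpec(
        n_genes=5_000,
        n_tfs=5,
        mark_changes=["H3K27ac-up", "H3K27ac-down"],
        evidence_density=0.05,
        true_params=PGenMiParams(w0=-2.0, w=np.zeros(10), alpha=0.2),
        seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 columns with hand-set bits."""
    cols = [
        EvidenceColumnKey("JUND", "H3K27ac", "up"),
        EvidenceColumnKey("FOSL1", "H3K27ac", "down"),
    ]
    values = np.array([[1, 0], [0, 1], [0, 0]], dtype=np.uint8)
    return EvidenceMatrix(["g1", "g2", "g3"], cols, values)


@pytest.fixture
def tiny_pvals():
    return DEPValueVector(["g1", "g2", "g3"], np.array([0.01, 0.5, 0.9]))
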