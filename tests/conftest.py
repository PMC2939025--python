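import numpy as np
import pytest

from hybridem import synthetic


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2, axis=1))))


def model_rmsd(model_a, model_b) -> float:
    """Cα RMSD over the residues the two models share, matched by number."""
    nums = sorted(set(model_a.residue_numbers()) & set(model_b.residue_numbers()))
    a = np.array([model_a.residue_ca("A", n).position for n in nums])
    b = np.array([model_b.residue_ca("A", n).position for n in nums])
    return rmsd(a, b)


@pytest.fixture(scope="session")
def manifest():
    """The default synthetic mini-polymerase system (seed 1)."""
    return synthetic.make_toy_system(synthetic.ToySystemSpec(seed=1))


@pytest.fixture(scope="session")
def truth_map(manifest):
    """Density simulated from the ground-truth model at default settings."""
    return synthetic.make_map(manifest)
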