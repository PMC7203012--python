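import numpy as np
import pytest

from polyrate.synthetic_data import make_history, sim_alignments


@pytest.fixture(scope="session")
def history():
    return make_history()


@pytest.fixture(scope="session")
def small_alignments(history):
    """50 neutral genes over a 5-tip prune; reused by read-only tests."""
    aln, truth = sim_alignments(
        history,
        n_genes=50,
        n_codons=60,
        omega_spec=1.0,
        seed=1234,
        taxa=["Gh_A", "Gt_A", "Gh_D", "Ga", "Gr"],
    )
    return aln, truth


@pytest.fixture
def rng():
    return np.random.default_rng(99)
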