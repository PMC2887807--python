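import numpy as np
import pytest

from phosite.profile_io import PssmProfile
from phosite.synthetic import SimConfig, simulate


def make_profile(protein_id="P1", sequence="MKSAT", scores=None, rng=None):
    if scores is None:
        if rng is None:
            rng = np.random.default_rng(0)
        scores = rng.integers(-5, 6, size=(len(sequence), 20))
    return PssmProfile(protein_id, sequence, np.asarray(scores))


def random_profile(rng, length=None, protein_id="P1"):
    """A random profile over the full amino-acid alphabet."""
    if length is None:
        length = int(rng.integers(5, 80))
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    sequence = "".join(alphabet[i] for i in rng.integers(0, 20, size=length))
    scores = rng.integers(-12, 13, size=(length, 20))
    return PssmProfile(protein_id, sequence, scores)


@pytest.fixture(scope="session")
def small_sim():
    """Mixed-residue fixture used by several suites (in-memory only)."""
    config = SimConfig(
        n_proteins=60,
        length_range=(300, 400),
        effect_size=4,
        signal_width=5,
        imbalance=4.0,
        seed=42,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """Same fixture written to disk, for file-path and CLI tests."""
    out = tmp_path_factory.mktemp("fixture")
    config = SimConfig(
        n_proteins=60,
        length_range=(300, 400),
        effect_size=4,
        signal_width=5,
        imbalance=4.0,
        seed=42,
    )
    simulate(config, out_dir=out)
    return out
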