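import numpy as np
import pytest

from herv_nahr.pair_finder import local_align
from herv_nahr.synthetic_data import ElementBlueprint, make_element_pair


@pytest.fixture(scope="session")
def blueprint():
    return ElementBlueprint()


@pytest.fixture(scope="session")
def small_blueprint():
    """Shorter element for alignment-heavy tests."""
    return ElementBlueprint(ltr_length=120, internal_length=1500, internal_deletions=((900, 1200),))


@pytest.fixture(scope="session")
def diverged_pair(blueprint):
    """A full-size pair at 3% divergence with indels, plus its alignment."""
    seq_a, seq_b, realized, variants = make_element_pair(
        blueprint, 0.03, seed=5, indel_rate=0.1
    )
    return {
        "seq_a": seq_a,
        "seq_b": seq_b,
        "realized_identity": realized,
        "variants": variants,
        "alignment": local_align(seq_a, seq_b),
    }


@pytest.fixture(scope="session")
def snv_pair(blueprint):
    """Indel-free pair: cis-morphisms are exactly the planted substitutions."""
    seq_a, seq_b, realized, variants = make_element_pair(blueprint, 0.02, seed=11)
    return {
        "seq_a": seq_a,
        "seq_b": seq_b,
        "realized_identity": realized,
        "variants": variants,
        "alignment": local_align(seq_a, seq_b),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
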