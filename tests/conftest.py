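import numpy as np
import pytest

from bsfoot.seqcore import NucleotideSequence
from bsfoot.synthetic import (
    ExposureModel,
    ReadSimConfig,
    simulate_bisulfite_reads,
    simulate_ty1_like_reference,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240718)


def random_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def small_reference():
    """A 400-nt reference with a planted IR at 151 (arm 12, loop 5)."""
    ref, ir = simulate_ty1_like_reference(
        400, {"arm": 12, "loop": 5, "position": 151}, seed=5
    )
    return ref, ir


@pytest.fixture(scope="session")
def small_simulation(small_reference):
    """Reads + truth from the small reference, two-regime exposure."""
    ref, ir = small_reference
    model = ExposureModel(boundary_pos=151, p_up=0.2, p_down=0.04, conv_eff=1.0)
    reads, truth = simulate_bisulfite_reads(
        ref, model, ReadSimConfig(n_reads=800, read_length=60, seed=17)
    )
    return ref, model, reads, truth
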