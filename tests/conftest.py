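import numpy as np
import pytest

from glicluster import (
    default_fixture_spec,
    enumerate_vocabulary,
    make_annotation,
    make_genome,
    make_toy_matrix,
)

CONSENSUS = "GACCACCCA"
SHARPNESS = 0.92  # lowest round value whose CIV (73.6) clears the core threshold of 70


@pytest.fixture(scope="session")
def ci_like_pwm():
    """A sharp 9-position matrix with the Ci consensus; every position in the core."""
    return make_toy_matrix(CONSENSUS, SHARPNESS)


@pytest.fixture(scope="session")
def vocab(ci_like_pwm):
    """Vocabulary at the standard 0.75 cutoff: MSS levels 1.0 / 0.892 / 0.784."""
    return enumerate_vocabulary(ci_like_pwm)


@pytest.fixture(scope="session")
def fixture_genome(vocab):
    """Scrubbed 100 kb genome with three planted clusters plus annotation."""
    spec = default_fixture_spec(seed=11)
    genome, truth = make_genome(spec, vocab)
    truth = make_annotation(spec, genome, truth)
    return genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_mss(seq, pwm):
    """Independent MSS oracle: plain-python CIV-weighted frequency ratio."""
    core = list(pwm.core_positions)
    num = 0.0
    den = 0.0
    for p, ch in zip(core, seq.upper()):
        num += pwm.civ[p] * pwm.rows[p, "ACGT".index(ch)]
        den += pwm.civ[p] * max(pwm.rows[p])
    return num / den
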