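import numpy as np
import pytest

from baritone.synthetic_data import make_template


def random_seq(rng, n, at=0.5):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def mutate_seq(seq, rate, rng):
    """Uniform substitutions (any different base) for test constructions."""
    out = []
    for c in seq:
        if c in "ACGT" and rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="session")
def sir_template():
    return make_template("Bari1", "SIR", 1726, seed=11)


@pytest.fixture(scope="session")
def lir_template():
    return make_template("Bari3", "LIR", 1717, seed=13)
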