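import numpy as np
import pytest

from toxkil import params
from toxkil.dynamics import Allele, Genotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def serial_example_lumped():
    """Parameter set of the serial-transfer example run."""
    return params.LumpedParams(
        L_cue=6.0, L_tox=6.0, R0_inv=0.125, bT_hat=0.072, C_R=0.1, C_C=0.02
    )


@pytest.fixture
def regulated_killer_lumped():
    """Fixed-habitat parameter set under which regulated killers evolve."""
    return params.LumpedParams(
        L_cue=6.0, L_tox=6.0, R0_inv=0.125, bT_hat=0.32, C_R=0.1, C_C=0.02
    )


@pytest.fixture
def krs_example_lumped():
    """Fixed-habitat parameter set yielding a non-regulating KRS system."""
    return params.LumpedParams(
        L_cue=3.7, L_tox=16.5, R0_inv=0.1, bT_hat=0.045, C_R=0.12, C_C=0.07
    )


@pytest.fixture
def raw_serial(serial_example_lumped):
    return params.expand_lumped(serial_example_lumped)


SENSITIVE = Genotype(Allele.OFF, Allele.OFF)
RESISTANT = Genotype(Allele.OFF, Allele.ON)
CONSTITUTIVE_KILLER = Genotype(Allele.ON, Allele.ON, pi_t=0.13)
REG_KILLER = Genotype(Allele.REG, Allele.ON, pi_t=0.8, theta=0.875)
REGREG_KILLER = Genotype(Allele.REG, Allele.REG, pi_t=1.0, theta=0.67)
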