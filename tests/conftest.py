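import numpy as np
import pytest

from kinkwlc.potentials import BendPotential, ChainSpec, Family, calibrate_rigidity

# canonical study conditions: a = 48 nm, l = 0.34 nm
A_NM = 48.0
L_NM = 0.34


@pytest.fixture(scope="session")
def quad():
    return calibrate_rigidity(Family.QUADRATIC, A_NM, L_NM)


@pytest.fixture(scope="session")
def linear_pot():
    return calibrate_rigidity(Family.LINEAR, A_NM, L_NM)


@pytest.fixture(scope="session")
def kink12(quad):
    return BendPotential(family=Family.KINKABLE, g=quad.g, h=12.0, b=0.3)


@pytest.fixture(scope="session")
def kink16(quad):
    return BendPotential(family=Family.KINKABLE, g=quad.g, h=16.0, b=0.3)


@pytest.fixture(scope="session")
def nick8(quad):
    return BendPotential(family=Family.NICK, g=quad.g, h=8.0, b=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def linear_spec(n_bp, pot, **kw):
    return ChainSpec(n_bp=n_bp, l=L_NM, a=A_NM, topology="linear", joint_potential=pot, **kw)


def circular_spec(n_bp, pot, **kw):
    return ChainSpec(n_bp=n_bp, l=L_NM, a=A_NM, topology="circular", joint_potential=pot, **kw)
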