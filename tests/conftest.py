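import numpy as np
import pytest

import phyllosim as ps


@pytest.fixture
def ring8():
    return ps.build_ring(8)


@pytest.fixture
def ring12():
    return ps.build_ring(12)


@pytest.fixture
def hex33():
    return ps.build_hex_torus(3, 3)


def o_params(**kw):
    """Compartment-free model base parameters (1D figure legend values)."""
    base = dict(A=1.0, Ep=1.0, Gp=1.0, Ga=0.2, p=1.0, Da=0.2)
    base.update(kw)
    return ps.Params(**base)


def a_params(**kw):
    """Apoplast model base parameters (1D figure legend values)."""
    base = dict(A=1.0, Ep=1.0, Eq=1.0, Gp=1.0, V=1.0, q=10.0, Ga=0.2,
                p=50.0, Da=1.0)
    base.update(kw)
    return ps.Params(**base)


def b_params(**kw):
    """Mediator model base parameters (1D figure legend values)."""
    base = dict(A=1.0, Ep=1.0, Eq=1.0, Gp=1.0, Gx=1.0, Da=1.0, V=1.0,
                p=10.0, q=10.0, Dx=10.0, Ga=0.2)
    base.update(kw)
    return ps.Params(**base)


def random_state(spec, params, lattice, rng, rel=0.5):
    """Random positive state in a band around the uniform equilibrium."""
    eq = ps.equilibrium(spec, params, lattice)
    st = eq.copy()
    for name, v in st.fields():
        setattr(st, name, v * rng.uniform(1.0 - rel, 1.0 + rel, size=v.shape))
    return st
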