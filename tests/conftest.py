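import numpy as np
import pytest

from phenokin import DerivedKinetics, KineticCoefficients


@pytest.fixture
def reactor_a_coeffs():
    """Published first-campaign Reactor A rate-polynomial coefficients."""
    return KineticCoefficients(k0=-1.113, k1=0.006, k2=-4.42e-6)


@pytest.fixture
def reactor_a_kinetics():
    """Full-precision root-space parameters matching reactor_a_coeffs,
    with the measured initial phenol concentration."""
    return DerivedKinetics(
        p=0.004040069306336217, q=221.7116169302922, h=1135.7544464181242,
        s0=1081.7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20221031)


def make_table(path, rows):
    """Write a measurement CSV from (reactor, time, analyte, conc) rows."""
    lines = ["reactor,time_h,analyte,conc_mg_L"]
    lines += [f"{r},{t},{a},{c}" for r, t, a, c in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
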