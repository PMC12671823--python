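import pytest

import iolgeom as g

from paper_tables import CASE1, LENSES, N_AMBIENT, N_IOL


@pytest.fixture(scope="session")
def wet_cell():
    return g.MediumSpec(n_ambient=N_AMBIENT)


@pytest.fixture(scope="session")
def case1_reading(wet_cell):
    """Worked-example reading: A=22.23 D, B=22.35 D, t=1.0 mm, n_iol=1.46."""
    return g.BenchReading(
        a_meas=CASE1["A"], b_meas=CASE1["B"], d=0.0, medium=wet_cell,
        t=CASE1["t"], n_iol=N_IOL,
    )


@pytest.fixture(scope="session")
def case1_lens(case1_reading):
    """Ground-truth design consistent with the worked-example readings."""
    res = g.retrieve_geometry(case1_reading)
    return g.LensDesign(
        n_iol=N_IOL, t=CASE1["t"],
        r_anterior=res.r_anterior, r_posterior=res.r_posterior,
    )


@pytest.fixture(scope="session")
def paper_readings(wet_cell):
    """The three example lenses (low/medium/high power) at d = 0."""
    return {
        label: g.BenchReading(
            a_meas=a, b_meas=b, d=0.0, medium=wet_cell, t=t, n_iol=N_IOL
        )
        for label, (a, b, t) in LENSES.items()
    }
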