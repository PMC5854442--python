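import pytest

from kaeff.parameters import Geometry, PairParameters


@pytest.fixture
def human_geometry():
    """Cytoplasmic volume / plasma-membrane area of a human cell."""
    return Geometry(V=1200.0, A=767.0)


@pytest.fixture
def unit_geometry():
    """V/A = 1 um; gamma = 500 at sigma = 1 nm."""
    return Geometry(V=50.0, A=50.0)


@pytest.fixture
def excess_lipid_params(unit_geometry):
    """Symmetric binders with PIP2-level lipid excess."""
    return PairParameters.from_molar(
        1e6, 1e6, 1e6, 1e-6, 1e-6, unit_geometry, sigma_nm=1.0,
        m_tot_per_um2=2.5e4,
    )


@pytest.fixture
def lipid_limited_params():
    """Lipids outnumbered by proteins (hard regime for the theory)."""
    return PairParameters.from_molar(
        1e6, 1e4, 1e4, 2e-6, 2e-6, Geometry(V=0.76, A=1.0), sigma_nm=1.0,
        m_tot_per_um2=1e3,
    )
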