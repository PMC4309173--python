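import numpy as np
import pytest

import enterosim as es

# kinetic/transport parameters randomized in perturbation studies
PERTURBABLE = [
    "Vmax_glut2_ap", "Vmax_glut2_bl", "Vmax_sglt1", "Vmax_pump", "Vmax_Na_bl",
    "P_glc_pc", "P_Na_pc", "Lp_ap", "Lp_bl", "Lp_pc", "Lp_cap",
    "P_cap_glc", "P_cap_Na", "cap_flow", "compliance_k",
    "Km_glut2", "Km_pump", "n_imp_cyt",
]


@pytest.fixture(scope="session")
def ref():
    """Frozen reference parameter set."""
    return es.REFERENCE


@pytest.fixture(scope="session")
def ref_steady(ref):
    """Steady state of the reference configuration."""
    return es.steady_state(ref)


@pytest.fixture(scope="session")
def fig1_result():
    return es.run_factorial()


@pytest.fixture(scope="session")
def fig2_result():
    return es.sweep_glut2()


@pytest.fixture(scope="session")
def fig4_modeA():
    return es.run_inhibitor_timecourse("A")


@pytest.fixture(scope="session")
def fig4_modeB():
    return es.run_inhibitor_timecourse("B")


@pytest.fixture
def isotonic_state(ref):
    """Interstitium and cytosol matched to the luminal boundary, V_int = V0."""
    V0 = ref.compliance_V0
    return es.CompartmentState(
        n_glc_cyt=ref.C_lum_glc * 0.5, n_Na_cyt=ref.C_lum_Na * 0.5, V_cyt=0.5,
        n_glc_int=ref.C_lum_glc * V0, n_Na_int=ref.C_lum_Na * V0, V_int=V0,
        C_glc_cap=ref.C_art_glc, C_Na_cap=ref.C_art_Na,
    )
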