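"""Unit and property tests of the algebraic flux laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import enterosim as es

conc = st.floats(min_value=0.0, max_value=1000.0, allow_nan=False)


# ---------------------------------------------------------------------------
# GLUT2 two-site carrier
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("C_out, C_in, Vmax, Km, expected", [
    (17.0, 0.0, 2.0, 17.0, 1.0),        # half-saturation gives Vmax/2
    (50.0, 50.0, 7.3, 17.0, 0.0),       # equilibrium
    (0.0, 0.0, 1.0, 17.0, 0.0),
    (1e9, 0.0, 2.0, 17.0, 2.0 * 1e9 / (17.0 + 1e9)),  # saturates below Vmax
])
def test_glut2_flux_values(C_out, C_in, Vmax, Km, expected):
    assert es.glut2_flux(C_out, C_in, Vmax, Km) == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(a=conc, b=conc)
def test_glut2_flux_antisymmetric_and_bounded(a, b):
    f = es.glut2_flux(a, b, 2.0, 17.0)
    assert f == pytest.approx(-es.glut2_flux(b, a, 2.0, 17.0), abs=1e-12)
    assert abs(f) < 2.0
    if a == b:
        assert f == 0.0
    else:
        assert (f > 0) == (a > b)


@pytest.mark.parametrize("kwargs", [
    dict(C_out=-1.0, C_in=0.0, Vmax=1.0, Km=17.0),
    dict(C_out=0.0, C_in=-1.0, Vmax=1.0, Km=17.0),
    dict(C_out=1.0, C_in=0.0, Vmax=1.0, Km=0.0),
    dict(C_out=1.0, C_in=0.0, Vmax=-1.0, Km=17.0),
])
def test_glut2_flux_domain_errors(kwargs):
    with pytest.raises(ValueError):
        es.glut2_flux(**kwargs)


# ---------------------------------------------------------------------------
# SGLT1
# ---------------------------------------------------------------------------

def test_sglt1_no_substrate_gives_zero(ref):
    assert es.sglt1_flux(0.0, 150.0, ref) == 0.0


def test_sglt1_product_of_half_saturations(ref):
    f = es.sglt1_flux(ref.Km_sglt1_glc, ref.Km_sglt1_Na, ref, scale=1.0)
    assert f == pytest.approx(ref.flux_scale * ref.Vmax_sglt1 / 4.0, rel=1e-12)


@settings(derandomize=True, max_examples=100)
@given(g=conc, na=conc)
def test_sglt1_nonnegative_bounded_and_blocked_by_phloridzin(g, na, ref):
    f = es.sglt1_flux(g, na, ref)
    assert 0.0 <= f <= ref.flux_scale * ref.Vmax_sglt1
    assert es.sglt1_flux(g, na, ref, scale=0.0) == 0.0


@settings(derandomize=True, max_examples=50)
@given(g=st.floats(0.0, 500.0), dg=st.floats(0.0, 100.0))
def test_sglt1_monotone_in_glucose(g, dg, ref):
    assert es.sglt1_flux(g + dg, 150.0, ref) >= es.sglt1_flux(g, 150.0, ref)


# ---------------------------------------------------------------------------
# Na pump and basolateral Na carrier
# ---------------------------------------------------------------------------

def test_na_pump_half_saturation_zero_and_limit(ref):
    vmax = ref.flux_scale * ref.Vmax_pump
    assert es.na_pump_flux(ref.Km_pump, ref) == pytest.approx(vmax / 2)
    assert es.na_pump_flux(0.0, ref) == 0.0
    assert es.na_pump_flux(1e12, ref) == pytest.approx(vmax, rel=1e-6)
    assert es.na_pump_flux(1e12, ref) < vmax
    with pytest.raises(ValueError):
        es.na_pump_flux(-1.0, ref)


def test_na_bl_two_site_form(ref):
    vmax = ref.flux_scale * ref.Vmax_Na_bl
    assert es.na_bl_flux(ref.Km_Na_bl, 0.0, ref) == pytest.approx(vmax / 2)
    assert es.na_bl_flux(140.0, 140.0, ref) == 0.0
    assert es.na_bl_flux(30.0, 140.0, ref) == pytest.approx(
        -es.na_bl_flux(140.0, 30.0, ref))


# ---------------------------------------------------------------------------
# Convective diffusion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("C_o, C_i, J_w, P, expected", [
    (10.0, 4.0, 0.0, 2.0, 12.0),     # pure diffusion
    (10.0, 4.0, 1.0, 2.0, 19.0),     # drag 7 + diffusion 12
    (6.0, 6.0, 0.5, 3.0, 3.0),       # pure solvent drag Jw*c
    (0.0, 0.0, 5.0, 1.0, 0.0),
])
def test_convective_diffusion_values(C_o, C_i, J_w, P, expected):
    assert es.convective_diffusion_flux(C_o, C_i, J_w, P) == pytest.approx(expected)


def test_convective_diffusion_rejects_negative_permeability():
    with pytest.raises(ValueError):
        es.convective_diffusion_flux(1.0, 1.0, 0.0, -0.1)


# ---------------------------------------------------------------------------
# Water fluxes
# ---------------------------------------------------------------------------

def test_paracellular_water_zero_when_no_driving(isotonic_state, ref):
    # matched concentrations and V_int = V0 (so P_in = 0)
    assert es.paracellular_water_flux(isotonic_state, ref) == pytest.approx(0.0, abs=1e-12)


def test_paracellular_water_pressure_driven_secretion(isotonic_state, ref):
    # isotonic but expanded interstitium: only the hydraulic term survives
    s = es.CompartmentState(
        n_glc_cyt=isotonic_state.n_glc_cyt, n_Na_cyt=isotonic_state.n_Na_cyt,
        V_cyt=isotonic_state.V_cyt,
        n_glc_int=ref.C_lum_glc * 0.4, n_Na_int=ref.C_lum_Na * 0.4, V_int=0.4,
        C_glc_cap=5.0, C_Na_cap=150.0)
    P_in = s.pressure(ref)
    assert P_in > 0
    assert es.paracellular_water_flux(s, ref) == pytest.approx(-ref.Lp_pc * P_in)


def test_paracellular_water_linear_in_na_gradient(ref):
    def flux(dNa):
        V0 = ref.compliance_V0
        s = es.CompartmentState(
            n_glc_cyt=1.0, n_Na_cyt=1.0, V_cyt=0.5,
            n_glc_int=ref.C_lum_glc * V0, n_Na_int=(ref.C_lum_Na + dNa) * V0,
            V_int=V0, C_glc_cap=5.0, C_Na_cap=150.0)
        return es.paracellular_water_flux(s, ref)

    base = flux(0.0)
    assert flux(10.0) - base == pytest.approx(2 * (flux(5.0) - base), rel=1e-9)


def test_transcellular_water_zero_at_osmotic_equilibrium(ref):
    p = ref.with_overrides(n_imp_cyt=0.0)
    s = es.CompartmentState(
        n_glc_cyt=p.C_lum_glc * 0.5, n_Na_cyt=p.C_lum_Na * 0.5, V_cyt=0.5,
        n_glc_int=1.0, n_Na_int=1.0, V_int=0.3, C_glc_cap=5.0, C_Na_cap=150.0)
    assert es.transcellular_water_flux("apical", s, p, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_transcellular_water_pure_coupled_component(ref):
    p = ref.with_overrides(Lp_ap=0.0)
    s = es.default_initial_state(p)
    J_glc = 50.0
    expected = p.n_w_per_glc * es.model.WATER_MOLAR_VOLUME * J_glc
    assert es.transcellular_water_flux("apical", s, p, J_glc) == pytest.approx(expected)


def test_transcellular_water_sign_for_hyperosmotic_cytosol(ref):
    # cytosol far hyperosmotic to the lumen pulls water in apically
    s = es.CompartmentState(
        n_glc_cyt=200.0, n_Na_cyt=100.0, V_cyt=0.5,
        n_glc_int=1.0, n_Na_int=45.0, V_int=0.3,
        C_glc_cap=5.0, C_Na_cap=150.0)
    assert es.transcellular_water_flux("apical", s, ref, 0.0) > 0


def test_transcellular_water_unknown_side(ref):
    s = es.default_initial_state(ref)
    with pytest.raises(ValueError, match="side"):
        es.transcellular_water_flux("lateral", s, ref, 0.0)


# ---------------------------------------------------------------------------
# Interstitial pressure
# ---------------------------------------------------------------------------

def test_interstitial_pressure_shape(ref):
    assert es.interstitial_pressure(ref.compliance_V0, ref) == 0.0
    grid = np.linspace(0.15, 1.0, 30)
    P = np.array([es.interstitial_pressure(v, ref) for v in grid])
    assert np.all(np.diff(P) > 0), "pressure must increase with volume"
    assert np.all(np.diff(P, 2) > -1e-9), "pressure-volume law must be convex"
    assert es.interstitial_pressure(1e-6, ref) >= ref.pressure_floor
    with pytest.raises(ValueError):
        es.interstitial_pressure(0.0, ref)


# ---------------------------------------------------------------------------
# Flux assembly and state derivative
# ---------------------------------------------------------------------------

def test_compute_fluxes_respects_blockades(ref, isotonic_state):
    p = ref.with_overrides(Vmax_glut2_ap=0.0)
    J = es.compute_fluxes(isotonic_state, p)
    assert J.J_glut2_ap == 0.0

    off_pc = es.ScaleSet(pc_scale=0.0, pc_water_scale=0.0)
    J = es.compute_fluxes(isotonic_state, ref, off_pc)
    assert J.J_pc_glc == 0.0 and J.J_pc_Na == 0.0 and J.J_w_pc == 0.0


def test_compute_fluxes_na_coupling_exact(ref, isotonic_state):
    J = es.compute_fluxes(isotonic_state, ref)
    assert J.J_Na_sglt1 == ref.n_Na_per_glc * J.J_sglt1


def test_all_fluxes_vanish_without_gradients_or_pumps(ref):
    # every compartment at the same composition, no pumps, no impermeant
    # osmolyte, reference interstitial volume: nothing moves
    p = ref.with_overrides(Vmax_sglt1=0.0, Vmax_pump=0.0, n_imp_cyt=0.0,
                           C_lum_glc=5.0, C_lum_Na=150.0,
                           C_art_glc=5.0, C_art_Na=150.0)
    V0 = p.compliance_V0
    s = es.CompartmentState(
        n_glc_cyt=5.0 * 0.5, n_Na_cyt=150.0 * 0.5, V_cyt=0.5,
        n_glc_int=5.0 * V0, n_Na_int=150.0 * V0, V_int=V0,
        C_glc_cap=5.0, C_Na_cap=150.0)
    J = es.compute_fluxes(s, p)
    for name, value in J.as_dict().items():
        assert value == pytest.approx(0.0, abs=1e-12), name


def test_rhs_telescoping_glucose_conservation(ref, ref_steady):
    # the combined cytosol+interstitium glucose derivative must equal
    # luminal entry minus capillary removal, for an arbitrary state
    s = es.CompartmentState(
        n_glc_cyt=30.0, n_Na_cyt=8.0, V_cyt=0.5,
        n_glc_int=10.0, n_Na_int=46.0, V_int=0.35,
        C_glc_cap=9.0, C_Na_cap=151.0)
    dy = es.rhs(0.0, s, ref)
    J = es.compute_fluxes(s, ref)
    lhs = dy[0] + dy[3]
    rhs_ = (J.J_sglt1 + J.J_glut2_ap + J.J_pc_glc) - J.J_cap_glc
    assert lhs == pytest.approx(rhs_, rel=1e-12)


def test_rhs_blocked_apical_and_paracellular(ref):
    scales = es.ScaleSet(sglt1_scale=0.0, glut2_ap_scale=0.0,
                         pc_scale=0.0, pc_water_scale=0.0)
    s = es.default_initial_state(ref)
    dy = es.rhs(0.0, s, ref, scales)
    J = es.compute_fluxes(s, ref, scales)
    assert dy[0] == pytest.approx(-J.J_glut2_bl)


def test_schedule_resolution_and_validation():
    ev1 = es.ScaleSet(sglt1_scale=0.0)
    ev2 = es.ScaleSet(sglt1_scale=0.0, glut2_ap_scale=0.0)
    sched = es.InhibitorSchedule(((0.5, ev1), (1.0, ev2)))
    assert sched.active(0.0) == es.BASELINE_SCALES
    assert sched.active(0.5) == ev1
    assert sched.active(0.75) == ev1
    assert sched.active(1.5) == ev2
    with pytest.raises(ValueError):
        es.InhibitorSchedule(((1.0, ev1), (0.5, ev2)))
    with pytest.raises(ValueError):
        es.ScaleSet(sglt1_scale=1.5)


def test_state_invariants():
    with pytest.raises(ValueError):
        es.CompartmentState(-1.0, 1.0, 0.5, 1.0, 1.0, 0.3, 5.0, 150.0)
    with pytest.raises(ValueError):
        es.CompartmentState(1.0, 1.0, 0.0, 1.0, 1.0, 0.3, 5.0, 150.0)
    s = es.CompartmentState(2.0, 4.0, 0.5, 3.0, 6.0, 0.3, 5.0, 150.0)
    assert s.C_glc_cyt == pytest.approx(4.0)
    assert s.C_Na_int == pytest.approx(20.0)


def test_parameter_invariants(ref):
    with pytest.raises(ValueError, match="Km_glut2"):
        ref.with_overrides(Km_glut2=-1.0)
    with pytest.raises(ValueError, match="sigma_Na"):
        ref.with_overrides(sigma_Na=1.2)
    with pytest.raises(ValueError, match="n_Na_per_glc"):
        ref.with_overrides(n_Na_per_glc=0.5)
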