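"""Kinetic model of intestinal glucose, sodium and water absorption.

The model follows a single absorptive unit of small-intestinal mucosa
through four compartments in series/parallel:

    lumen  --SGLT1 / apical GLUT2-->  enterocyte cytosol
    lumen  --tight junction (paracellular)-->  interstitium
    cytosol  --basolateral GLUT2 / Na pump / Na carrier-->  interstitium
    interstitium  --capillary wall + perfusion-->  villus capillary blood

The lumen is an infinite reservoir of fixed composition; the capillary is
a well-mixed compartment flushed by perfusion at the afferent arterial
composition.  State variables are solute *amounts* and water *volumes*
(cytosol, interstitium) plus mean capillary concentrations, so mass is
conserved exactly under volume change.

Carrier kinetics
----------------
* GLUT2 (apical, disputed, and basolateral, constitutive) is a symmetric
  two-site carrier: J = Vmax * (g_o/(1+g_o) - g_i/(1+g_i)) with
  g = C / Km and Km = 17 mM.  A negative apical flux is glucose
  "backflux" from cytosol to lumen.
* SGLT1 is secondary-active and effectively unidirectional (the export
  site has very low glucose affinity), modelled as an irreversible
  product of Michaelis terms in luminal glucose and Na, with a strict
  2 Na : 1 glucose stoichiometry.
* The basolateral Na exit carrier uses the same two-site form as GLUT2
  (Km 25 mM); the Na/K pump is a simple saturating export,
  J = Vmax * Na_cyt / (Na_cyt + Km).

Water and solute coupling
-------------------------
Osmotic water flow across each barrier is Lp * (RT * sigma-weighted
osmolarity difference - hydrostatic term), with NaCl counted as two
osmotic particles and glucose as one.  Carrier glucose flux drags a
fixed number of water molecules per glucose across the apical and
basolateral membranes.  Solute crossing a water-swept barrier (tight
junction, capillary wall) follows the convective-diffusion law
J = Jw*(Co+Ci)/2 + P*(Co-Ci) (solvent drag plus diffusion).  The
interstitium has a nonlinear (exponential) pressure-volume relation, and
interstitial pressure feeds back on paracellular and capillary water
flow.

Units: concentrations mM, volumes ml per g tissue, time hours, solute
fluxes umol/h per g, water fluxes ml/h per g, pressure mm Hg.  Carrier
Vmax values in configs are expressed in "model flux units" (1 unit ~ the
SGLT1 uptake rate with 50 mM luminal glucose) and converted internally
with ``flux_scale``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, fields as dc_fields, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

__all__ = [
    "ModelParameters",
    "CompartmentState",
    "FluxVector",
    "ScaleSet",
    "InhibitorSchedule",
    "Trajectory",
    "ScenarioResult",
    "RunManifest",
    "IntegrationError",
    "SteadyStateError",
    "REFERENCE",
    "BASELINE_SCALES",
    "EMPTY_SCHEDULE",
    "STATE_FIELDS",
    "FLUX_FIELDS",
    "fig4_schedule",
    "glut2_flux",
    "sglt1_flux",
    "na_pump_flux",
    "na_bl_flux",
    "convective_diffusion_flux",
    "paracellular_water_flux",
    "transcellular_water_flux",
    "interstitial_pressure",
    "compute_fluxes",
    "rhs",
    "integrate",
    "steady_state",
    "default_initial_state",
    "run_factorial",
    "sweep_glut2",
    "sweep_pglc",
    "find_crossover",
    "run_inhibitor_timecourse",
    "load_config",
    "write_result",
    "make_fixtures",
    "plot_scenario",
]

logger = logging.getLogger("enterosim")

#: molar volume of water, ml per umol
WATER_MOLAR_VOLUME = 1.8e-5

#: reporting grid spacing for time courses, h
REPORT_DT = 0.005

#: default integrator tolerances
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

ARTIFACT_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """All kinetic constants, permeabilities and boundary conditions.

    Defaults are the frozen reference parameter set.  It reproduces the
    high-clearance condition used for the inhibitor time courses
    (Q_cap = 10, apical GLUT2 Vmax = 2) and satisfies the model's
    registration point: with paracellular glucose permeability
    0.015 cm/s the luminal concentration at which paracellular and
    SGLT1 glucose fluxes are equal lies between 20 and 30 mM.
    """

    # --- carrier kinetics (Vmax in model flux units; Km in mM) ---
    Km_glut2: float = 17.0           # GLUT2 half-saturation
    Vmax_glut2_ap: float = 2.0       # apical GLUT2 maximum (0 = absent)
    Vmax_glut2_bl: float = 13.3      # basolateral GLUT2 maximum
    Vmax_sglt1: float = 1.63         # SGLT1 glucose maximum
    Km_sglt1_glc: float = 17.9       # SGLT1 luminal glucose half-saturation
    Km_sglt1_Na: float = 30.0        # SGLT1 luminal Na half-saturation
    n_Na_per_glc: float = 2.0        # SGLT1 Na:glucose stoichiometry
    n_w_per_glc: float = 210.0       # water molecules cotransported per glucose
    Vmax_pump: float = 8.3           # Na pump maximum
    Km_pump: float = 20.0            # Na pump half-saturation, mM
    Vmax_Na_bl: float = 2.5          # basolateral Na carrier maximum
    Km_Na_bl: float = 25.0           # basolateral Na carrier Km, mM

    # --- paracellular pathway ---
    P_glc_pc: float = 0.015          # paracellular glucose permeability, cm/s
    P_Na_pc: float = 0.03            # paracellular Na permeability, cm/s
    pc_area_factor: float = 730.0    # (umol/h/mM) per (cm/s): junction area x units

    # --- hydraulic conductivities, ml/h per mm Hg ---
    Lp_ap: float = 1.5e-4
    Lp_bl: float = 1.5e-4
    Lp_pc: float = 3.0e-5
    Lp_cap: float = 3.0e-2
    lymph_coeff: float = 1.0e-3      # pressure-proportional interstitial relief

    # --- reflection coefficients ---
    sigma_Na: float = 0.8
    sigma_glc: float = 0.9

    # --- capillary exchange and perfusion ---
    P_cap_glc: float = 1.36          # capillary glucose permeability, umol/h/mM
    P_cap_Na: float = 2.0            # capillary Na permeability, umol/h/mM
    Q_cap: float = 10.0              # clearance multiplier (1 = low, 10 = high)
    cap_flow: float = 1.36           # baseline perfusion, ml/h
    V_cap: float = 0.1               # capillary volume, ml

    # --- boundary concentrations, mM ---
    C_art_glc: float = 5.0
    C_art_Na: float = 150.0
    C_lum_glc: float = 50.0
    C_lum_Na: float = 150.0

    # --- osmotic / mechanical constants ---
    osmotic_factor: float = 19.3     # mm Hg per mM (RT at 37 C)
    compliance_k: float = 5.0        # interstitial stiffness, mm Hg
    compliance_V0: float = 0.30      # interstitial reference volume, ml
    pressure_floor: float = -3.0     # lower clip on interstitial pressure, mm Hg
    V_cyt_ref: float = 0.55          # reference enterocyte volume, ml
    n_imp_cyt: float = 105.0         # impermeant cytosolic osmolyte, umol

    # --- unit conversion ---
    flux_scale: float = 60.0         # umol/h per model flux unit

    # --- scenario behaviour flags ---
    phloretin_blocks_water: bool = False  # mode B: also scale Lp_pc to 0

    def __post_init__(self) -> None:
        nonneg = (
            "Km_glut2 Vmax_glut2_ap Vmax_glut2_bl Vmax_sglt1 Km_sglt1_glc "
            "Km_sglt1_Na Vmax_pump Km_pump Vmax_Na_bl Km_Na_bl P_glc_pc "
            "P_Na_pc pc_area_factor Lp_ap Lp_bl Lp_pc Lp_cap lymph_coeff "
            "P_cap_glc P_cap_Na Q_cap cap_flow V_cap C_art_glc C_art_Na "
            "C_lum_glc C_lum_Na osmotic_factor compliance_k flux_scale "
            "n_imp_cyt"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {getattr(self, name)}")
        for name in ("sigma_Na", "sigma_glc"):
            s = getattr(self, name)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"parameter {name} must lie in [0, 1], got {s}")
        if self.n_Na_per_glc < 1:
            raise ValueError(f"parameter n_Na_per_glc must be >= 1, got {self.n_Na_per_glc}")
        for name in ("compliance_V0", "V_cyt_ref", "V_cap", "flux_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {getattr(self, name)}")

    def with_overrides(self, **kw) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kw)

    # effective (absolute-unit) coefficients -------------------------------
    @property
    def peff_glc_pc(self) -> float:
        """Paracellular glucose conductance, umol/h per mM."""
        return self.P_glc_pc * self.pc_area_factor

    @property
    def peff_Na_pc(self) -> float:
        """Paracellular Na conductance, umol/h per mM."""
        return self.P_Na_pc * self.pc_area_factor


@dataclass(frozen=True)
class ScaleSet:
    """Multiplicative inhibitor factors, all in [0, 1].

    ``pc_scale`` scales the paracellular *solute* fluxes (diffusion and
    solvent drag together: a blocked junction passes no solute);
    ``pc_water_scale`` scales the paracellular water path (Lp_pc).
    """

    sglt1_scale: float = 1.0
    glut2_ap_scale: float = 1.0
    pc_scale: float = 1.0
    pc_water_scale: float = 1.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must lie in [0, 1], got {v}")


BASELINE_SCALES = ScaleSet()


@dataclass(frozen=True)
class InhibitorSchedule:
    """Timed step changes of the inhibitor scale factors.

    Each event is ``(time, ScaleSet)``; the scale set applies from its
    event time until the next event.  Before the first event the
    baseline (all ones) applies.
    """

    events: tuple[tuple[float, ScaleSet], ...] = ()

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule event times must be strictly increasing")

    def active(self, t: float) -> ScaleSet:
        """Scale set in force at time ``t`` (events act at t >= event time)."""
        current = BASELINE_SCALES
        for t_ev, scales in self.events:
            if t >= t_ev:
                current = scales
            else:
                break
        return current

    def times(self) -> list[float]:
        return [t for t, _ in self.events]


EMPTY_SCHEDULE = InhibitorSchedule()


@dataclass
class CompartmentState:
    """Solute amounts and water volumes of the mobile compartments.

    Cytosol and interstitium carry amounts (umol) and volumes (ml); the
    fixed-volume capillary carries mean concentrations (mM).
    """

    n_glc_cyt: float
    n_Na_cyt: float
    V_cyt: float
    n_glc_int: float
    n_Na_int: float
    V_int: float
    C_glc_cap: float
    C_Na_cap: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"state field {f.name} must be finite and >= 0, got {v}")
        if self.V_cyt <= 0 or self.V_int <= 0:
            raise ValueError("compartment volumes must be positive")

    # derived concentrations, mM
    @property
    def C_glc_cyt(self) -> float:
        return self.n_glc_cyt / self.V_cyt

    @property
    def C_Na_cyt(self) -> float:
        return self.n_Na_cyt / self.V_cyt

    @property
    def C_glc_int(self) -> float:
        return self.n_glc_int / self.V_int

    @property
    def C_Na_int(self) -> float:
        return self.n_Na_int / self.V_int

    def pressure(self, p: ModelParameters) -> float:
        """Interstitial pressure, mm Hg (pure function of V_int)."""
        return interstitial_pressure(self.V_int, p)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "CompartmentState":
        return cls(*(float(v) for v in y[:8]))

    @classmethod
    def from_array_clipped(cls, y: Sequence[float]) -> "CompartmentState":
        """As :meth:`from_array` but flooring amounts at zero and volumes
        at a tiny positive value.

        Adaptive steppers and root finders may probe a hair below zero
        near a depleted pool or an emptying compartment; the integrator's
        terminal guard still aborts any step that actually reaches zero
        volume.
        """
        v = [max(float(x), 0.0) for x in y[:8]]
        v[2] = max(v[2], 1e-12)
        v[5] = max(v[5], 1e-12)
        return cls(*v)


STATE_FIELDS = [f.name for f in dc_fields(CompartmentState)]


@dataclass(frozen=True)
class FluxVector:
    """Every instantaneous flux, positive in the absorptive direction.

    Absorptive means lumen->cell, cell->interstitium,
    lumen->interstitium and interstitium->capillary.  Solute fluxes in
    umol/h, water fluxes in ml/h.
    """

    J_sglt1: float        # glucose via SGLT1, lumen->cytosol
    J_glut2_ap: float     # glucose via apical GLUT2 (negative = backflux)
    J_glut2_bl: float     # glucose via basolateral GLUT2, cytosol->interstitium
    J_pc_glc: float       # paracellular glucose, lumen->interstitium
    J_Na_sglt1: float     # Na cotransported with SGLT1 glucose
    J_Na_pump: float      # Na pump, cytosol->interstitium
    J_Na_bl: float        # basolateral Na carrier, cytosol->interstitium
    J_pc_Na: float        # paracellular Na, lumen->interstitium
    J_cap_glc: float      # glucose, interstitium->capillary
    J_cap_Na: float       # Na, interstitium->capillary
    J_w_ap: float         # water, lumen->cytosol
    J_w_bl: float         # water, cytosol->interstitium
    J_w_pc: float         # water, lumen->interstitium (paracellular)
    J_w_cap: float        # water, interstitium->capillary

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


FLUX_FIELDS = [f.name for f in dc_fields(FluxVector)]


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state if available."""

    def __init__(self, message: str, last_state: CompartmentState | None = None,
                 last_time: float | None = None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """Steady-state search failed to converge."""


# ---------------------------------------------------------------------------
# Algebraic flux laws
# ---------------------------------------------------------------------------

def glut2_flux(C_out: float, C_in: float, Vmax: float, Km: float) -> float:
    """Symmetric two-site carrier flux, positive from *out* to *in*.

    J = Vmax * (g_o/(1+g_o) - g_i/(1+g_i)),  g = C/Km.

    Antisymmetric under argument swap and bounded in (-Vmax, Vmax).
    """
    if C_out < 0 or C_in < 0:
        raise ValueError("carrier substrate concentrations must be >= 0")
    if Km <= 0:
        raise ValueError("carrier Km must be > 0")
    if Vmax < 0:
        raise ValueError("carrier Vmax must be >= 0")
    g_out = C_out / Km
    g_in = C_in / Km
    return Vmax * (g_out / (1.0 + g_out) - g_in / (1.0 + g_in))


def sglt1_flux(C_glc_lum: float, C_Na_lum: float, p: ModelParameters,
               scale: float = 1.0) -> float:
    """SGLT1 glucose flux (model flux units x flux_scale => umol/h).

    Irreversible product of Michaelis terms in luminal glucose and Na;
    zero backflux (the export site has negligible glucose affinity).
    """
    if C_glc_lum < 0 or C_Na_lum < 0:
        raise ValueError("SGLT1 substrate concentrations must be >= 0")
    if not 0.0 <= scale <= 1.0:
        raise ValueError("SGLT1 inhibitor scale must lie in [0, 1]")
    return (scale * p.flux_scale * p.Vmax_sglt1
            * C_glc_lum / (C_glc_lum + p.Km_sglt1_glc)
            * C_Na_lum / (C_Na_lum + p.Km_sglt1_Na))


def na_pump_flux(C_Na_cyt: float, p: ModelParameters) -> float:
    """Na pump export, Michaelis-Menten in cytosolic Na (umol/h)."""
    if C_Na_cyt < 0:
        raise ValueError("cytosolic Na concentration must be >= 0")
    return p.flux_scale * p.Vmax_pump * C_Na_cyt / (C_Na_cyt + p.Km_pump)


def na_bl_flux(C_Na_cyt: float, C_Na_int: float, p: ModelParameters) -> float:
    """Basolateral Na carrier: two-site form, positive cytosol->interstitium."""
    return glut2_flux(C_Na_cyt, C_Na_int, p.flux_scale * p.Vmax_Na_bl, p.Km_Na_bl)


def convective_diffusion_flux(C_o: float, C_i: float, J_w: float, P_i: float) -> float:
    """Solute flux across a water-swept barrier: Jw*(Co+Ci)/2 + P*(Co-Ci)."""
    if C_o < 0 or C_i < 0:
        raise ValueError("concentrations must be >= 0")
    if P_i < 0:
        raise ValueError("permeability must be >= 0")
    return J_w * (C_o + C_i) / 2.0 + P_i * (C_o - C_i)


def interstitial_pressure(V_int: float, p: ModelParameters) -> float:
    """Interstitial pressure, mm Hg: exponential compliance law.

    P = k * (exp((V - V0)/V0) - 1), clipped below at ``pressure_floor``.
    Strictly increasing and convex, with P(V0) = 0.
    """
    if V_int <= 0:
        raise ValueError("interstitial volume must be > 0")
    # exponent capped to keep far-out-of-range probes finite
    x = min((V_int - p.compliance_V0) / p.compliance_V0, 60.0)
    P = p.compliance_k * (math.exp(x) - 1.0)
    return max(P, p.pressure_floor)


def paracellular_water_flux(state: CompartmentState, p: ModelParameters,
                            pc_scale: float = 1.0) -> float:
    """Tight-junction water flux, ml/h, positive lumen->interstitium.

    Osmotic driving (interstitium hypertonic to lumen pulls water in)
    minus the hydrostatic interstitial pressure pushing water back:

        Jw = scale * Lp_pc * (RT*[2*(Na_in-Na_lum)*sNa + (G_in-G_lum)*sG] - P_in)
    """
    of = p.osmotic_factor
    dpi = (2.0 * (state.C_Na_int - p.C_lum_Na) * p.sigma_Na
           + (state.C_glc_int - p.C_lum_glc) * p.sigma_glc) * of
    return pc_scale * p.Lp_pc * (dpi - state.pressure(p))


def transcellular_water_flux(side: str, state: CompartmentState, p: ModelParameters,
                             coupled_glc_flux: float = 0.0) -> float:
    """Water flux across the apical or basolateral membrane, ml/h.

    Osmotic term (sigma-weighted, Na counted twice, plus the impermeant
    cytosolic osmolyte at sigma 1) plus carrier-coupled water,
    n_w_per_glc * v_w * (glucose flux through that membrane's carriers).
    Positive is absorptive: lumen->cytosol apically, cytosol->
    interstitium basolaterally.
    """
    of = p.osmotic_factor
    osm_cyt = (2.0 * state.C_Na_cyt * p.sigma_Na
               + state.C_glc_cyt * p.sigma_glc
               + p.n_imp_cyt / state.V_cyt)
    if side == "apical":
        osm_lum = 2.0 * p.C_lum_Na * p.sigma_Na + p.C_lum_glc * p.sigma_glc
        osmotic = p.Lp_ap * of * (osm_cyt - osm_lum)
    elif side == "basolateral":
        osm_int = (2.0 * state.C_Na_int * p.sigma_Na
                   + state.C_glc_int * p.sigma_glc)
        osmotic = p.Lp_bl * of * (osm_int - osm_cyt)
    else:
        raise ValueError(f"unknown membrane side {side!r}; use 'apical' or 'basolateral'")
    return osmotic + p.n_w_per_glc * WATER_MOLAR_VOLUME * coupled_glc_flux


def _capillary_water_flux(state: CompartmentState, p: ModelParameters) -> float:
    """Water uptake into the capillary, ml/h, positive interstitium->capillary.

    The fenestrated villus endothelium reflects small crystalloids
    hardly at all (sigma ~ 0 for Na and glucose), so water exchange is
    driven by interstitial hydrostatic pressure, with the plasma
    oncotic offset folded into the pressure law's zero point.  A small
    pressure-proportional term stands in for lymphatic drainage.
    """
    P_in = state.pressure(p)
    return p.Q_cap * p.Lp_cap * P_in + p.lymph_coeff * max(P_in, 0.0)


def compute_fluxes(state: CompartmentState, p: ModelParameters,
                   scales: ScaleSet = BASELINE_SCALES) -> FluxVector:
    """Evaluate every flux law at one instant."""
    J_sglt1 = sglt1_flux(p.C_lum_glc, p.C_lum_Na, p, scales.sglt1_scale)
    J_glut2_ap = glut2_flux(p.C_lum_glc, state.C_glc_cyt,
                            scales.glut2_ap_scale * p.flux_scale * p.Vmax_glut2_ap,
                            p.Km_glut2)
    J_glut2_bl = glut2_flux(state.C_glc_cyt, state.C_glc_int,
                            p.flux_scale * p.Vmax_glut2_bl, p.Km_glut2)
    J_Na_pump = na_pump_flux(state.C_Na_cyt, p)
    J_Na_bl = na_bl_flux(state.C_Na_cyt, state.C_Na_int, p)

    J_w_pc = paracellular_water_flux(state, p, scales.pc_water_scale)
    J_pc_glc = scales.pc_scale * convective_diffusion_flux(
        p.C_lum_glc, state.C_glc_int, J_w_pc, p.peff_glc_pc)
    J_pc_Na = scales.pc_scale * convective_diffusion_flux(
        p.C_lum_Na, state.C_Na_int, J_w_pc, p.peff_Na_pc)

    J_w_ap = transcellular_water_flux("apical", state, p, J_sglt1 + J_glut2_ap)
    J_w_bl = transcellular_water_flux("basolateral", state, p, J_glut2_bl)
    J_w_cap = _capillary_water_flux(state, p)

    J_cap_glc = convective_diffusion_flux(
        state.C_glc_int, state.C_glc_cap, J_w_cap, p.Q_cap * p.P_cap_glc)
    J_cap_Na = convective_diffusion_flux(
        state.C_Na_int, state.C_Na_cap, J_w_cap, p.Q_cap * p.P_cap_Na)

    return FluxVector(
        J_sglt1=J_sglt1,
        J_glut2_ap=J_glut2_ap,
        J_glut2_bl=J_glut2_bl,
        J_pc_glc=J_pc_glc,
        J_Na_sglt1=p.n_Na_per_glc * J_sglt1,
        J_Na_pump=J_Na_pump,
        J_Na_bl=J_Na_bl,
        J_pc_Na=J_pc_Na,
        J_cap_glc=J_cap_glc,
        J_cap_Na=J_cap_Na,
        J_w_ap=J_w_ap,
        J_w_bl=J_w_bl,
        J_w_pc=J_w_pc,
        J_w_cap=J_w_cap,
    )


# ---------------------------------------------------------------------------
# Time derivative of the system state
# ---------------------------------------------------------------------------

#: indices of the cumulative boundary-flux integrals appended to the core state
N_CORE = 8
N_AUX = 6  # glc in, glc out, Na in, Na out, water in, water out


def _derivatives(state: CompartmentState, p: ModelParameters,
                 scales: ScaleSet) -> tuple[np.ndarray, FluxVector]:
    J = compute_fluxes(state, p, scales)
    F = p.Q_cap * p.cap_flow
    dy = np.empty(N_CORE + N_AUX)
    dy[0] = J.J_sglt1 + J.J_glut2_ap - J.J_glut2_bl            # n_glc_cyt
    dy[1] = J.J_Na_sglt1 - J.J_Na_pump - J.J_Na_bl             # n_Na_cyt
    dy[2] = J.J_w_ap - J.J_w_bl                                # V_cyt
    dy[3] = J.J_glut2_bl + J.J_pc_glc - J.J_cap_glc            # n_glc_int
    dy[4] = J.J_Na_pump + J.J_Na_bl + J.J_pc_Na - J.J_cap_Na   # n_Na_int
    dy[5] = J.J_w_bl + J.J_w_pc - J.J_w_cap                    # V_int
    dy[6] = (F * (p.C_art_glc - state.C_glc_cap) + J.J_cap_glc) / p.V_cap
    dy[7] = (F * (p.C_art_Na - state.C_Na_cap) + J.J_cap_Na) / p.V_cap
    # cumulative boundary fluxes (for conservation audits)
    dy[8] = J.J_sglt1 + J.J_glut2_ap + J.J_pc_glc              # glucose entering from lumen
    dy[9] = J.J_cap_glc                                        # glucose leaving to blood
    dy[10] = J.J_Na_sglt1 + J.J_pc_Na                          # Na entering from lumen
    dy[11] = J.J_cap_Na                                        # Na leaving to blood
    dy[12] = J.J_w_ap + J.J_w_pc                               # water entering from lumen
    dy[13] = J.J_w_cap                                         # water leaving to blood
    return dy, J


def rhs(t: float, state: CompartmentState | Sequence[float], p: ModelParameters,
        schedule: InhibitorSchedule | ScaleSet = EMPTY_SCHEDULE) -> np.ndarray:
    """Time derivative of the (augmented) state vector at time ``t``.

    ``schedule`` may be an :class:`InhibitorSchedule` (resolved at
    ``t``) or a fixed :class:`ScaleSet`.  Accepts a
    :class:`CompartmentState` or a raw state vector (core 8 entries, or
    core + 6 cumulative boundary integrals); returns the 14-entry
    derivative.
    """
    scales = schedule.active(t) if isinstance(schedule, InhibitorSchedule) else schedule
    if not isinstance(state, CompartmentState):
        state = CompartmentState.from_array(np.asarray(state, dtype=float))
    dy, _ = _derivatives(state, p, scales)
    return dy


def default_initial_state(p: ModelParameters) -> CompartmentState:
    """A physiologically sensible starting state (and steady-state guess)."""
    return CompartmentState(
        n_glc_cyt=10.0 * p.V_cyt_ref,
        n_Na_cyt=15.0 * p.V_cyt_ref,
        V_cyt=p.V_cyt_ref,
        n_glc_int=p.C_art_glc * p.compliance_V0,
        n_Na_int=p.C_art_Na * p.compliance_V0,
        V_int=p.compliance_V0,
        C_glc_cap=p.C_art_glc,
        C_Na_cap=p.C_art_Na,
    )


# ---------------------------------------------------------------------------
# Solver: time integration with events, steady-state location
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled solution of the model ODEs on a uniform reporting grid."""

    t: np.ndarray                    # (N,), h, strictly increasing
    y: np.ndarray                    # (N, 14) core state + cumulative integrals
    params: ModelParameters
    schedule: InhibitorSchedule

    def state(self, i: int) -> CompartmentState:
        return CompartmentState.from_array_clipped(self.y[i])

    def states(self) -> list[CompartmentState]:
        return [self.state(i) for i in range(len(self.t))]

    def fluxes(self, i: int) -> FluxVector:
        return compute_fluxes(self.state(i), self.params, self.schedule.active(self.t[i]))

    @property
    def final_state(self) -> CompartmentState:
        return self.state(len(self.t) - 1)

    def conservation_residuals(self) -> dict[str, float]:
        """Relative mass-balance residuals over the whole trajectory.

        For glucose and Na: |change of (cytosol + interstitium) content
        - (cumulative luminal entry - cumulative capillary removal)|
        relative to total throughput; likewise for water volume.
        """
        y0, y1 = self.y[0], self.y[-1]
        out = {}
        for name, (a, b), (i_in, i_out) in (
            ("glucose", (0, 3), (8, 9)),
            ("Na", (1, 4), (10, 11)),
            ("water", (2, 5), (12, 13)),
        ):
            d_state = (y1[a] - y0[a]) + (y1[b] - y0[b])
            net_boundary = (y1[i_in] - y0[i_in]) - (y1[i_out] - y0[i_out])
            scale = max(abs(y1[i_in] - y0[i_in]), abs(y1[i_out] - y0[i_out]),
                        abs(y0[a]) + abs(y0[b]), 1e-12)
            out[name] = abs(d_state - net_boundary) / scale
        return out

    def frame(self) -> pd.DataFrame:
        """Tidy per-sample table of concentrations, volumes and fluxes."""
        rows = []
        for i, t in enumerate(self.t):
            s = self.state(i)
            J = self.fluxes(i)
            sc = self.schedule.active(t)
            row = {
                "t": t,
                "C_glc_cyt": s.C_glc_cyt, "C_Na_cyt": s.C_Na_cyt,
                "C_glc_int": s.C_glc_int, "C_Na_int": s.C_Na_int,
                "C_glc_cap": s.C_glc_cap, "C_Na_cap": s.C_Na_cap,
                "V_cyt": s.V_cyt, "V_int": s.V_int,
                "P_in": s.pressure(self.params),
                "sglt1_scale": sc.sglt1_scale, "glut2_ap_scale": sc.glut2_ap_scale,
                "pc_scale": sc.pc_scale,
            }
            row.update(J.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


_GUARD_EPS = 1e-9


def _make_guards() -> list:
    def v_cyt_guard(t, y, *args):
        return y[2] - _GUARD_EPS

    def v_int_guard(t, y, *args):
        return y[5] - _GUARD_EPS

    for g in (v_cyt_guard, v_int_guard):
        g.terminal = True
        g.direction = -1
    return [v_cyt_guard, v_int_guard]


def integrate(initial: CompartmentState, p: ModelParameters,
              schedule: InhibitorSchedule = EMPTY_SCHEDULE,
              t_end: float = 2.0, *, rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, max_step: float = np.inf,
              report_dt: float = REPORT_DT, method: str = "LSODA") -> Trajectory:
    """Integrate the model from ``initial`` to ``t_end`` hours.

    The integration is restarted exactly at every schedule event time so
    that the discontinuous scale changes never straddle an internal
    step.  States are continuous across events; fluxes are not.  A
    terminal guard aborts (with :class:`IntegrationError`) if either
    compartment volume would reach zero.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    seg_edges = [0.0] + [t for t in schedule.times() if 0.0 < t < t_end] + [t_end]
    grid = np.arange(0.0, t_end + report_dt / 2, report_dt)
    grid[-1] = min(grid[-1], t_end)

    y0 = np.concatenate([initial.to_array(), np.zeros(N_AUX)])
    ts: list[float] = []
    ys: list[np.ndarray] = []
    guards = _make_guards()
    for t0, t1 in zip(seg_edges, seg_edges[1:]):
        scales = schedule.active(t0)
        f = lambda t, y: _derivatives(CompartmentState.from_array_clipped(y), p, scales)[0]
        seg_grid = grid[(grid >= t0 - 1e-12) & (grid <= t1 + 1e-12)]
        t_eval = np.unique(np.clip(np.concatenate([[t0], seg_grid, [t1]]), t0, t1))
        sol = solve_ivp(f, (t0, t1), y0, method=method, rtol=rtol, atol=atol,
                        max_step=max_step, t_eval=t_eval, events=guards)
        if sol.status == 1:  # guard fired
            last = CompartmentState.from_array(sol.y[:, -1]) if sol.y.size else initial
            raise IntegrationError(
                f"compartment volume reached zero near t = {sol.t[-1]:.4g} h",
                last_state=last, last_time=float(sol.t[-1]) if sol.t.size else t0)
        if not sol.success:
            last = CompartmentState.from_array(sol.y[:, -1]) if sol.y.size else initial
            raise IntegrationError(f"integrator failure: {sol.message}",
                                   last_state=last,
                                   last_time=float(sol.t[-1]) if sol.t.size else t0)
        keep = slice(0, len(sol.t) - 1) if t1 < t_end else slice(0, len(sol.t))
        ts.extend(sol.t[keep])
        ys.extend(sol.y[:, keep].T)
        y0 = sol.y[:, -1]
    t_arr = np.asarray(ts)
    # drop duplicated samples at segment starts
    uniq = np.concatenate([[True], np.diff(t_arr) > 1e-12])
    return Trajectory(t=t_arr[uniq], y=np.asarray(ys)[uniq], params=p, schedule=schedule)


def _relative_rates(y8: np.ndarray, p: ModelParameters, scales: ScaleSet) -> np.ndarray:
    """Core-state time derivatives scaled by characteristic pool sizes, 1/h.

    The scales are fixed (typical amounts/volumes of the reference
    tissue), not the current state: a relative |dy/y| measure would
    spuriously vanish on degenerate branches where a pool grows without
    bound.
    """
    state = CompartmentState.from_array_clipped(y8)
    dy, _ = _derivatives(state, p, scales)
    Vr, V0 = p.V_cyt_ref, p.compliance_V0
    typical = np.array([50.0 * Vr, 150.0 * Vr, Vr,
                        50.0 * V0, 150.0 * V0, V0, 50.0, 150.0])
    return dy[:N_CORE] / typical


def steady_state(p: ModelParameters, scales: ScaleSet = BASELINE_SCALES,
                 guess: CompartmentState | None = None, *,
                 tol: float = 1e-10, verify_tol: float = 1e-8) -> CompartmentState:
    """Locate the steady state of the model for a fixed scale set.

    Damped root finding (in log state space, so positivity is built in)
    on the flux balance, with a long-time integration fallback; the
    result is accepted only if the scaled derivative norm is below
    ``verify_tol``.
    """
    if guess is None:
        guess = default_initial_state(p)
    z0 = np.log(np.maximum(guess.to_array(), 1e-12))

    def f(z: np.ndarray) -> np.ndarray:
        return _relative_rates(np.exp(z), p, scales)

    def try_root(z_init: np.ndarray) -> CompartmentState | None:
        try:
            sol = root(f, z_init, method="hybr", tol=tol)
        except (ValueError, FloatingPointError, OverflowError):
            return None
        if not sol.success:
            return None
        y = np.exp(sol.x)
        if np.linalg.norm(_relative_rates(y, p, scales)) < verify_tol:
            return CompartmentState.from_array(y)
        return None

    result = try_root(z0)
    if result is None:
        # fallback: relax toward the steady state by integration, then polish
        fixed = InhibitorSchedule(((0.0, scales),))
        y = guess
        for t_chunk in (5.0, 20.0, 75.0, 150.0, 250.0):
            traj = integrate(y, p, fixed, t_end=t_chunk,
                             rtol=1e-9, atol=1e-11, report_dt=t_chunk / 4)
            y = traj.final_state
            result = try_root(np.log(np.maximum(y.to_array(), 1e-12)))
            if result is not None:
                break
            if np.max(np.abs(_relative_rates(y.to_array(), p, scales))) < 1e-9:
                result = y
                break
    if result is None:
        raise SteadyStateError("steady-state search did not converge "
                               "(root finding and long-time integration both failed)")
    return result


# ---------------------------------------------------------------------------
# Scenarios: the four computational experiments and the registration point
# ---------------------------------------------------------------------------

REFERENCE = ModelParameters()

#: low apical GLUT2 Vmax used as the factorial baseline ("low activity"):
#: a 4-fold increase reaches the titration maximum of 2 model flux units.
FIG1_GLUT2_LOW = 0.5

LUMINAL_GRID = tuple(float(g) for g in np.arange(0.0, 100.1, 5.0))
PGLC_GRID = tuple(float(x) for x in np.linspace(0.0, 0.02, 9))


@dataclass
class ScenarioResult:
    """Output of one computational experiment.

    ``table`` holds one row per panel / grid point / time sample with
    raw fluxes (umol/h) plus ``*_norm`` columns divided by
    ``normalization`` (the scenario's baseline SGLT1 glucose flux).
    Derived sums: net apical glucose flux = J_sglt1 + J_glut2_ap; net
    transluminal flux adds J_pc_glc.
    """

    scenario_id: str
    config: dict
    table: pd.DataFrame
    normalization: float
    trajectory: Trajectory | None = None

    def __post_init__(self) -> None:
        if not self.normalization > 0:
            raise ValueError("normalization constant must be > 0")


def _steady_row(p: ModelParameters, scales: ScaleSet = BASELINE_SCALES,
                guess: CompartmentState | None = None) -> tuple[dict, CompartmentState]:
    s = steady_state(p, scales, guess)
    J = compute_fluxes(s, p, scales)
    row = {
        "C_glc_cyt": s.C_glc_cyt, "C_Na_cyt": s.C_Na_cyt,
        "C_glc_int": s.C_glc_int, "C_Na_int": s.C_Na_int,
        "C_glc_cap": s.C_glc_cap, "C_Na_cap": s.C_Na_cap,
        "V_cyt": s.V_cyt, "V_int": s.V_int, "P_in": s.pressure(p),
    }
    row.update(J.as_dict())
    row["net_apical_glc"] = J.J_sglt1 + J.J_glut2_ap
    row["net_transluminal_glc"] = J.J_sglt1 + J.J_glut2_ap + J.J_pc_glc
    return row, s


def _add_normalized(df: pd.DataFrame, norm: float) -> pd.DataFrame:
    for c in FLUX_FIELDS + ["net_apical_glc", "net_transluminal_glc"]:
        if c in df.columns:
            df[c + "_norm"] = df[c] / norm
    return df


def run_factorial(p: ModelParameters | None = None,
                  glut2_factors: Sequence[float] = (1.0, 4.0),
                  clearance_factors: Sequence[float] = (1.0, 10.0)) -> ScenarioResult:
    """Factorial snapshot: apical GLUT2 (x1, x4) against capillary clearance (x1, x10).

    Panels A-D at 50 mM luminal glucose / 5 mM arterial glucose; fluxes
    are reported normalized to panel A's SGLT1 uptake rate.
    """
    base = (p or REFERENCE).with_overrides(C_lum_glc=50.0)
    panels = []
    labels = iter("ABCDEFGH")
    norm = None
    # panel order A=(g1,c1) B=(g4,c1) C=(g1,c10) D=(g4,c10)
    combos = [(gf, cf) for cf in clearance_factors for gf in glut2_factors]
    guess = None
    for label, (gf, cf) in zip(labels, combos):
        pp = base.with_overrides(Vmax_glut2_ap=FIG1_GLUT2_LOW * gf, Q_cap=cf)
        row, s = _steady_row(pp, guess=guess)
        guess = s
        row.update(panel=label, glut2_factor=gf, clearance_factor=cf)
        panels.append(row)
        if norm is None:
            norm = row["J_sglt1"]
        logger.info("factorial panel %s: glut2 x%g clearance x%g", label, gf, cf)
    df = _add_normalized(pd.DataFrame(panels), norm)
    return ScenarioResult("fig1_factorial", {"base": _params_dict(base)}, df, norm)


def sweep_glut2(p: ModelParameters | None = None,
                luminal_grid: Sequence[float] = LUMINAL_GRID,
                vmax_values: Sequence[float] = (0.0, 2.0)) -> ScenarioResult:
    """Titrate apical GLUT2 (absent vs maximal) over luminal glucose.

    Steady-state fluxes, concentrations and cell volume at every grid
    point, under the high-clearance condition.
    """
    base = p or REFERENCE
    rows = []
    for vmax in vmax_values:
        guess = None
        for g in luminal_grid:
            pp = base.with_overrides(Vmax_glut2_ap=vmax, C_lum_glc=float(g))
            row, s = _steady_row(pp, guess=guess)
            guess = s
            row.update(Vmax_glut2_ap=vmax, C_lum_glc=float(g))
            rows.append(row)
        logger.info("glut2 sweep at Vmax %g done (%d points)", vmax, len(luminal_grid))
    norm = sglt1_flux(50.0, base.C_lum_Na, base)
    df = _add_normalized(pd.DataFrame(rows), norm)
    return ScenarioResult("fig2_glut2_sweep", {"base": _params_dict(base)}, df, norm)


def sweep_pglc(p: ModelParameters | None = None,
               pglc_grid: Sequence[float] = PGLC_GRID,
               with_crossover: bool = True) -> ScenarioResult:
    """Sweep paracellular glucose permeability from 0 to 0.02 cm/s.

    Reports the steady state at the reference luminal glucose for each
    permeability, and (optionally) the luminal concentration at which
    paracellular and SGLT1 glucose fluxes cross.
    """
    base = p or REFERENCE
    rows = []
    guess = None
    for pg in pglc_grid:
        pp = base.with_overrides(P_glc_pc=float(pg))
        row, s = _steady_row(pp, guess=guess)
        guess = s
        row["P_glc_pc"] = float(pg)
        if with_crossover:
            x = find_crossover(pp)
            row["crossover_mM"] = np.nan if x is None else x
        rows.append(row)
        logger.info("P_glc sweep point %g cm/s done", pg)
    norm = sglt1_flux(50.0, base.C_lum_Na, base)
    df = _add_normalized(pd.DataFrame(rows), norm)
    return ScenarioResult("fig3_pglc_sweep", {"base": _params_dict(base)}, df, norm)


def find_crossover(p: ModelParameters | None = None, *,
                   pglc: float | None = None,
                   bracket: tuple[float, float] = (0.5, 200.0),
                   xtol: float = 0.05) -> float | None:
    """Luminal glucose at which steady-state paracellular flux equals SGLT1 flux.

    Scans the bracket for a sign change of J_pc_glc - J_sglt1 (both at
    steady state), then refines by bracketed bisection to ``xtol`` mM.
    Returns ``None`` when no crossover exists in the bracket (e.g. at
    zero paracellular permeability the crossover concentration is
    infinite).
    """
    base = p or REFERENCE
    if pglc is not None:
        base = base.with_overrides(P_glc_pc=float(pglc))

    cache: dict[float, float] = {}
    guess_holder: list[CompartmentState | None] = [None]

    def f(g: float) -> float:
        if g in cache:
            return cache[g]
        pp = base.with_overrides(C_lum_glc=float(g))
        s = steady_state(pp, guess=guess_holder[0])
        guess_holder[0] = s
        J = compute_fluxes(s, pp)
        val = J.J_pc_glc - J.J_sglt1
        cache[g] = val
        return val

    lo, hi = bracket
    scan = np.concatenate([[lo], np.arange(5.0, hi + 1e-9, 5.0)])
    prev_g, prev_f = None, None
    for g in scan:
        try:
            fg = f(float(g))
        except SteadyStateError:
            logger.warning("crossover scan: steady state failed at %g mM", g)
            prev_g, prev_f = None, None
            continue
        if prev_f is not None and prev_f < 0.0 <= fg:
            x = brentq(f, prev_g, float(g), xtol=xtol)
            logger.info("crossover located at %.2f mM (P_glc_pc = %g cm/s)",
                        x, base.P_glc_pc)
            return float(x)
        prev_g, prev_f = float(g), fg
    logger.info("no paracellular/SGLT1 crossover in (%g, %g] mM at P_glc_pc = %g",
                lo, hi, base.P_glc_pc)
    return None


def fig4_schedule(mode: str, p: ModelParameters) -> InhibitorSchedule:
    """Phloridzin at 0.5 h (SGLT1 off), phloretin at 1.0 h.

    Mode A: phloretin blocks only apical GLUT2.  Mode B: it also blocks
    the paracellular glucose and Na permeabilities (and the paracellular
    water path if ``phloretin_blocks_water`` is set).
    """
    if mode not in ("A", "B"):
        raise ValueError(f"phloretin mode must be 'A' or 'B', got {mode!r}")
    after_phloridzin = ScaleSet(sglt1_scale=0.0)
    if mode == "A":
        after_phloretin = ScaleSet(sglt1_scale=0.0, glut2_ap_scale=0.0)
    else:
        pc_w = 0.0 if p.phloretin_blocks_water else 1.0
        after_phloretin = ScaleSet(sglt1_scale=0.0, glut2_ap_scale=0.0,
                                   pc_scale=0.0, pc_water_scale=pc_w)
    return InhibitorSchedule(((0.5, after_phloridzin), (1.0, after_phloretin)))


def run_inhibitor_timecourse(mode: str = "A", p: ModelParameters | None = None,
                             t_end: float = 2.0, **integrate_opts) -> ScenarioResult:
    """Sequential phloridzin-then-phloretin time course (30 mM luminal glucose).

    Starts from the pre-inhibitor steady state (apical GLUT2 Vmax 2,
    capillary clearance x10, arterial glucose 5 mM), blocks SGLT1 at
    0.5 h and apical GLUT2 (mode A) or apical GLUT2 plus the
    paracellular solute path (mode B) at 1.0 h.
    """
    base = (p or REFERENCE).with_overrides(C_lum_glc=30.0, Vmax_glut2_ap=2.0,
                                           Q_cap=10.0)
    schedule = fig4_schedule(mode, base)
    logger.info("fig4 mode %s: pre-equilibrating", mode)
    s0 = steady_state(base)
    traj = integrate(s0, base, schedule, t_end=t_end, **integrate_opts)
    df = traj.frame()
    df["net_apical_glc"] = df["J_sglt1"] + df["J_glut2_ap"]
    df["net_transluminal_glc"] = df["net_apical_glc"] + df["J_pc_glc"]
    norm = compute_fluxes(s0, base).J_sglt1
    df = _add_normalized(df, norm)
    return ScenarioResult(f"fig4_inhibitor_mode{mode}",
                          {"base": _params_dict(base), "mode": mode},
                          df, norm, trajectory=traj)


# ---------------------------------------------------------------------------
# Configuration, persistence, plotting, fixtures
# ---------------------------------------------------------------------------

_PARAM_FIELDS = {f.name for f in dc_fields(ModelParameters)}
_SCALE_KEYS = {"time", "sglt1_scale", "glut2_ap_scale", "pc_scale", "pc_water_scale"}


def _params_dict(p: ModelParameters) -> dict:
    return {f.name: getattr(p, f.name) for f in dc_fields(ModelParameters)}


def load_config(path: str | Path | None = None
                ) -> tuple[ModelParameters, InhibitorSchedule, dict]:
    """Read a YAML scenario config; unknown keys are a hard error.

    Recognized top-level keys: every :class:`ModelParameters` field name
    (missing ones fall back to the frozen reference values), a
    ``schedule:`` event list and a free-form ``scenario:`` mapping.
    """
    if path is None:
        return REFERENCE, EMPTY_SCHEDULE, {}
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _PARAM_FIELDS - {"schedule", "scenario"}
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    overrides = {k: v for k, v in raw.items() if k in _PARAM_FIELDS}
    try:
        params = REFERENCE.with_overrides(**overrides)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e
    events = []
    for i, ev in enumerate(raw.get("schedule") or []):
        bad = set(ev) - _SCALE_KEYS
        if bad:
            raise ValueError(f"{path}: schedule[{i}]: unknown keys {sorted(bad)}")
        if "time" not in ev:
            raise ValueError(f"{path}: schedule[{i}]: missing 'time'")
        scales = ScaleSet(**{k: float(v) for k, v in ev.items() if k != "time"})
        events.append((float(ev["time"]), scales))
    try:
        schedule = InhibitorSchedule(tuple(events))
    except ValueError as e:
        raise ValueError(f"{path}: schedule: {e}") from e
    scenario = raw.get("scenario") or {}
    logger.info("loaded config %s (%d overrides, %d events)",
                path, len(overrides), len(events))
    return params, schedule, scenario


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every scenario output."""

    scenario_id: str
    config_hash: str
    artifact_version: str
    solver_options: dict
    wall_time_s: float
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def write_result(result: ScenarioResult, outdir: str | Path, *,
                 solver_options: dict | None = None,
                 wall_time_s: float = 0.0) -> RunManifest:
    """Write a scenario's tidy TSV table plus a JSON manifest.

    Floats are printed with 10 significant digits; re-running the same
    config yields byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / f"{result.scenario_id}.tsv"
    result.table.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    manifest = RunManifest(
        scenario_id=result.scenario_id,
        config_hash=_config_hash(result.config),
        artifact_version=ARTIFACT_VERSION,
        solver_options=solver_options or {"rtol": DEFAULT_RTOL, "atol": DEFAULT_ATOL},
        wall_time_s=wall_time_s,
        outputs=[tsv.name],
    )
    (outdir / f"{result.scenario_id}.manifest.json").write_text(manifest.to_json())
    logger.info("wrote %s (%d rows)", tsv, len(result.table))
    return manifest


FIXTURE_CONFIGS: dict[str, dict] = {
    "reference.yaml": {},
    "fig1.yaml": {"C_lum_glc": 50.0, "Vmax_glut2_ap": FIG1_GLUT2_LOW, "Q_cap": 1.0,
                  "scenario": {"kind": "factorial"}},
    "fig2.yaml": {"Q_cap": 10.0, "scenario": {"kind": "glut2_sweep"}},
    "fig3.yaml": {"Q_cap": 10.0, "scenario": {"kind": "pglc_sweep"}},
    "fig4_modeA.yaml": {
        "C_lum_glc": 30.0, "Vmax_glut2_ap": 2.0, "Q_cap": 10.0,
        "schedule": [{"time": 0.5, "sglt1_scale": 0.0},
                     {"time": 1.0, "sglt1_scale": 0.0, "glut2_ap_scale": 0.0}],
        "scenario": {"kind": "inhibitor_timecourse", "mode": "A"}},
    "fig4_modeB.yaml": {
        "C_lum_glc": 30.0, "Vmax_glut2_ap": 2.0, "Q_cap": 10.0,
        "schedule": [{"time": 0.5, "sglt1_scale": 0.0},
                     {"time": 1.0, "sglt1_scale": 0.0, "glut2_ap_scale": 0.0,
                      "pc_scale": 0.0}],
        "scenario": {"kind": "inhibitor_timecourse", "mode": "B"}},
    "smoke.yaml": {
        "C_lum_glc": 30.0, "Vmax_glut2_ap": 2.0, "Q_cap": 10.0,
        "schedule": [{"time": 0.1, "sglt1_scale": 0.0}],
        "scenario": {"kind": "inhibitor_timecourse", "mode": "A",
                     "t_end": 0.2, "rtol": 1e-6, "atol": 1e-8,
                     "report_dt": 0.02}},
}


def make_fixtures(outdir: str | Path = "config") -> list[Path]:
    """Emit the figure scenario configs and a fast smoke config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # reference.yaml spells out the frozen parameter set in full
    configs = dict(FIXTURE_CONFIGS)
    configs["reference.yaml"] = _params_dict(REFERENCE)
    written = []
    for name, cfg in configs.items():
        path = outdir / name
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        written.append(path)
    logger.info("wrote %d fixture configs to %s", len(written), outdir)
    return written


def plot_scenario(result: ScenarioResult, outdir: str | Path) -> list[Path]:
    """One flux panel and one concentration/volume panel per scenario (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = result.table
    if "t" in df.columns:
        x, xlabel = df["t"], "time (h)"
    elif "C_lum_glc" in df.columns:
        x, xlabel = df["C_lum_glc"], "luminal glucose (mM)"
    elif "P_glc_pc" in df.columns:
        x, xlabel = df["P_glc_pc"], "paracellular glucose permeability (cm/s)"
    else:
        x, xlabel = np.arange(len(df)), "panel index"

    files = []
    fig, ax = plt.subplots(figsize=(6, 4))
    for col, label in (("J_sglt1_norm", "SGLT1"), ("J_glut2_ap_norm", "apical GLUT2"),
                       ("J_pc_glc_norm", "paracellular"),
                       ("net_transluminal_glc_norm", "transluminal total"),
                       ("J_cap_glc_norm", "interstitium->capillary")):
        if col in df.columns:
            ax.plot(x, df[col], label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("glucose flux (normalized to baseline SGLT1)")
    ax.legend(fontsize=8)
    ax.axhline(0, color="k", lw=0.5)
    f1 = outdir / f"{result.scenario_id}_fluxes.png"
    fig.savefig(f1, dpi=120)
    plt.close(fig)
    files.append(f1)

    fig, ax = plt.subplots(figsize=(6, 4))
    for col, label in (("C_glc_cyt", "cytosol"), ("C_glc_int", "interstitium"),
                       ("C_glc_cap", "capillary")):
        if col in df.columns:
            ax.plot(x, df[col], label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("glucose (mM)")
    ax2 = ax.twinx()
    if "V_cyt" in df.columns:
        ax2.plot(x, df["V_cyt"], "g--", label="V_cyt")
        ax2.set_ylabel("cell volume (ml)")
    ax.legend(fontsize=8, loc="upper left")
    f2 = outdir / f"{result.scenario_id}_concentrations.png"
    fig.savefig(f2, dpi=120)
    plt.close(fig)
    files.append(f2)
    return files
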