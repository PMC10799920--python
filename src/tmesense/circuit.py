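"""Promoter input functions and the circuit ODE right-hand side.

Model structure
---------------
Let ``A(u)`` be the sensing-promoter activity under environment ``u`` and
``B = N_u + N_f + D`` the total biomass (live cells plus debris) competing
for the shared batch resource, with carrying capacity ``K``.

``phi = max(1 - B/K, 0)`` is the nutrient/metabolic-activity factor: the
specific growth rate is ``mu = r * phi`` and gene expression is scaled by
the same factor, the standard growth-rate coupling of batch-culture
expression (protein synthesis stops as the culture enters stationary phase).

State equations (per-hour rates):

    dN_u/dt = mu N_u - F N_u - delta(E) N_u
    dN_f/dt = mu N_f + F N_u - delta(E) N_f
    dR/dt   = syn_R * phi - (gamma_R + mu) R
    dE/dt   = alpha_E A(u) phi - (gamma_E + mu) E        (SWITCH_LYSIS)
    dD/dt   = delta(E) (N_u + N_f) - gamma_D D

with the flip propensity ``F = k_flip * A(u) * phi / gamma_I`` (quasi-
steady-state integrase, irreversible), reporter synthesis
``syn_R = g_A A(u)`` for DIRECT and ``alpha_P7`` (strong constitutive
promoter, flipped cells) for SWITCH topologies, and Hill-type death
``delta(E) = delta_max E^h / (K_E^h + E^h)``.

Debris decays slowly (``gamma_D``); because it occupies carrying capacity
while it lasts, lysis strains show depressed OD and, by inflating the OD
denominator, depressed normalized fluorescence — and the freed capacity on
debris decay re-ignites growth, giving the damped population oscillations
characteristic of lysis circuits.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    CircuitState,
    ConfigurationError,
    EnvironmentSignal,
    HillParams,
    ParameterError,
    PromoterSpec,
    StrainSpec,
)

__all__ = [
    "hill_response",
    "promoter_activity",
    "death_rate",
    "derivatives",
    "rhs",
    "observed_outputs",
    "DEBRIS_DECAY_RATE",
]

#: first-order decay rate of lysed-cell debris (1/h); frees carrying capacity
DEBRIS_DECAY_RATE = 0.02


def hill_response(signal: float, params: HillParams) -> float:
    """Hill activity of a promoter at a non-negative signal level.

    Activating: ``basal + span * s^n / (K^n + s^n)``;
    repressing: ``basal + span * K^n / (K^n + s^n)``.
    The result lies in ``[basal, basal + span]``.
    """
    if not isinstance(params, HillParams):
        raise ParameterError("params must be a HillParams instance")
    s = float(signal)
    if not math.isfinite(s) or s < 0:
        raise ParameterError(f"signal must be finite and >= 0, got {signal!r}")
    # work on log-ratio scale to avoid overflow at large s or n
    if s == 0.0:
        occ = 0.0
    else:
        ratio = params.coefficient * (math.log(s) - math.log(params.half_max))
        if ratio > 700.0:
            occ = 1.0
        elif ratio < -700.0:
            occ = 0.0
        else:
            occ = 1.0 / (1.0 + math.exp(-ratio))  # s^n / (K^n + s^n)
    if params.mode == "repressing":
        occ = 1.0 - occ
    return params.basal + params.span * occ


def promoter_activity(promoter: PromoterSpec, env: EnvironmentSignal) -> float:
    """Activity (units/h) of a promoter in a given environment.

    Selects the promoter's signal channel (lactate in mM, proton in M,
    oxygen in % v/v) and applies its Hill function; constitutive promoters
    return ``const_activity`` regardless of the environment.
    """
    if promoter.id == "constitutive":
        return float(promoter.const_activity)
    signal = env.channel_value(promoter.channel)
    return hill_response(signal, promoter.hill)


def death_rate(lysis_protein: float, strain: StrainSpec) -> float:
    """Hill-type per-cell death rate from the phiX174E lysis protein."""
    if not strain.has_lysis or lysis_protein <= 0.0:
        return 0.0
    p = strain.lysis
    e_h = lysis_protein ** p.death_coefficient
    return p.max_death_rate * e_h / (p.death_half_max ** p.death_coefficient + e_h)


def rhs(t: float, y: np.ndarray, strain: StrainSpec, env: EnvironmentSignal,
        external_biomass: float = 0.0) -> np.ndarray:
    """Packed-vector ODE right-hand side (solver-facing).

    ``external_biomass`` adds competitor biomass from co-cultured strains to
    the shared carrying-capacity term (used by the consortium simulator).
    """
    n_u, n_f, r_pc, e_pc, debris = y
    # negative round-off from the solver is treated as zero
    n_u = max(n_u, 0.0)
    n_f = max(n_f, 0.0)
    r_pc = max(r_pc, 0.0)
    e_pc = max(e_pc, 0.0)
    debris = max(debris, 0.0)

    g = strain.growth
    biomass = n_u + n_f + debris + external_biomass
    phi = max(1.0 - biomass / g.carrying_capacity, 0.0)
    mu = g.growth_rate * phi

    activity = promoter_activity(strain.sensing, env)

    if strain.has_switch:
        flip = strain.switch.flip_rate_constant * activity * phi / strain.switch.integrase_degradation
        syn_r = promoter_activity(strain.strong, env)
    else:
        flip = 0.0
        syn_r = strain.reporter.direct_expression_gain * activity

    delta = death_rate(e_pc, strain)

    d_nu = mu * n_u - flip * n_u - delta * n_u
    d_nf = mu * n_f + flip * n_u - delta * n_f
    d_r = syn_r * phi - (strain.reporter.reporter_decay + mu) * r_pc
    if strain.has_lysis:
        p = strain.lysis
        d_e = p.lysis_expression_rate * activity * phi - (p.lysis_protein_decay + mu) * e_pc
    else:
        d_e = 0.0
    d_debris = delta * (n_u + n_f) - DEBRIS_DECAY_RATE * debris
    return np.array([d_nu, d_nf, d_r, d_e, d_debris])


def derivatives(state: CircuitState, time: float, strain: StrainSpec,
                env: EnvironmentSignal) -> CircuitState:
    """Rate of change of a :class:`CircuitState` (typed wrapper over rhs)."""
    dy = rhs(time, state.to_array(), strain, env)
    # rates may legitimately be negative; bypass CircuitState validation
    out = CircuitState.__new__(CircuitState)
    for name, val in zip(("n_unflipped", "n_flipped", "reporter_per_cell",
                          "lysis_protein_per_cell", "debris"), dy):
        object.__setattr__(out, name, float(val))
    return out


def observed_outputs(state: CircuitState, strain: StrainSpec) -> dict:
    """Plate-reader observables for one state.

    Returns ``od600``, ``total_fluor`` (A.U., includes the flat instrument
    background) and ``normalized_fluor`` = (total - background) / od600 —
    the background-subtracted, OD-normalized readout. Only live cells carry
    measurable reporter; in SWITCH topologies only flipped cells express it.
    """
    m = strain.measurement
    od600 = m.od_scale_cells * state.n_live + m.od_scale_debris * state.debris
    reporting = state.n_flipped if strain.has_switch else state.n_unflipped
    total_fluor = m.background_fluor + m.fluor_scale * state.reporter_per_cell * reporting
    if od600 <= 0.0:
        raise ParameterError("normalization undefined: OD600 is zero")
    normalized = (total_fluor - m.background_fluor) / od600
    return {"od600": od600, "total_fluor": total_fluor, "normalized_fluor": normalized}
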