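"""Perpetrator pharmacokinetics and CYP activity dynamics for drug-drug
interaction scenarios.

Each perpetrator is described by a one-compartment oral PK model (closed-form
superposition over its regimen) and per-enzyme inhibition constants:
competitive inhibition acts instantaneously on enzyme activity through
1/(1 + Iu/Ki_u); mechanism-based inactivation (MBI) drives an enzyme-turnover
ODE dE/dt = kdeg*(1 - E) - kinact*Iu/(KI_u + Iu)*E.  The victim PBPK system
consumes the product of the two as a time-varying activity multiplier.

The three shipped scenarios follow the interaction simulation matrix:
gemfibrozil 600 mg BID (CYP2C8), quinidine 200 mg QD (CYP2D6), ritonavir
100 mg QD (CYP3A4 strong + CYP2D6 weak), each dosed for 12 days with the
victim course starting on day 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field
from scipy.integrate import solve_ivp

from .drug import ConfigurationError


class InhibitionTerms(BaseModel):
    """Competitive and/or mechanism-based constants for one enzyme."""

    ki_u: Optional[float] = Field(default=None, gt=0.0)  # uM, competitive
    ki_mbi_u: Optional[float] = Field(default=None, gt=0.0)  # KI_u, uM
    kinact: Optional[float] = Field(default=None, gt=0.0)  # 1/h

    def model_post_init(self, _ctx) -> None:
        if self.ki_u is None and (self.ki_mbi_u is None or self.kinact is None):
            raise ConfigurationError(
                "an inhibited enzyme needs competitive and/or complete MBI terms"
            )


class PerpetratorParameters(BaseModel):
    name: str
    molecular_weight: float = Field(gt=0.0)  # g/mol
    dose_mg: float = Field(gt=0.0)
    interval_h: float = Field(gt=0.0)
    duration_days: float = Field(default=12.0, gt=0.0)
    ka: float = Field(gt=0.0)  # 1/h
    v_over_f: float = Field(gt=0.0)  # L
    cl_over_f: float = Field(gt=0.0)  # L/h
    fu_plasma: float = Field(gt=0.0, le=1.0)
    inhibition: dict[str, InhibitionTerms]
    kdeg: float = Field(default=math.log(2.0) / 36.0, gt=0.0)  # 1/h CYP turnover

    def dose_times(self) -> np.ndarray:
        n = int(math.floor(self.duration_days * 24.0 / self.interval_h + 1e-9))
        return np.arange(n) * self.interval_h


def perpetrator_concentration(params: PerpetratorParameters, t) -> np.ndarray:
    """Unbound perpetrator concentration (uM) at time(s) ``t`` (h from the
    first perpetrator dose): one-compartment first-order absorption,
    superposed over all administered doses."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ke = params.cl_over_f / params.v_over_f
    ka = params.ka
    if abs(ka - ke) < 1e-12:
        ka *= 1.0 + 1e-9
    c = np.zeros_like(t)
    coeff = params.dose_mg / params.v_over_f * ka / (ka - ke)
    for td in params.dose_times():
        dt = t - td
        m = dt >= 0
        c[m] += coeff * (np.exp(-ke * dt[m]) - np.exp(-ka * dt[m]))
    c_unbound_mg_l = params.fu_plasma * c
    return c_unbound_mg_l / params.molecular_weight * 1000.0  # uM


def competitive_multiplier(iu: float, ki_u: float) -> float:
    """Instantaneous activity multiplier under competitive inhibition."""
    if iu < 0 or ki_u <= 0:
        raise ValueError("require Iu >= 0 and Ki_u > 0")
    return 1.0 / (1.0 + iu / ki_u)


def mbi_turnover(e: float, iu: float, ki_mbi_u: float, kinact: float,
                 kdeg: float) -> float:
    """dE/dt for the active-enzyme fraction under mechanism-based
    inactivation with first-order turnover."""
    if e < 0:
        raise ValueError("active fraction must be non-negative")
    return kdeg * (1.0 - e) - kinact * iu / (ki_mbi_u + iu) * e


def mbi_steady_state(iu: float, ki_mbi_u: float, kinact: float,
                     kdeg: float) -> float:
    lam = kinact * iu / (ki_mbi_u + iu)
    return kdeg / (kdeg + lam)


def static_aucr_bound(fm: float) -> float:
    """Complete-inhibition ceiling on the victim AUC ratio: 1/(1 - fm)."""
    if not 0.0 <= fm < 1.0:
        raise ValueError("fm must lie in [0, 1)")
    return 1.0 / (1.0 - fm)


@dataclass
class DDIScenario:
    """Perpetrator + timing relative to the victim course."""

    perpetrator: PerpetratorParameters
    victim_offset_h: float = 48.0  # victim first dose, h after perpetrator start

    def label(self) -> str:
        return self.perpetrator.name


def enzyme_activity_profile(scenario: DDIScenario, t_end: float,
                            dt: float = 0.25):
    """Precompute per-enzyme activity multipliers on a dense grid.

    Solves the MBI turnover ODE for each affected enzyme against the
    closed-form unbound perpetrator concentration, multiplies in the
    competitive term, and returns ``activity(t) -> {enzyme: multiplier}``
    suitable for the PBPK integrator.  Times are hours from the perpetrator's
    first dose.
    """
    perp = scenario.perpetrator
    grid = np.arange(0.0, t_end + dt, dt / 2.0)
    iu_grid = perpetrator_concentration(perp, grid)
    profiles: dict[str, np.ndarray] = {}
    for enzyme, terms in perp.inhibition.items():
        e_grid = np.ones_like(grid)
        if terms.ki_mbi_u is not None and terms.kinact is not None:
            iu_of = lambda t: float(np.interp(t, grid, iu_grid))  # noqa: E731

            def rhs(t, y, _terms=terms):
                return [mbi_turnover(y[0], iu_of(t), _terms.ki_mbi_u,
                                     _terms.kinact, perp.kdeg)]

            sol = solve_ivp(rhs, (0.0, grid[-1]), [1.0], t_eval=grid,
                            method="LSODA", rtol=1e-8, atol=1e-10)
            e_grid = sol.y[0]
        if terms.ki_u is not None:
            e_grid = e_grid / (1.0 + iu_grid / terms.ki_u)
        profiles[enzyme] = e_grid

    def activity(t: float) -> dict[str, float]:
        return {enz: float(np.interp(t, grid, prof))
                for enz, prof in profiles.items()}

    return activity
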