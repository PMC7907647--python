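"""Virtual clinical trials: PK metrics, 10x10 trial designs, baseline-relative
exposure ratios, lung-uptake calibration and pediatric dose matching.

The trial design mirrors the validation/simulation convention of 10 trials of
10 subjects (n = 100) per scenario; exposure ratios are ratios of arithmetic
means of individual PK parameters (geometric-mean ratios are also reported),
with AUC taken over 10 days (240 h) from the first victim dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import brentq

from .ddi import DDIScenario, enzyme_activity_profile
from .drug import DrugParameters, Regimen, regimen_a, weight_based_regimen
from .engine import ModelStructure, SimulationResult, build_model, simulate
from .population import (
    PopulationSpec,
    healthy_adult,
    sample_individual,
    typical_individual,
)

DEFAULT_OBSERVABLES = (("HCQ", "plasma"), ("HCQ", "lung_tissue"))


@dataclass
class PKMetrics:
    cmax: float
    tmax: float
    auc: float
    troughs: dict[float, float]


def pk_metrics(times_h: np.ndarray, concentrations: np.ndarray,
               auc_window_h: float, start_h: float = 0.0,
               predose_times: Sequence[float] = ()) -> PKMetrics:
    """Cmax/Tmax over the window, linear-trapezoid AUC on [start, start+window],
    troughs at the stated pre-dose times."""
    times = np.asarray(times_h, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    end = start_h + auc_window_h
    if end > times[-1] + 1e-9:
        raise ValueError("AUC window extends beyond the simulated span")
    mask = (times >= start_h - 1e-9) & (times <= end + 1e-9)
    t_w, c_w = times[mask], conc[mask]
    i_max = int(np.argmax(c_w))
    auc = float(np.trapezoid(c_w, t_w))
    troughs = {float(tp): float(np.interp(tp, times, conc)) for tp in predose_times}
    return PKMetrics(cmax=float(c_w[i_max]), tmax=float(t_w[i_max]),
                     auc=auc, troughs=troughs)


class TrialDesign(BaseModel):
    population: PopulationSpec
    regimen: Regimen = Field(default_factory=regimen_a)
    ddi: Optional[object] = None  # DDIScenario
    n_trials: int = Field(default=10, gt=0)
    n_subjects_per_trial: int = Field(default=10, gt=0)
    seed: int = 0
    auc_window_h: float = Field(default=240.0, gt=0.0)
    observables: tuple = DEFAULT_OBSERVABLES

    model_config = {"arbitrary_types_allowed": True}


@dataclass
class ExposureSummary:
    """Per-subject PK parameters for one scenario plus summary accessors."""

    design: TrialDesign
    table: pd.DataFrame  # trial, subject, analyte, matrix, cmax, auc
    incomplete_trials: list[int] = field(default_factory=list)

    def _sel(self, analyte: str, matrix: str) -> pd.DataFrame:
        return self.table[(self.table.analyte == analyte)
                          & (self.table.matrix == matrix)]

    def mean(self, metric: str, analyte: str, matrix: str) -> float:
        return float(self._sel(analyte, matrix)[metric].mean())

    def sd(self, metric: str, analyte: str, matrix: str) -> float:
        return float(self._sel(analyte, matrix)[metric].std(ddof=1))

    def geomean(self, metric: str, analyte: str, matrix: str) -> float:
        vals = self._sel(analyte, matrix)[metric]
        return float(np.exp(np.log(vals[vals > 0]).mean()))

    def per_trial_means(self, metric: str, analyte: str, matrix: str) -> pd.Series:
        return self._sel(analyte, matrix).groupby("trial")[metric].mean()

    @property
    def n_subjects(self) -> int:
        return self.table.groupby(["trial", "subject"]).ngroups


class RatioResult(BaseModel):
    r_cmax_plasma: float = Field(gt=0.0)
    r_auc_plasma: float = Field(gt=0.0)
    r_cmax_lung: float = Field(gt=0.0)
    r_auc_lung: float = Field(gt=0.0)
    geometric: dict[str, float] = Field(default_factory=dict)


def simulate_subject(drugs: Sequence[DrugParameters], individual, design: TrialDesign
                     ) -> tuple[SimulationResult, float]:
    """One subject's simulation under the design; returns the result and the
    time of the first victim dose (AUC window origin)."""
    regimen = design.regimen
    scenario: Optional[DDIScenario] = design.ddi
    if scenario is not None:
        regimen = regimen.shifted(scenario.victim_offset_h)
        start = scenario.victim_offset_h
        t_end = start + design.auc_window_h
        activity = enzyme_activity_profile(scenario, t_end)
        model = build_model(drugs, individual, regimen, interactions=scenario)
        res = simulate(model, t_end, activity=activity)
    else:
        start = regimen.events[0].time_h
        t_end = start + design.auc_window_h
        model = build_model(drugs, individual, regimen)
        res = simulate(model, t_end)
    return res, start


def run_trials(design: TrialDesign, drugs: Sequence[DrugParameters]
               ) -> ExposureSummary:
    """Run the full virtual-trial grid with per-trial seed substreams."""
    rows = []
    incomplete = []
    root = np.random.SeedSequence(design.seed)
    trial_seeds = root.spawn(design.n_trials)
    for trial, tseed in enumerate(trial_seeds):
        subject_seeds = tseed.spawn(design.n_subjects_per_trial)
        for subject, sseed in enumerate(subject_seeds):
            individual = sample_individual(design.population, sseed)
            try:
                res, start = simulate_subject(drugs, individual, design)
            except Exception:
                incomplete.append(trial)
                continue
            predose = [e.time_h for e in res.model.regimen.events]
            for analyte, matrix in design.observables:
                conc = res.concentration(analyte, matrix)
                m = pk_metrics(res.times, conc, design.auc_window_h,
                               start_h=start, predose_times=predose)
                rows.append(dict(trial=trial, subject=subject, analyte=analyte,
                                 matrix=matrix, cmax=m.cmax, auc=m.auc,
                                 tmax=m.tmax))
    table = pd.DataFrame(rows)
    return ExposureSummary(design=design, table=table,
                           incomplete_trials=sorted(set(incomplete)))


def exposure_ratio(test: ExposureSummary, baseline: ExposureSummary) -> RatioResult:
    """Baseline-relative exposure ratios (arithmetic-mean ratios per metric
    and matrix; geometric-mean ratios reported alongside)."""
    if abs(test.design.auc_window_h - baseline.design.auc_window_h) > 1e-9:
        raise ValueError("AUC windows differ between test and baseline")
    if set(map(tuple, test.design.observables)) != set(map(tuple, baseline.design.observables)):
        raise ValueError("observables differ between test and baseline")

    def r(metric, matrix):
        return (test.mean(metric, "HCQ", matrix)
                / baseline.mean(metric, "HCQ", matrix))

    def rg(metric, matrix):
        return (test.geomean(metric, "HCQ", matrix)
                / baseline.geomean(metric, "HCQ", matrix))

    return RatioResult(
        r_cmax_plasma=r("cmax", "plasma"), r_auc_plasma=r("auc", "plasma"),
        r_cmax_lung=r("cmax", "lung_tissue"), r_auc_lung=r("auc", "lung_tissue"),
        geometric={"r_cmax_plasma": rg("cmax", "plasma"),
                   "r_auc_plasma": rg("auc", "plasma"),
                   "r_cmax_lung": rg("cmax", "lung_tissue"),
                   "r_auc_lung": rg("auc", "lung_tissue")},
    )


def lung_kp(result: SimulationResult, t_h: float, analyte: str = "HCQ") -> float:
    """Lung-tissue to plasma concentration ratio at time ``t_h``."""
    c_lung = float(np.interp(t_h, result.times, result.concentration(analyte,
                                                                     "lung_tissue")))
    c_plasma = float(np.interp(t_h, result.times, result.concentration(analyte,
                                                                       "plasma")))
    if c_plasma <= 0:
        raise ValueError("plasma concentration is zero; Kp undefined")
    return c_lung / c_plasma


DAY6_TROUGH_H = 120.0  # pre-dose position on day 6 of the standard course


def _kp_at_trough(drugs: Sequence[DrugParameters], clint_t: float,
                  regimen: Regimen, trough_h: float) -> float:
    parent = drugs[0].model_copy(deep=True)
    parent.lung.clint_t = clint_t
    adult = healthy_adult()
    model = build_model([parent, *drugs[1:]], adult, regimen)
    res = simulate(model, max(trough_h, regimen.events[-1].time_h + 0.25))
    return lung_kp(res, trough_h, parent.name)


def calibrate_lung_uptake(
    drugs: Sequence[DrugParameters],
    target_kp: float = 200.0,
    regimen: Optional[Regimen] = None,
    trough_h: float = DAY6_TROUGH_H,
    tol: float = 0.005,
) -> float:
    """Solve for the lung active-uptake intrinsic clearance CLint_T (L/h) that
    reproduces ``target_kp`` at the day-6 pre-dose trough in the baseline
    typical adult; monotonicity of Kp in CLint_T is verified while bracketing."""
    regimen = regimen or regimen_a()
    passive = _kp_at_trough(drugs, 0.0, regimen, trough_h)
    if target_kp <= passive:
        raise ValueError(
            f"target Kp {target_kp:g} is not above the passive-only Kp {passive:.3g}"
        )
    lo, f_lo = 0.0, passive - target_kp
    hi, f_hi = 10.0, None
    prev = passive
    while hi < 1e7:
        kp_hi = _kp_at_trough(drugs, hi, regimen, trough_h)
        if kp_hi < prev - 1e-9:
            raise RuntimeError("lung Kp not monotone in CLint_T during bracketing")
        prev = kp_hi
        f_hi = kp_hi - target_kp
        if f_hi > 0:
            break
        lo, f_lo = hi, f_hi
        hi *= 4.0
    if f_hi is None or f_hi <= 0:
        raise ValueError("could not bracket the lung uptake calibration target")
    clint = brentq(lambda c: _kp_at_trough(drugs, c, regimen, trough_h) - target_kp,
                   lo, hi, rtol=tol * 0.2)
    achieved = _kp_at_trough(drugs, clint, regimen, trough_h)
    if abs(achieved - target_kp) > tol * 2 * target_kp:
        raise RuntimeError(f"calibration landed at Kp {achieved:.4g}, "
                           f"outside tolerance of {target_kp:g}")
    return float(clint)


def first_dose_cmax(drugs: Sequence[DrugParameters], individual,
                    dose_mg_salt: float, t_end: float = 12.0) -> float:
    """Plasma Cmax of the parent after a single oral dose."""
    reg = Regimen(label="single", events=[dict(time_h=0.0,
                                               amount_mg_salt=dose_mg_salt)])
    model = build_model(drugs, individual, reg)
    res = simulate(model, t_end)
    return float(res.concentration(drugs[0].name, "plasma").max())


def optimize_pediatric_dose(
    band: PopulationSpec,
    drugs: Sequence[DrugParameters],
    adult_reference_cmax: Optional[float] = None,
    tol: float = 0.01,
) -> float:
    """Weight-based loading dose (mg/kg of salt) whose first-dose plasma Cmax
    in the band-typical child matches the 600 mg / 70 kg adult reference;
    the maintenance dose is one third of the loading dose by construction."""
    if band.category != "pediatric":
        raise ValueError("dose optimization expects a pediatric population spec")
    if adult_reference_cmax is None:
        adult_reference_cmax = first_dose_cmax(drugs, healthy_adult(), 600.0)
    child = typical_individual(band)

    def f(mg_per_kg: float) -> float:
        cmax = first_dose_cmax(drugs, child, mg_per_kg * child.body_weight)
        return cmax - adult_reference_cmax

    lo, hi = 0.5, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("dose search bracket does not contain the target")
    dose = brentq(f, lo, hi, rtol=tol * 0.2)
    return float(dose)


def pediatric_regimen(loading_mg_per_kg: float, band: PopulationSpec) -> Regimen:
    child = typical_individual(band)
    return weight_based_regimen(loading_mg_per_kg, child.body_weight)
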