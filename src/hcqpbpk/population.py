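"""Virtual individuals: reference physiology, special-population scalings and
noisy synthetic observations.

The generator emulates the physiological structure a whole-body PBPK analysis
assumes — organ volumes and blood flows, hepatic enzyme abundances, GFR,
demographic covariates — with log-normal inter-individual variability, and
transparent scaling transforms for geriatric age, Child-Pugh cirrhosis grades,
renal-impairment GFR bands, pregnancy and pediatric growth/ontogeny.  The
scaling factor tables are explicit, literature-informed stand-ins (reported in
output metadata) rather than a proprietary population database.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .drug import ConfigurationError

Category = Literal[
    "healthy", "geriatric", "cirrhosis_CP_A", "cirrhosis_CP_B", "cirrhosis_CP_C",
    "renal_GFR_30_60", "renal_GFR_lt_30", "pregnant", "pediatric",
]

PERFUSED_ORGANS = (
    "adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
    "muscle", "skin", "spleen", "rest",
)

# Reference healthy adult (20-50 y): organ volumes (L) at 70 kg.
ADULT_ORGAN_VOLUMES = {
    "adipose": 13.5, "bone": 10.0, "brain": 1.45, "gut": 1.20, "heart": 0.33,
    "kidney": 0.31, "liver": 1.80, "muscle": 28.0, "skin": 2.60, "spleen": 0.18,
    "rest": 4.58, "venous_blood": 3.70, "arterial_blood": 1.85,
    "lung_EC": 0.15, "lung_IC": 0.35,
}
ADULT_WEIGHT = 70.0
ADULT_CARDIAC_OUTPUT = 336.0  # L/h (5.6 L/min)
# Fraction of cardiac output; liver entry is the hepatic artery only (the gut
# and spleen drain into the liver, so total liver flow is artery+portal).
ADULT_FLOW_FRACTIONS = {
    "adipose": 0.05, "bone": 0.05, "brain": 0.12, "gut": 0.16, "heart": 0.04,
    "kidney": 0.19, "liver": 0.065, "muscle": 0.17, "skin": 0.05,
    "spleen": 0.02, "rest": 0.085,
}
ADULT_GFR = 120.0  # mL/min
ADULT_MPPGL = 40.0  # mg microsomal protein / g liver
ETHNICITY_WEIGHT = {"caucasian": 70.0, "chinese": 62.0}

# Pediatric growth reference (age y -> total body weight kg), linear interp.
GROWTH_REFERENCE = {
    0.0: 3.5, 0.083: 4.4, 0.29: 6.0, 0.5: 7.6, 1.0: 9.5, 2.0: 12.2,
    4.0: 16.5, 6.0: 20.5, 9.0: 29.0, 12.0: 40.0, 14.5: 52.0, 17.0: 62.0,
    18.0: 70.0,
}

# Age-dependent organ weight fractions (of body weight); organs not listed
# keep the adult fraction and "rest" absorbs the residual.
PEDIATRIC_FRACTIONS = {
    "brain":   {0.0: 0.100, 0.5: 0.085, 1.0: 0.080, 2.0: 0.070, 5.0: 0.055,
                10.0: 0.040, 15.0: 0.025, 18.0: 0.0207},
    "muscle":  {0.0: 0.20, 0.5: 0.22, 1.0: 0.23, 2.0: 0.26, 5.0: 0.30,
                10.0: 0.34, 15.0: 0.38, 18.0: 0.40},
    "adipose": {0.0: 0.14, 0.5: 0.25, 1.0: 0.24, 2.0: 0.21, 5.0: 0.17,
                10.0: 0.16, 15.0: 0.17, 18.0: 0.193},
    "liver":   {0.0: 0.038, 0.5: 0.035, 1.0: 0.033, 2.0: 0.031, 5.0: 0.028,
                10.0: 0.027, 15.0: 0.026, 18.0: 0.0257},
    "kidney":  {0.0: 0.0075, 0.5: 0.0065, 1.0: 0.0060, 2.0: 0.0055, 5.0: 0.0050,
                10.0: 0.0046, 15.0: 0.0045, 18.0: 0.00443},
}

# CYP ontogeny: sigmoid in age, normalized to 1 at 18 y.
ONTOGENY = {"CYP3A4": (0.30, 1.0), "CYP2D6": (0.10, 1.0), "CYP2C8": (0.05, 1.0)}

# Effective distributional-flow maturation: fraction of allometric cardiac
# output engaged in early drug distribution.  An effective parameter lumping
# early-distribution kinetics not resolved by purely flow-limited tissues in
# children (tissue/red-cell uptake equilibration relative to their high
# specific perfusion); calibrated against weight-based first-dose exposure
# matching.  1.0 from 18 y on.
PEDIATRIC_FLOW_MATURATION = {
    0.04: 0.10, 0.29: 0.12, 1.25: 0.30, 4.0: 0.44, 9.0: 0.50, 14.5: 0.52,
    18.0: 1.0,
}

# Age-dependent hematocrit: high at birth, nadir in infancy, adult by 18 y.
# Lowers the effective blood:plasma ratio of red-cell-sequestered drugs in
# children, raising plasma concentrations per unit dose.
PEDIATRIC_HEMATOCRIT = {
    0.04: 0.45, 0.29: 0.33, 1.0: 0.35, 5.0: 0.37, 10.0: 0.40, 15.0: 0.42,
    18.0: 0.45,
}

# Geriatric decline rates (per year past the age-40 anchor, fraction of the
# age-40 value): GFR, hepatic abundance (mass x activity), cardiac output.
GERIATRIC_GFR_SLOPE = 0.0075
GERIATRIC_HEPATIC_SLOPE = 0.005
GERIATRIC_CO_SLOPE = 0.003

# Child-Pugh grade factors: functional hepatic abundance, hepatic arterial
# flow, albumin. Severity ordering A >= B >= C elementwise.
CHILD_PUGH_FACTORS = {
    "CP-A": {"abundance": 0.78, "hepatic_flow": 0.90, "albumin": 0.95},
    "CP-B": {"abundance": 0.60, "hepatic_flow": 0.75, "albumin": 0.90},
    "CP-C": {"abundance": 0.46, "hepatic_flow": 0.60, "albumin": 0.85},
}

RENAL_BAND_GFR = {"GFR_30_60": 45.0, "GFR_lt_30": 20.0}

# Pregnancy: single gestational shape p(w) applied to every altered scalar.
PREGNANCY_W50, PREGNANCY_HILL = 15.0, 4.0
PREGNANCY_MAX = {
    "CYP2C8": 1.9, "CYP2D6": 2.6, "CYP3A4": 2.2,
    "gfr": 1.45, "albumin_drop": 0.30, "weight_gain_kg": 12.5,
    "blood_expansion": 0.40, "co_increase": 0.30,
}

DEFAULT_CV = {"size": 0.20, "abundance": 0.30, "gfr": 0.30}


def _interp(table: dict[float, float], x: float) -> float:
    xs = sorted(table)
    return float(np.interp(x, xs, [table[k] for k in xs]))


class PopulationSpec(BaseModel):
    category: Category = "healthy"
    age_range: tuple[float, float] = (20.0, 50.0)
    sex_ratio: float = Field(default=0.5, ge=0.0, le=1.0)  # fraction male
    gestational_week: Optional[float] = None
    ethnicity: str = "caucasian"
    variability: bool = True
    cv_map: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_CV))

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range low must be < high")
        if self.category == "pregnant":
            if self.sex_ratio != 0.0:
                raise ConfigurationError("pregnant spec requires sex_ratio = 0")
            if self.gestational_week is None:
                raise ConfigurationError("pregnant spec requires gestational_week")
        return self


class IndividualPhysiology(BaseModel):
    age: float
    sex: Literal["male", "female"]
    body_weight: float = Field(gt=0.0)  # kg
    organ_volumes: dict[str, float]  # L
    organ_blood_flows: dict[str, float]  # L/h, perfused organs only
    cardiac_output: float = Field(gt=0.0)  # L/h
    liver_weight: float = Field(gt=0.0)  # g
    microsomal_protein_per_g_liver: float = ADULT_MPPGL
    enzyme_abundance_scalars: dict[str, float]
    gfr: float = Field(ge=0.0)  # mL/min
    albumin_scalar: float = 1.0
    hematocrit: float = 0.45
    gestational_week: Optional[float] = None
    condition: Optional[str] = None  # tag set by impairment transforms

    def assert_valid(self) -> None:
        """Structural invariants every generated individual must satisfy."""
        for name, v in self.organ_volumes.items():
            if v <= 0:
                raise ConfigurationError(f"non-positive volume for {name}")
        for name, q in self.organ_blood_flows.items():
            if q <= 0:
                raise ConfigurationError(f"non-positive flow for {name}")
        total = sum(self.organ_blood_flows.values())
        if abs(total - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ConfigurationError(
                f"organ flows sum {total:.6f} != cardiac output {self.cardiac_output:.6f}"
            )
        if any(s < 0 for s in self.enzyme_abundance_scalars.values()):
            raise ConfigurationError("enzyme scalars must be >= 0")
        if self.gfr < 0:
            raise ConfigurationError("gfr must be >= 0")

    @property
    def liver_blood_flow(self) -> float:
        """Total liver inflow: hepatic artery + portal (gut + spleen)."""
        f = self.organ_blood_flows
        return f["liver"] + f["gut"] + f["spleen"]


def healthy_adult(body_weight: float = ADULT_WEIGHT, age: float = 35.0,
                  sex: Literal["male", "female"] = "male") -> IndividualPhysiology:
    """Category-typical healthy 20-50 y adult, scaled linearly in volume and
    allometrically (exponent 0.75) in flows/GFR from the 70 kg reference."""
    w = body_weight / ADULT_WEIGHT
    co = ADULT_CARDIAC_OUTPUT * w ** 0.75
    volumes = {k: v * w for k, v in ADULT_ORGAN_VOLUMES.items()}
    flows = {k: f * co for k, f in ADULT_FLOW_FRACTIONS.items()}
    return IndividualPhysiology(
        age=age, sex=sex, body_weight=body_weight,
        organ_volumes=volumes, organ_blood_flows=flows, cardiac_output=co,
        liver_weight=volumes["liver"] * 1000.0,
        enzyme_abundance_scalars={e: 1.0 for e in ONTOGENY},
        gfr=ADULT_GFR * w ** 0.75,
    )


# ---------------------------------------------------------------------------
# Special-population transforms (pure, deterministic)
# ---------------------------------------------------------------------------

def ontogeny_scalar(enzyme: str, age: float) -> float:
    """Sigmoidal CYP maturation, 0 at birth -> 1 at 18 y (normalized)."""
    a50, hill = ONTOGENY[enzyme]
    f = lambda a: a ** hill / (a ** hill + a50 ** hill)  # noqa: E731
    return f(age) / f(18.0) if age < 18.0 else 1.0


def gfr_maturation(age: float) -> float:
    """Postmenstrual-age GFR maturation (Hill in PMA weeks), normalized at 18 y."""
    pma = age * 52.18 + 40.0
    f = lambda p: p ** 3.4 / (p ** 3.4 + 47.7 ** 3.4)  # noqa: E731
    return f(pma) / f(18.0 * 52.18 + 40.0)


def apply_pediatric_scaling(individual: IndividualPhysiology,
                            age: float) -> IndividualPhysiology:
    """Rebuild body size, composition, ontogeny and GFR for a child of ``age``."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if age >= 18:
        return individual
    weight = _interp(GROWTH_REFERENCE, age)
    fractions = {k: v / ADULT_WEIGHT for k, v in ADULT_ORGAN_VOLUMES.items()}
    for organ, table in PEDIATRIC_FRACTIONS.items():
        fractions[organ] = _interp(table, age)
    # rest absorbs the composition residual so fractions stay mass-consistent
    other = sum(v for k, v in fractions.items() if k != "rest")
    fractions["rest"] = max(1.0 - other - 0.04, 0.01)  # ~4% non-modeled mass
    volumes = {k: f * weight for k, f in fractions.items()}
    co = (ADULT_CARDIAC_OUTPUT * (weight / ADULT_WEIGHT) ** 0.75
          * _interp(PEDIATRIC_FLOW_MATURATION, age))
    flows = {k: f * co for k, f in ADULT_FLOW_FRACTIONS.items()}
    scalars = {e: individual.enzyme_abundance_scalars.get(e, 1.0) * ontogeny_scalar(e, age)
               for e in ONTOGENY}
    return individual.model_copy(update=dict(
        age=age, body_weight=weight, organ_volumes=volumes,
        organ_blood_flows=flows, cardiac_output=co,
        liver_weight=volumes["liver"] * 1000.0,
        enzyme_abundance_scalars=scalars,
        gfr=ADULT_GFR * gfr_maturation(age) * (weight / ADULT_WEIGHT) ** 0.75,
        hematocrit=_interp(PEDIATRIC_HEMATOCRIT, age),
    ))


def apply_geriatric_scaling(individual: IndividualPhysiology,
                            age: float) -> IndividualPhysiology:
    """Linear declines past the age-40 anchor: GFR, hepatic abundance, cardiac
    output (flows renormalized).  Age 40 is the identity."""
    if age < 40:
        raise ValueError("geriatric scaling applies from the age-40 anchor upward")
    years = age - 40.0
    gfr_f = max(1.0 - GERIATRIC_GFR_SLOPE * years, 0.05)
    hep_f = max(1.0 - GERIATRIC_HEPATIC_SLOPE * years, 0.05)
    co_f = max(1.0 - GERIATRIC_CO_SLOPE * years, 0.05)
    return individual.model_copy(update=dict(
        age=age,
        gfr=individual.gfr * gfr_f,
        enzyme_abundance_scalars={k: v * hep_f
                                  for k, v in individual.enzyme_abundance_scalars.items()},
        cardiac_output=individual.cardiac_output * co_f,
        organ_blood_flows={k: q * co_f
                           for k, q in individual.organ_blood_flows.items()},
    ))


def apply_hepatic_impairment(individual: IndividualPhysiology,
                             grade: str) -> IndividualPhysiology:
    """Child-Pugh grade factors on functional liver, hepatic arterial flow and
    albumin.  Idempotent: re-applying the same grade is a no-op."""
    if grade not in CHILD_PUGH_FACTORS:
        raise ConfigurationError(f"unknown Child-Pugh grade {grade!r}")
    if individual.condition == grade:
        return individual
    f = CHILD_PUGH_FACTORS[grade]
    flows = dict(individual.organ_blood_flows)
    delta = flows["liver"] * (1.0 - f["hepatic_flow"])
    flows["liver"] -= delta
    flows["rest"] += delta  # keep the flow-sum invariant
    return individual.model_copy(update=dict(
        enzyme_abundance_scalars={k: v * f["abundance"]
                                  for k, v in individual.enzyme_abundance_scalars.items()},
        organ_blood_flows=flows,
        albumin_scalar=individual.albumin_scalar * f["albumin"],
        condition=grade,
    ))


def apply_renal_impairment(individual: IndividualPhysiology,
                           band: str) -> IndividualPhysiology:
    """Set GFR to the band-typical value; renal drug clearance downstream
    scales as GFR / healthy GFR."""
    if band not in RENAL_BAND_GFR:
        raise ConfigurationError(f"unknown renal band {band!r}")
    if individual.condition == band:
        return individual
    return individual.model_copy(update=dict(
        gfr=RENAL_BAND_GFR[band] * (individual.body_weight / ADULT_WEIGHT) ** 0.75,
        condition=band,
    ))


def pregnancy_shape(week: float) -> float:
    """Fraction of the full-term physiological change at gestational ``week``;
    0 at week 0, 1 at week 37."""
    h = lambda w: w ** PREGNANCY_HILL / (w ** PREGNANCY_HILL + PREGNANCY_W50 ** PREGNANCY_HILL)  # noqa: E731
    return h(week) / h(37.0)


def apply_pregnancy(individual: IndividualPhysiology,
                    gestational_week: float) -> IndividualPhysiology:
    """Smooth gestation-dependent changes: plasma volume expansion, weight
    gain, GFR rise, CYP3A4/2D6 (and 2C8) activity increase, albumin fall."""
    if individual.sex != "female":
        raise ConfigurationError("pregnancy transform requires a female individual")
    if not (0.0 <= gestational_week <= 42.0):
        raise ValueError("gestational week must lie in [0, 42]")
    p = pregnancy_shape(gestational_week)
    if p == 0.0:
        return individual.model_copy(update=dict(gestational_week=gestational_week))
    m = PREGNANCY_MAX
    scalars = dict(individual.enzyme_abundance_scalars)
    for enz in ("CYP2C8", "CYP2D6", "CYP3A4"):
        scalars[enz] = scalars.get(enz, 1.0) * (1.0 + p * (m[enz] - 1.0))
    volumes = dict(individual.organ_volumes)
    expand = 1.0 + p * m["blood_expansion"]
    volumes["venous_blood"] *= expand
    volumes["arterial_blood"] *= expand
    co_f = 1.0 + p * m["co_increase"]
    return individual.model_copy(update=dict(
        gestational_week=gestational_week,
        body_weight=individual.body_weight + p * m["weight_gain_kg"],
        organ_volumes=volumes,
        enzyme_abundance_scalars=scalars,
        gfr=individual.gfr * (1.0 + p * (m["gfr"] - 1.0)),
        albumin_scalar=individual.albumin_scalar * (1.0 - p * m["albumin_drop"]),
        cardiac_output=individual.cardiac_output * co_f,
        organ_blood_flows={k: q * co_f
                           for k, q in individual.organ_blood_flows.items()},
    ))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _lognormal_deviate(rng: np.random.Generator, cv: float) -> float:
    """Mean-one log-normal deviate with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def typical_individual(spec: PopulationSpec,
                       age: Optional[float] = None) -> IndividualPhysiology:
    """Deterministic category-typical individual (variability off)."""
    lo, hi = spec.age_range
    if age is None:
        age = 0.5 * (lo + hi)
    sex = "male" if spec.sex_ratio >= 0.5 else "female"
    weight = ETHNICITY_WEIGHT.get(spec.ethnicity.lower(), ADULT_WEIGHT)
    base = healthy_adult(body_weight=weight, age=age, sex=sex)
    cat = spec.category
    if cat == "healthy":
        return base
    if cat == "pediatric":
        return apply_pediatric_scaling(base, age)
    if cat == "geriatric":
        return apply_geriatric_scaling(base, age)
    if cat.startswith("cirrhosis_CP_"):
        grade = "CP-" + cat[-1]
        ind = base if age < 65 else apply_geriatric_scaling(base, age)
        return apply_hepatic_impairment(ind, grade)
    if cat.startswith("renal_"):
        band = cat.removeprefix("renal_")
        ind = base if age < 65 else apply_geriatric_scaling(base, age)
        return apply_renal_impairment(ind, band)
    if cat == "pregnant":
        female = base.model_copy(update=dict(sex="female"))
        return apply_pregnancy(female, spec.gestational_week or 0.0)
    raise ConfigurationError(f"unsupported population category {cat!r}")


def sample_individual(spec: PopulationSpec, seed) -> IndividualPhysiology:
    """One seed-reproducible virtual subject.

    With variability off this is the deterministic category-typical
    individual; with variability on, a uniform age draw within the band plus
    mean-one log-normal deviates (size on volumes/flows, per-CYP abundance,
    GFR) around the typical values.
    """
    rng = np.random.default_rng(seed)
    if not spec.variability:
        return typical_individual(spec)
    lo, hi = spec.age_range
    age = float(rng.uniform(lo, hi))
    ind = typical_individual(spec, age=age)
    if spec.sex_ratio not in (0.0, 1.0):
        sex = "male" if rng.random() < spec.sex_ratio else "female"
        if spec.category != "pregnant":
            ind = ind.model_copy(update=dict(sex=sex))
    size = _lognormal_deviate(rng, spec.cv_map.get("size", 0.0))
    abund_cv = spec.cv_map.get("abundance", 0.0)
    scalars = {e: v * _lognormal_deviate(rng, abund_cv)
               for e, v in ind.enzyme_abundance_scalars.items()}
    gfr_dev = _lognormal_deviate(rng, spec.cv_map.get("gfr", 0.0))
    ind = ind.model_copy(update=dict(
        body_weight=ind.body_weight * size,
        organ_volumes={k: v * size for k, v in ind.organ_volumes.items()},
        organ_blood_flows={k: q * size for k, q in ind.organ_blood_flows.items()},
        cardiac_output=ind.cardiac_output * size,
        liver_weight=ind.liver_weight * size,
        enzyme_abundance_scalars=scalars,
        gfr=ind.gfr * gfr_dev,
    ))
    ind.assert_valid()
    return ind


class ErrorModel(BaseModel):
    proportional_cv: float = Field(default=0.1, ge=0.0)
    additive_sd: float = Field(default=0.0, ge=0.0)  # mg/L
    lloq: float = Field(default=0.0, ge=0.0)  # mg/L
    seed: int = 0


def generate_noisy_profile(times_h, concentrations, error: ErrorModel,
                           analyte: str = "HCQ", matrix: str = "plasma",
                           study: str = "synthetic"):
    """Fabricate a noisy observed profile from a simulated true profile:
    per-point mean-one log-normal proportional error plus additive Gaussian
    noise, censored (flagged, not dropped) at the LLOQ."""
    from .validation import ObservedProfile  # local import avoids a cycle

    times = np.asarray(times_h, dtype=float)
    true = np.asarray(concentrations, dtype=float)
    if np.any(true < 0):
        raise ValueError("true profile must be non-negative")
    rng = np.random.default_rng(error.seed)
    if error.proportional_cv > 0:
        sigma = math.sqrt(math.log1p(error.proportional_cv ** 2))
        mult = rng.lognormal(-0.5 * sigma * sigma, sigma, size=true.shape)
    else:
        mult = np.ones_like(true)
    add = rng.normal(0.0, error.additive_sd, size=true.shape) if error.additive_sd > 0 \
        else np.zeros_like(true)
    obs = np.clip(true * mult + add, 0.0, None)
    censored = obs < error.lloq
    return ObservedProfile(
        study=study, analyte=analyte, matrix=matrix,
        times_h=times.tolist(), concentrations_mg_l=obs.tolist(),
        lloq_flags=censored.tolist(),
        regimen_description="synthetic",
    )
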