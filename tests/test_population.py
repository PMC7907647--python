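"""Virtual-population generator: typical individuals, special-population
transforms, variability statistics and the noisy-observation fabricator."""

import numpy as np
import pytest
from pydantic import ValidationError
from hypothesis import given, settings
from hypothesis import strategies as st

from hcqpbpk.drug import ConfigurationError
from hcqpbpk.population import (
    ErrorModel,
    PopulationSpec,
    apply_geriatric_scaling,
    apply_hepatic_impairment,
    apply_pediatric_scaling,
    apply_pregnancy,
    apply_renal_impairment,
    generate_noisy_profile,
    gfr_maturation,
    healthy_adult,
    ontogeny_scalar,
    sample_individual,
    typical_individual,
)

CATEGORIES = ["healthy", "geriatric", "cirrhosis_CP_A", "cirrhosis_CP_B",
              "cirrhosis_CP_C", "renal_GFR_30_60", "renal_GFR_lt_30",
              "pregnant", "pediatric"]


def _spec(category, **kw):
    if category == "geriatric":
        kw.setdefault("age_range", (65, 75))
    elif category == "pediatric":
        kw.setdefault("age_range", (2, 6))
    elif category == "pregnant":
        kw.setdefault("sex_ratio", 0.0)
        kw.setdefault("gestational_week", 25)
    return PopulationSpec(category=category, **kw)


def test_healthy_typical_is_70_kg_adult():
    ind = typical_individual(PopulationSpec(variability=False))
    assert ind.body_weight == pytest.approx(70.0)
    ind.assert_valid()


def test_flow_sum_invariant_holds():
    adult = healthy_adult()
    assert sum(adult.organ_blood_flows.values()) == pytest.approx(
        adult.cardiac_output, rel=1e-12)


def test_seed_determinism():
    spec = PopulationSpec()
    a = sample_individual(spec, 1234)
    b = sample_individual(spec, 1234)
    assert a == b
    c = sample_individual(spec, 1235)
    assert c != a


def test_variability_off_returns_typical():
    spec = PopulationSpec(variability=False)
    assert sample_individual(spec, 7) == typical_individual(spec)


def test_law_of_large_numbers_weight_distribution():
    spec = PopulationSpec()
    weights = np.array([sample_individual(spec, s).body_weight
                        for s in np.random.SeedSequence(0).spawn(10_000)])
    assert weights.mean() == pytest.approx(70.0, rel=0.02)
    cv = weights.std() / weights.mean()
    assert cv == pytest.approx(spec.cv_map["size"], rel=0.20)


@given(st.sampled_from(CATEGORIES), st.integers(0, 2**31 - 1))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_every_sampled_individual_satisfies_invariants(category, seed):
    ind = sample_individual(_spec(category), seed)
    ind.assert_valid()
    assert ind.body_weight > 0
    if category.startswith("renal") or category.startswith("cirrhosis"):
        assert ind.condition is not None


# --- pediatric ------------------------------------------------------------

def test_ontogeny_adult_limit_and_monotonicity():
    for enz in ("CYP3A4", "CYP2D6", "CYP2C8"):
        assert ontogeny_scalar(enz, 17.99) == pytest.approx(1.0, abs=0.05)
        ages = np.linspace(0.01, 18, 50)
        vals = [ontogeny_scalar(enz, a) for a in ages]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    assert ontogeny_scalar("CYP3A4", 0.04) < 0.5  # two-week-old neonate


def test_gfr_maturation_reaches_adult():
    assert gfr_maturation(18.0) == pytest.approx(1.0, abs=1e-6)
    assert gfr_maturation(0.04) < 0.5


def test_pediatric_scaling_rebuilds_size_and_enzymes():
    adult = healthy_adult()
    child = apply_pediatric_scaling(adult, 4.0)
    child.assert_valid()
    assert child.body_weight == pytest.approx(16.5, rel=0.01)
    assert all(v < 1.01 for v in child.enzyme_abundance_scalars.values())
    assert child.gfr < adult.gfr
    with pytest.raises(ValueError):
        apply_pediatric_scaling(adult, -1.0)


# --- geriatric ------------------------------------------------------------

def test_geriatric_declines_monotone_with_age():
    adult = healthy_adult()
    g65 = apply_geriatric_scaling(adult, 65.0)
    g95 = apply_geriatric_scaling(adult, 95.0)
    assert g95.gfr < g65.gfr < adult.gfr
    assert g95.cardiac_output < g65.cardiac_output
    g65.assert_valid(), g95.assert_valid()


def test_geriatric_age_40_anchor_is_identity():
    adult = healthy_adult()
    same = apply_geriatric_scaling(adult, 40.0)
    assert same.gfr == pytest.approx(adult.gfr)
    assert same.cardiac_output == pytest.approx(adult.cardiac_output)


# --- hepatic & renal impairment ------------------------------------------

def test_child_pugh_severity_ordering_and_idempotence():
    adult = healthy_adult()
    grades = [apply_hepatic_impairment(adult, g) for g in ("CP-A", "CP-B", "CP-C")]
    scalars = [g.enzyme_abundance_scalars["CYP3A4"] for g in grades]
    assert scalars[0] >= scalars[1] >= scalars[2]
    assert scalars[2] <= 0.5  # CP-C at most half of healthy abundance
    albs = [g.albumin_scalar for g in grades]
    assert albs[0] >= albs[1] >= albs[2]
    twice = apply_hepatic_impairment(grades[2], "CP-C")
    assert twice == grades[2]
    with pytest.raises(ConfigurationError):
        apply_hepatic_impairment(adult, "CP-D")


def test_renal_bands_and_multiplier_ordering():
    adult = healthy_adult()
    moderate = apply_renal_impairment(adult, "GFR_30_60")
    severe = apply_renal_impairment(adult, "GFR_lt_30")
    assert severe.gfr / adult.gfr == pytest.approx(20.0 / 120.0, rel=1e-9)
    assert moderate.gfr > severe.gfr
    with pytest.raises(ConfigurationError):
        apply_renal_impairment(adult, "GFR_0")


# --- pregnancy ------------------------------------------------------------

def test_pregnancy_week0_identity_and_monotone_course():
    female = healthy_adult(sex="female")
    w0 = apply_pregnancy(female, 0.0)
    assert w0.gfr == female.gfr and w0.body_weight == female.body_weight
    weeks = [apply_pregnancy(female, w) for w in (13, 25, 37)]
    for attr in ("gfr", "body_weight", "cardiac_output"):
        vals = [getattr(w, attr) for w in weeks]
        assert vals[0] < vals[1] < vals[2]
    albs = [w.albumin_scalar for w in weeks]
    assert albs[0] > albs[1] > albs[2]
    cyp = [w.enzyme_abundance_scalars["CYP3A4"] for w in weeks]
    assert cyp[0] < cyp[1] < cyp[2]
    for w in weeks:
        w.assert_valid()


def test_pregnancy_rejects_male():
    with pytest.raises(ConfigurationError):
        apply_pregnancy(healthy_adult(sex="male"), 25.0)


def test_pregnant_spec_requires_female_cohort():
    with pytest.raises((ConfigurationError, ValidationError)):
        PopulationSpec(category="pregnant", sex_ratio=0.5, gestational_week=25)


# --- noisy observations ---------------------------------------------------

def test_noise_free_profile_is_identity():
    times = np.arange(0.0, 10.0)
    true = np.linspace(1.0, 0.1, 10)
    prof = generate_noisy_profile(times, true, ErrorModel(proportional_cv=0.0,
                                                          additive_sd=0.0))
    assert np.allclose(prof.concentrations_mg_l, true)
    assert not any(prof.lloq_flags)


def test_noise_seed_reproducible():
    times = np.arange(1.0, 13.0)
    true = np.full(12, 0.5)
    em = ErrorModel(proportional_cv=0.2, seed=42)
    a = generate_noisy_profile(times, true, em)
    b = generate_noisy_profile(times, true, em)
    assert a.concentrations_mg_l == b.concentrations_mg_l


def test_noise_empirical_cv_matches_configured():
    rngs = range(1000)
    true = np.full(4, 1.0)
    vals = np.concatenate([
        generate_noisy_profile(np.arange(4.0), true,
                               ErrorModel(proportional_cv=0.25, seed=s)
                               ).concentrations_mg_l
        for s in rngs])
    cv = vals.std() / vals.mean()
    assert cv == pytest.approx(0.25, rel=0.10)


def test_lloq_censoring_flags_not_drops():
    prof = generate_noisy_profile([0.0, 1.0], [1.0, 1e-6],
                                  ErrorModel(proportional_cv=0.0, lloq=0.01))
    assert len(prof.concentrations_mg_l) == 2
    assert prof.lloq_flags == [False, True]
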