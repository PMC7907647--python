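"""PBPK engine: conservation, linearity, superposition, closed-form limits
and integrator cross-checks."""

import numpy as np
import pytest

from hcqpbpk.drug import DrugParameters, Regimen, regimen_a
from hcqpbpk.engine import (
    LungSubmodel,
    absorption_rates,
    build_model,
    fraction_absorbed,
    lung_exchange,
    mass_balance,
    simulate,
)
from hcqpbpk.population import healthy_adult

SINGLE_DOSE = Regimen(label="single", events=[dict(time_h=0.0,
                                                   amount_mg_salt=600.0)])


def _renal_only(hcq, **extra):
    """HCQ variant eliminated exclusively by the kidney (no CYP pathways)."""
    return hcq.model_copy(update={
        "fm_map": {"CYP2C8": 0.0, "CYP2D6": 0.0, "CYP3A4": 0.0, "renal": 1.0},
        "metabolite_links": [], **extra})


# --- structure ------------------------------------------------------------

def test_state_counts_parent_only_vs_coupled(hcq, drugs, adult):
    solo = build_model([hcq], adult, SINGLE_DOSE)
    pair = build_model(drugs, adult, SINGLE_DOSE)
    # gut chain (9) + organs (15) + 4 accumulators
    assert solo.n_states == 28
    # metabolite adds its organ set (15) + hepatic/renal accumulators
    assert pair.n_states == 28 + 17


def test_zero_formation_fraction_keeps_metabolite_empty(hcq, dhcq, adult):
    links = [l.model_copy(update={"formation_fraction": 0.0})
             for l in hcq.metabolite_links]
    parent = hcq.model_copy(update={"metabolite_links": links})
    model = build_model([parent, dhcq], adult, SINGLE_DOSE)
    res = simulate(model, 48.0)
    lay = model.layouts["DHCQ"]
    cols = list(lay.organs.values()) + list(lay.eliminated.values())
    assert np.all(res.states[:, cols] == 0.0)


# --- conservation & balance ----------------------------------------------

def test_conservation_with_all_clearances_off(hcq, adult):
    drug = _renal_only(hcq)
    ind = adult.model_copy(update={"gfr": 0.0})
    model = build_model([drug], ind, SINGLE_DOSE)
    res = simulate(model, 96.0)
    lay = model.layouts["HCQ"]
    total = (res.states[:, lay.gut].sum(axis=1)
             + res.states[:, list(lay.organs.values())].sum(axis=1))
    dose = model.events[0][1]
    assert np.all(np.abs(total[1:] - dose) <= 1e-8 * dose)


def test_mass_balance_default_scenario(baseline_result):
    assert mass_balance(baseline_result) <= 1e-6


def test_zero_dose_simulation_is_identically_zero(drugs, adult):
    reg = Regimen(label="late", events=[dict(time_h=90.0, amount_mg_salt=1.0)])
    res = simulate(build_model(drugs, adult, reg), 96.0)
    before = res.states[res.times < 90.0]
    assert np.all(before == 0.0)


def test_mass_balance_error_shrinks_with_solver_tolerance(drugs, adult):
    model = build_model(drugs, adult, SINGLE_DOSE)
    loose = mass_balance(simulate(model, 24.0, method="bdf", rtol=1e-5,
                                  atol=1e-7))
    tight = mass_balance(simulate(model, 24.0, method="bdf", rtol=1e-9,
                                  atol=1e-11))
    assert tight < loose


# --- linearity & superposition -------------------------------------------

def test_dose_linearity_exact(drugs, adult, regimen):
    res1 = simulate(build_model(drugs, adult, regimen), 144.0)
    res2 = simulate(build_model(drugs, adult, regimen.scaled(2.0)), 144.0)
    assert np.allclose(res2.states, 2.0 * res1.states, rtol=1e-12, atol=1e-12)


def test_bid_accumulation_matches_single_dose_superposition(drugs, adult):
    doses = [dict(time_h=12.0 * k, amount_mg_salt=200.0) for k in range(6)]
    multi = simulate(build_model(drugs, adult,
                                 Regimen(label="bid", events=doses)), 96.0)
    single = simulate(build_model(drugs, adult, Regimen(
        label="one", events=[dict(time_h=0.0, amount_mg_salt=200.0)])), 96.0)
    super_c = np.zeros_like(multi.times)
    c1 = single.concentration("HCQ", "plasma")
    for k in range(6):
        shift = int(12.0 * k / 0.25)
        super_c[shift:] += c1[:len(super_c) - shift]
    got = multi.concentration("HCQ", "plasma")
    assert np.allclose(got[1:], super_c[1:], rtol=5e-3, atol=1e-12)


# --- analytic limits ------------------------------------------------------

def test_renal_only_auc_matches_clearance_closed_form(hcq, adult):
    """AUC_inf(plasma) = fa * Dose_base / CL_R for a linear renal-only model."""
    drug = _renal_only(hcq)
    model = build_model([drug], adult, SINGLE_DOSE)
    res = simulate(model, 4000.0, dt=0.5)
    auc = np.trapezoid(res.concentration("HCQ", "plasma"), res.times)
    dose = model.events[0][1]
    expected = model.fa * dose / drug.reference_plasma_clearance
    assert auc == pytest.approx(expected, rel=0.005)


def test_lung_two_pool_steady_state_matches_closed_form(drugs, adult):
    """At whole-body steady state the intracellular:extracellular unbound
    ratio equals (PS + CLint_T)/PS * trapping."""
    model = build_model(drugs, adult, SINGLE_DOSE)
    a = model.full_matrix()
    b = np.zeros(model.n_states)
    lay = model.layouts["HCQ"]
    b[lay.organs["venous_blood"]] = 1.0  # constant 1 mg/h infusion
    # steady state of x' = A x + b, restricted to non-accumulator states:
    keep = [i for i in range(model.n_states)
            if i not in {j for l in model.layouts.values()
                         for j in l.eliminated.values()}
            and i != lay.gut.stop - 1]  # drop sink + accumulators
    a_red = a[np.ix_(keep, keep)]
    x = np.linalg.solve(a_red, -b[keep])
    pos = {i: k for k, i in enumerate(keep)}
    vols = model.individual.organ_volumes
    c_ec = x[pos[lay.organs["lung_EC"]]] / vols["lung_EC"]
    c_ic = x[pos[lay.organs["lung_IC"]]] / vols["lung_IC"]
    lung = model.lung["HCQ"]
    expected = lung.steady_state_unbound_ratio()
    assert c_ic / c_ec == pytest.approx(expected, rel=0.005)


def test_lung_exchange_passive_equilibrium():
    lung = LungSubmodel(0.15, 0.35, 5.0, 0.0, 1.0)
    assert lung.steady_state_unbound_ratio() == pytest.approx(1.0)
    # flux balance at equal unbound concentrations
    d_ec, d_ic = lung_exchange(0.15, 0.35, lung, fu_blood=0.07)
    assert d_ec == pytest.approx(0.0, abs=1e-12)
    assert d_ic == pytest.approx(0.0, abs=1e-12)


def test_lung_uptake_monotone_in_clint(drugs, adult):
    from hcqpbpk.trials import lung_kp

    kps = []
    for clint in (0.0, 5.0, 10.0):
        parent = drugs[0].model_copy(deep=True)
        parent.lung.clint_t = clint
        res = simulate(build_model([parent, drugs[1]], adult, regimen_a()),
                       144.0)
        kps.append(lung_kp(res, 132.0))
    assert kps[0] < kps[1] < kps[2]


def test_eliminated_fractions_recover_configured_fm(drugs, adult):
    """Running the course to completion, the per-pathway eliminated amounts
    split according to the configured clearance fractions."""
    model = build_model(drugs, adult, SINGLE_DOSE)
    res = simulate(model, 4000.0, dt=0.5)
    elim = {k: v[-1] for k, v in res.eliminated("HCQ").items()}
    total = sum(elim.values())
    assert total == pytest.approx(model.fa * model.events[0][1], rel=1e-3)
    # oral first-pass extraction (~5% hepatic) shifts the absolute split
    # slightly toward the CYPs relative to the systemic-clearance fractions
    for pathway, fm in drugs[0].fm_map.items():
        assert elim[pathway] / total == pytest.approx(fm, abs=0.02)
    # hepatic flux split across the three CYPs matches fm ratios exactly
    hep = {k: v for k, v in elim.items() if k != "renal"}
    hep_total = sum(hep.values())
    for enz, amount in hep.items():
        assert amount / hep_total == pytest.approx(
            drugs[0].fm_map[enz] / 0.733, rel=1e-9)


# --- absorption chain -----------------------------------------------------

def test_zero_permeability_sends_dose_to_sink(hcq, adult):
    drug = _renal_only(hcq, papp_caco2=0.0)
    model = build_model([drug], adult, SINGLE_DOSE)
    assert model.fa == 0.0
    res = simulate(model, 48.0)
    lay = model.layouts["HCQ"]
    sink = res.states[-1, lay.gut.stop - 1]
    assert sink == pytest.approx(model.events[0][1], rel=1e-6)
    assert res.concentration("HCQ", "plasma").max() == 0.0


def test_fraction_absorbed_limits():
    assert fraction_absorbed(0.0, 2.0) == 0.0
    assert fraction_absorbed(1e6, 2.0) == pytest.approx(1.0)
    assert 0.6 <= fraction_absorbed(0.784, 7 / 3.32) <= 1.0


def test_absorption_rates_conserve_mass():
    amounts = np.array([10.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.0])
    d, portal = absorption_rates(amounts, kge=4.0, kt=2.0,
                                 ka=np.full(7, 0.8))
    assert d.sum() + portal == pytest.approx(0.0, abs=1e-12)


def test_default_fa_in_expected_band(baseline_result):
    assert 0.6 <= baseline_result.model.fa <= 1.0


# --- integrator cross-checks ---------------------------------------------

def test_expm_and_bdf_agree(drugs, adult):
    model = build_model(drugs, adult, SINGLE_DOSE)
    exact = simulate(model, 48.0)
    stiff = simulate(model, 48.0, method="bdf", rtol=1e-8, atol=1e-10)
    c1 = exact.concentration("HCQ", "plasma")
    c2 = stiff.concentration("HCQ", "plasma")
    assert c2.max() == pytest.approx(c1.max(), rel=1e-3)


def test_bdf_tolerance_convergence(drugs, adult):
    model = build_model(drugs, adult, SINGLE_DOSE)
    loose = simulate(model, 24.0, method="bdf", rtol=1e-6, atol=1e-8)
    tight = simulate(model, 24.0, method="bdf", rtol=3e-7, atol=4e-9)
    cm_l = loose.concentration("HCQ", "plasma").max()
    cm_t = tight.concentration("HCQ", "plasma").max()
    assert abs(cm_l - cm_t) / cm_t < 1e-3


def test_t_end_must_cover_regimen(drugs, adult, regimen):
    model = build_model(drugs, adult, regimen)
    with pytest.raises(ValueError):
        simulate(model, 96.0)  # last dose at 108 h


def test_blood_plasma_observables_related_by_bp(baseline_result, hcq):
    blood = baseline_result.concentration("HCQ", "blood")
    plasma = baseline_result.concentration("HCQ", "plasma")
    assert np.allclose(blood, plasma * hcq.blood_plasma_ratio, rtol=1e-12)
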