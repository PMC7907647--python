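"""Observed-data I/O, fold/interval verification and the metabolite
clearance fit with synthetic-data parameter recovery."""

import numpy as np
import pytest

from hcqpbpk.drug import regimen_a
from hcqpbpk.engine import build_model, simulate
from hcqpbpk.population import (
    ErrorModel,
    PopulationSpec,
    generate_noisy_profile,
    healthy_adult,
    sample_individual,
)
from hcqpbpk.validation import (
    ObservedProfile,
    fit_dhcq_hepatic_clint,
    fold_check,
    interval_coverage,
    read_observed_profiles,
    write_observed_profiles,
)


def _profile(**kw):
    base = dict(study="s1", analyte="HCQ", matrix="plasma",
                times_h=[1.0, 2.0, 4.0], concentrations_mg_l=[0.1, 0.2, 0.15])
    base.update(kw)
    return ObservedProfile(**base)


def test_roundtrip_is_lossless(tmp_path):
    prof = _profile(concentrations_mg_l=[0.123456789012, 0.2, 0.15])
    path = tmp_path / "obs.csv"
    write_observed_profiles([prof], path)
    back = read_observed_profiles(path)
    assert len(back) == 1
    assert np.allclose(back[0].concentrations_mg_l, prof.concentrations_mg_l,
                       rtol=1e-12, atol=0)
    assert back[0].times_h == prof.times_h


def test_unit_normalization_ng_ml(tmp_path):
    path = tmp_path / "obs.csv"
    path.write_text(
        "time_h,conc,unit,analyte,matrix,study,lloq_flag\n"
        "1.0,100.0,ng/mL,HCQ,plasma,s1,False\n"
        "2.0,0.05,mg/L,HCQ,plasma,s1,False\n")
    profs = read_observed_profiles(path)
    assert profs[0].concentrations_mg_l == pytest.approx([0.1, 0.05])


def test_serum_matrix_rejected_with_reason(tmp_path):
    path = tmp_path / "obs.csv"
    path.write_text(
        "time_h,conc,unit,analyte,matrix,study,lloq_flag\n"
        "1.0,0.1,mg/L,HCQ,serum,s1,False\n"
        "1.0,0.1,mg/L,HCQ,plasma,s2,False\n")
    reasons = []
    profs = read_observed_profiles(path, reasons)
    assert len(profs) == 1 and profs[0].study == "s2"
    assert any("serum" in r for r in reasons)
    with pytest.raises(Exception):
        _profile(matrix="serum")


def test_unknown_unit_raises(tmp_path):
    path = tmp_path / "obs.csv"
    path.write_text("time_h,conc,unit,analyte,matrix,study,lloq_flag\n"
                    "1.0,0.1,furlongs,HCQ,plasma,s1,False\n")
    with pytest.raises(ValueError, match="unit"):
        read_observed_profiles(path)


@pytest.mark.parametrize("pred, obs, boundary, verdict", [
    (1.0, 1.0, 2.0, True),
    (2.0, 1.0, 2.0, True),   # inclusive at the boundary
    (2.01, 1.0, 2.0, False),
    (1.0, 1.24, 1.25, True),
])
def test_fold_check_examples(pred, obs, boundary, verdict):
    assert fold_check(pred, obs, boundary) is verdict
    assert fold_check(obs, pred, boundary) is verdict  # symmetric
    with pytest.raises(ValueError):
        fold_check(0.0, 1.0)


def test_interval_coverage_extremes():
    rng = np.random.default_rng(0)
    times = np.linspace(0, 24, 13)
    preds = np.exp(rng.normal(0, 0.3, size=(50, 13))) * np.exp(-times / 12)
    median = np.median(preds, axis=0)
    obs = _profile(times_h=times[1:].tolist(),
                   concentrations_mg_l=median[1:].tolist())
    assert interval_coverage(preds, times, obs) == 1.0
    far = _profile(times_h=times[1:].tolist(),
                   concentrations_mg_l=(10 * median[1:]).tolist())
    assert interval_coverage(preds, times, far) == 0.0
    with pytest.raises(ValueError):
        interval_coverage(preds[:5], times, obs)  # too few subjects


def test_interval_self_coverage_near_nominal(drugs):
    """Observations drawn from the simulated population itself should fall in
    the 5th-95th band about 90% of the time."""
    spec = PopulationSpec()
    seeds = np.random.SeedSequence(21).spawn(50)
    sims = [simulate(build_model(drugs, sample_individual(spec, s),
                                 regimen_a()), 240.0, dt=0.5) for s in seeds]
    times = sims[0].times
    preds = np.vstack([r.concentration("HCQ", "plasma") for r in sims])
    keep = slice(24, None, 24)  # 12-hourly, skipping the pre-dose zeros
    rng = np.random.default_rng(7)
    hits = []
    for _ in range(30):
        rows = rng.integers(0, preds.shape[0], size=preds[:, keep].shape[1])
        obs = ObservedProfile(
            study="self", analyte="HCQ", matrix="plasma",
            times_h=times[keep].tolist(),
            concentrations_mg_l=[preds[r, i] for r, i in
                                 zip(rows, range(*keep.indices(len(times))))])
        hits.append(interval_coverage(preds, times, obs))
    assert np.mean(hits) == pytest.approx(0.9, abs=0.05)


# --- metabolite clearance fit --------------------------------------------

def _dhcq_simulator(drugs, times, dt=0.5):
    adult = healthy_adult()
    reg = regimen_a()

    def simulate_fn(clint):
        met = drugs[1].model_copy(update={"hepatic_clu_int": clint})
        model = build_model([drugs[0], met], adult, reg)
        res = simulate(model, 240.0, dt=dt)
        return np.interp(times, res.times, res.concentration("DHCQ", "plasma"))

    return simulate_fn


def test_fit_recovers_noise_free_truth(drugs):
    times = np.linspace(12, 228, 12)
    fn = _dhcq_simulator(drugs, times)
    truth = fn(60.0)
    obs = ObservedProfile(study="syn", analyte="DHCQ", matrix="plasma",
                          times_h=times.tolist(),
                          concentrations_mg_l=truth.tolist())
    fit = fit_dhcq_hepatic_clint(obs, fn)
    assert fit.identifiable
    assert fit.estimate == pytest.approx(60.0, rel=0.01)
    assert fit.ci_90[0] <= fit.estimate <= fit.ci_90[1]


def test_fit_recovers_under_proportional_noise(drugs):
    times = np.linspace(12, 228, 12)
    fn = _dhcq_simulator(drugs, times)
    truth = fn(60.0)
    for seed in (1, 2, 3):
        noisy = generate_noisy_profile(times, truth,
                                       ErrorModel(proportional_cv=0.10,
                                                  seed=seed),
                                       analyte="DHCQ")
        fit = fit_dhcq_hepatic_clint(noisy, fn)
        assert fit.identifiable
        assert abs(fit.estimate - 60.0) / 60.0 < 0.15


def test_fit_flags_degenerate_input(drugs):
    times = np.linspace(12, 228, 5)
    fn = _dhcq_simulator(drugs, times)
    censored = ObservedProfile(study="c", analyte="DHCQ", matrix="plasma",
                               times_h=times.tolist(),
                               concentrations_mg_l=[0.0] * 5,
                               lloq_flags=[True] * 5)
    fit = fit_dhcq_hepatic_clint(censored, fn)
    assert not fit.identifiable
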