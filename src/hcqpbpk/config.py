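"""Configuration schema, packaged defaults and the scenario runner.

Drug parameter files and scenario files are YAML; every scenario resolves to
a frozen "effective config" echoed next to its outputs together with the seed
and package version, so any output directory can reproduce itself.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .ddi import DDIScenario, PerpetratorParameters
from .drug import ConfigurationError, DrugParameters, Regimen, regimen_a
from .engine import SimulationResult, build_model, simulate
from .population import PopulationSpec, typical_individual
from .trials import TrialDesign, exposure_ratio, run_trials

_DATA = resources.files("hcqpbpk") / "data"


def _load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_drug(name_or_path: str) -> DrugParameters:
    """Load a packaged drug config by short name (``hcq``, ``dhcq``) or any
    YAML file path."""
    p = Path(name_or_path)
    if p.suffix in (".yml", ".yaml") and p.exists():
        return DrugParameters(**_load_yaml(p))
    packaged = _DATA / f"{name_or_path.lower()}.yaml"
    with resources.as_file(packaged) as f:
        if not f.exists():
            raise ConfigurationError(f"no drug config {name_or_path!r}")
        return DrugParameters(**_load_yaml(f))


def load_perpetrator(name_or_path: str) -> PerpetratorParameters:
    p = Path(name_or_path)
    if p.suffix in (".yml", ".yaml") and p.exists():
        return PerpetratorParameters(**_load_yaml(p))
    packaged = _DATA / f"{name_or_path.lower()}.yaml"
    with resources.as_file(packaged) as f:
        if not f.exists():
            raise ConfigurationError(f"no perpetrator config {name_or_path!r}")
        return PerpetratorParameters(**_load_yaml(f))


def default_drugs() -> list[DrugParameters]:
    """The coupled parent + metabolite pair used by every shipped scenario."""
    return [load_drug("hcq"), load_drug("dhcq")]


class ScenarioConfig(BaseModel):
    """One simulation scenario: population, regimen, optional interaction."""

    name: str
    kind: str = "population"  # population | ddi | simulate
    drugs: list[str] = Field(default_factory=lambda: ["hcq", "dhcq"])
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    regimen: str = "regimen_a"
    perpetrator: Optional[str] = None
    n_trials: int = 10
    n_subjects_per_trial: int = 10
    auc_window_h: float = 240.0
    seed: Optional[int] = None

    model_config = {"extra": "forbid"}

    def resolve_regimen(self) -> Regimen:
        if self.regimen == "regimen_a":
            return regimen_a()
        raise ConfigurationError(f"unknown regimen keyword {self.regimen!r}")


def load_scenario(name_or_path: str) -> ScenarioConfig:
    """Load a packaged scenario by name or a YAML file path; schema
    violations surface with pydantic field paths."""
    p = Path(name_or_path)
    if p.suffix in (".yml", ".yaml") and p.exists():
        raw = _load_yaml(p)
    else:
        packaged = _DATA / "scenarios" / f"{name_or_path}.yaml"
        with resources.as_file(packaged) as f:
            if not f.exists():
                raise ConfigurationError(f"no scenario {name_or_path!r}")
            raw = _load_yaml(f)
    try:
        return ScenarioConfig(**raw)
    except ValidationError as err:
        raise ConfigurationError(f"invalid scenario {name_or_path!r}: {err}") from err


def list_scenarios() -> list[str]:
    with resources.as_file(_DATA / "scenarios") as d:
        return sorted(f.stem for f in Path(d).glob("*.yaml"))


def export_result(result: SimulationResult, path, metadata: dict,
                  every: int = 1) -> None:
    """Tidy series export (time_h, analyte, matrix, concentration_mg_L) with a
    commented metadata header block; ``every`` thins the output grid."""
    rows = []
    for drug in result.model.drugs:
        for matrix in ("plasma", "blood", "lung_tissue"):
            conc = result.concentration(drug.name, matrix)
            rows.extend(dict(time_h=t, analyte=drug.name, matrix=matrix,
                             concentration_mg_L=c)
                        for t, c in zip(result.times[::every], conc[::every]))
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_exported_result(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _design(config: ScenarioConfig, spec: PopulationSpec, seed: int,
            ddi: Optional[DDIScenario]) -> TrialDesign:
    return TrialDesign(
        population=spec, regimen=config.resolve_regimen(), ddi=ddi,
        n_trials=config.n_trials, n_subjects_per_trial=config.n_subjects_per_trial,
        seed=seed, auc_window_h=config.auc_window_h,
    )


def run_scenario(config: ScenarioConfig, out_dir, seed: Optional[int] = None) -> dict:
    """Execute the scenario pipeline and write results + metadata to
    ``out_dir``.  Population/DDI scenarios emit a baseline-relative ratio
    table; plain ``simulate`` scenarios emit the typical-individual series."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.seed
    if seed is None and config.kind in ("population", "ddi"):
        raise ConfigurationError("population runs require a seed")
    drugs = [load_drug(n) for n in config.drugs]
    effective = json.loads(config.model_dump_json())
    effective.update(seed=seed, package_version=__version__)
    meta = dict(scenario=config.name, seed=seed, package_version=__version__,
                drugs={d.name: json.loads(d.model_dump_json()) for d in drugs})

    if config.kind == "simulate":
        individual = typical_individual(config.population)
        regimen = config.resolve_regimen()
        model = build_model(drugs, individual, regimen)
        res = simulate(model, config.auc_window_h)
        export_result(res, out / "series.csv", meta)
        summary = {"series": str(out / "series.csv")}
    elif config.kind in ("population", "ddi"):
        ddi = None
        if config.kind == "ddi":
            if config.perpetrator is None:
                raise ConfigurationError("ddi scenario needs a perpetrator")
            ddi = DDIScenario(perpetrator=load_perpetrator(config.perpetrator))
        baseline_spec = PopulationSpec(variability=config.population.variability)
        baseline = run_trials(_design(config, baseline_spec, seed, None), drugs)
        test_spec = config.population if config.kind == "population" \
            else baseline_spec
        test = run_trials(_design(config, test_spec, seed, ddi), drugs)
        ratios = exposure_ratio(test, baseline)
        table = pd.DataFrame([dict(
            scenario=config.name,
            r_cmax_plasma=ratios.r_cmax_plasma, r_auc_plasma=ratios.r_auc_plasma,
            r_cmax_lung=ratios.r_cmax_lung, r_auc_lung=ratios.r_auc_lung,
            **{f"geo_{k}": v for k, v in ratios.geometric.items()},
        )])
        table.to_csv(out / "ratios.csv", index=False)
        test.table.to_csv(out / "subjects.csv", index=False)
        summary = {"ratios": table.iloc[0].to_dict()}
    else:
        raise ConfigurationError(f"unknown scenario kind {config.kind!r}")

    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(effective, fh, sort_keys=True)
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return summary
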