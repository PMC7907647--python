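"""Drug-specific parameters and the derivations that turn printed constraints
into simulator inputs.

Hydroxychloroquine (HCQ) is dosed as the sulfate salt; the simulator works in
base equivalents throughout.  Elimination is resolved into four pathways —
CYP2C8, CYP2D6, CYP3A4 and renal — whose fractional contributions (fm) are the
model's central disposition contract: per-pathway clearances are assembled as
``fm_i * reference_plasma_clearance`` so the configured fractions hold exactly
regardless of the absolute clearance chosen.

Units: amounts mg, clearances L/h, permeabilities cm/s, time h.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

PATHWAYS = ("CYP2C8", "CYP2D6", "CYP3A4", "renal")
CYP_PATHWAYS = ("CYP2C8", "CYP2D6", "CYP3A4")

FM_TOL = 1e-9


class ConfigurationError(ValueError):
    """Raised when drug/physiology configuration violates a model contract."""


class MetaboliteLink(BaseModel):
    """One parent->metabolite formation route through a hepatic enzyme."""

    enzyme: str
    formation_fraction: float = Field(ge=0.0, le=1.0)
    product: str


class LungConfig(BaseModel):
    """Per-drug lung submodel inputs (geometry lives in the physiology config)."""

    trapping: float = Field(default=1.0, gt=0.0)
    clint_t: float = Field(default=0.0, ge=0.0)  # L/h, apparent active uptake


class DrugParameters(BaseModel):
    """Physicochemical + disposition parameter bundle for one analyte.

    ``fm_map`` / ``reference_plasma_clearance`` drive the pathway-resolved
    clearance assembly (parent drug).  Metabolites may instead carry explicit
    ``renal_clearance_plasma`` and ``hepatic_clu_int`` values.
    """

    name: str
    molecular_weight_base: float = Field(gt=0.0)  # g/mol
    molecular_weight_salt: Optional[float] = Field(default=None, gt=0.0)
    pka_values: list[float] = Field(default_factory=list)  # basic pKa, diprotic base
    logp: float = 0.0
    fu_plasma: float = Field(gt=0.0, le=1.0)
    blood_plasma_ratio: float = Field(gt=0.0)
    papp_caco2: float = Field(default=0.0, ge=0.0)  # cm/s
    fm_map: Optional[dict[str, float]] = None
    reference_plasma_clearance: Optional[float] = Field(default=None, gt=0.0)  # L/h
    renal_clearance_plasma: Optional[float] = Field(default=None, ge=0.0)  # L/h
    hepatic_clu_int: Optional[float] = Field(default=None, ge=0.0)  # L/h unbound blood
    vss_reference_plasma: Optional[float] = Field(default=None, gt=0.0)  # L
    lung: LungConfig = Field(default_factory=LungConfig)
    metabolite_links: list[MetaboliteLink] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "DrugParameters":
        if self.fm_map is not None:
            bad = [k for k in self.fm_map if k not in PATHWAYS]
            if bad:
                raise ConfigurationError(f"unknown elimination pathways {bad}")
            if any(not (0.0 <= v <= 1.0) for v in self.fm_map.values()):
                raise ConfigurationError("fm values must lie in [0, 1]")
            if abs(sum(self.fm_map.values()) - 1.0) > FM_TOL:
                raise ConfigurationError(
                    f"fm_map must sum to 1 (got {sum(self.fm_map.values()):.12f})"
                )
            for link in self.metabolite_links:
                if link.enzyme not in self.fm_map:
                    raise ConfigurationError(
                        f"metabolite link enzyme {link.enzyme!r} not in fm_map"
                    )
        if self.molecular_weight_salt is not None:
            if not (0.0 < self.salt_factor < 1.0):
                raise ConfigurationError("salt factor must lie in (0, 1)")
        return self

    @property
    def salt_factor(self) -> float:
        if self.molecular_weight_salt is None:
            raise ConfigurationError(f"{self.name}: no salt molecular weight configured")
        return self.molecular_weight_base / self.molecular_weight_salt

    @property
    def fu_blood(self) -> float:
        return self.fu_plasma / self.blood_plasma_ratio


class ClearanceComponents(BaseModel):
    """Pathway-resolved plasma clearances that reconstruct the configured total."""

    components: dict[str, float]  # pathway -> L/h plasma
    total_plasma_clearance: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "ClearanceComponents":
        s = sum(self.components.values())
        if abs(s - self.total_plasma_clearance) > FM_TOL * self.total_plasma_clearance:
            raise ConfigurationError("clearance components do not sum to total")
        return self

    @property
    def hepatic_plasma_clearance(self) -> float:
        return sum(v for k, v in self.components.items() if k != "renal")

    @property
    def renal_plasma_clearance(self) -> float:
        return self.components.get("renal", 0.0)

    def fractions(self) -> dict[str, float]:
        return {k: v / self.total_plasma_clearance for k, v in self.components.items()}


class DoseEvent(BaseModel):
    time_h: float = Field(ge=0.0)
    amount_mg_salt: float = Field(gt=0.0)
    route: str = "oral"


class Regimen(BaseModel):
    label: str
    events: list[DoseEvent]

    @model_validator(mode="after")
    def _check(self) -> "Regimen":
        times = [e.time_h for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigurationError("dose events must be strictly ordered in time")
        return self

    def scaled(self, factor: float) -> "Regimen":
        """Same schedule with every dose multiplied by ``factor`` (>0)."""
        return Regimen(
            label=f"{self.label} x{factor:g}",
            events=[
                DoseEvent(time_h=e.time_h, amount_mg_salt=e.amount_mg_salt * factor,
                          route=e.route)
                for e in self.events
            ],
        )

    def shifted(self, offset_h: float) -> "Regimen":
        return Regimen(
            label=self.label,
            events=[
                DoseEvent(time_h=e.time_h + offset_h, amount_mg_salt=e.amount_mg_salt,
                          route=e.route)
                for e in self.events
            ],
        )


def regimen_a(start_h: float = 0.0) -> Regimen:
    """COVID-19 treatment course: hydroxychloroquine sulfate 600 mg twice daily
    on day 1, then 200 mg twice daily on days 2-5 (10 oral doses over 5 days)."""
    events = []
    for day in range(5):
        amount = 600.0 if day == 0 else 200.0
        for tod in (0.0, 12.0):
            events.append(DoseEvent(time_h=start_h + 24.0 * day + tod,
                                    amount_mg_salt=amount))
    return Regimen(label="Regimen A", events=events)


def weight_based_regimen(loading_mg_per_kg: float, body_weight_kg: float,
                         start_h: float = 0.0) -> Regimen:
    """Pediatric weight-based course: loading dose BID on day 1, one third of
    the loading dose BID on days 2-5 (salt mg/kg)."""
    events = []
    for day in range(5):
        per_kg = loading_mg_per_kg if day == 0 else loading_mg_per_kg / 3.0
        for tod in (0.0, 12.0):
            events.append(DoseEvent(time_h=start_h + 24.0 * day + tod,
                                    amount_mg_salt=per_kg * body_weight_kg))
    return Regimen(label=f"weight-based {loading_mg_per_kg:g} mg/kg", events=events)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def salt_to_base_amount(amount_mg_salt: float, drug: DrugParameters) -> float:
    """Convert a salt dose (mg) to base equivalents (mg)."""
    if amount_mg_salt < 0:
        raise ValueError("dose amount must be non-negative")
    if amount_mg_salt == 0.0:
        return 0.0
    if drug.molecular_weight_salt is None:
        raise ConfigurationError(
            f"{drug.name}: salt-dosed but no salt molecular weight configured"
        )
    return amount_mg_salt * drug.salt_factor


def caco2_to_calu3(papp_caco2_1e7: float) -> float:
    """Map Caco-2 apparent permeability to the bronchial-epithelium (Calu-3)
    scale via the linear cell-line correlation; both in 1e-7 cm/s."""
    if papp_caco2_1e7 < 0:
        raise ValueError("permeability must be non-negative")
    return 0.5881 * papp_caco2_1e7 + 4.5594


def caco2_to_human_peff(
    papp_caco2: float, *, slope: float = 0.4926, intercept: float = -0.1454
) -> float:
    """Caco-2 Papp (cm/s) -> human jejunal effective permeability Peff (cm/s).

    Log-log linear correlation: log10(Peff[1e-4 cm/s]) =
    slope * log10(Papp[1e-6 cm/s]) + intercept.  Monotone increasing in Papp.
    """
    if papp_caco2 <= 0:
        raise ValueError("Caco-2 permeability must be positive")
    if slope <= 0:
        raise ConfigurationError("Peff correlation slope must be positive")
    import math

    log_peff = slope * math.log10(papp_caco2 * 1e6) + intercept
    return max(10.0 ** log_peff * 1e-4, 0.0)


def derive_clearance_components(drug: DrugParameters) -> ClearanceComponents:
    """Split the reference plasma clearance into pathway components by fm."""
    if drug.fm_map is None or drug.reference_plasma_clearance is None:
        raise ConfigurationError(
            f"{drug.name}: fm_map and reference_plasma_clearance required"
        )
    total = drug.reference_plasma_clearance
    return ClearanceComponents(
        components={k: v * total for k, v in drug.fm_map.items()},
        total_plasma_clearance=total,
    )


def well_stirred_clearance(clu_int: float, hepatic_blood_flow: float,
                           fu_blood: float) -> float:
    """Forward well-stirred liver model: CLh = Q*fu_B*CLu,int/(Q + fu_B*CLu,int)."""
    return (hepatic_blood_flow * fu_blood * clu_int
            / (hepatic_blood_flow + fu_blood * clu_int))


def invert_well_stirred(target_hepatic_clearance: float, hepatic_blood_flow: float,
                        fu_blood: float) -> float:
    """Unbound intrinsic clearance that reproduces a target hepatic (blood)
    clearance under the well-stirred model: CLu,int = Q*CLh/(fu_B*(Q-CLh))."""
    q, clh = hepatic_blood_flow, target_hepatic_clearance
    if clh < 0:
        raise ValueError("hepatic clearance must be non-negative")
    if clh == 0.0:
        return 0.0
    if clh >= q:
        raise ValueError(
            f"target hepatic clearance {clh:g} exceeds hepatic blood flow {q:g} "
            "(flow-limited, not invertible)"
        )
    return q * clh / (fu_blood * (q - clh))
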