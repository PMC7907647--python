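"""Mechanistic tissue:plasma partition coefficients for ionizable bases.

Implements a tissue-composition method of the Rodgers–Rowland family for
moderate-to-strong bases: partitioning into tissue water follows pH-dependent
ionization (ion trapping in the more acidic cell water), the ionized species
associates with tissue acidic phospholipids (association constant back-derived
from red-cell partitioning via the blood:plasma ratio), and the neutral species
partitions into neutral lipids/phospholipids via logP.

Hydroxychloroquine is a diprotic base (two basic pKa), so the ionization term
is X(pH) = 10^(pKa1-pH) + 10^(pKa1+pKa2-2pH).

Predicted Kp values may be uniformly rescaled by a single factor so that the
whole-body steady-state volume of distribution matches a configured reference
(``kp_scale_for_vss``); the scalar, not the raw prediction, is what the
downstream simulator consumes.
"""

from __future__ import annotations

from .drug import ConfigurationError, DrugParameters

# Fractional tissue composition: extracellular water, intracellular water,
# neutral lipid, neutral phospholipid (vol/vol), acidic phospholipid (mg/g).
# Values are the standard published composition table used by
# composition-based Kp methods; "rest" reuses muscle.
TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "adipose": {"f_ew": 0.135, "f_iw": 0.017, "f_nl": 0.853, "f_np": 0.0016, "ap": 0.40},
    "bone":    {"f_ew": 0.100, "f_iw": 0.346, "f_nl": 0.017, "f_np": 0.0017, "ap": 0.67},
    "brain":   {"f_ew": 0.162, "f_iw": 0.620, "f_nl": 0.039, "f_np": 0.0015, "ap": 0.40},
    "gut":     {"f_ew": 0.282, "f_iw": 0.475, "f_nl": 0.038, "f_np": 0.0125, "ap": 2.41},
    "heart":   {"f_ew": 0.320, "f_iw": 0.456, "f_nl": 0.014, "f_np": 0.0111, "ap": 2.25},
    "kidney":  {"f_ew": 0.273, "f_iw": 0.483, "f_nl": 0.012, "f_np": 0.0242, "ap": 5.03},
    "liver":   {"f_ew": 0.161, "f_iw": 0.573, "f_nl": 0.014, "f_np": 0.0240, "ap": 4.56},
    "lung":    {"f_ew": 0.336, "f_iw": 0.446, "f_nl": 0.022, "f_np": 0.0128, "ap": 3.91},
    "muscle":  {"f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010, "f_np": 0.0072, "ap": 1.53},
    "skin":    {"f_ew": 0.382, "f_iw": 0.291, "f_nl": 0.060, "f_np": 0.0044, "ap": 1.32},
    "spleen":  {"f_ew": 0.207, "f_iw": 0.579, "f_nl": 0.0077, "f_np": 0.0113, "ap": 3.18},
    "rest":    {"f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010, "f_np": 0.0072, "ap": 1.53},
}

BLOOD_CELL_COMPOSITION = {"f_iw": 0.603, "f_nl": 0.0017, "f_np": 0.0029, "ap": 0.5}

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELL = 7.22


def _ionization(pka_values: list[float], ph: float) -> float:
    """Cumulative ionized:neutral ratio X for a (poly)protic base at ``ph``."""
    pkas = sorted(pka_values, reverse=True)
    x, cum = 0.0, 0.0
    for pka in pkas:
        cum += pka - ph
        x += 10.0 ** cum
    return x


def _lipid_term(logp: float, f_nl: float, f_np: float) -> float:
    p = 10.0 ** logp
    return p * f_nl + (0.3 * p + 0.7) * f_np


def acidic_phospholipid_affinity(drug: DrugParameters,
                                 hematocrit: float = 0.45) -> float:
    """Association constant of the ionized base with acidic phospholipids,
    back-derived from the blood:plasma ratio via red-cell partitioning."""
    x_p = _ionization(drug.pka_values, PH_PLASMA)
    x_bc = _ionization(drug.pka_values, PH_BLOOD_CELL)
    if x_bc <= 1e-12:
        return 0.0
    bc = BLOOD_CELL_COMPOSITION
    kpu_bc = (drug.blood_plasma_ratio - (1.0 - hematocrit)) / (
        hematocrit * drug.fu_plasma
    )
    residual = (
        kpu_bc
        - (1.0 + x_bc) / (1.0 + x_p) * bc["f_iw"]
        - _lipid_term(drug.logp, bc["f_nl"], bc["f_np"]) / (1.0 + x_p)
    )
    return max(residual, 0.0) * (1.0 + x_p) / (bc["ap"] * x_bc)


def predict_tissue_kp(
    drug: DrugParameters,
    tissue_composition: dict[str, float],
    plasma_ph: float = PH_PLASMA,
    tissue_ph: float = PH_INTRACELLULAR,
    ka_ap: float | None = None,
    hematocrit: float = 0.45,
) -> float:
    """Total tissue:plasma partition coefficient (dimensionless, > 0)."""
    for key in ("f_ew", "f_iw", "f_nl", "f_np"):
        if not (0.0 <= tissue_composition.get(key, -1.0) <= 1.0):
            raise ConfigurationError(f"invalid tissue composition entry {key!r}")
    if not (0.0 < plasma_ph < 14.0 and 0.0 < tissue_ph < 14.0):
        raise ConfigurationError("invalid pH")
    x_p = _ionization(drug.pka_values, plasma_ph)
    x_iw = _ionization(drug.pka_values, tissue_ph)
    if ka_ap is None:
        ka_ap = acidic_phospholipid_affinity(drug, hematocrit)
    tc = tissue_composition
    kpu = (
        tc["f_ew"]
        + (1.0 + x_iw) / (1.0 + x_p) * tc["f_iw"]
        + ka_ap * tc.get("ap", 0.0) * x_iw / (1.0 + x_p)
        + _lipid_term(drug.logp, tc["f_nl"], tc["f_np"]) / (1.0 + x_p)
    )
    return kpu * drug.fu_plasma


def predict_all_kps(drug: DrugParameters, hematocrit: float = 0.45,
                    scale: float = 1.0) -> dict[str, float]:
    """Kp for every perfusion-limited tissue in the composition table."""
    ka_ap = acidic_phospholipid_affinity(drug, hematocrit)
    return {
        organ: scale * predict_tissue_kp(drug, comp, ka_ap=ka_ap,
                                         hematocrit=hematocrit)
        for organ, comp in TISSUE_COMPOSITION.items()
    }


def kp_scale_for_vss(
    drug: DrugParameters,
    organ_volumes: dict[str, float],
    blood_volume_l: float,
    vss_reference_plasma: float,
    hematocrit: float = 0.45,
) -> float:
    """Uniform Kp scalar so that Vss (plasma-referenced) matches the reference.

    Vss = V_blood * B/P + sum_T V_T * s * Kp_T  =>  solve for s.
    """
    kps = predict_all_kps(drug, hematocrit)
    tissue_sum = sum(
        v * kps[organ]
        for organ, v in organ_volumes.items()
        if organ in kps
    )
    blood_part = blood_volume_l * drug.blood_plasma_ratio
    if vss_reference_plasma <= blood_part:
        raise ConfigurationError("reference Vss smaller than the blood pool itself")
    if tissue_sum <= 0:
        raise ConfigurationError("no tissue partitioning to scale")
    return (vss_reference_plasma - blood_part) / tissue_sum
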