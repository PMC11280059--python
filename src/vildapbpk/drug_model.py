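"""Vildagliptin-specific constants and derived quantities.

Holds the drug parameter set (physicochemistry, absorption, binding,
Michaelis–Menten hydrolysis, renal clearance), the tissue-composition
partition-coefficient calculation, the CKD plasma-protein adjustment of the
unbound fraction, and the clearance terms used by the engine.

Partitioning follows the tissue-composition method of Poulin & Theil: each
tissue:plasma coefficient is a lipid-weighted ratio of solvation capacities,

    Kt:p = [P·(f_nl + 0.3 f_ph) + (f_w + 0.7 f_ph)]_tissue
           ---------------------------------------------- · fu_p / fu_t
           [P·(f_nl + 0.3 f_ph) + (f_w + 0.7 f_ph)]_plasma

with the octanol:water coefficient P for non-adipose tissues (tissue binding
approximated by fu_t = 1 / (1 + 0.5·(1−fu_p)/fu_p)) and the
ionization-corrected vegetable-oil:water coefficient for adipose (fu_t = 1).
For a base with pKa 9.7 the adipose term is strongly ionization-suppressed,
so adipose partitioning is low despite the lipophilicity of the neutral form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import load_drug_yaml, load_tissue_composition
from .physiology import EGFR_HEALTHY_REFERENCE, Physiology

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class DrugParameters:
    """All drug-dependent model inputs (defaults reproduce the packaged YAML)."""

    name: str = "vildagliptin"
    molecular_weight: float = 303.4          # g/mol
    logP: float = 1.55                       # model input (optimized)
    logP_literature: float = 1.12            # retained as metadata
    pKa_base: float = 9.7
    water_solubility_mg_ml: float = 60.0
    fu_plasma: float = 0.907
    binding_protein: str = "albumin"
    specific_intestinal_permeability_cm_s: float = 5.0e-4
    weibull_t50_min: float = 50.0
    weibull_shape: float = 1.0
    Km_uM: float = 190.0
    Vmax_nmol_L_s: float = 23.31
    renal_clearance_L_h: float = 13.0
    renal_clearance_L_h_kg: float = 0.18
    blood_plasma_ratio: float = 1.0
    metabolic_renal_dependence: float = 0.85
    metabolic_scaling: float = 1.0           # calibrated via VildagliptinPBPK.fit
    intestinal_sa_per_volume_cm: float = 1.8
    colonic_sa_fraction: float = 0.25        # colon/small-intestine area ratio
    colonic_residence_h: float = 20.0

    def __post_init__(self) -> None:
        for fld in ("molecular_weight", "pKa_base", "water_solubility_mg_ml",
                    "specific_intestinal_permeability_cm_s", "weibull_t50_min",
                    "weibull_shape", "Km_uM", "Vmax_nmol_L_s",
                    "renal_clearance_L_h", "renal_clearance_L_h_kg",
                    "blood_plasma_ratio", "metabolic_scaling",
                    "intestinal_sa_per_volume_cm", "colonic_residence_h"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be positive")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must lie in (0, 1]")
        if not 0 <= self.metabolic_renal_dependence <= 1:
            raise ValueError("metabolic_renal_dependence must lie in [0, 1]")
        if not 0 <= self.colonic_sa_fraction <= 1:
            raise ValueError("colonic_sa_fraction must lie in [0, 1]")

    @classmethod
    def default(cls) -> "DrugParameters":
        """Load the packaged vildagliptin parameter file."""
        raw = load_drug_yaml()
        return cls(
            name=raw["name"],
            molecular_weight=raw["molecular_weight_g_mol"],
            logP=raw["logP"]["input"],
            logP_literature=raw["logP"]["literature"],
            pKa_base=raw["pKa_base"],
            water_solubility_mg_ml=raw["water_solubility_mg_ml"],
            fu_plasma=raw["fu_plasma"],
            binding_protein=raw["plasma_binding_protein"],
            specific_intestinal_permeability_cm_s=(
                raw["specific_intestinal_permeability_cm_s"]),
            weibull_t50_min=raw["weibull_t50_min"],
            weibull_shape=raw["weibull_shape"],
            Km_uM=raw["Km_uM"],
            Vmax_nmol_L_s=raw["Vmax_nmol_L_s"],
            renal_clearance_L_h=raw["renal_clearance_L_h"],
            renal_clearance_L_h_kg=raw["renal_clearance_L_h_kg"],
            blood_plasma_ratio=raw["blood_plasma_ratio"],
            metabolic_renal_dependence=raw["metabolic_renal_dependence"],
            metabolic_scaling=raw["metabolic_scaling"] or 1.0,
            intestinal_sa_per_volume_cm=raw["intestinal_sa_per_volume_cm"],
            colonic_sa_fraction=raw["colonic_sa_fraction"],
            colonic_residence_h=raw["colonic_residence_h"],
        )

    def with_scaling(self, metabolic_scaling: float) -> "DrugParameters":
        return replace(self, metabolic_scaling=metabolic_scaling)

    @property
    def Km_ng_ml(self) -> float:
        # µmol/L × g/mol = µg/L = ng/mL
        return self.Km_uM * self.molecular_weight


def adjust_fu(fu_plasma: float, protein_scaling: float) -> float:
    """Disease-adjusted unbound fraction under binding-protein scaling.

    Scaling the binding-protein concentration by ``s`` scales the bound:free
    ratio by ``s``:  fu' = 1 / (1 + s·(1/fu − 1)). Lower protein (s < 1, as in
    CKD) raises the unbound fraction; s → 0 gives fu' → 1.
    """
    if not 0 < fu_plasma <= 1:
        raise ValueError("fu_plasma must lie in (0, 1]")
    if protein_scaling < 0:
        raise ValueError("protein_scaling must be >= 0")
    if protein_scaling == 1.0:
        return fu_plasma
    return 1.0 / (1.0 + protein_scaling * (1.0 / fu_plasma - 1.0))


def fraction_neutral(pKa_base: float, pH: float = 7.4) -> float:
    """Henderson–Hasselbalch neutral fraction of a monoprotic base."""
    return 1.0 / (1.0 + 10.0 ** (pKa_base - pH))


def oil_water_coefficient(logP: float, pKa_base: float,
                          pH: float = 7.4) -> float:
    """Ionization-corrected vegetable-oil:water distribution coefficient.

    log P_vo:w = 1.115·log P_o:w − 1.35, multiplied by the neutral fraction
    at plasma pH (the ionized species is assumed not to partition into oil).
    """
    p_vow = 10.0 ** (1.115 * logP - 1.35)
    return p_vow * fraction_neutral(pKa_base, pH)


def _solvation_capacity(p: float, f_water: float, f_nl: float,
                        f_ph: float) -> float:
    return p * (f_nl + 0.3 * f_ph) + (f_water + 0.7 * f_ph)


def partition_coefficients(drug: DrugParameters,
                           composition: pd.DataFrame | None = None,
                           fu: float | None = None) -> dict[str, float]:
    """Tissue:plasma partition coefficients for every tissue in the table.

    ``composition`` must carry ``f_water``, ``f_neutral_lipid`` and
    ``f_phospholipid`` per tissue plus a ``plasma`` row; defaults to the
    packaged table. ``fu`` is the (possibly disease-adjusted) plasma unbound
    fraction, defaulting to the drug's healthy value.
    """
    if composition is None:
        composition = load_tissue_composition()
    if fu is None:
        fu = drug.fu_plasma
    if "plasma" not in composition.index:
        raise KeyError("composition table must contain a 'plasma' row")

    p_ow = 10.0 ** drug.logP
    d_vow = oil_water_coefficient(drug.logP, drug.pKa_base)
    plasma = composition.loc["plasma"]
    fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu) / fu)

    kps: dict[str, float] = {}
    for tissue, row in composition.iterrows():
        if tissue == "plasma":
            continue
        p = d_vow if tissue == "adipose" else p_ow
        num = _solvation_capacity(p, row.f_water, row.f_neutral_lipid,
                                  row.f_phospholipid)
        den = _solvation_capacity(p, plasma.f_water, plasma.f_neutral_lipid,
                                  plasma.f_phospholipid)
        binding = fu if tissue == "adipose" else fu / fu_t
        kp = num / den * binding
        if kp <= 0:
            raise ValueError(f"non-positive partition coefficient for {tissue}")
        kps[tissue] = kp
    return kps


def renal_clearance(drug: DrugParameters, phys: Physiology) -> float:
    """Renal plasma clearance in L/h, linear in eGFR.

    CL_R = CL_R/kg × body weight × eGFR / eGFR_healthy. A healthy 72.2-kg
    subject recovers the literature 13 L/h.
    """
    if phys.egfr_ml_min <= 0:
        raise ValueError("eGFR must be positive")
    return (drug.renal_clearance_L_h_kg * phys.body_weight
            * phys.egfr_ml_min / EGFR_HEALTHY_REFERENCE)


def metabolic_rate(concentration_unbound_uM: float, drug: DrugParameters,
                   volume_L: float, scaling: float | None = None) -> float:
    """Michaelis–Menten hydrolysis rate in µmol/h for one organ.

    ``concentration_unbound_uM`` is the unbound tissue-water concentration;
    ``volume_L`` the organ volume. At C << Km the rate is linear with
    intrinsic clearance scaling × Vmax/Km × volume.
    """
    c = np.asarray(concentration_unbound_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if scaling is None:
        scaling = drug.metabolic_scaling
    vmax_uM_h = drug.Vmax_nmol_L_s * SECONDS_PER_HOUR / 1000.0
    rate = scaling * vmax_uM_h * c / (drug.Km_uM + c) * volume_L
    return float(rate) if np.isscalar(concentration_unbound_uM) else rate
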