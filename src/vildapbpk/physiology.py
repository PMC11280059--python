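"""Virtual individuals: system-dependent parameters for the whole-body model.

A :class:`Physiology` carries everything the simulation engine needs about a
subject — organ volumes and perfusion, cardiac output, renal function, GI
transit, hematocrit and the plasma-protein scaling that modifies drug binding
in chronic kidney disease (CKD).

Conventions
-----------
* Volumes in L, flows in L/h, eGFR in mL/min (the per-1.73 m² label is treated
  as mL/min for the reference body size; no BSA rescaling).
* The liver's ``blood_flow`` is the hepatic-artery flow; portal inflow from
  gut, spleen and pancreas is routed through the liver by the engine.
* The healthy reference eGFR is 110 mL/min (:data:`EGFR_HEALTHY_REFERENCE`);
  renal processes scale linearly with eGFR relative to this value.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datasets import load_reference_anatomy

REFERENCE_BODY_WEIGHT = 70.0  # kg, weight of the embedded anatomy table
REFERENCE_CARDIAC_OUTPUT = 336.0  # L/h at 70 kg (5.6 L/min)
EGFR_HEALTHY_REFERENCE = 110.0  # mL/min assigned to the healthy reference

#: Organs drained directly into the venous pool (liver handles the splanchnic
#: organs' outflow; lung sits between venous and arterial blood).
SYSTEMIC_ORGANS = (
    "heart", "brain", "muscle", "adipose", "skin", "bone",
    "liver", "kidney", "gut", "spleen", "pancreas", "rest",
)


@dataclass(frozen=True)
class CKDStage:
    """Pathophysiological parameter set for one renal-function category."""

    label: str
    egfr_ml_min: float
    gastric_emptying_min: float
    intestinal_transit_h: float
    hematocrit: float
    protein_scaling: float


HEALTHY = CKDStage("healthy", EGFR_HEALTHY_REFERENCE, 15.0, 2.1, 0.47, 1.0)
MODERATE_CKD = CKDStage("moderate", 48.0, 20.63, 2.94, 0.42, 0.93)
SEVERE_CKD = CKDStage("severe", 29.0, 39.0, 4.12, 0.37, 0.83)

STAGES = {s.label: s for s in (HEALTHY, MODERATE_CKD, SEVERE_CKD)}


@dataclass(frozen=True)
class Organ:
    volume_L: float
    blood_flow_L_h: float


@dataclass
class Physiology:
    """Complete system-parameter set for one virtual individual."""

    body_weight: float
    age: float
    sex: str
    organs: dict[str, Organ]
    lung_volume_L: float
    arterial_volume_L: float
    venous_volume_L: float
    cardiac_output_L_h: float
    hematocrit: float
    egfr_ml_min: float
    gastric_emptying_min: float
    intestinal_transit_h: float
    protein_scaling: float
    fu_effective: float
    stage: str = "healthy"
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, organ in self.organs.items():
            if organ.volume_L <= 0:
                raise ValueError(f"organ volume must be positive: {name}")
            if organ.blood_flow_L_h <= 0:
                raise ValueError(f"organ blood flow must be positive: {name}")
        for fld in ("lung_volume_L", "arterial_volume_L", "venous_volume_L",
                    "cardiac_output_L_h", "egfr_ml_min",
                    "gastric_emptying_min", "intestinal_transit_h",
                    "protein_scaling"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if not 0 < self.fu_effective <= 1:
            raise ValueError("fu_effective must lie in (0, 1]")
        total = sum(o.blood_flow_L_h for o in self.organs.values())
        if abs(total - self.cardiac_output_L_h) > 1e-6 * self.cardiac_output_L_h:
            raise ValueError("systemic organ flows must sum to cardiac output")

    def copy(self) -> "Physiology":
        return copy.deepcopy(self)

    def total_volume_L(self) -> float:
        return (sum(o.volume_L for o in self.organs.values())
                + self.lung_volume_L + self.arterial_volume_L
                + self.venous_volume_L)

    def to_record(self) -> dict:
        rec = {
            "subject_id": self.subject_id, "stage": self.stage,
            "body_weight": self.body_weight, "age": self.age, "sex": self.sex,
            "cardiac_output_L_h": self.cardiac_output_L_h,
            "hematocrit": self.hematocrit, "egfr_ml_min": self.egfr_ml_min,
            "gastric_emptying_min": self.gastric_emptying_min,
            "intestinal_transit_h": self.intestinal_transit_h,
            "protein_scaling": self.protein_scaling,
            "fu_effective": self.fu_effective,
        }
        for name, organ in self.organs.items():
            rec[f"V_{name}"] = organ.volume_L
            rec[f"Q_{name}"] = organ.blood_flow_L_h
        return rec


def build_reference_individual(body_weight: float = 70.0, sex: str = "M",
                               age: float = 30.0,
                               fu_plasma: float = 0.907) -> Physiology:
    """Construct a healthy individual by linear scaling of the 70-kg anatomy.

    Organ volumes, blood volumes, flows and cardiac output scale with
    ``body_weight / 70``; hematocrit, eGFR and GI parameters take the healthy
    reference values.
    """
    if not 30 <= body_weight <= 150:
        raise ValueError(f"body_weight out of range [30, 150]: {body_weight}")
    if not 18 <= age <= 85:
        raise ValueError(f"age out of range [18, 85]: {age}")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F': {sex!r}")

    anatomy = load_reference_anatomy()
    scale = body_weight / REFERENCE_BODY_WEIGHT
    co = REFERENCE_CARDIAC_OUTPUT * scale
    organs = {
        name: Organ(volume_L=row.volume_L * scale,
                    blood_flow_L_h=row.flow_fraction * co)
        for name, row in anatomy.iterrows()
        if name in SYSTEMIC_ORGANS
    }
    return Physiology(
        body_weight=body_weight, age=age, sex=sex, organs=organs,
        lung_volume_L=anatomy.loc["lung", "volume_L"] * scale,
        arterial_volume_L=anatomy.loc["arterial_blood", "volume_L"] * scale,
        venous_volume_L=anatomy.loc["venous_blood", "volume_L"] * scale,
        cardiac_output_L_h=co,
        hematocrit=HEALTHY.hematocrit,
        egfr_ml_min=HEALTHY.egfr_ml_min,
        gastric_emptying_min=HEALTHY.gastric_emptying_min,
        intestinal_transit_h=HEALTHY.intestinal_transit_h,
        protein_scaling=HEALTHY.protein_scaling,
        fu_effective=fu_plasma,
        stage="healthy",
    )


def apply_ckd(phys: Physiology, stage: CKDStage,
              fu_plasma: float = 0.907) -> Physiology:
    """Return a copy of ``phys`` with the stage's disease parameters applied.

    Overwrites eGFR, gastric emptying, intestinal transit, hematocrit and the
    plasma-protein scaling, and recomputes the effective unbound fraction from
    the drug's healthy plasma fu (binding-site dilution). Idempotent; the
    healthy stage restores the reference state.
    """
    from .drug_model import adjust_fu

    out = phys.copy()
    out.egfr_ml_min = stage.egfr_ml_min
    out.gastric_emptying_min = stage.gastric_emptying_min
    out.intestinal_transit_h = stage.intestinal_transit_h
    out.hematocrit = stage.hematocrit
    out.protein_scaling = stage.protein_scaling
    out.fu_effective = adjust_fu(fu_plasma, stage.protein_scaling)
    out.stage = stage.label
    out.validate()
    return out


@dataclass
class PopulationSpec:
    """Demographic recipe for a virtual population."""

    n: int
    female_fraction: float = 0.5
    age_range: tuple[float, float] = (18.0, 45.0)
    weight_mean: float = 70.0
    weight_sd: float = 7.0
    ckd_stage: CKDStage = HEALTHY
    seed: int = 0
    variability_cv: float = 0.15  # log-normal CV on organ volumes and flows

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if isinstance(self.ckd_stage, str):
            self.ckd_stage = STAGES[self.ckd_stage]

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        raw = yaml.safe_load(open(path))
        if "ckd_stage" in raw and isinstance(raw["ckd_stage"], str):
            raw["ckd_stage"] = STAGES[raw["ckd_stage"]]
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)


def sample_population(spec: PopulationSpec,
                      fu_plasma: float = 0.907) -> list[Physiology]:
    """Draw ``spec.n`` virtual individuals, deterministic given ``spec.seed``.

    Weights come from a normal truncated to the engine's valid range, ages
    uniform over ``age_range``, sex Bernoulli(female_fraction). Organ volumes
    and flows receive independent log-normal inter-individual variability
    (CV ``variability_cv``); flows are renormalized so every individual
    conserves cardiac output exactly.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = 30.0, 150.0
    if spec.weight_sd > 0:
        a = (lo - spec.weight_mean) / spec.weight_sd
        b = (hi - spec.weight_mean) / spec.weight_sd
        weights = stats.truncnorm.rvs(a, b, loc=spec.weight_mean,
                                      scale=spec.weight_sd, size=spec.n,
                                      random_state=rng)
    else:
        weights = np.full(spec.n, spec.weight_mean)
    ages = rng.uniform(*spec.age_range, size=spec.n)
    female = rng.random(spec.n) < spec.female_fraction

    cv = spec.variability_cv
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0

    population = []
    for i in range(spec.n):
        phys = build_reference_individual(
            body_weight=float(weights[i]), sex="F" if female[i] else "M",
            age=float(ages[i]), fu_plasma=fu_plasma)
        if sigma > 0:
            names = list(phys.organs)
            vol_mult = np.exp(rng.normal(-sigma**2 / 2, sigma, len(names)))
            flow_mult = np.exp(rng.normal(-sigma**2 / 2, sigma, len(names)))
            co_mult = float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
            co = phys.cardiac_output_L_h * co_mult
            raw_flows = np.array(
                [phys.organs[n].blood_flow_L_h for n in names]) * flow_mult
            raw_flows *= co / raw_flows.sum()  # conserve cardiac output
            phys.cardiac_output_L_h = co
            phys.organs = {
                n: Organ(phys.organs[n].volume_L * vol_mult[j],
                         float(raw_flows[j]))
                for j, n in enumerate(names)
            }
        if spec.ckd_stage.label != "healthy":
            phys = apply_ckd(phys, spec.ckd_stage, fu_plasma=fu_plasma)
        phys.subject_id = i
        phys.validate()
        population.append(phys)
    return population


def population_to_frame(population: list[Physiology]) -> pd.DataFrame:
    """One row per individual; round-trips through CSV."""
    return pd.DataFrame([p.to_record() for p in population])
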