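"""Top-level modelling interface: :class:`VildagliptinPBPK` and its results.

The model couples the packaged drug parameter set to the virtual-physiology
and ODE-engine modules. Its single free parameter is the metabolic scaling
factor: the printed Michaelis–Menten constants define only the shape of the
hydrolysis saturation, not the enzyme abundance, so the intrinsic capacity is
calibrated once by :meth:`VildagliptinPBPK.fit` against the reference
intravenous clearance (25 mg infusion, NCA clearance 52.1 L/h). Everything
downstream — oral and CKD predictions, populations, dose adjustment — uses
the fitted parameter unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import drug_model, nca, pbpk_engine
from .dose_adjustment import (DoseRecommendation, ExposureComparison,
                              find_equivalent_dose)
from .drug_model import DrugParameters
from .pbpk_engine import (ConcentrationProfile, DoseRegimen, SimulationConfig,
                          mean_profile, simulate, simulate_population)
from .physiology import (HEALTHY, STAGES, CKDStage, Physiology,
                         PopulationSpec, build_reference_individual,
                         sample_population)

#: Demographics of the packaged clinical studies used as defaults
#: (healthy oral/IV reference study and the CKD study).
REFERENCE_SUBJECT = {"body_weight": 68.1, "sex": "M", "age": 30.0}
CKD_STUDY_DEMOGRAPHICS = {
    "healthy": {"weight_mean": 63.1, "female_fraction": 0.56},
    "moderate": {"weight_mean": 62.4, "female_fraction": 0.62},
    "severe": {"weight_mean": 63.7, "female_fraction": 0.61},
}


class VildagliptinPBPK:
    """Whole-body PBPK model of vildagliptin.

    Parameters
    ----------
    drug :
        Drug parameter set; defaults to the packaged vildagliptin values.
    config :
        Solver/output settings shared by all simulations.
    target_iv_clearance :
        NCA clearance (L/h) of the reference 25 mg IV infusion that
        :meth:`fit` calibrates the metabolic scaling against.
    """

    def __init__(self, drug: DrugParameters | None = None,
                 config: SimulationConfig | None = None,
                 target_iv_clearance: float = 52.1,
                 iv_dose_mg: float = 25.0,
                 iv_infusion_min: float = 30.0,
                 reference_subject: dict | None = None):
        self.drug = drug if drug is not None else DrugParameters.default()
        self.config = config if config is not None else SimulationConfig()
        self.target_iv_clearance = target_iv_clearance
        self.iv_regimen = DoseRegimen("iv_infusion", iv_dose_mg,
                                      infusion_duration_min=iv_infusion_min)
        self.reference_subject = dict(REFERENCE_SUBJECT,
                                      **(reference_subject or {}))

    def _reference_physiology(self) -> Physiology:
        return build_reference_individual(fu_plasma=self.drug.fu_plasma,
                                          **self.reference_subject)

    def iv_clearance(self, metabolic_scaling: float) -> float:
        """NCA clearance of the reference IV simulation at a given scaling."""
        drug = self.drug.with_scaling(metabolic_scaling)
        profile = simulate(self._reference_physiology(), drug,
                           self.iv_regimen, self.config)
        return nca.compute_nca(profile).cl_over_f_L_h

    def fit(self, bracket: tuple[float, float] = (1.0, 5e4),
            xtol: float = 1e-3) -> "PBPKResults":
        """Calibrate the metabolic scaling to the target IV clearance.

        Clearance is monotone in the scaling, so a bracketed root search
        converges; raises if the target lies outside the achievable range
        (renal-only floor to the perfusion-limited ceiling).
        """
        target = self.target_iv_clearance

        def objective(log_s: float) -> float:
            return self.iv_clearance(np.exp(log_s)) - target

        lo, hi = np.log(bracket[0]), np.log(bracket[1])
        f_lo, f_hi = objective(lo), objective(hi)
        if f_lo * f_hi > 0:
            raise ValueError(
                "target IV clearance not bracketed by the scaling range; "
                f"achievable [{target + f_lo:.1f}, {target + f_hi:.1f}] L/h")
        log_s = brentq(objective, lo, hi, xtol=xtol)
        scaling = float(np.exp(log_s))
        achieved = self.iv_clearance(scaling)
        return PBPKResults(model=self, metabolic_scaling=scaling,
                           fitted_iv_clearance=achieved)


@dataclass
class PBPKResults:
    """Calibrated model: simulation, population PK and dose-adjustment API."""

    model: VildagliptinPBPK
    metabolic_scaling: float
    fitted_iv_clearance: float

    @property
    def drug(self) -> DrugParameters:
        return self.model.drug.with_scaling(self.metabolic_scaling)

    @property
    def config(self) -> SimulationConfig:
        return self.model.config

    # ------------------------------------------------------------------ #
    def simulate_subject(self, dose_mg: float, route: str = "oral",
                         stage: str | CKDStage = "healthy",
                         phys: Physiology | None = None,
                         **regimen_kw) -> ConcentrationProfile:
        """Simulate one (by default reference) subject."""
        from .physiology import apply_ckd

        if phys is None:
            phys = self.model._reference_physiology()
        stage = STAGES[stage] if isinstance(stage, str) else stage
        if stage.label != "healthy":
            phys = apply_ckd(phys, stage, fu_plasma=self.drug.fu_plasma)
        regimen = DoseRegimen(route, dose_mg, **regimen_kw)
        return simulate(phys, self.drug, regimen, self.config)

    def population_spec(self, stage: str | CKDStage = "healthy",
                        n: int = 100, seed: int = 0,
                        weight_mean: float | None = None,
                        weight_sd: float | None = None,
                        female_fraction: float | None = None,
                        age_range: tuple[float, float] = (18.0, 45.0)
                        ) -> PopulationSpec:
        """Demographic spec with study-matched defaults per stage."""
        stage = STAGES[stage] if isinstance(stage, str) else stage
        if stage.label == "healthy":
            # healthy oral/IV reference study: 68.1 ± 7.1 kg, 45% female
            if weight_mean is None:
                weight_mean = self.model.reference_subject["body_weight"]
            if weight_sd is None:
                weight_sd = 7.1
            if female_fraction is None:
                female_fraction = 0.45
        else:
            # CKD study prints group means only; SD taken as a 15% CV
            demo = CKD_STUDY_DEMOGRAPHICS[stage.label]
            if weight_mean is None:
                weight_mean = demo["weight_mean"]
            if weight_sd is None:
                weight_sd = 0.15 * weight_mean
            if female_fraction is None:
                female_fraction = demo["female_fraction"]
            age_range = (18.0, 85.0)
        return PopulationSpec(n=n, female_fraction=female_fraction,
                              age_range=age_range, weight_mean=weight_mean,
                              weight_sd=weight_sd, ckd_stage=stage, seed=seed)

    def simulate_study(self, dose_mg: float, route: str = "oral",
                       stage: str | CKDStage = "healthy", n: int = 100,
                       seed: int = 0,
                       spec: PopulationSpec | None = None) -> "StudyResult":
        """Simulate a virtual population and summarise it with NCA."""
        if spec is None:
            spec = self.population_spec(stage, n=n, seed=seed)
        population = sample_population(spec, fu_plasma=self.drug.fu_plasma)
        regimen = DoseRegimen(route, dose_mg)
        profiles = simulate_population(population, self.drug, regimen,
                                       self.config)
        mean_prof = mean_profile(profiles)
        return StudyResult(
            spec=spec, regimen=regimen, profiles=profiles,
            mean_profile_=mean_prof,
            mean_profile_nca=nca.compute_nca(mean_prof),
            nca_table=nca.nca_table(profiles),
            fu_effective=population[0].fu_effective)

    # ------------------------------------------------------------------ #
    def recommend_ckd_dose(self, stage: str | CKDStage,
                           initial_dose: float = 50.0,
                           metric: str = "total", n: int = 50,
                           seed: int = 0, tolerance: float = 0.05
                           ) -> DoseRecommendation:
        """Equivalent CKD dose matching healthy exposure at ``initial_dose``.

        The healthy reference population is demographically matched to the
        CKD study; the CKD population is re-simulated at each bisection
        candidate dose.
        """
        stage = STAGES[stage] if isinstance(stage, str) else stage
        healthy = self.simulate_study(initial_dose, "oral", "healthy",
                                      spec=self._ckd_matched_healthy_spec(
                                          n=n, seed=seed))
        ckd_spec = self.population_spec(stage, n=n, seed=seed + 1)
        population = sample_population(ckd_spec,
                                       fu_plasma=self.drug.fu_plasma)
        fu_ckd = population[0].fu_effective

        def ckd_auc(dose: float) -> float:
            regimen = DoseRegimen("oral", dose)
            profiles = simulate_population(population, self.drug, regimen,
                                           self.config)
            aucs = nca.nca_table(profiles)["auc_inf_ng_h_ml"].astype(float)
            mean_auc = float(aucs.mean())
            return mean_auc * (fu_ckd if metric == "unbound" else 1.0)

        ref = self._study_mean_auc(healthy, metric)
        return find_equivalent_dose(ckd_auc, ref, initial_dose,
                                    metric=metric, tolerance=tolerance)

    def _ckd_matched_healthy_spec(self, n: int, seed: int) -> PopulationSpec:
        demo = CKD_STUDY_DEMOGRAPHICS["healthy"]
        return PopulationSpec(
            n=n, female_fraction=demo["female_fraction"],
            age_range=(18.0, 85.0), weight_mean=demo["weight_mean"],
            weight_sd=0.15 * demo["weight_mean"], ckd_stage=HEALTHY,
            seed=seed)

    @staticmethod
    def _study_mean_auc(study: "StudyResult", metric: str) -> float:
        aucs = study.nca_table["auc_inf_ng_h_ml"].astype(float)
        mean_auc = float(aucs.mean())
        return mean_auc * (study.fu_effective if metric == "unbound" else 1.0)

    def exposure_comparison(self, study: "StudyResult",
                            label: str) -> ExposureComparison:
        return ExposureComparison(
            label=label, dose_mg=study.regimen.dose_mg,
            auc_total=study.nca_table["auc_inf_ng_h_ml"]
                           .astype(float).to_numpy(),
            fu_effective=study.fu_effective)

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        """Plain-text summary of the calibrated model."""
        d = self.drug
        ref = self.model.reference_subject
        cl_r = drug_model.renal_clearance(
            d, self.model._reference_physiology())
        lines = [
            "Whole-body PBPK model: vildagliptin".center(68),
            "=" * 68,
            f"{'Reference subject':<34}{ref['body_weight']:.1f} kg, "
            f"{ref['sex']}, {ref['age']:.0f} y",
            f"{'Calibration target (IV CL, L/h)':<34}"
            f"{self.model.target_iv_clearance:.2f}",
            f"{'Fitted IV clearance (L/h)':<34}"
            f"{self.fitted_iv_clearance:.2f}",
            f"{'Metabolic scaling (fitted)':<34}{self.metabolic_scaling:.1f}",
            f"{'Renal clearance, reference (L/h)':<34}{cl_r:.2f}",
            "-" * 68,
            f"{'logP (input / literature)':<34}{d.logP} / {d.logP_literature}",
            f"{'fu plasma':<34}{d.fu_plasma}",
            f"{'Km (µM) / Vmax (nmol/L/s)':<34}{d.Km_uM} / {d.Vmax_nmol_L_s}",
            f"{'Weibull t50 (min) / shape':<34}"
            f"{d.weibull_t50_min} / {d.weibull_shape}",
            f"{'Renal dependence of metabolism':<34}"
            f"{d.metabolic_renal_dependence}",
            "=" * 68,
        ]
        return "\n".join(lines)


@dataclass
class StudyResult:
    """One simulated virtual study (population + NCA summaries)."""

    spec: PopulationSpec
    regimen: DoseRegimen
    profiles: list[ConcentrationProfile]
    mean_profile_: ConcentrationProfile
    mean_profile_nca: nca.PKParameters
    nca_table: pd.DataFrame
    fu_effective: float

    @property
    def mean_profile(self) -> ConcentrationProfile:
        return self.mean_profile_

    def population_summary(self) -> pd.DataFrame:
        return nca.summarize_population_pk(
            self.nca_table.dropna(subset=["auc_inf_ng_h_ml"]))
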