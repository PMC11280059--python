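"""Synthetic "observed" studies for end-to-end testing.

The published concentration–time profiles behind the evaluation tables were
digitized from the literature and are not redistributable as data; this
module emulates them. A study is simulated from its printed demographics with
the engine itself, sampled at a sparse clinical grid, and perturbed with
multiplicative log-normal residual noise (digitization + assay error). A
deliberate clearance mis-specification can be injected to verify that the
two-fold acceptance criterion detects it: under linear kinetics a c-fold
clearance error is exactly a 1/c scaling of the exposure, which is how the
injection is applied.

Everything is deterministic given the study seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import nca
from .datasets import load_fixture_tables
from .drug_model import DrugParameters
from .pbpk_engine import (ConcentrationProfile, DoseRegimen, SimulationConfig,
                          mean_profile, simulate_population)
from .physiology import STAGES, PopulationSpec, sample_population

#: Sparse clinical sampling grid (h) typical of the digitized studies.
DEFAULT_SAMPLING_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                          12.0, 24.0)


@dataclass
class StudySpec:
    """Recipe for one synthetic observed study."""

    study_id: str
    route: str = "oral"
    dose_mg: float = 50.0
    n_subjects: int = 12
    female_fraction: float = 0.5
    age_range: tuple[float, float] = (18.0, 45.0)
    weight_mean: float = 70.0
    weight_sd: float = 7.0
    population: str = "healthy"     # healthy / mild / moderate / severe
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    residual_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be >= 0")
        if self.population not in ("healthy", "mild", "moderate", "severe"):
            raise ValueError(f"unknown population: {self.population!r}")

    @property
    def stage(self):
        # the mild group carries no printed stage parameters; its physiology
        # is treated as healthy
        label = "healthy" if self.population == "mild" else self.population
        return STAGES[label]

    def population_spec(self, variability_cv: float = 0.15) -> PopulationSpec:
        return PopulationSpec(
            n=self.n_subjects, female_fraction=self.female_fraction,
            age_range=self.age_range, weight_mean=self.weight_mean,
            weight_sd=self.weight_sd, ckd_stage=self.stage,
            seed=self.seed, variability_cv=variability_cv)

    @classmethod
    def from_yaml(cls, path) -> "StudySpec":
        raw = yaml.safe_load(open(path))
        for key in ("age_range", "sampling_times"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticStudy:
    spec: StudySpec
    profiles: list[ConcentrationProfile]        # noisy, at sampling times
    mean_profile: ConcentrationProfile
    model_profiles: list[ConcentrationProfile]  # noise-free engine output

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.profiles],
                         ignore_index=True)


def generate_observed_study(spec: StudySpec, drug: DrugParameters,
                            config: SimulationConfig | None = None,
                            variability_cv: float = 0.15,
                            clearance_fold_error: float = 1.0
                            ) -> SyntheticStudy:
    """Simulate a study and dress it up as sparse noisy observations.

    ``clearance_fold_error`` > 1 emulates a generator whose clearance is that
    many fold higher than the evaluating model's (exposure scaled by its
    inverse); 1.0 means the generator and the model agree.
    """
    if config is None:
        config = SimulationConfig()
    if clearance_fold_error <= 0:
        raise ValueError("clearance_fold_error must be positive")

    pop_spec = spec.population_spec(variability_cv=variability_cv)
    population = sample_population(pop_spec, fu_plasma=drug.fu_plasma)
    regimen = DoseRegimen(spec.route, spec.dose_mg)
    model_profiles = simulate_population(population, drug, regimen, config)

    rng = np.random.default_rng([spec.seed, 7919])
    sigma = np.sqrt(np.log1p(spec.residual_cv ** 2))
    t_obs = np.asarray(spec.sampling_times, dtype=float)

    observed = []
    for p in model_profiles:
        base = np.interp(t_obs, p.times, p.concentrations)
        base = base / clearance_fold_error
        noise = np.exp(rng.normal(0.0, sigma, size=t_obs.size)) \
            if sigma > 0 else np.ones_like(t_obs)
        observed.append(ConcentrationProfile(
            times=t_obs.copy(), concentrations=base * noise,
            dose_mg=spec.dose_mg, route=spec.route, subject_id=p.subject_id,
            fu_effective=p.fu_effective))
    return SyntheticStudy(spec=spec, profiles=observed,
                          mean_profile=mean_profile(observed),
                          model_profiles=model_profiles)


def study_specs_from_table3(seed: int = 0) -> list[StudySpec]:
    """One StudySpec per packaged demographic row (one dose per study row)."""
    table3 = load_fixture_tables()["table3"]
    specs = []
    for i, row in table3.iterrows():
        doses = [float(d) for d in str(row.doses_mg).split(";")]
        weight_sd = (float(row.weight_sd_kg)
                     if pd.notna(row.weight_sd_kg)
                     else 0.15 * float(row.weight_mean_kg))
        for dose in doses:
            specs.append(StudySpec(
                study_id=f"study{row.study}_{row.population}_"
                         f"{row.route}{dose:g}",
                route="oral" if row.route == "oral" else "iv_infusion",
                dose_mg=dose, n_subjects=int(row.n),
                female_fraction=float(row.female_pct) / 100.0,
                age_range=(float(row.age_min), float(row.age_max)),
                weight_mean=float(row.weight_mean_kg), weight_sd=weight_sd,
                population=str(row.population), seed=seed + i))
    return specs


load_fixture_tables = load_fixture_tables  # re-exported per module surface
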