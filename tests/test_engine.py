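"""Whole-body simulation: mass balance, analytic limits, dose linearity."""

import numpy as np
import pytest

from vildapbpk import nca
from vildapbpk.pbpk_engine import (DoseRegimen, SimulationConfig,
                                   mean_profile, simulate,
                                   simulate_population)
from vildapbpk.physiology import (SEVERE_CKD, PopulationSpec,
                                  build_reference_individual,
                                  sample_population)

IV25 = DoseRegimen("iv_infusion", 25.0)
ORAL50 = DoseRegimen("oral", 50.0)


def test_zero_dose_gives_zero_everything(reference_phys, drug):
    prof = simulate(reference_phys, drug, DoseRegimen("oral", 0.0))
    assert np.all(prof.concentrations == 0)
    assert all(v == 0 for k, v in prof.mass_ledger.items() if k != "time_h")


@pytest.mark.parametrize("regimen", [IV25, ORAL50],
                         ids=["iv_infusion", "oral_weibull"])
def test_mass_balance_within_0p1_percent(fitted_results, reference_phys,
                                         regimen):
    prof = simulate(reference_phys, fitted_results.drug, regimen)
    assert prof.mass_balance_error() < 1e-3
    # absorbed complements whatever never left the gut lumen
    led = prof.mass_ledger
    assert led["absorbed"] == pytest.approx(
        regimen.dose_mg - led["unreleased_in_gut"], rel=1e-3)


def test_iv_bolus_matches_monoexponential_limit(reference_phys, drug):
    """With uniform partitioning and a single linear clearance the whole
    body collapses to one well-mixed volume: AUC = D/CL and lambda_z = CL/V."""
    drug_lin = drug.with_scaling(1e-9)   # metabolism off; renal only
    kps = {o: 1.0 for o in
           list(reference_phys.organs) + ["lung"]}
    regimen = DoseRegimen("iv_infusion", 25.0, infusion_duration_min=30.0)
    config = SimulationConfig(duration_h=48.0, output_interval_h=0.02,
                              rtol=1e-9, atol=1e-11)
    prof = simulate(reference_phys, drug_lin, regimen, config, kps=kps)
    res = nca.compute_nca(prof)
    from vildapbpk.drug_model import renal_clearance
    cl = renal_clearance(drug_lin, reference_phys)   # fu cancels (ratio 1)
    v_total = reference_phys.total_volume_L()
    # exact linear-kinetics identity
    assert res.auc_inf_ng_h_ml == pytest.approx(25e3 / cl, rel=1e-3)
    # terminal eigenvalue of the mamillary system sits at, but never above,
    # the one-compartment rate CL/Vss
    assert res.lambda_z_per_h <= cl / v_total * (1 + 1e-6)
    assert res.lambda_z_per_h == pytest.approx(cl / v_total, rel=0.15)


def test_dose_proportionality_25_to_200(fitted_results, reference_phys):
    res = {}
    for dose in (25.0, 200.0):
        prof = simulate(reference_phys, fitted_results.drug,
                        DoseRegimen("oral", dose))
        res[dose] = nca.compute_nca(prof)
    assert res[200].auc_inf_ng_h_ml / res[25].auc_inf_ng_h_ml == \
        pytest.approx(8.0, rel=0.02)
    assert res[200].cmax_ng_ml / res[25].cmax_ng_ml == \
        pytest.approx(8.0, rel=0.02)


def test_solver_tolerance_convergence(fitted_results, reference_phys):
    base = SimulationConfig(rtol=1e-7, atol=1e-9)
    tight = SimulationConfig(rtol=5e-8, atol=5e-10)
    a = nca.compute_nca(simulate(reference_phys, fitted_results.drug,
                                 ORAL50, base))
    b = nca.compute_nca(simulate(reference_phys, fitted_results.drug,
                                 ORAL50, tight))
    assert a.cmax_ng_ml == pytest.approx(b.cmax_ng_ml, rel=1e-3)
    assert a.auc_inf_ng_h_ml == pytest.approx(b.auc_inf_ng_h_ml, rel=1e-3)


def test_healthy_oral_tmax_one_to_two_hours(fitted_results, reference_phys):
    prof = simulate(reference_phys, fitted_results.drug, ORAL50)
    res = nca.compute_nca(prof)
    assert 1.0 <= res.tmax_h <= 2.0


def test_solution_formulation_faster_than_weibull(fitted_results,
                                                  reference_phys):
    solid = simulate(reference_phys, fitted_results.drug, ORAL50)
    solution = simulate(reference_phys, fitted_results.drug,
                        DoseRegimen("oral", 50.0, formulation="solution"))
    assert (nca.compute_nca(solution).tmax_h
            <= nca.compute_nca(solid).tmax_h)


class TestPopulation:
    def test_single_reference_subject_equals_simulate(self, fitted_results):
        spec = PopulationSpec(n=1, weight_mean=68.1, weight_sd=0.0,
                              female_fraction=0.0, age_range=(30, 30),
                              variability_cv=0.0, seed=0)
        pop = sample_population(spec,
                                fu_plasma=fitted_results.drug.fu_plasma)
        via_pop = simulate_population(pop, fitted_results.drug, ORAL50)[0]
        direct = simulate(pop[0], fitted_results.drug, ORAL50)
        np.testing.assert_allclose(via_pop.concentrations,
                                   direct.concentrations)

    def test_variability_propagates_to_cmax_cv(self, fitted_results):
        spec = PopulationSpec(n=60, weight_mean=68.1, weight_sd=7.1, seed=2)
        pop = sample_population(spec,
                                fu_plasma=fitted_results.drug.fu_plasma)
        profiles = simulate_population(pop, fitted_results.drug, ORAL50)
        cmax = np.array([nca.compute_nca(p).cmax_ng_ml for p in profiles])
        cv = cmax.std(ddof=1) / cmax.mean()
        assert 0.08 <= cv <= 0.30

    def test_ckd_population_exceeds_healthy_exposure(self, fitted_results):
        kw = dict(weight_mean=63.5, weight_sd=6.0, seed=4)
        healthy = sample_population(
            PopulationSpec(n=12, **kw),
            fu_plasma=fitted_results.drug.fu_plasma)
        severe = sample_population(
            PopulationSpec(n=12, ckd_stage=SEVERE_CKD, **kw),
            fu_plasma=fitted_results.drug.fu_plasma)
        auc = {}
        for label, pop in (("healthy", healthy), ("severe", severe)):
            profiles = simulate_population(pop, fitted_results.drug, ORAL50)
            auc[label] = np.mean([nca.compute_nca(p).auc_inf_ng_h_ml
                                  for p in profiles])
        assert auc["severe"] > auc["healthy"]

    def test_mean_profile_requires_common_grid(self, fitted_results,
                                               reference_phys):
        p1 = simulate(reference_phys, fitted_results.drug, ORAL50)
        p2 = simulate(reference_phys, fitted_results.drug, ORAL50,
                      SimulationConfig(duration_h=12.0))
        with pytest.raises(ValueError, match="common time grid"):
            mean_profile([p1, p2])
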