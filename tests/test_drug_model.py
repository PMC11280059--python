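"""Drug constants, binding adjustment, partitioning and clearance terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vildapbpk import drug_model
from vildapbpk.datasets import load_tissue_composition
from vildapbpk.drug_model import (DrugParameters, adjust_fu, metabolic_rate,
                                  oil_water_coefficient,
                                  partition_coefficients, renal_clearance)
from vildapbpk.physiology import build_reference_individual


class TestAdjustFu:
    def test_identity_scaling(self):
        assert adjust_fu(0.907, 1.0) == pytest.approx(0.907)

    def test_severe_ckd_scaling(self):
        # 1 / (1 + 0.83 * (1/0.907 - 1)) evaluated by hand
        assert adjust_fu(0.907, 0.83) == pytest.approx(0.921570, abs=1e-6)

    def test_no_binding_protein_limit(self):
        assert adjust_fu(0.3, 0.0) == 1.0

    @given(fu=st.floats(0.01, 1.0), s1=st.floats(0.01, 5.0),
           s2=st.floats(0.01, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_decreasing_in_scaling(self, fu, s1, s2):
        lo, hi = sorted((s1, s2))
        f_lo, f_hi = adjust_fu(fu, lo), adjust_fu(fu, hi)
        assert 0 < f_hi <= 1 and 0 < f_lo <= 1
        if hi > lo and fu < 1:
            assert f_lo > f_hi


class TestPartitionCoefficients:
    def test_plasma_like_tissue_is_unity(self, drug):
        comp = load_tissue_composition()
        comp.loc["phantom"] = comp.loc["plasma"]
        kps = partition_coefficients(drug, comp, fu=drug.fu_plasma)
        # composition identical to plasma and fu_tissue == fu_plasma
        fu = drug.fu_plasma
        fu_t = 1.0 / (1.0 + 0.5 * (1 - fu) / fu)
        assert kps["phantom"] * fu_t / fu == pytest.approx(1.0, rel=1e-12)

    def test_matches_independent_evaluation(self, drug):
        """Independent spreadsheet-style recomputation to 6 decimals."""
        comp = load_tissue_composition()
        kps = partition_coefficients(drug, comp, fu=drug.fu_plasma)
        p = 10 ** drug.logP
        d = (10 ** (1.115 * drug.logP - 1.35)
             / (1 + 10 ** (drug.pKa_base - 7.4)))
        fu = drug.fu_plasma
        fu_t = 1 / (1 + 0.5 * (1 - fu) / fu)
        pl = comp.loc["plasma"]
        for tissue, row in comp.iterrows():
            if tissue == "plasma":
                continue
            pp = d if tissue == "adipose" else p
            num = (pp * (row.f_neutral_lipid + 0.3 * row.f_phospholipid)
                   + row.f_water + 0.7 * row.f_phospholipid)
            den = (pp * (pl.f_neutral_lipid + 0.3 * pl.f_phospholipid)
                   + pl.f_water + 0.7 * pl.f_phospholipid)
            expected = num / den * (fu if tissue == "adipose" else fu / fu_t)
            assert kps[tissue] == pytest.approx(expected, abs=1e-6), tissue

    def test_base_ionization_suppresses_adipose(self, drug):
        # for a pKa 9.7 base the adipose (oil) term is ionization-corrected,
        # so muscle partitions higher than adipose despite the lipophilicity
        kps = partition_coefficients(drug)
        assert kps["muscle"] > kps["adipose"]

    def test_monotone_in_lipophilicity(self, drug):
        lo = partition_coefficients(drug)
        hi = partition_coefficients(
            DrugParameters(logP=drug.logP + np.log10(2.0)))
        for tissue in lo:
            assert hi[tissue] > lo[tissue]

    def test_missing_organ_composition_raises(self, drug):
        comp = load_tissue_composition().drop(index="plasma")
        with pytest.raises(KeyError, match="plasma"):
            partition_coefficients(drug, comp)


class TestClearances:
    def test_healthy_reference_renal_clearance(self, drug):
        phys = build_reference_individual(72.2, "M", 30)
        assert renal_clearance(drug, phys) == pytest.approx(13.0, rel=1e-3)

    def test_linear_in_egfr(self, drug):
        phys = build_reference_individual(72.2, "M", 30)
        base = renal_clearance(drug, phys)
        phys.egfr_ml_min = 29.0
        assert renal_clearance(drug, phys) == pytest.approx(
            base * 29.0 / 110.0, rel=1e-12)

    def test_metabolic_rate_zero_and_midpoint(self, drug):
        assert metabolic_rate(0.0, drug, 1.8) == 0.0
        vmax_uM_h = drug.Vmax_nmol_L_s * 3.6
        half = metabolic_rate(drug.Km_uM, drug, 1.8, scaling=2.0)
        assert half == pytest.approx(0.5 * 2.0 * vmax_uM_h * 1.8, rel=1e-12)

    def test_metabolic_rate_linear_limit(self, drug):
        # series expansion: at C = 1 uM << Km = 190 uM the rate sits within
        # 1% of C * Vmax/Km * V
        rate = metabolic_rate(1.0, drug, 1.8)
        linear = drug.Vmax_nmol_L_s * 3.6 / drug.Km_uM * 1.8
        assert rate == pytest.approx(linear, rel=0.01)
        assert rate < linear

    def test_negative_concentration_rejected(self, drug):
        with pytest.raises(ValueError):
            metabolic_rate(-1.0, drug, 1.8)


def test_default_drug_reproduces_parameter_table(drug):
    assert drug.molecular_weight == 303.4
    assert drug.logP == 1.55 and drug.logP_literature == 1.12
    assert drug.Km_uM == 190.0 and drug.Vmax_nmol_L_s == 23.31
    assert drug.fu_plasma == 0.907
    assert drug.renal_clearance_L_h == 13.0
    assert drug.weibull_t50_min == 50.0
    assert drug.specific_intestinal_permeability_cm_s == 5e-4
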