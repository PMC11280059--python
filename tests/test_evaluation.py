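"""Qualification statistics: R ratios, AFE conventions, VPC coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vildapbpk import load_fixture_tables
from vildapbpk.evaluation import (afe, evaluate_predictions, fold_error,
                                  mean_r_ratio, r_ratio, two_fold_pass, vpc)
from vildapbpk.pbpk_engine import ConcentrationProfile


class TestRRatio:
    @pytest.mark.parametrize("pred,obs,expected", [
        (127, 140, 0.90),       # printed table row
        (3519, 2366, 1.48),     # printed table row (rounded there)
        (50, 50, 1.00),
    ])
    def test_printed_rows(self, pred, obs, expected):
        assert r_ratio(pred, obs) == pytest.approx(expected, abs=0.01)

    def test_fold_error_is_same_quotient(self):
        assert fold_error(3.0, 2.0) == r_ratio(3.0, 2.0)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError, match="observed"):
            r_ratio(1.0, 0.0)

    def test_two_fold_window(self):
        assert two_fold_pass(0.5) and two_fold_pass(2.0)
        assert not two_fold_pass(0.49) and not two_fold_pass(2.01)


class TestAFE:
    def test_unity(self):
        assert afe([1.0, 1.0, 1.0]) == 1.0

    def test_symmetric_cancellation(self):
        assert afe([2.0, 0.5], "signed") == pytest.approx(1.0)
        assert afe([2.0, 0.5], "magnitude") == pytest.approx(1.0)

    def test_magnitude_folds_underprediction(self):
        assert afe([0.5, 0.5], "signed") == pytest.approx(0.5)
        assert afe([0.5, 0.5], "magnitude") == pytest.approx(2.0)

    def test_signed_equals_geometric_mean(self):
        fe = [1.3, 0.7, 2.1, 0.4, 1.0]
        product = np.prod(fe) ** (1 / len(fe))   # independent route
        assert afe(fe, "signed") == pytest.approx(product, rel=1e-12)

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=20),
           st.floats(0.2, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_and_scale_consistency(self, fe, c):
        assert afe(fe, "signed") == pytest.approx(
            afe(list(reversed(fe)), "signed"), rel=1e-9)
        assert afe([c * x for x in fe], "signed") == pytest.approx(
            c * afe(fe, "signed"), rel=1e-9)
        assert afe(fe, "magnitude") >= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            afe([])
        with pytest.raises(ValueError):
            afe([1.0, -2.0])


class TestMeanRRatio:
    def test_trivial_cases(self):
        res = mean_r_ratio([1.0, 1.0, 1.0])
        assert res["mean"] == 1.0
        assert res["ci_low"] == pytest.approx(1.0)
        assert mean_r_ratio([0.5, 1.5])["mean"] == pytest.approx(1.0)

    def test_single_value_has_no_ci(self):
        res = mean_r_ratio([0.9])
        assert res["mean"] == 0.9 and not res["ci_defined"]


@pytest.fixture(scope="module")
def table1():
    return load_fixture_tables()["table1"]


class TestAgainstPackagedTables:
    """The packaged study table must reproduce its own printed statistics."""

    def test_r_columns_recompute(self, table1):
        for _, row in table1.iterrows():
            for p in ("cmax", "auc", "cl"):
                assert r_ratio(row[f"{p}_pred"], row[f"{p}_obs"]) == \
                    pytest.approx(row[f"{p}_r"], abs=0.01)

    def test_oral_healthy_cl_afe(self, table1):
        oh = table1[(table1.route == "oral") & (table1.population == "healthy")]
        assert len(oh) == 14
        fe = (oh.cl_pred / oh.cl_obs).tolist()
        assert afe(fe, "magnitude") == pytest.approx(1.23, abs=0.005)

    def test_renal_failure_cl_afe_needs_magnitude_convention(self, table1):
        ckd = table1[table1.population == "ckd"]
        fe = (ckd.cl_pred / ckd.cl_obs).tolist()
        assert afe(fe, "magnitude") == pytest.approx(1.30, abs=0.005)
        assert afe(fe, "signed") < 1.0     # all under-predicted

    def test_mean_auc_ratio_oral_healthy(self, table1):
        oh = table1[(table1.route == "oral") & (table1.population == "healthy")]
        assert mean_r_ratio(oh.auc_r)["mean"] == pytest.approx(0.82,
                                                               abs=0.005)


class TestVPC:
    @staticmethod
    def _profiles(conc_matrix, t):
        return [ConcentrationProfile(t, c, 50.0, "oral", subject_id=i)
                for i, c in enumerate(conc_matrix)]

    def test_identical_profiles_collapse_bands(self):
        t = np.linspace(0, 24, 25)
        base = 100 * np.exp(-0.2 * t)
        res = vpc(self._profiles(np.tile(base, (20, 1)), t))
        for col in ("p5", "p95", "min", "max"):
            np.testing.assert_allclose(res["bands"][col], base)

    def test_observed_equal_to_mean_is_inside(self):
        t = np.linspace(0, 24, 25)
        rng = np.random.default_rng(0)
        mat = 100 * np.exp(-0.2 * t) * rng.lognormal(0, 0.2, (200, t.size))
        obs = ConcentrationProfile(t, mat.mean(axis=0), 50.0, "oral")
        res = vpc(self._profiles(mat, t), obs)
        assert res["observed_inside_fraction"] == 1.0

    def test_band_coverage_oracle(self):
        # 5-95 band from 1000 log-normal profiles covers ~90% of fresh
        # replicates drawn from the same law
        t = np.linspace(0.5, 24, 20)
        base = 100 * np.exp(-0.2 * t)
        rng = np.random.default_rng(1)
        sim = base * rng.lognormal(0, 0.2, (1000, t.size))
        res = vpc(self._profiles(sim, t))
        fresh = base * rng.lognormal(0, 0.2, (500, t.size))
        lo = res["bands"]["p5"].to_numpy()
        hi = res["bands"]["p95"].to_numpy()
        coverage = np.mean((fresh >= lo) & (fresh <= hi))
        assert coverage == pytest.approx(0.90, abs=0.02)

    def test_empty_simulation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vpc([])


def test_evaluate_predictions_isolates_bad_rows():
    table = pd.DataFrame({
        "parameter": ["auc", "auc", "auc"],
        "observed": [100.0, 0.0, 200.0],
        "predicted": [110.0, 50.0, 150.0],
    })
    report = evaluate_predictions(table)
    assert report.per_profile["flagged"].tolist() == [False, True, False]
    assert report.per_parameter.loc["auc", "n"] == 2
    assert report.per_parameter.loc["auc", "all_two_fold"]
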