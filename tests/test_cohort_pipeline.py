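"""Cohort orchestration, comparison statistics and reporting."""

import math

import numpy as np
import pandas as pd
import pytest

from secondrisk import (
    CohortResult,
    DoseGrid,
    Patient,
    compare_groups,
    compare_techniques,
    cumulative_ear,
    default_risk_config,
    dvh_from_grid,
    ear_from_oed,
    generate_phantom,
    oed,
    run_cohort_analysis,
    write_report,
)
from secondrisk.synthetic_data import PhantomSpec

from conftest import COARSE_SHAPE, COARSE_SPACING, coarse_cohort_spec


def uniform_patient(dose=2.0, age=30.0):
    phantom = generate_phantom(
        PhantomSpec(distance_cm=2.5, spacing_mm=COARSE_SPACING, shape=COARSE_SHAPE), seed=1
    )
    grid = DoseGrid(np.full(COARSE_SHAPE, dose), COARSE_SPACING)
    grids = {t: grid for t in ("W-TF", "2F-IMRT")}
    return Patient("P01", "G2", "left", 2.5, age, phantom, grids)


class TestRunCohortAnalysis:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_cohort_analysis([])

    def test_uniform_patient_matches_direct_composition(self):
        """Pipeline values must equal independent per-organ closed-form calls."""
        patient = uniform_patient()
        result = run_cohort_analysis([patient], include_setup_error=False)
        config = default_risk_config()
        for organ in ("CB", "CL", "IL"):
            dvh = dvh_from_grid(patient.dose_grids["W-TF"], patient.phantom.masks[organ])
            for model in ("linear", "mechanistic"):
                expected_oed = oed(dvh, organ, model, config)
                row = result.risks.query(
                    "technique == 'W-TF' and organ == @organ and model == @model"
                ).iloc[0]
                assert row["oed_gy"] == pytest.approx(expected_oed, rel=1e-12)
                assert row["ear_norm"] == pytest.approx(
                    ear_from_oed(expected_oed, config.risk_for(organ), agex=30, agea=70),
                    rel=1e-12,
                )

    def test_age_policies_agree_at_age_30(self):
        result = run_cohort_analysis([uniform_patient(age=30.0)], include_setup_error=False)
        pd.testing.assert_series_equal(
            result.risks["ear_actual"], result.risks["ear_norm"], check_names=False
        )

    def test_age_normalization_ratio_identity(self):
        age = 44.0
        result = run_cohort_analysis([uniform_patient(age=age)], include_setup_error=False)
        config = default_risk_config()
        for organ in ("CB", "CL"):
            part = result.risks[result.risks.organ == organ]
            gamma_e = config.risk_for(organ).gamma_e
            expected = math.exp(gamma_e * (30.0 - age))
            np.testing.assert_allclose(
                part["ear_norm"] / part["ear_actual"], expected, rtol=1e-12
            )

    def test_every_cell_present(self, small_cohort):
        result = run_cohort_analysis(small_cohort, include_setup_error=False)
        assert len(result.risks) == len(small_cohort) * 4 * 3 * 4  # pat x tech x organ x model
        assert result.risks["ear_norm"].notna().all()

    def test_uniform_dose_yields_zero_setup_error_delta(self):
        result = run_cohort_analysis([uniform_patient()], include_setup_error=True)
        assert np.allclose(result.setup_error["delta_abs"], 0.0, atol=1e-12)


class TestCompareTechniques:
    def _toy_result(self, offset):
        base = np.linspace(1.0, 2.0, 8)
        rows = []
        for i, b in enumerate(base):
            for technique, value in (("2F-IMRT", b), ("VMAT", b + offset)):
                rows.append(
                    {
                        "patient": f"P{i}",
                        "technique": technique,
                        "organ": "CB",
                        "model": "mechanistic",
                        "group": "G1",
                        "ear_norm": value,
                    }
                )
        return CohortResult(pd.DataFrame(rows), pd.DataFrame(), pd.DataFrame())

    def test_identical_samples_have_unit_rr_and_no_signal(self):
        out = compare_techniques(self._toy_result(0.0)).iloc[0]
        assert out["rr_median"] == pytest.approx(1.0)
        assert out["wilcoxon_p"] == 1.0

    def test_constant_offset_is_detected(self):
        out = compare_techniques(self._toy_result(0.5)).iloc[0]
        assert out["wilcoxon_p"] < 0.05
        assert out["rr_median"] > 1.0

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            compare_techniques(self._toy_result(0.1), baseline="6F-IMRT")


class TestCompareGroups:
    def _toy_result(self, means, n_per_group=4, jitter=0.05):
        rng = np.random.default_rng(0)
        rows = []
        i = 0
        for group, mu in zip(("G1", "G2", "G3"), means):
            for _ in range(n_per_group):
                rows.append(
                    {
                        "patient": f"P{i}",
                        "technique": "VMAT",
                        "organ": "CB",
                        "model": "mechanistic",
                        "group": group,
                        "ear_norm": mu + rng.normal(0, jitter),
                    }
                )
                i += 1
        return CohortResult(pd.DataFrame(rows), pd.DataFrame(), pd.DataFrame())

    def test_identical_groups_give_negligible_f(self):
        out = compare_groups(self._toy_result([1.0, 1.0, 1.0])).iloc[0]
        assert out["anova_p"] > 0.05

    def test_separated_means_detected(self):
        out = compare_groups(self._toy_result([1.0, 2.0, 4.0])).iloc[0]
        assert out["anova_p"] < 0.05
        assert 0.0 <= out["levene_p"] <= 1.0

    def test_single_patient_group_rejected(self):
        result = self._toy_result([1.0, 2.0, 3.0], n_per_group=1)
        with pytest.raises(ValueError, match="at least two patients"):
            compare_groups(result)


class TestCumulativeEar:
    def _toy_result(self):
        risks = pd.DataFrame(
            [
                {"patient": "P1", "group": "G1", "technique": "VMAT",
                 "organ": "CB", "model": "mechanistic", "ear_norm": 10.0},
                {"patient": "P1", "group": "G1", "technique": "VMAT",
                 "organ": "CL", "model": "mechanistic", "ear_norm": 5.0},
            ]
        )
        return CohortResult(risks, pd.DataFrame(), pd.DataFrame())

    def test_simple_sum(self):
        out = cumulative_ear(self._toy_result())
        assert out.iloc[0]["ear_pre"] == 15.0
        assert np.isnan(out.iloc[0]["ear_post"])  # no setup-error table

    def test_missing_organ_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cumulative_ear(self._toy_result(), organs=("CB", "IL"))

    def test_column_sum_on_pipeline_table(self, small_cohort):
        result = run_cohort_analysis(small_cohort[:2], include_setup_error=False)
        out = cumulative_ear(result)
        part = result.risks.query("model == 'mechanistic' and organ in ('CB', 'CL')")
        expected = part.groupby(["patient", "technique"])["ear_norm"].sum()
        for _, row in out.iterrows():
            assert row["ear_pre"] == pytest.approx(expected[row["patient"], row["technique"]])


class TestReporting:
    def test_identical_seed_gives_byte_identical_report(self, tmp_path):
        from secondrisk import generate_cohort

        for run in ("a", "b"):
            cohort = generate_cohort(coarse_cohort_spec(3), seed=21)
            result = run_cohort_analysis(cohort, include_setup_error=True)
            write_report(result, tmp_path / run)
        for name in ("risks.csv", "plan_quality.csv", "setup_error.csv", "metadata.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
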