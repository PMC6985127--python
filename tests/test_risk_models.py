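"""OED dose-response models, parameter registry and EAR scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secondrisk import (
    DifferentialDVH,
    DoseGrid,
    DoseResponseParams,
    OrganMask,
    RiskParams,
    default_risk_config,
    dvh_from_grid,
    ear_from_oed,
    load_risk_config,
    oed,
    oed_linear,
    oed_linear_exponential,
    oed_mechanistic,
    oed_plateau,
    relative_risk,
)
from secondrisk.risk_models import mechanistic_response

from conftest import random_dvh

BREAST = {"alpha_linexp": 0.041, "alpha_plateau": 0.115, "alpha_mech": 0.044, "R": 0.15}
LUNG = {"alpha_linexp": 0.022, "alpha_plateau": 0.056, "alpha_mech": 0.042, "R": 0.83}


def uniform_dvh(dose, volume=100.0):
    """Single occupied bin centered exactly on `dose`."""
    half = 0.01
    return DifferentialDVH([0.0, dose - half, dose + half], [0.0, volume], "organ")


def mechanistic_scalar(dose, a, r):
    """Independent scalar transcription of the mechanistic response."""
    return (
        math.exp(-a * dose)
        / (a * r)
        * (
            1
            - 2 * r
            + r**2 * math.exp(a * dose)
            - (1 - r) ** 2 * math.exp(-(a * r / (1 - r)) * dose)
        )
    )


class TestClosedForms:
    @pytest.mark.parametrize("dose", [1.0, 2.0, 25.0, 50.0])
    @pytest.mark.parametrize("site", [BREAST, LUNG], ids=["breast", "lung"])
    def test_uniform_dose_matches_scalar_oracles(self, dose, site):
        dvh = uniform_dvh(dose)
        assert oed_linear(dvh) == pytest.approx(dose, rel=1e-12)
        assert oed_linear_exponential(dvh, site["alpha_linexp"]) == pytest.approx(
            dose * math.exp(-site["alpha_linexp"] * dose), rel=1e-12
        )
        assert oed_plateau(dvh, site["alpha_plateau"]) == pytest.approx(
            (1 - math.exp(-site["alpha_plateau"] * dose)) / site["alpha_plateau"], rel=1e-12
        )
        assert oed_mechanistic(dvh, site["alpha_mech"], site["R"]) == pytest.approx(
            mechanistic_scalar(dose, site["alpha_mech"], site["R"]), rel=1e-10
        )

    def test_zero_dose_gives_zero_oed(self):
        dvh = DifferentialDVH([0.0, 1e-12, 1.0], [50.0, 0.0], "organ")
        assert oed_linear(dvh) == pytest.approx(0.0, abs=1e-12)
        assert oed_mechanistic(dvh, 0.044, 0.15) == pytest.approx(0.0, abs=1e-10)


class TestLimits:
    def test_all_models_approach_mean_dose_as_alpha_vanishes(self):
        dvh = random_dvh(np.random.default_rng(2))
        mean = oed_linear(dvh)
        tiny = 1e-9
        assert oed_linear_exponential(dvh, tiny) == pytest.approx(mean, rel=1e-6)
        assert oed_plateau(dvh, tiny) == pytest.approx(mean, rel=1e-6)
        assert oed_mechanistic(dvh, tiny, 0.15) == pytest.approx(mean, rel=1e-6)

    def test_mechanistic_response_is_linear_at_low_dose(self):
        d = 0.01
        assert mechanistic_response(d, 0.044, 0.15) / d == pytest.approx(1.0, rel=0.01)

    def test_plateau_bounded_by_inverse_alpha(self):
        alpha = 0.115
        assert oed_plateau(uniform_dvh(50.0), alpha) < 1 / alpha
        assert oed_plateau(uniform_dvh(500.0), alpha) == pytest.approx(1 / alpha, rel=1e-9)


class TestProperties:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_cell_kill_models_never_exceed_mean_dose(self, seed):
        dvh = random_dvh(np.random.default_rng(seed))
        mean = oed_linear(dvh)
        assert oed_linear_exponential(dvh, 0.041) <= mean + 1e-12
        assert oed_plateau(dvh, 0.115) <= mean + 1e-12

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_oed_invariant_under_volume_rescaling(self, seed, scale):
        dvh = random_dvh(np.random.default_rng(seed))
        scaled = DifferentialDVH(dvh.bin_edges, dvh.bin_volumes * scale, "organ")
        assert oed_mechanistic(scaled, 0.044, 0.15) == pytest.approx(
            oed_mechanistic(dvh, 0.044, 0.15), rel=1e-12
        )

    def test_grid_dvh_oed_matches_voxelwise_sum(self):
        rng = np.random.default_rng(17)
        bin_width = 0.05
        grid = DoseGrid(rng.uniform(0, 55, (12, 12, 12)), (2, 2, 2))
        mask = OrganMask(rng.random((12, 12, 12)) < 0.5, "organ")
        dvh = dvh_from_grid(grid, mask, bin_width)
        doses = grid.values[mask.values]
        brute = mechanistic_response(doses, 0.044, 0.15).mean()
        assert oed_mechanistic(dvh, 0.044, 0.15) == pytest.approx(brute, abs=bin_width / 2)


class TestParameterValidation:
    def test_mechanistic_rejects_degenerate_repopulation(self):
        dvh = uniform_dvh(2.0)
        for r in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                oed_mechanistic(dvh, 0.044, r)

    def test_missing_or_negative_alpha_rejected(self):
        dvh = uniform_dvh(2.0)
        with pytest.raises(ValueError):
            oed_linear_exponential(dvh, None)
        with pytest.raises(ValueError):
            oed_plateau(dvh, -0.1)

    def test_params_dataclass_validation(self):
        with pytest.raises(ValueError):
            DoseResponseParams("mechanistic", alpha_prime=0.044, R=1.2)
        with pytest.raises(ValueError):
            RiskParams(beta_prime=-1, gamma_e=0.0, gamma_a=0.0)


class TestRegistry:
    def test_default_config_carries_breast_and_lung_entries(self):
        config = default_risk_config()
        cb = config.dose_response_for("CB", "mechanistic")
        assert (cb.alpha_prime, cb.R) == (0.044, 0.15)
        lung = config.dose_response_for("CL", "mechanistic")
        assert (lung.alpha_prime, lung.R) == (0.042, 0.83)
        assert config.dose_response_for("CB", "linear_exponential").alpha_prime == 0.041
        assert config.dose_response_for("CB", "plateau").alpha_prime == 0.115
        assert config.dose_response_for("IL", "linear_exponential").alpha_prime == 0.022
        assert config.dose_response_for("IL", "plateau").alpha_prime == 0.056

    def test_dispatch_routes_to_each_model(self):
        config = default_risk_config()
        dvh = uniform_dvh(2.0)
        assert oed(dvh, "CB", "linear", config) == pytest.approx(2.0)
        assert oed(dvh, "CB", "mechanistic", config) == pytest.approx(
            mechanistic_scalar(2.0, 0.044, 0.15), rel=1e-10
        )

    def test_custom_mapping_roundtrip(self):
        config = load_risk_config(
            {
                "thyroid": {
                    "plateau": {"alpha_prime": 0.03},
                    "ear": {"beta_prime": 2.5, "gamma_e": -0.05, "gamma_a": 2.0},
                }
            }
        )
        assert config.dose_response_for("thyroid", "plateau").alpha_prime == 0.03
        with pytest.raises(KeyError):
            config.dose_response_for("thyroid", "mechanistic")


class TestEar:
    RISK = RiskParams(beta_prime=8.2, gamma_e=-0.037, gamma_a=1.7)

    def test_reference_ages_give_unit_modifier(self):
        assert ear_from_oed(3.0, self.RISK, agex=30, agea=70) == pytest.approx(3.0 * 8.2)

    def test_zero_oed_gives_zero_ear(self):
        assert ear_from_oed(0.0, self.RISK) == 0.0

    def test_cohort_median_age_modifier(self):
        # exposure at 41.6 y, attained age 70: modifier exp(11.6 * gamma_e)
        expected = 2.0 * 8.2 * math.exp(11.6 * -0.037)
        assert ear_from_oed(2.0, self.RISK, agex=41.6, agea=70) == pytest.approx(expected)

    def test_age_modifier_ratio_identity(self):
        ref = ear_from_oed(1.0, self.RISK, agex=30, agea=70)
        other = ear_from_oed(1.0, self.RISK, agex=45, agea=60)
        expected = math.exp(-0.037 * 15 + 1.7 * math.log(60 / 70))
        assert other / ref == pytest.approx(expected, rel=1e-12)

    def test_invalid_ages_rejected(self):
        with pytest.raises(ValueError):
            ear_from_oed(1.0, self.RISK, agex=30, agea=-1)


class TestRelativeRisk:
    def test_ratios(self):
        assert relative_risk(5.0, 2.0) == 2.5
        assert relative_risk(3.0, 3.0) == 1.0
        assert relative_risk(0.0, 2.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_risk(1.0, 0.0)
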