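"""Organ equivalent dose (OED) dose-response models and excess absolute risk.

The OED of an inhomogeneously irradiated organ is the uniform dose that would
carry the same second-cancer induction risk under a chosen dose-response
model.  From a differential DVH with bin volumes V_i at bin-center doses D_i
and total volume V_0:

* linear:             OED = (1/V_0) sum_i V_i D_i                    (= mean dose)
* linear-exponential: OED = (1/V_0) sum_i V_i D_i exp(-a D_i)
* plateau:            OED = (1/V_0) sum_i V_i (1 - exp(-a D_i)) / a
* mechanistic:        OED = (1/V_0) sum_i V_i f(D_i) with

      f(D) = exp(-a D) / (a R) *
             [1 - 2R + R^2 exp(a D) - (1-R)^2 exp(-(a R/(1-R)) D)]

where a (written alpha') is the fitted cell-sterilisation coefficient per Gy
(fraction-size effects folded into the fit) and R in (0,1) the repopulation/
repair fraction.  f(D)/D -> 1 as D -> 0: all models agree with the linear
model at low dose.  f is evaluated in the algebraically combined form
[(1-2R)e^{-aD} + R^2 - (1-R)^2 e^{-aD/(1-R)}]/(aR), which avoids the
exp(+aD) overflow of the literal expression at high dose.

The excess absolute risk (EAR, cases per 10,000 person-years) scales the OED
by a population slope and age-modifying factors:

    EAR = OED * beta' * exp[gamma_e (agex - 30) + gamma_a ln(agea / 70)]

with agex the age at exposure and agea the attained age; at agex=30,
agea=70 the modifier is exactly 1.

Default organ parameters ship in ``data/risk_parameters.yaml``; breast and
lung dose-response coefficients come from combined fits to atomic-bomb
survivor and Hodgkin-patient data (alpha/beta = 3 Gy), the EAR population
parameters from Schneider's site-specific dose-response work.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from .dvh import DifferentialDVH

__all__ = [
    "MODELS",
    "DoseResponseParams",
    "RiskParams",
    "OrganRiskConfig",
    "load_risk_config",
    "default_risk_config",
    "oed_linear",
    "oed_linear_exponential",
    "oed_plateau",
    "oed_mechanistic",
    "oed",
    "ear_from_oed",
    "relative_risk",
]

MODELS = ("linear", "linear_exponential", "plateau", "mechanistic")


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of one OED dose-response model for one organ."""

    model: str
    alpha_prime: float | None = None  # Gy^-1
    R: float | None = None  # repopulation/repair fraction, mechanistic only

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.model != "linear":
            if self.alpha_prime is None or self.alpha_prime <= 0:
                raise ValueError(f"model {self.model!r} requires alpha_prime > 0")
        if self.model == "mechanistic":
            if self.R is None or not 0 < self.R < 1:
                raise ValueError("mechanistic model requires 0 < R < 1")


@dataclass(frozen=True)
class RiskParams:
    """EAR population parameters for one organ.

    beta_prime: initial dose-response slope, cases per 10,000 person-years
    per Gy; gamma_e / gamma_a: age-at-exposure and attained-age modifiers;
    agex / agea: default ages (years) used when none are given per call.
    """

    beta_prime: float
    gamma_e: float
    gamma_a: float
    agex: float = 30.0
    agea: float = 70.0

    def __post_init__(self) -> None:
        if self.beta_prime <= 0:
            raise ValueError("beta_prime must be positive")
        if not (self.agea > self.agex > 0):
            raise ValueError("require agea > agex > 0")


@dataclass(frozen=True)
class OrganRiskConfig:
    """Registry mapping organ label -> per-model dose-response + EAR params."""

    dose_response: Mapping[str, Mapping[str, DoseResponseParams]]
    risk: Mapping[str, RiskParams]

    def dose_response_for(self, organ_label: str, model: str) -> DoseResponseParams:
        try:
            return self.dose_response[organ_label][model]
        except KeyError:
            raise KeyError(
                f"no {model!r} dose-response parameters for organ {organ_label!r}"
            ) from None

    def risk_for(self, organ_label: str) -> RiskParams:
        try:
            return self.risk[organ_label]
        except KeyError:
            raise KeyError(f"no EAR parameters for organ {organ_label!r}") from None

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(self.dose_response)


def load_risk_config(source) -> OrganRiskConfig:
    """Load an organ parameter registry from a YAML mapping or open file/path.

    Expected layout per organ::

        CB:
          site: breast
          linear_exponential: {alpha_prime: 0.041}
          plateau: {alpha_prime: 0.115}
          mechanistic: {alpha_prime: 0.044, R: 0.15}
          ear: {beta_prime: 8.2, gamma_e: -0.037, gamma_a: 1.7}
    """
    if isinstance(source, Mapping):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    dose_response: dict[str, dict[str, DoseResponseParams]] = {}
    risk: dict[str, RiskParams] = {}
    for organ, entry in raw.items():
        models = {"linear": DoseResponseParams("linear")}
        for model in ("linear_exponential", "plateau", "mechanistic"):
            if model in entry:
                models[model] = DoseResponseParams(model, **entry[model])
        dose_response[organ] = models
        if "ear" in entry:
            risk[organ] = RiskParams(**entry["ear"])
    return OrganRiskConfig(dose_response, risk)


def default_risk_config() -> OrganRiskConfig:
    """The packaged default registry (breast and lung organs CB, CL, IL)."""
    ref = importlib.resources.files("secondrisk").joinpath("data/risk_parameters.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return load_risk_config(raw)


def _dose_volume(dvh: DifferentialDVH) -> tuple[np.ndarray, np.ndarray, float]:
    v0 = dvh.total_volume
    if v0 <= 0:
        raise ValueError("empty organ: total volume is zero")
    return dvh.bin_centers, dvh.bin_volumes, v0


def oed_linear(dvh: DifferentialDVH) -> float:
    """Linear-model OED (Gy); identical to the mean organ dose."""
    d, v, v0 = _dose_volume(dvh)
    return float(np.dot(v, d) / v0)


def oed_linear_exponential(dvh: DifferentialDVH, alpha_prime: float) -> float:
    """Linear-exponential OED (Gy): cell kill attenuates risk exponentially."""
    if alpha_prime is None or alpha_prime <= 0:
        raise ValueError("alpha_prime must be positive")
    d, v, v0 = _dose_volume(dvh)
    return float(np.dot(v, d * np.exp(-alpha_prime * d)) / v0)


def oed_plateau(dvh: DifferentialDVH, alpha_prime: float) -> float:
    """Plateau OED (Gy): risk saturates at 1/alpha' at high dose."""
    if alpha_prime is None or alpha_prime <= 0:
        raise ValueError("alpha_prime must be positive")
    d, v, v0 = _dose_volume(dvh)
    return float(np.dot(v, -np.expm1(-alpha_prime * d) / alpha_prime) / v0)


def mechanistic_response(dose, alpha_prime: float, R: float):
    """Per-dose mechanistic response f(D) in Gy (see module docstring)."""
    if alpha_prime is None or alpha_prime <= 0:
        raise ValueError("alpha_prime must be positive")
    if R is None or not 0 < R < 1:
        # R -> 0 and R -> 1 are removable singularities; reject rather than
        # special-case.
        raise ValueError("R must lie strictly between 0 and 1")
    d = np.asarray(dose, dtype=float)
    a = alpha_prime
    bracket = (
        (1.0 - 2.0 * R) * np.exp(-a * d)
        + R * R
        - (1.0 - R) ** 2 * np.exp(-a * d / (1.0 - R))
    )
    return bracket / (a * R)


def oed_mechanistic(dvh: DifferentialDVH, alpha_prime: float, R: float) -> float:
    """Full mechanistic OED (Gy) with repopulation/repair fraction R."""
    d, v, v0 = _dose_volume(dvh)
    return float(np.dot(v, mechanistic_response(d, alpha_prime, R)) / v0)


def oed(
    dvh: DifferentialDVH,
    organ_label: str,
    model: str,
    config: OrganRiskConfig | None = None,
) -> float:
    """Dispatch to the requested OED model with registry parameters."""
    if config is None:
        config = default_risk_config()
    params = config.dose_response_for(organ_label, model)
    if model == "linear":
        return oed_linear(dvh)
    if model == "linear_exponential":
        return oed_linear_exponential(dvh, params.alpha_prime)
    if model == "plateau":
        return oed_plateau(dvh, params.alpha_prime)
    if model == "mechanistic":
        return oed_mechanistic(dvh, params.alpha_prime, params.R)
    raise ValueError(f"unknown model {model!r}")


def ear_from_oed(
    oed_gy: float,
    risk: RiskParams,
    agex: float | None = None,
    agea: float | None = None,
) -> float:
    """EAR per 10,000 person-years for a given OED.

    ``agex``/``agea`` override the registry defaults; the age modifier is
    exactly 1 at agex=30, agea=70.
    """
    agex = risk.agex if agex is None else agex
    agea = risk.agea if agea is None else agea
    if agea <= 0 or agex <= 0:
        raise ValueError("ages must be positive")
    modifier = math.exp(risk.gamma_e * (agex - 30.0) + risk.gamma_a * math.log(agea / 70.0))
    return float(oed_gy * risk.beta_prime * modifier)


def relative_risk(ear_a: float, ear_b: float) -> float:
    """Risk of plan/technique a relative to baseline b: EAR_a / EAR_b."""
    if ear_b == 0:
        raise ZeroDivisionError("baseline EAR is zero; relative risk undefined")
    return float(ear_a / ear_b)
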