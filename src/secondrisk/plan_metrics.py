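"""Target conformity/homogeneity indices and organ-at-risk constraint checks.

CI = (V_T,ref / V_T) * (V_T,ref / V_ref): the product of target coverage by
the reference isodose and the selectivity of that isodose; 1 is ideal.
HI = (D_2 - D_98) / D_50 on the target DVH; 0 (perfectly even dose) is ideal.

The default constraint set is the whole-breast protocol used throughout this
package: prescription 50 Gy in 2 Gy fractions, plan accepted when 95% of the
PTV receives 95% of the prescription; lung/heart V_x and mean/max-dose limits
as listed in ``DEFAULT_CONSTRAINTS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dvh import (
    CumulativeDVH,
    DifferentialDVH,
    DoseGrid,
    OrganMask,
    dose_at_volume,
    max_dose,
    mean_dose,
    volume_at_dose,
)

__all__ = [
    "ConstraintResult",
    "PlanQualityReport",
    "conformity_index",
    "conformity_index_from_grid",
    "homogeneity_index",
    "coverage",
    "check_constraints",
    "DEFAULT_PRESCRIPTION_GY",
    "DEFAULT_REFERENCE_FRACTION",
]

DEFAULT_PRESCRIPTION_GY = 50.0
DEFAULT_REFERENCE_FRACTION = 0.95  # plan-acceptance isodose: 95% of prescription


@dataclass(frozen=True)
class ConstraintResult:
    organ: str
    metric: str
    limit: float
    observed: float
    passed: bool


@dataclass(frozen=True)
class PlanQualityReport:
    """Per-plan quality summary: CI, HI, PTV coverage and constraint results."""

    ci: float
    hi: float
    coverage: float  # % of PTV receiving the reference (95%) isodose
    constraint_results: tuple[ConstraintResult, ...] = field(default_factory=tuple)

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.constraint_results)


def conformity_index(v_t_ref: float, v_t: float, v_ref: float) -> float:
    """CI from the three volumes (cm3): target-in-isodose, target, isodose.

    A plan whose reference isodose covers none of the target has CI = 0,
    including the degenerate case of an empty reference isodose.
    """
    if v_t <= 0:
        raise ValueError("target volume must be positive")
    if v_t_ref == 0:
        return 0.0
    if v_ref <= 0:
        raise ValueError("reference-isodose volume must be positive")
    if v_t_ref < 0 or v_t_ref > min(v_t, v_ref) * (1 + 1e-9):
        raise ValueError("covered volume cannot exceed target or isodose volume")
    return float((v_t_ref / v_t) * (v_t_ref / v_ref))


def conformity_index_from_grid(
    grid: DoseGrid,
    ptv_mask: OrganMask,
    body_mask: OrganMask | None = None,
    reference_dose: float = DEFAULT_REFERENCE_FRACTION * DEFAULT_PRESCRIPTION_GY,
) -> float:
    """CI with volumes extracted from a dose grid at the reference isodose.

    ``body_mask`` bounds the reference-isodose volume; the whole grid is used
    when it is omitted.
    """
    if grid.values.shape != ptv_mask.values.shape:
        raise ValueError("grid/mask mismatch: shapes differ")
    hot = grid.values >= reference_dose
    in_body = hot if body_mask is None else (hot & body_mask.values)
    vv = grid.voxel_volume_cm3
    v_t = ptv_mask.voxel_count * vv
    v_ref = float(in_body.sum()) * vv
    v_t_ref = float((hot & ptv_mask.values).sum()) * vv
    return conformity_index(v_t_ref, v_t, v_ref)


def homogeneity_index(target_dvh: CumulativeDVH | DifferentialDVH) -> float:
    """HI = (D_2 - D_98) / D_50 on the target DVH (dimensionless, >= 0)."""
    d2 = dose_at_volume(target_dvh, 2.0)
    d98 = dose_at_volume(target_dvh, 98.0)
    d50 = dose_at_volume(target_dvh, 50.0)
    if d50 <= 0:
        raise ValueError("median target dose must be positive")
    return float((d2 - d98) / d50)


def coverage(
    target_dvh,
    prescription: float = DEFAULT_PRESCRIPTION_GY,
    reference_fraction: float = DEFAULT_REFERENCE_FRACTION,
) -> float:
    """% of the target receiving at least the reference fraction of prescription."""
    return volume_at_dose(target_dvh, reference_fraction * prescription, relative=True)


# (organ, metric, limit); metric grammar: "Vx<p" = volume above x Gy under p %,
# "Dmean<d" / "Dmax<d" in Gy.  Heart rules depend on laterality relative to
# the treated breast.
DEFAULT_CONSTRAINTS = {
    "IL": [("V10", 30.0), ("V20", 20.0), ("V30", 10.0), ("Dmean", 15.0)],
    "heart_ipsilateral": [("V10", 20.0), ("V20", 15.0), ("V30", 20.0)],
    "heart_contralateral": [("V5", 15.0)],
    "spinal_cord": [("Dmax", 40.0)],
}


def _evaluate_metric(dvh, metric: str) -> float:
    if metric.startswith("V"):
        return volume_at_dose(dvh, float(metric[1:]), relative=True)
    if metric == "Dmean":
        return mean_dose(dvh)
    if metric == "Dmax":
        return max_dose(dvh)
    raise ValueError(f"unknown constraint metric {metric!r}")


def check_constraints(
    dvhs: dict[str, DifferentialDVH],
    laterality: str = "left",
    constraints: dict | None = None,
) -> tuple[ConstraintResult, ...]:
    """Evaluate each dose constraint against the per-organ DVHs.

    ``dvhs`` maps organ labels (IL, heart, spinal_cord, ...) to DVHs; the
    heart rule applied depends on ``laterality`` of the treated breast
    (the heart is ipsilateral to a left-sided target).  Organs without a DVH
    are skipped.  Limits are strict inequalities.
    """
    if laterality not in ("left", "right"):
        raise ValueError("laterality must be 'left' or 'right'")
    rules = DEFAULT_CONSTRAINTS if constraints is None else constraints
    results = []
    for organ, organ_rules in rules.items():
        if organ.startswith("heart_"):
            side = organ.split("_", 1)[1]
            heart_side = "ipsilateral" if laterality == "left" else "contralateral"
            if side != heart_side or "heart" not in dvhs:
                continue
            dvh = dvhs["heart"]
            label = "heart"
        else:
            if organ not in dvhs:
                continue
            dvh = dvhs[organ]
            label = organ
        for metric, limit in organ_rules:
            observed = _evaluate_metric(dvh, metric)
            results.append(ConstraintResult(label, metric, limit, observed, observed < limit))
    return tuple(results)


def plan_quality_report(
    grid: DoseGrid,
    ptv_mask: OrganMask,
    organ_dvhs: dict[str, DifferentialDVH],
    target_dvh: DifferentialDVH,
    laterality: str = "left",
    prescription: float = DEFAULT_PRESCRIPTION_GY,
    reference_fraction: float = DEFAULT_REFERENCE_FRACTION,
) -> PlanQualityReport:
    """Assemble CI, HI, coverage and constraint checks into one report."""
    ci = conformity_index_from_grid(
        grid, ptv_mask, reference_dose=reference_fraction * prescription
    )
    hi = homogeneity_index(target_dvh)
    cov = coverage(target_dvh, prescription, reference_fraction)
    checks = check_constraints(organ_dvhs, laterality=laterality)
    return PlanQualityReport(ci=ci, hi=hi, coverage=cov, constraint_results=checks)
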