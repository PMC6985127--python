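"""End-to-end cohort analysis: risk tables, comparisons and reports.

Runs the full chain on a (synthetic or user-supplied) cohort: per-patient
per-technique organ DVHs -> OED under the linear, linear-exponential,
plateau and mechanistic dose-response models -> EAR under two age policies
(actual age at exposure with attained age 70, and normalized agex=30/agea=70)
-> plan-quality indices -> setup-error deltas -> technique and group
comparison statistics (paired Wilcoxon signed-rank; one-way ANOVA with a
Levene variance pre-check; significance at P < 0.05, no multiple-testing
correction) -> cumulative contralateral risk (CB + CL) before and after
setup-error simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import DEFAULT_BIN_WIDTH, dvh_from_grid, read_dvh_csv, write_dvh_csv
from .plan_metrics import plan_quality_report
from .risk_models import (
    MODELS,
    OrganRiskConfig,
    default_risk_config,
    ear_from_oed,
    oed,
    relative_risk,
)
from .setup_error import axis_shift_set, max_difference, simulate_setup_errors
from .synthetic_data import Patient, TECHNIQUES

__all__ = [
    "CohortResult",
    "run_cohort_analysis",
    "compare_techniques",
    "compare_groups",
    "cumulative_ear",
    "write_report",
    "read_dvh_csv",
    "write_dvh_csv",
]

RISK_ORGANS = ("CB", "CL", "IL")

_FLOAT_FMT = "%.10g"


@dataclass
class CohortResult:
    """Long-format result tables of one cohort analysis.

    risks: one row per patient x technique x organ x model with OED (Gy),
    EAR at actual age (ear_actual) and age-normalized EAR (ear_norm), both
    per 10,000 person-years with attained age 70.
    plan_quality: CI/HI/coverage per patient x technique.
    setup_error: worst-case setup-error deltas per patient x technique x
    organ x model (empty when the simulation was skipped).
    """

    risks: pd.DataFrame
    plan_quality: pd.DataFrame
    setup_error: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def run_cohort_analysis(
    cohort: list[Patient],
    config: OrganRiskConfig | None = None,
    models: tuple[str, ...] = MODELS,
    organs: tuple[str, ...] = RISK_ORGANS,
    bin_width: float = DEFAULT_BIN_WIDTH,
    include_setup_error: bool = True,
    shift_mm: float = 5.0,
    attained_age: float = 70.0,
) -> CohortResult:
    """Compute the full per-patient risk table for every technique and organ."""
    if not cohort:
        raise ValueError("empty cohort")
    if config is None:
        config = default_risk_config()
    risk_rows, quality_rows, setup_rows = [], [], []
    for patient in cohort:
        masks = patient.phantom.masks
        risk_masks = {o: masks[o] for o in organs}
        for technique, grid in patient.dose_grids.items():
            dvhs = {name: dvh_from_grid(grid, mask, bin_width) for name, mask in masks.items()}
            for organ in organs:
                risk = config.risk_for(organ)
                for model in models:
                    oed_gy = oed(dvhs[organ], organ, model, config)
                    risk_rows.append(
                        {
                            "patient": patient.patient_id,
                            "age": patient.age,
                            "laterality": patient.laterality,
                            "group": patient.group,
                            "distance_cm": patient.distance_cm,
                            "technique": technique,
                            "organ": organ,
                            "model": model,
                            "oed_gy": oed_gy,
                            "ear_actual": ear_from_oed(
                                oed_gy, risk, agex=patient.age, agea=attained_age
                            ),
                            "ear_norm": ear_from_oed(oed_gy, risk, agex=30.0, agea=attained_age),
                        }
                    )
            report = plan_quality_report(
                grid,
                masks["PTV"],
                organ_dvhs=dvhs,
                target_dvh=dvhs["PTV"],
                laterality=patient.laterality,
            )
            quality_rows.append(
                {
                    "patient": patient.patient_id,
                    "technique": technique,
                    "ci": report.ci,
                    "hi": report.hi,
                    "coverage_pct": report.coverage,
                    "constraints_passed": report.all_passed,
                }
            )
            if include_setup_error:
                per_shift = simulate_setup_errors(
                    grid,
                    risk_masks,
                    shifts=axis_shift_set(shift_mm),
                    config=config,
                    models=models,
                    bin_width=bin_width,
                    agex=30.0,
                    agea=attained_age,
                )
                worst = max_difference(per_shift)
                worst.insert(0, "technique", technique)
                worst.insert(0, "patient", patient.patient_id)
                setup_rows.append(worst)
    risks = pd.DataFrame(risk_rows)
    quality = pd.DataFrame(quality_rows)
    setup = (
        pd.concat(setup_rows, ignore_index=True)
        if setup_rows
        else pd.DataFrame(
            columns=[
                "patient", "technique", "worst_shift", "organ", "model",
                "oed_pre", "oed_post", "ear_pre", "ear_post",
                "delta_abs", "delta_pct", "ear_delta_abs",
            ]
        )
    )
    meta = {
        "n_patients": len(cohort),
        "models": list(models),
        "organs": list(organs),
        "bin_width_gy": bin_width,
        "shift_mm": shift_mm if include_setup_error else None,
        "attained_age": attained_age,
        "age_normalization": {"agex": 30.0, "agea": attained_age},
        "multiple_testing_correction": "none",
        "laterality_pooling": "pooled",
    }
    return CohortResult(risks=risks, plan_quality=quality, setup_error=setup, metadata=meta)


def compare_techniques(
    result: CohortResult,
    baseline: str = "2F-IMRT",
    value: str = "ear_norm",
) -> pd.DataFrame:
    """Paired comparison of each technique against the baseline.

    Per organ x model x technique: relative risk (mean and median of the
    per-patient EAR ratios vs baseline) and the Wilcoxon signed-rank p-value
    (exact for n <= 25, normal approximation beyond).
    """
    risks = result.risks
    if baseline not in set(risks["technique"]):
        raise ValueError(f"baseline technique {baseline!r} not present")
    rows = []
    for (organ, model), part in risks.groupby(["organ", "model"], sort=True):
        wide = part.pivot(index="patient", columns="technique", values=value)
        base = wide[baseline]
        for technique in sorted(wide.columns):
            if technique == baseline:
                continue
            paired = wide[technique]
            ratios = np.array(
                [relative_risk(a, b) for a, b in zip(paired, base)]
            )
            diffs = paired - base
            if np.allclose(diffs, 0):
                p = 1.0
            else:
                method = "exact" if len(diffs) <= 25 else "approx"
                p = float(stats.wilcoxon(paired, base, method=method).pvalue)
            rows.append(
                {
                    "organ": organ,
                    "model": model,
                    "technique": technique,
                    "baseline": baseline,
                    "rr_mean": float(ratios.mean()),
                    "rr_median": float(np.median(ratios)),
                    "wilcoxon_p": p,
                    "significant": p < 0.05,
                    "n": int(len(diffs)),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(result: CohortResult, value: str = "ear_norm") -> pd.DataFrame:
    """One-way ANOVA across the anatomic groups G1/G2/G3, per organ x
    technique x model, with Levene's variance-homogeneity pre-check."""
    risks = result.risks
    rows = []
    for (organ, technique, model), part in risks.groupby(
        ["organ", "technique", "model"], sort=True
    ):
        samples = [g[value].to_numpy() for _, g in part.groupby("group", sort=True)]
        labels = sorted(part["group"].unique())
        if len(samples) < 2:
            raise ValueError("group comparison needs at least two groups")
        if any(len(s) < 2 for s in samples):
            raise ValueError("every group needs at least two patients")
        # degenerate spreads (tiny groups) make these statistics 0/0; report
        # the resulting NaN rather than warn
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat, p = stats.f_oneway(*samples)
            _, levene_p = stats.levene(*samples)
        row = {
            "organ": organ,
            "technique": technique,
            "model": model,
            "anova_F": float(f_stat),
            "anova_p": float(p),
            "levene_p": float(levene_p),
            "significant": p < 0.05,
        }
        for label, sample in zip(labels, samples):
            row[f"mean_{label}"] = float(sample.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_ear(
    result: CohortResult,
    organs: tuple[str, ...] = ("CB", "CL"),
    model: str = "mechanistic",
    value: str = "ear_norm",
) -> pd.DataFrame:
    """Cumulative contralateral EAR per patient x technique.

    ``ear_pre`` sums the named organs' EARs from the unperturbed plans;
    ``ear_post`` sums the worst-case post-setup-error EARs (NaN when the
    setup-error simulation was skipped).
    """
    risks = result.risks[result.risks["model"] == model]
    present = set(risks["organ"])
    missing = [o for o in organs if o not in present]
    if missing:
        raise ValueError(f"organs missing from the result table: {missing}")
    pre = (
        risks[risks["organ"].isin(organs)]
        .groupby(["patient", "group", "technique"], sort=True)[value]
        .sum()
        .rename("ear_pre")
        .reset_index()
    )
    setup = result.setup_error
    if not setup.empty:
        post = (
            setup[(setup["model"] == model) & (setup["organ"].isin(organs))]
            .groupby(["patient", "technique"], sort=True)["ear_post"]
            .sum()
            .rename("ear_post")
            .reset_index()
        )
        out = pre.merge(post, on=["patient", "technique"], how="left")
    else:
        out = pre.assign(ear_post=float("nan"))
    return out


def write_report(result: CohortResult, out_dir, fmt: str = "csv") -> dict[str, Path]:
    """Write the result tables and metadata; byte-deterministic for a given
    cohort seed and configuration (stable row order, fixed float format)."""
    if fmt != "csv":
        raise ValueError("only the csv report format is supported")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "risks": result.risks.sort_values(
            ["patient", "technique", "organ", "model"], kind="mergesort"
        ),
        "plan_quality": result.plan_quality.sort_values(
            ["patient", "technique"], kind="mergesort"
        ),
        "setup_error": result.setup_error.sort_values(
            ["patient", "technique", "organ", "model"], kind="mergesort"
        )
        if not result.setup_error.empty
        else result.setup_error,
    }
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
        paths[name] = path
    meta_path = out / "metadata.json"
    meta_path.write_text(
        json.dumps(result.metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    paths["metadata"] = meta_path
    return paths
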