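"""Synthetic phantoms, technique-specific dose grids and cohorts.

The generator stands in for planning CTs and treatment-planning-system dose
grids, which are not publicly available for this kind of study.  It produces
dose distributions with the statistical structure the risk analysis assumes:

* a near-uniform ~50 Gy target dose with technique-dependent in-field
  heterogeneity (arc techniques most homogeneous, wedged tangents least);
* out-of-field dose falling off with distance r from the field edge as the
  sum of a steep scatter term ``scatter_coeff * exp(-r/penumbra_mm)`` and a
  shallow leakage term ``leakage_floor * exp(-r/leakage_decay_mm)`` (head
  leakage and collimator scatter decay far more slowly than patient scatter);
* technique-ordered low-dose baths: leakage lowest for two-field tangential
  IMRT, highest for arc delivery (more monitor units, more fields);
* three anatomic groups by contralateral-breast-to-sternum distance
  (G1 < 2 cm, G2 2-3 cm, G3 > 3 cm), realised by placing the contralateral
  breast at the specified gap from the field edge.

Each patient carries one phantom and four technique dose grids driven by a
single per-patient seed, so technique comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dvh import DoseGrid, OrganMask

__all__ = [
    "TechniquePreset",
    "DEFAULT_PRESETS",
    "TECHNIQUES",
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "Patient",
    "group_for_distance",
    "generate_phantom",
    "generate_dose_grid",
    "generate_cohort",
]

TECHNIQUES = ("W-TF", "2F-IMRT", "6F-IMRT", "VMAT")

GROUP_DISTANCE_RANGES_CM = {"G1": (1.0, 2.0), "G2": (2.0, 3.0), "G3": (3.0, 4.5)}

DEFAULT_PRESCRIPTION_GY = 50.0


@dataclass(frozen=True)
class TechniquePreset:
    """Dose-structure parameters of one delivery technique.

    in_field_sd: relative dose SD inside the PTV (drives HI/CI);
    penumbra_mm: decay length of the steep near-field scatter term;
    scatter_coeff: its amplitude relative to prescription at the field edge;
    leakage_floor: amplitude of the shallow leakage term (MU/leakage proxy);
    leakage_decay_mm: shared decay length of the leakage term.
    """

    name: str
    in_field_sd: float
    penumbra_mm: float
    leakage_floor: float
    scatter_coeff: float
    leakage_decay_mm: float = 150.0

    def __post_init__(self) -> None:
        if not 0 <= self.in_field_sd < 0.2:
            raise ValueError("in_field_sd must lie in [0, 0.2)")
        if self.penumbra_mm <= 0 or self.leakage_decay_mm <= 0:
            raise ValueError("decay lengths must be positive")
        if self.leakage_floor < 0 or self.scatter_coeff < 0:
            raise ValueError("dose amplitudes must be non-negative")


# Preset constants are fixed once to encode the qualitative technique
# orderings (leakage: 2F-IMRT < W-TF <= 6F-IMRT < VMAT; in-field SD:
# VMAT <= 6F-IMRT <= 2F-IMRT <= W-TF).  The wedged-tangent preset is
# leakage-dominated with a small steep-scatter amplitude: its out-of-field
# dose is flat in space, which makes it the least sensitive to setup error
# while keeping its contralateral dose between the 2F-IMRT and 6F-IMRT
# levels at the cohort median.
DEFAULT_PRESETS: dict[str, TechniquePreset] = {
    "W-TF": TechniquePreset("W-TF", in_field_sd=0.030, penumbra_mm=12.0,
                            leakage_floor=0.010, scatter_coeff=0.010),
    "2F-IMRT": TechniquePreset("2F-IMRT", in_field_sd=0.025, penumbra_mm=12.0,
                               leakage_floor=0.002, scatter_coeff=0.12),
    "6F-IMRT": TechniquePreset("6F-IMRT", in_field_sd=0.018, penumbra_mm=12.0,
                               leakage_floor=0.011, scatter_coeff=0.13),
    "VMAT": TechniquePreset("VMAT", in_field_sd=0.012, penumbra_mm=12.0,
                            leakage_floor=0.020, scatter_coeff=0.14),
}


def validate_preset_ordering(presets: dict[str, TechniquePreset]) -> None:
    """Check the qualitative orderings a preset set must encode."""
    f = {name: presets[name].leakage_floor for name in TECHNIQUES}
    if not (f["2F-IMRT"] < f["W-TF"] <= f["6F-IMRT"] < f["VMAT"]):
        raise ValueError("leakage_floor ordering 2F-IMRT < W-TF <= 6F-IMRT < VMAT violated")
    s = {name: presets[name].in_field_sd for name in TECHNIQUES}
    if not (s["VMAT"] <= s["6F-IMRT"] <= s["2F-IMRT"] <= s["W-TF"]):
        raise ValueError("in_field_sd ordering VMAT <= 6F-IMRT <= 2F-IMRT <= W-TF violated")


def group_for_distance(distance_cm: float) -> str:
    """Anatomic group from contralateral-breast-to-sternum distance."""
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    if distance_cm < 2.0:
        return "G1"
    if distance_cm <= 3.0:
        return "G2"
    return "G3"


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric chest phantom: grid geometry plus organ placement.

    Organ geometry is fixed in millimetres on a 300 x 300 x 200 mm volume
    (x = left-right, y = anterior-posterior, z = superior-inferior); the
    contralateral breast sits ``distance_cm`` from the medial field edge.
    ``size_jitter`` scales organ semi-axes by up to +/- that fraction.
    """

    laterality: str = "left"
    distance_cm: float = 2.5
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    shape: tuple[int, int, int] = (120, 120, 80)
    size_jitter: float = 0.08

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        group_for_distance(self.distance_cm)  # validates positivity
        extent = tuple(n * s for n, s in zip(self.shape, self.spacing_mm))
        if extent[0] < 295 or extent[1] < 295 or extent[2] < 195:
            raise ValueError("grid extent must cover ~300 x 300 x 200 mm")

    @property
    def group(self) -> str:
        return group_for_distance(self.distance_cm)


@dataclass(frozen=True)
class Phantom:
    """Generated organ masks plus the distance map used by the dose model."""

    spec: PhantomSpec
    masks: dict[str, OrganMask]
    distance_to_ptv_mm: np.ndarray  # 0 inside the PTV

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.spec.spacing_mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.spec.shape


def _coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(spec.shape, spec.spacing_mm)
    ]
    if spec.laterality == "right":
        # mirror the lateral axis so "contralateral" stays anatomically correct
        extent_x = spec.shape[0] * spec.spacing_mm[0]
        axes[0] = extent_x - axes[0]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _box(x, y, z, lo, hi) -> np.ndarray:
    return (
        (x >= lo[0]) & (x <= hi[0])
        & (y >= lo[1]) & (y <= hi[1])
        & (z >= lo[2]) & (z <= hi[2])
    )


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> Phantom:
    """Build the organ masks (PTV, CB, CL, IL, heart) for one patient.

    Deterministic given ``seed``; the seed drives only the per-organ size
    jitter.  The treated-breast PTV is a lateral half-chest ellipsoid; the
    contralateral breast's nearest surface lies ``distance_cm`` from the
    PTV's medial edge; lungs are posterior boxes; contralateral structures
    sit far enough from the field edge to be leakage-dominated.
    """
    rng = np.random.default_rng(seed)
    j = lambda: 1.0 + rng.uniform(-spec.size_jitter, spec.size_jitter)  # noqa: E731
    x, y, z = _coords(spec)
    d_mm = 10.0 * spec.distance_cm

    ptv_semi = (35.0 * j(), 40.0 * j(), 40.0 * j())
    ptv = _ellipsoid(x, y, z, (190.0 + ptv_semi[0], 80.0, 100.0), ptv_semi)

    cb_semi = (35.0 * j(), 35.0 * j(), 38.0 * j())
    cb_center = (190.0 - d_mm - cb_semi[0], 80.0, 100.0)
    cb = _ellipsoid(x, y, z, cb_center, cb_semi) & ~ptv

    il = _box(x, y, z, (185.0, 125.0, 55.0 * j()), (260.0, 185.0, 145.0)) & ~ptv
    cl = _box(x, y, z, (40.0, 125.0, 55.0 * j()), (115.0, 185.0, 145.0)) & ~ptv
    heart = _ellipsoid(x, y, z, (160.0, 140.0, 80.0), (30.0 * j(), 25.0 * j(), 30.0 * j())) & ~ptv

    masks = {
        "PTV": OrganMask(ptv, "PTV"),
        "CB": OrganMask(cb, "CB"),
        "CL": OrganMask(cl, "CL"),
        "IL": OrganMask(il, "IL"),
        "heart": OrganMask(heart, "heart"),
    }
    for name, mask in masks.items():
        if mask.voxel_count == 0:
            raise ValueError(f"empty organ: {name} mask has no voxels")
    distance = ndimage.distance_transform_edt(~ptv, sampling=spec.spacing_mm)
    return Phantom(spec=spec, masks=masks, distance_to_ptv_mm=distance)


def generate_dose_grid(
    phantom: Phantom,
    technique: TechniquePreset | str,
    prescription: float = DEFAULT_PRESCRIPTION_GY,
    seed: int | None = None,
    out_field_noise_sd: float = 0.05,
) -> DoseGrid:
    """Synthesize the 3D dose distribution of one technique on a phantom.

    Inside the PTV the dose is ``prescription * N(1, in_field_sd)`` per
    voxel; outside it decays with distance r (mm) to the PTV surface as
    ``prescription * [scatter * exp(-r/penumbra) + floor * exp(-r/leak)]``
    with multiplicative noise.  Reusing one ``seed`` across techniques on
    the same phantom reuses the same noise field, pairing the plans.
    """
    preset = DEFAULT_PRESETS[technique] if isinstance(technique, str) else technique
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    rng = np.random.default_rng(seed)
    r = phantom.distance_to_ptv_mm
    in_field = phantom.masks["PTV"].values
    rel = (
        preset.scatter_coeff * np.exp(-r / preset.penumbra_mm)
        + preset.leakage_floor * np.exp(-r / preset.leakage_decay_mm)
    )
    rel[in_field] = 1.0
    sd = np.where(in_field, preset.in_field_sd, out_field_noise_sd)
    noise = rng.standard_normal(r.shape)
    dose = prescription * rel * (1.0 + sd * noise)
    np.clip(dose, 0.0, None, out=dose)
    return DoseGrid(dose, phantom.spacing)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: defaults mirror the 26-patient planning study."""

    n_patients: int = 26
    group_ratio: tuple[int, int, int] = (4, 5, 4)
    laterality_ratio: tuple[int, int] = (1, 1)
    age_range: tuple[int, int] = (30, 50)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    shape: tuple[int, int, int] = (120, 120, 80)
    prescription: float = DEFAULT_PRESCRIPTION_GY

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("cohort needs at least one patient")
        if any(r <= 0 for r in self.group_ratio) or any(r <= 0 for r in self.laterality_ratio):
            raise ValueError("ratios must be positive")

    def group_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of n_patients to G1:G2:G3."""
        total = sum(self.group_ratio)
        exact = [self.n_patients * r / total for r in self.group_ratio]
        counts = [int(e) for e in exact]
        remainders = sorted(
            range(3), key=lambda i: exact[i] - counts[i], reverse=True
        )
        for i in range(self.n_patients - sum(counts)):
            counts[remainders[i % 3]] += 1
        return dict(zip(("G1", "G2", "G3"), counts))


@dataclass(frozen=True)
class Patient:
    patient_id: str
    group: str
    laterality: str
    distance_cm: float
    age: float
    phantom: Phantom
    dose_grids: dict[str, DoseGrid]


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    presets: dict[str, TechniquePreset] | None = None,
    seed: int = 0,
) -> list[Patient]:
    """Generate the synthetic cohort: one phantom + four plans per patient.

    Group sizes follow the 4:5:4 ratio, lateralities alternate 1:1 within
    each group, distances are drawn uniformly inside each group's range and
    ages uniformly in ``age_range``.  Fully reproducible from ``seed``.
    """
    if presets is None:
        presets = DEFAULT_PRESETS
    validate_preset_ordering(presets)
    counts = spec.group_counts()
    patient_seeds = np.random.SeedSequence(seed).generate_state(
        2 * spec.n_patients, dtype=np.uint32
    )
    patients: list[Patient] = []
    idx = 0
    for group, count in counts.items():
        lo, hi = GROUP_DISTANCE_RANGES_CM[group]
        for k in range(count):
            anatomy_seed = int(patient_seeds[2 * idx])
            plan_seed = int(patient_seeds[2 * idx + 1])
            rng = np.random.default_rng(anatomy_seed)
            laterality = ("left", "right")[k % 2]
            distance = float(rng.uniform(lo, hi))
            if group == "G2":
                distance = min(distance, 3.0)
            age = float(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
            phantom = generate_phantom(
                PhantomSpec(
                    laterality=laterality,
                    distance_cm=distance,
                    spacing_mm=spec.spacing_mm,
                    shape=spec.shape,
                ),
                seed=anatomy_seed,
            )
            grids = {
                name: generate_dose_grid(
                    phantom, preset, prescription=spec.prescription, seed=plan_seed
                )
                for name, preset in presets.items()
            }
            patients.append(
                Patient(
                    patient_id=f"P{idx + 1:02d}",
                    group=group,
                    laterality=laterality,
                    distance_cm=distance,
                    age=age,
                    phantom=phantom,
                    dose_grids=grids,
                )
            )
            idx += 1
    return patients
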