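"""Dose-volume histogram containers and standard dosimetric metrics.

A differential DVH records the organ volume (cm3) absorbing dose within each
dose bin; a cumulative DVH records the volume at or above each dose level.
Both forms, the reduction of a voxelized dose grid to a DVH, and the usual
plan-evaluation metrics (V_x, D_y, mean/max dose) live here.

Conventions
-----------
* Dose is in Gy, volume in cm3 (absolute) or % of the organ volume (relative).
* Grid axes are (x = left-right, y = anterior-posterior, z = superior-inferior),
  voxel-center coordinates, spacing in mm.
* ``V_x`` is the volume receiving *more than* x Gy; a bin counts if its center
  exceeds x.
* ``D_y`` is the dose covering y% of the structure, linearly interpolated on
  the cumulative curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DifferentialDVH",
    "CumulativeDVH",
    "DoseGrid",
    "OrganMask",
    "dvh_from_grid",
    "cumulative_from_differential",
    "differential_from_cumulative",
    "volume_at_dose",
    "dose_at_volume",
    "mean_dose",
    "max_dose",
    "read_dvh_csv",
    "write_dvh_csv",
]

DEFAULT_BIN_WIDTH = 0.05
"""Default DVH bin width in Gy — fine relative to the 2 Gy fraction scale."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential dose-volume histogram of one organ.

    ``bin_edges`` (length n+1, Gy, strictly increasing, non-negative) bound n
    bins; ``bin_volumes`` (length n, cm3, non-negative) is the organ volume
    absorbing dose within each bin.  The bin-center dose represents the bin in
    every dose-weighted sum (midpoint rule).
    """

    bin_edges: np.ndarray
    bin_volumes: np.ndarray
    organ_label: str = ""

    def __post_init__(self) -> None:
        edges = _as_float_array(self.bin_edges, "bin_edges")
        vols = _as_float_array(self.bin_volumes, "bin_volumes")
        if edges.size != vols.size + 1:
            raise ValueError("bin_edges must have one more entry than bin_volumes")
        if edges[0] < 0:
            raise ValueError("bin_edges must be non-negative")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(vols < 0):
            raise ValueError("bin_volumes must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_volumes", vols)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_volume(self) -> float:
        """V_0, the total organ volume in cm3."""
        return float(self.bin_volumes.sum())


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative dose-volume histogram: volume at or above each dose level.

    ``volume_at_or_above[i]`` is the volume receiving at least
    ``dose_levels[i]``.  When derived from a differential DVH the levels are
    all n+1 bin edges and the curve ends at 0, making the conversion
    lossless.  ``normalization`` is ``"absolute"`` (cm3) or ``"relative"``
    (% of V_0, first entry 100).
    """

    dose_levels: np.ndarray
    volume_at_or_above: np.ndarray
    normalization: str = "absolute"
    organ_label: str = ""

    def __post_init__(self) -> None:
        levels = _as_float_array(self.dose_levels, "dose_levels")
        vols = _as_float_array(self.volume_at_or_above, "volume_at_or_above")
        if levels.size != vols.size or levels.size == 0:
            raise ValueError("dose_levels and volume_at_or_above must match and be non-empty")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("dose_levels must be strictly increasing")
        if np.any(np.diff(vols) > 1e-9 * max(1.0, vols[0])):
            raise ValueError("not a cumulative DVH: volume_at_or_above must be non-increasing")
        if self.normalization not in ("absolute", "relative"):
            raise ValueError("normalization must be 'absolute' or 'relative'")
        object.__setattr__(self, "dose_levels", levels)
        object.__setattr__(self, "volume_at_or_above", vols)

    @property
    def total_volume(self) -> float:
        return float(self.volume_at_or_above[0])


@dataclass(frozen=True)
class DoseGrid:
    """Voxelized 3D absorbed-dose distribution (Gy) on a regular grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("dose values must be finite and non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive components (mm)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class OrganMask:
    """Binary organ occupancy on the same lattice as its paired DoseGrid."""

    values: np.ndarray
    organ_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        if values.ndim != 3:
            raise ValueError("mask values must be a 3D array")
        object.__setattr__(self, "values", values)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


def dvh_from_grid(
    grid: DoseGrid, mask: OrganMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DifferentialDVH:
    """Reduce a dose grid over an organ mask to a differential DVH.

    Bins are uniform, width ``bin_width`` Gy, spanning [0, max masked dose].
    V_0 equals (masked voxel count) x voxel volume exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if grid.values.shape != mask.values.shape:
        raise ValueError("grid/mask mismatch: shapes differ")
    doses = grid.values[mask.values]
    if doses.size == 0:
        raise ValueError(f"empty organ: mask '{mask.organ_label}' selects no voxels")
    dmax = float(doses.max())
    # one bin more than dmax/width so the maximum always lies inside the top
    # bin (never on the ambiguous right edge)
    n_bins = int(np.floor(dmax / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    volumes = counts * grid.voxel_volume_cm3
    return DifferentialDVH(edges, volumes, organ_label=mask.organ_label)


def cumulative_from_differential(
    dvh: DifferentialDVH, relative: bool = False
) -> CumulativeDVH:
    """Convert differential to cumulative form.

    The cumulative curve is sampled at all n+1 bin edges; the volume at the
    top edge is 0, so the conversion is lossless (see
    :func:`differential_from_cumulative`).
    """
    vols = np.append(np.cumsum(dvh.bin_volumes[::-1])[::-1], 0.0)
    if relative:
        v0 = dvh.total_volume
        if v0 <= 0:
            raise ValueError("empty organ: total volume is zero")
        vols = 100.0 * vols / v0
    return CumulativeDVH(
        dvh.bin_edges.copy(),
        vols,
        normalization="relative" if relative else "absolute",
        organ_label=dvh.organ_label,
    )


def differential_from_cumulative(cdvh: CumulativeDVH) -> DifferentialDVH:
    """Invert :func:`cumulative_from_differential` (exact roundtrip).

    Successive differences of the cumulative curve become bin volumes.  A
    curve that does not end at zero (a truncated export) gets a synthetic
    final bin holding the residual volume, one level-spacing wide.
    """
    if cdvh.normalization != "absolute":
        raise ValueError("differential conversion requires an absolute cumulative DVH")
    levels = cdvh.dose_levels
    vols = cdvh.volume_at_or_above
    if vols[-1] != 0.0:
        widths = np.diff(levels)
        last_width = widths[-1] if widths.size else 1.0
        levels = np.append(levels, levels[-1] + last_width)
        vols = np.append(vols, 0.0)
    if levels.size < 2:
        raise ValueError("cumulative DVH needs at least two dose levels")
    bin_volumes = -np.diff(vols)
    # tolerate -0.0 from fp cancellation
    bin_volumes = np.where(np.abs(bin_volumes) < 1e-12 * max(1.0, vols[0]), 0.0, bin_volumes)
    return DifferentialDVH(levels, bin_volumes, organ_label=cdvh.organ_label)


def _require_differential(dvh) -> DifferentialDVH:
    if isinstance(dvh, DifferentialDVH):
        return dvh
    if isinstance(dvh, CumulativeDVH):
        return differential_from_cumulative(dvh)
    raise TypeError("expected a DifferentialDVH or CumulativeDVH")


def volume_at_dose(dvh, x: float, relative: bool = True) -> float:
    """V_x: organ volume receiving more than ``x`` Gy.

    A bin contributes if its center dose exceeds ``x``.  Relative output is %
    of V_0 (default, the reporting convention for V_x); absolute is cm3.
    """
    if x < 0:
        raise ValueError("dose threshold must be non-negative")
    d = _require_differential(dvh)
    vol = float(d.bin_volumes[d.bin_centers > x].sum())
    if relative:
        v0 = d.total_volume
        if v0 <= 0:
            raise ValueError("empty organ: total volume is zero")
        return 100.0 * vol / v0
    return vol


def dose_at_volume(dvh, y: float) -> float:
    """D_y: the smallest dose at which the relative volume-at-or-above drops
    below y %, linearly interpolated between dose levels.

    Differential input is sampled at bin centers (each level carries the
    volume at or above its bin), so a uniform-dose organ returns the same
    dose for every y — D_2 = D_50 = D_98 and HI = 0 exactly.  D_100 is the
    minimum organ dose; y below the top-bin volume clamps to the highest
    level.
    """
    if not 0 < y <= 100:
        raise ValueError("y must be in (0, 100] percent")
    if isinstance(dvh, DifferentialDVH):
        v0 = dvh.total_volume
        if v0 <= 0:
            raise ValueError("empty organ: total volume is zero")
        levels = dvh.bin_centers
        vols = 100.0 * np.cumsum(dvh.bin_volumes[::-1])[::-1] / v0
    elif isinstance(dvh, CumulativeDVH):
        v0 = dvh.total_volume
        if v0 <= 0:
            raise ValueError("empty organ: total volume is zero")
        levels = dvh.dose_levels
        vols = dvh.volume_at_or_above
        if dvh.normalization != "relative":
            vols = 100.0 * vols / v0
    else:
        raise TypeError("expected a DifferentialDVH or CumulativeDVH")
    below = np.nonzero(vols < y)[0]
    if below.size == 0:  # y at or below the terminal volume: highest level
        return float(levels[-1])
    j = below[0]
    if j == 0:
        return float(levels[0])
    v_hi, v_lo = vols[j - 1], vols[j]
    frac = (v_hi - y) / (v_hi - v_lo)
    return float(levels[j - 1] + frac * (levels[j] - levels[j - 1]))


def mean_dose(dvh) -> float:
    """Volume-weighted mean dose over bin centers (Gy)."""
    d = _require_differential(dvh)
    v0 = d.total_volume
    if v0 <= 0:
        raise ValueError("empty organ: total volume is zero")
    return float(np.dot(d.bin_volumes, d.bin_centers) / v0)


def max_dose(dvh) -> float:
    """Upper edge of the highest occupied dose bin (Gy)."""
    d = _require_differential(dvh)
    occupied = np.nonzero(d.bin_volumes > 0)[0]
    if occupied.size == 0:
        raise ValueError("empty organ: no occupied dose bin")
    return float(d.bin_edges[occupied[-1] + 1])


# ---------------------------------------------------------------------------
# CSV dialect: header organ,type,dose_gy,volume; one row per differential bin
# edge (n+1 rows, the last carries the top edge with volume 0) or per
# cumulative level; UTF-8, '.' decimal.
# ---------------------------------------------------------------------------

def write_dvh_csv(path, dvhs: Iterable[DifferentialDVH | CumulativeDVH]) -> None:
    """Write one or more DVHs to a CSV file in the package dialect."""
    rows = []
    for dvh in dvhs:
        if isinstance(dvh, DifferentialDVH):
            doses = dvh.bin_edges
            vols = np.append(dvh.bin_volumes, 0.0)
            kind = "differential"
        elif isinstance(dvh, CumulativeDVH):
            doses = dvh.dose_levels
            vols = dvh.volume_at_or_above
            kind = f"cumulative_{dvh.normalization}"
        else:
            raise TypeError("expected DVH objects")
        for d, v in zip(doses, vols):
            rows.append((dvh.organ_label, kind, d, v))
    frame = pd.DataFrame(rows, columns=["organ", "type", "dose_gy", "volume"])
    frame.to_csv(path, index=False, float_format="%.10g")


def read_dvh_csv(path) -> list[DifferentialDVH | CumulativeDVH]:
    """Read DVHs written by :func:`write_dvh_csv`."""
    frame = pd.read_csv(path)
    required = {"organ", "type", "dose_gy", "volume"}
    if not required.issubset(frame.columns):
        raise ValueError(f"DVH CSV must have columns {sorted(required)}")
    out: list[DifferentialDVH | CumulativeDVH] = []
    for (organ, kind), part in frame.groupby(["organ", "type"], sort=False):
        doses = part["dose_gy"].to_numpy(dtype=float)
        vols = part["volume"].to_numpy(dtype=float)
        if kind == "differential":
            out.append(DifferentialDVH(doses, vols[:-1], organ_label=str(organ)))
        elif kind in ("cumulative_absolute", "cumulative_relative"):
            out.append(
                CumulativeDVH(
                    doses,
                    vols,
                    normalization=kind.split("_", 1)[1],
                    organ_label=str(organ),
                )
            )
        else:
            raise ValueError(f"unknown DVH type {kind!r}")
    return out
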