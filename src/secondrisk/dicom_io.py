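"""Optional DICOM RT-DOSE ingestion.

Adapter producing a :class:`~secondrisk.dvh.DoseGrid` from an RT-DOSE file
or dataset; the core package never depends on it (pydicom is imported here
only).  Structure-set rasterization (RT-STRUCT contours to OrganMask) is
out of the adapter's scope — masks are expected on the dose lattice
already, e.g. from an upstream contouring tool.
"""

from __future__ import annotations

import numpy as np

from .dvh import DoseGrid

__all__ = ["dose_grid_from_rtdose"]


def dose_grid_from_rtdose(source) -> DoseGrid:
    """Read an RT-DOSE file (path or pydicom dataset) into a DoseGrid.

    Requires absolute dose in Gy (``DoseUnits == "GY"``) on a regular grid
    with uniform frame spacing.  The DICOM (frame, row, column) = (z, y, x)
    array is transposed to this package's (x = L-R, y = A-P, z = S-I) order.
    """
    import pydicom

    ds = source if isinstance(source, pydicom.Dataset) else pydicom.dcmread(source)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError("not an RT-DOSE dataset")
    if getattr(ds, "DoseUnits", "GY") != "GY":
        raise ValueError("relative-dose RT-DOSE not supported; need absolute Gy")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    if values.ndim == 2:
        values = values[np.newaxis]
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform frame spacing not supported")
    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
    spacing = (dx, dy, float(dz[0]) if dz.size else dx)
    origin = tuple(float(v) for v in getattr(ds, "ImagePositionPatient", (0.0, 0.0, 0.0)))
    return DoseGrid(values.transpose(2, 1, 0), spacing, origin)
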