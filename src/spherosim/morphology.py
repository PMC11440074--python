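"""Per-cell morphometrics on 3D label masks.

Seven features per cell: volume (voxel count), surface (border-voxel
count), major/minor principal axis lengths, eccentricity, volume-to-surface
ratio, and sphericity. A voxel is a border voxel when at least one of its
six face neighbors lies outside the cell (the lattice edge counts as
outside). Axis lengths come from the ellipsoid with the same normalized
second central moments as the voxel set, so they match
``skimage.measure.regionprops`` conventions; eccentricity is defined from
the extreme axes as ``sqrt(1 - (minor/major)^2)`` and sphericity as
``pi^(1/3) * (6 V)^(2/3) / surface``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .io_formats import LabelVolume

__all__ = ["FEATURE_COLUMNS", "compute_features", "border_voxel_surface"]

#: Feature columns, in canonical order, used for similarity scoring.
FEATURE_COLUMNS = (
    "volume",
    "surface",
    "v_over_a",
    "sphericity",
    "major_axis",
    "minor_axis",
    "eccentricity",
)

_ALL_COLUMNS = ("cell_id",) + FEATURE_COLUMNS


def border_voxel_surface(lattice: np.ndarray) -> dict[int, int]:
    """Count border voxels per label: cell voxels with a face neighbor outside the cell."""
    padded = np.pad(lattice, 1, constant_values=-1)
    border = np.zeros_like(lattice, dtype=bool)
    core = (slice(1, -1),) * 3
    for axis in range(3):
        for shift in (1, -1):
            border |= np.roll(padded, shift, axis=axis)[core] != lattice
    border &= lattice > 0
    ids = lattice[border]
    if ids.size == 0:
        return {}
    counts = np.bincount(ids)
    return {int(i): int(counts[i]) for i in np.nonzero(counts)[0] if i > 0}


def compute_features(vol: LabelVolume) -> pd.DataFrame:
    """One row of the seven features per nonzero label, sorted by cell_id."""
    lattice = vol.lattice
    ids, volumes = np.unique(lattice[lattice > 0], return_counts=True)
    if ids.size == 0:
        return pd.DataFrame(columns=list(_ALL_COLUMNS))
    surface = border_voxel_surface(lattice)
    axes: dict[int, tuple[float, float]] = {}
    for prop in regionprops(lattice):
        try:
            major = float(prop.axis_major_length)
            minor = float(prop.axis_minor_length)
        except ValueError:  # degenerate moment matrix (e.g. single voxel line)
            major = minor = 0.0
        axes[int(prop.label)] = (major, minor)

    rows = []
    for lab, v in zip(ids, volumes):
        lab = int(lab)
        a = surface[lab]
        major, minor = axes[lab]
        ecc = float(np.sqrt(1.0 - (minor / major) ** 2)) if major > 0 else 0.0
        rows.append(
            {
                "cell_id": lab,
                "volume": float(v),
                "surface": float(a),
                "v_over_a": float(v) / a,
                "sphericity": float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a),
                "major_axis": major,
                "minor_axis": minor,
                "eccentricity": ecc,
            }
        )
    return pd.DataFrame(rows, columns=list(_ALL_COLUMNS))
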