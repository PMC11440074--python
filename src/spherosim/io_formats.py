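"""Readers and writers for the formats the pipeline touches.

Three families of I/O live here:

* multi-page TIFF label stacks (z as the page axis) with a JSON sidecar
  carrying voxel spacing and provenance,
* the CompuCell3D Potts Initial File (PIF) text format, one record per
  line with inclusive coordinate ranges,
* tabular feature CSVs and JSON score reports.

The in-memory axis convention is ``(x, y, z)`` with ``z`` the slice axis;
on disk TIFF pages are z-slices, so arrays are transposed on the way in
and out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LabelVolume",
    "PifRecord",
    "read_label_tiff",
    "write_label_tiff",
    "write_pif",
    "read_pif",
    "write_feature_table",
    "read_feature_table",
    "write_report",
    "read_report",
    "DEFAULT_CELLTYPE",
    "RESERVED_CELLTYPES",
]

#: Celltype token emitted for every segmented cell (single-cell-type model).
DEFAULT_CELLTYPE = "Cell"
#: Tokens that must not be assigned to segmented labels.
RESERVED_CELLTYPES = frozenset({"Wall", "Medium"})


@dataclass
class LabelVolume:
    """A 3D integer lattice of cell IDs plus physical voxel spacing.

    ``lattice[x, y, z]`` holds the cell ID at that voxel; 0 is medium.
    ``spacing`` is ``(dx, dy, dz)`` in micrometres.
    """

    lattice: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.lattice = np.asarray(self.lattice)
        if self.lattice.ndim != 3:
            raise ValueError(f"lattice must be 3D, got ndim={self.lattice.ndim}")
        if not np.issubdtype(self.lattice.dtype, np.integer):
            raise TypeError(f"lattice must be integer-typed, got {self.lattice.dtype}")
        if any(s < 1 for s in self.lattice.shape):
            raise ValueError(f"lattice dimensions must each be >= 1, got {self.lattice.shape}")
        if self.lattice.size and self.lattice.min() < 0:
            raise ValueError("lattice contains negative IDs")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.lattice.shape)

    def labels(self) -> np.ndarray:
        """Sorted array of nonzero cell IDs present in the lattice."""
        ids = np.unique(self.lattice)
        return ids[ids > 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.lattice.copy(), self.spacing)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (
            self.lattice.shape == other.lattice.shape
            and bool(np.array_equal(self.lattice, other.lattice))
            and self.spacing == other.spacing
        )


@dataclass(frozen=True)
class PifRecord:
    """One PIF line: a cell ID, a celltype token, and an inclusive box."""

    cell_id: int
    celltype: str
    x1: int
    x2: int
    y1: int
    y2: int
    z1: int
    z2: int

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError(f"cell_id must be positive, got {self.cell_id}")
        for lo, hi, ax in ((self.x1, self.x2, "x"), (self.y1, self.y2, "y"), (self.z1, self.z2, "z")):
            if lo < 0:
                raise ValueError(f"negative {ax} coordinate: {lo}")
            if lo > hi:
                raise ValueError(f"{ax}1 > {ax}2 ({lo} > {hi})")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_label_tiff(vol: LabelVolume, path: str | Path, extra: Mapping | None = None) -> Path:
    """Write a LabelVolume as a multi-page int32 TIFF plus a JSON sidecar.

    Pages are z-slices; the sidecar records voxel spacing and any ``extra``
    metadata (e.g. a synthetic-generation manifest).
    """
    path = Path(path)
    pages = np.ascontiguousarray(vol.lattice.transpose(2, 1, 0)).astype(np.int32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {"spacing": list(vol.spacing), "axis_order": "xyz", "shape_xyz": list(vol.shape)}
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_label_tiff(path: str | Path, spacing: tuple[float, float, float] | None = None) -> LabelVolume:
    """Read a multi-page TIFF label stack into a LabelVolume.

    Spacing is taken from the JSON sidecar written by :func:`write_label_tiff`
    unless explicitly supplied; a stack with neither is an error — spacing is
    never guessed silently.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(f"label TIFF must be integer-typed, got dtype {data.dtype}")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D or 3D stack, got ndim={data.ndim}")
    if spacing is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no voxel spacing for {path}: sidecar {sidecar.name} missing and none supplied"
            )
        spacing = tuple(json.loads(sidecar.read_text())["spacing"])
    return LabelVolume(data.transpose(2, 1, 0), spacing)


def write_pif(
    vol: LabelVolume,
    celltype_map: Mapping[int, str] | None = None,
    default_celltype: str = DEFAULT_CELLTYPE,
) -> str:
    """Render a LabelVolume as PIF text, one line per nonzero voxel.

    Line syntax is ``cell_ID celltype x1 x2 y1 y2 z1 z2`` with both
    coordinates of each axis equal (single-voxel records). Medium voxels
    emit no line. Voxel order is canonical: z-major, then y, then x.
    """
    ids = vol.labels()
    celltype_map = dict(celltype_map or {})
    for i in ids:
        i = int(i)
        if i not in celltype_map:
            celltype_map[i] = default_celltype
        if celltype_map[i] in RESERVED_CELLTYPES:
            raise ValueError(f"celltype {celltype_map[i]!r} is reserved (cell {i})")
    missing = [int(i) for i in ids if celltype_map.get(int(i)) is None]
    if missing:
        raise ValueError(f"no celltype token for cell IDs {missing}")

    # z-major ordering: iterate the (z, y, x) view so np.argwhere scans canonically
    zyx = vol.lattice.transpose(2, 1, 0)
    coords = np.argwhere(zyx != 0)
    lines = []
    for z, y, x in coords:
        cid = int(zyx[z, y, x])
        lines.append(f"{cid} {celltype_map[cid]} {x} {x} {y} {y} {z} {z}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_pif(
    text: str,
    shape: tuple[int, int, int] | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[LabelVolume, dict[int, str]]:
    """Parse PIF text into a LabelVolume and a cell-ID → celltype map.

    Coordinate ranges are inclusive on both ends and expanded into voxels;
    later lines overwrite earlier ones on collision. Without an explicit
    ``shape`` the minimal enclosing lattice is returned.
    """
    records: list[PifRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 8:
            raise ValueError(f"PIF line {lineno}: expected 8 fields, got {len(parts)}: {raw!r}")
        try:
            cid = int(parts[0])
            x1, x2, y1, y2, z1, z2 = (int(p) for p in parts[2:])
        except ValueError as exc:
            raise ValueError(f"PIF line {lineno}: non-integer field in {raw!r}") from exc
        try:
            records.append(PifRecord(cid, parts[1], x1, x2, y1, y2, z1, z2))
        except ValueError as exc:
            raise ValueError(f"PIF line {lineno}: {exc}") from exc

    if shape is None:
        if not records:
            shape = (1, 1, 1)
        else:
            shape = (
                max(r.x2 for r in records) + 1,
                max(r.y2 for r in records) + 1,
                max(r.z2 for r in records) + 1,
            )
    lattice = np.zeros(shape, dtype=np.int32)
    celltypes: dict[int, str] = {}
    for r in records:
        if r.x2 >= shape[0] or r.y2 >= shape[1] or r.z2 >= shape[2]:
            raise ValueError(f"record for cell {r.cell_id} exceeds lattice shape {shape}")
        lattice[r.x1 : r.x2 + 1, r.y1 : r.y2 + 1, r.z1 : r.z2 + 1] = r.cell_id
        celltypes[r.cell_id] = r.celltype
    return LabelVolume(lattice, spacing), celltypes


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-cell feature table as CSV with stable column order.

    Floats use 17 significant digits so numeric values round-trip losslessly.
    """
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_report(report, path: str | Path) -> Path:
    """Serialize a score report (any object with ``to_dict``, or a dict) as JSON."""
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
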