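"""Label-mask cleanup and isotropic resampling.

Stages, applied in this fixed order by :func:`preprocess_pipeline`:

1. remove labels smaller than a voxel-count threshold,
2. per-label morphological closing then opening,
3. merge or delete "thin" labels confined to one or two z-planes,
4. nearest-neighbor z-upsampling to an isotropic voxel size.

Stages never invent new IDs (a thin-label merge reuses the lowest
participating ID) and the nonzero-voxel count never grows in the removal
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import LabelVolume

__all__ = [
    "PreprocessConfig",
    "PreprocessLog",
    "remove_small_labels",
    "close_open_labels",
    "resolve_thin_labels",
    "upsample_isotropic",
    "preprocess_pipeline",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PreprocessConfig:
    min_volume: int = 5
    max_thin_planes: int = 2
    closing_radius: int = 1
    opening_radius: int = 1

    def __post_init__(self) -> None:
        if self.min_volume < 1:
            raise ValueError(f"min_volume must be >= 1, got {self.min_volume}")
        if self.max_thin_planes < 1:
            raise ValueError(f"max_thin_planes must be >= 1, got {self.max_thin_planes}")
        if self.closing_radius < 0 or self.opening_radius < 0:
            raise ValueError("structuring-element radii must be >= 0")


@dataclass
class PreprocessLog:
    """IDs touched by each stage."""

    removed_small: list[int] = field(default_factory=list)
    changed_morphology: list[int] = field(default_factory=list)
    merged_thin: dict[int, int] = field(default_factory=dict)  # absorbed ID -> surviving ID
    deleted_thin: list[int] = field(default_factory=list)
    upsampled: bool = False

    def to_dict(self) -> dict:
        return {
            "removed_small": [int(i) for i in self.removed_small],
            "changed_morphology": [int(i) for i in self.changed_morphology],
            "merged_thin": {str(k): int(v) for k, v in self.merged_thin.items()},
            "deleted_thin": [int(i) for i in self.deleted_thin],
            "upsampled": self.upsampled,
        }


def _volumes(lattice: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids, counts = np.unique(lattice[lattice > 0], return_counts=True)
    return ids, counts


def remove_small_labels(
    vol: LabelVolume, min_volume: int = 5, log: PreprocessLog | None = None
) -> LabelVolume:
    """Delete labels with a volume strictly smaller than ``min_volume`` voxels."""
    ids, counts = _volumes(vol.lattice)
    small = ids[counts < min_volume]
    if log is not None:
        log.removed_small.extend(int(i) for i in small)
    if len(small) == 0:
        return vol.copy()
    lattice = vol.lattice.copy()
    lattice[np.isin(lattice, small)] = 0
    return LabelVolume(lattice, vol.spacing)


def _ball_structure(radius: int) -> np.ndarray:
    # Chebyshev (L-inf) ball: the full (2r+1)^3 cube. The Euclidean r=1 ball
    # is the 6-cross, whose opening shaves the edges of every convex solid;
    # the box SE leaves axis-aligned convex labels untouched.
    n = 2 * radius + 1
    return np.ones((n, n, n), dtype=bool)


def close_open_labels(vol: LabelVolume, cfg: PreprocessConfig = PreprocessConfig()) -> LabelVolume:
    """Morphologically close then open each label independently.

    Each label's binary mask is processed on its own (grayscale morphology on
    the raw ID image would mix labels). Conflicts are resolved in favor of
    the original owner: a label may only claim voxels that were medium, and
    a lower ID wins a contested medium voxel. A label whose opening would
    erase it entirely is kept unchanged — deletion is the job of the explicit
    size/thinness filters, not the smoothing stage.
    """
    if cfg.closing_radius == 0 and cfg.opening_radius == 0:
        return vol.copy()
    orig = vol.lattice
    out = np.zeros_like(orig)
    pad = max(cfg.closing_radius, cfg.opening_radius) + 1
    close_se = _ball_structure(cfg.closing_radius)
    open_se = _ball_structure(cfg.opening_radius)
    objects = ndimage.find_objects(orig)
    for lab in np.unique(orig):
        if lab == 0:
            continue
        sl = objects[int(lab) - 1] if int(lab) - 1 < len(objects) else None
        if sl is None:  # non-dense labels: fall back to full-volume slice
            sl = tuple(slice(0, s) for s in orig.shape)
        window = tuple(
            slice(max(0, s.start - pad), min(dim, s.stop + pad))
            for s, dim in zip(sl, orig.shape)
        )
        mask = orig[window] == lab
        proc = mask
        if cfg.closing_radius > 0:
            proc = ndimage.binary_closing(proc, structure=close_se)
        if cfg.opening_radius > 0:
            proc = ndimage.binary_opening(proc, structure=open_se)
        if not proc.any():
            proc = mask
        owner_ok = (orig[window] == lab) | ((orig[window] == 0) & (out[window] == 0))
        out_w = out[window]
        out_w[proc & owner_ok] = lab
    return LabelVolume(out, vol.spacing)


def _z_extents(lattice: np.ndarray) -> dict[int, int]:
    """z-plane span (count of planes in the bounding box) per label."""
    extents: dict[int, int] = {}
    for lab, sl in enumerate(ndimage.find_objects(lattice), start=1):
        if sl is not None:
            extents[lab] = sl[2].stop - sl[2].start
    # find_objects misses nothing for positive dense labels, but IDs may be sparse
    present = set(int(i) for i in np.unique(lattice) if i > 0)
    for lab in present - set(extents):
        zs = np.unique(np.argwhere(lattice == lab)[:, 2])
        extents[lab] = int(zs.max() - zs.min() + 1)
    return {k: v for k, v in extents.items() if k in present}


def _adjacency_pairs(lattice: np.ndarray) -> set[tuple[int, int]]:
    """Unordered pairs of distinct labels sharing at least one face."""
    pairs: set[tuple[int, int]] = set()
    for axis in range(3):
        a = np.moveaxis(lattice, axis, 0)[:-1]
        b = np.moveaxis(lattice, axis, 0)[1:]
        diff = (a != b) & (a > 0) & (b > 0)
        if diff.any():
            for u, v in zip(a[diff].ravel(), b[diff].ravel()):
                pairs.add((int(min(u, v)), int(max(u, v))))
    return pairs


def resolve_thin_labels(
    vol: LabelVolume, max_thin_planes: int = 2, log: PreprocessLog | None = None
) -> LabelVolume:
    """Merge chains of face-adjacent thin labels; delete orphan thin labels.

    A label is "thin" when its z-extent is at most ``max_thin_planes``
    planes. Thin labels that touch other thin labels merge under the lowest
    participating ID (transitively, so chains collapse to one label); a thin
    label whose neighbors are all non-thin, or that has no labelled
    neighbor, is deleted. Non-thin labels never change.
    """
    lattice = vol.lattice.copy()
    extents = _z_extents(lattice)
    thin = {lab for lab, ext in extents.items() if ext <= max_thin_planes}
    if not thin:
        return LabelVolume(lattice, vol.spacing)

    pairs = _adjacency_pairs(lattice)
    # union-find over thin-thin adjacencies
    parent = {lab: lab for lab in thin}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    thin_has_thin_neighbor: set[int] = set()
    for u, v in pairs:
        if u in thin and v in thin:
            thin_has_thin_neighbor.update((u, v))
            ru, rv = find(u), find(v)
            if ru != rv:
                lo, hi = min(ru, rv), max(ru, rv)
                parent[hi] = lo

    for lab in sorted(thin):
        if lab in thin_has_thin_neighbor:
            root = find(lab)
            if root != lab:
                lattice[lattice == lab] = root
                if log is not None:
                    log.merged_thin[lab] = root
        else:
            lattice[lattice == lab] = 0
            if log is not None:
                log.deleted_thin.append(lab)
    return LabelVolume(lattice, vol.spacing)


def upsample_isotropic(vol: LabelVolume, log: PreprocessLog | None = None) -> LabelVolume:
    """Nearest-neighbor upsample along z to match the x-y voxel size.

    The new slice count is ``n_z * dz / dx`` rounded half away from zero.
    Every output slice is an exact copy of some input slice; x and y are
    untouched and the output spacing is isotropic.
    """
    dx, dy, dz = vol.spacing
    if not np.isclose(dx, dy, rtol=1e-9, atol=0.0):
        raise ValueError(f"x-y spacing must be isotropic, got dx={dx}, dy={dy}")
    if dz < dx:
        raise ValueError(f"dz must be >= dx for z-upsampling, got dz={dz}, dx={dx}")
    n_z = vol.shape[2]
    ratio = dz / dx
    new_nz = int(np.floor(n_z * ratio + 0.5))  # round half away from zero (positive input)
    if new_nz == n_z:
        out = LabelVolume(vol.lattice.copy(), (dx, dx, dx))
    else:
        # nearest source slice for each output slice center
        src = np.floor((np.arange(new_nz) + 0.5) * n_z / new_nz).astype(np.int64)
        np.clip(src, 0, n_z - 1, out=src)
        out = LabelVolume(vol.lattice[:, :, src], (dx, dx, dx))
    if log is not None:
        log.upsampled = new_nz != n_z
    return out


def preprocess_pipeline(
    vol: LabelVolume,
    cfg: PreprocessConfig = PreprocessConfig(),
    upsample: bool = True,
) -> tuple[LabelVolume, PreprocessLog]:
    """Run the full cleanup: remove-small → close/open → resolve-thin → upsample."""
    log = PreprocessLog()
    out = remove_small_labels(vol, cfg.min_volume, log=log)
    before = out.lattice
    out = close_open_labels(out, cfg)
    changed = np.unique(np.concatenate([before[before != out.lattice], out.lattice[before != out.lattice]]))
    log.changed_morphology = sorted(int(i) for i in changed if i > 0)
    out = resolve_thin_labels(out, cfg.max_thin_planes, log=log)
    if upsample:
        out = upsample_isotropic(out, log=log)
    return out, log
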