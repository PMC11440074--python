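"""Synthetic spheroid label masks with controllable segmentation artifacts.

The generator packs a digital ball with the Voronoi cells of jittered grid
seed points, producing convex-ish, space-filling labels that resemble a
segmented cell aggregate. A separate injector plants the artifact classes
a real segmentation exhibits — sub-threshold debris, labels confined to
one or two z-planes, and over/under-sized cells — and returns a manifest
so downstream cleanup can be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import LabelVolume

__all__ = ["SpheroidSpec", "ArtifactSpec", "ArtifactManifest", "generate_spheroid", "inject_artifacts"]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class SpheroidSpec:
    """Recipe for one synthetic spheroid; identical specs give bit-identical volumes."""

    n_cells: int
    radius: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    jitter: float = 0.35

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.radius < 2:
            raise ValueError(f"radius must be >= 2, got {self.radius}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.jitter < 0:
            raise ValueError(f"jitter must be >= 0, got {self.jitter}")


@dataclass(frozen=True)
class ArtifactSpec:
    """Counts of each artifact class to inject."""

    n_debris: int = 0
    n_slivers: int = 0
    n_outliers: int = 0

    def __post_init__(self) -> None:
        if min(self.n_debris, self.n_slivers, self.n_outliers) < 0:
            raise ValueError("artifact counts must be >= 0")


@dataclass
class ArtifactManifest:
    """Which labels were injected/altered, for exact verification downstream."""

    debris_ids: list[int] = field(default_factory=list)
    sliver_ids: list[int] = field(default_factory=list)
    outlier_ids: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "debris_ids": [int(i) for i in self.debris_ids],
            "sliver_ids": [int(i) for i in self.sliver_ids],
            "outlier_ids": [int(i) for i in self.outlier_ids],
        }


#: Medium margin around the generated aggregate (lets a wall shell be added
#: later without touching any cell).
_PAD = 2


def _ball_mask(radius: int) -> np.ndarray:
    n = 2 * radius + 1 + 2 * _PAD
    ax = np.arange(n) - (radius + _PAD)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= radius * radius


def generate_spheroid(spec: SpheroidSpec, return_seeds: bool = False):
    """Voronoi-pack a digital ball with ``n_cells`` labels.

    Seed points are drawn from a jittered cubic grid restricted to the
    ball; every ball voxel is assigned to its nearest seed, then stray
    digitization fragments are reabsorbed so each label is 6-connected.
    Label IDs are 1..n_cells. Raises if the ball cannot hold ``n_cells``
    voxels. With ``return_seeds`` the (lattice-frame) seed coordinates of
    each label are returned alongside, for verification.
    """
    rng = np.random.default_rng(spec.seed)
    ball = _ball_mask(spec.radius)
    ball_voxels = np.argwhere(ball)
    if spec.n_cells > len(ball_voxels):
        raise ValueError(
            f"cannot pack {spec.n_cells} cells into a ball of {len(ball_voxels)} voxels"
        )

    # Cubic grid with pitch giving roughly n_cells sites inside the ball.
    pitch = max(1.0, (len(ball_voxels) / spec.n_cells) ** (1.0 / 3.0))
    grid_1d = np.arange(-spec.radius, spec.radius + 1e-9, pitch)
    gx, gy, gz = np.meshgrid(grid_1d, grid_1d, grid_1d, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(grid, axis=1) <= spec.radius * 0.95
    candidates = grid[inside]
    center = spec.radius + _PAD
    if len(candidates) < spec.n_cells:
        # fall back to random interior voxels for the shortfall
        extra_idx = rng.choice(len(ball_voxels), size=spec.n_cells, replace=False)
        candidates = np.vstack([candidates, ball_voxels[extra_idx] - center])
    chosen = candidates[rng.choice(len(candidates), size=spec.n_cells, replace=False)]
    seeds = chosen + rng.normal(scale=spec.jitter * pitch, size=chosen.shape)
    # keep jittered seeds inside the ball
    norms = np.linalg.norm(seeds, axis=1)
    over = norms > spec.radius * 0.98
    if over.any():
        seeds[over] *= (spec.radius * 0.98 / norms[over])[:, None]

    tree = cKDTree(seeds)
    _, owner = tree.query(ball_voxels - center)
    lattice = np.zeros(ball.shape, dtype=np.int32)
    lattice[tuple(ball_voxels.T)] = owner + 1
    _reabsorb_fragments(lattice)
    # guarantee every label survived fragment repair
    present = np.unique(lattice)
    missing = set(range(1, spec.n_cells + 1)) - set(int(i) for i in present)
    if missing:  # pragma: no cover - repair only removes non-largest fragments
        raise RuntimeError(f"labels lost during generation: {sorted(missing)}")
    vol = LabelVolume(lattice, spec.spacing)
    if return_seeds:
        return vol, seeds + center
    return vol


def _reabsorb_fragments(lattice: np.ndarray) -> None:
    """Reassign non-largest 6-connected fragments of each label to a face neighbor."""
    for _ in range(20):
        changed = False
        for lab in np.unique(lattice):
            if lab == 0:
                continue
            mask = lattice == lab
            comp, n = ndimage.label(mask, structure=_FACE_STRUCT)
            if n <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, n + 1):
                if c == keep:
                    continue
                frag = comp == c
                # majority face-neighbor label (excluding this label)
                dil = ndimage.binary_dilation(frag, structure=_FACE_STRUCT) & ~frag
                neigh = lattice[dil]
                neigh = neigh[(neigh != lab) & (neigh != 0)]
                if len(neigh):
                    target = int(np.bincount(neigh).argmax())
                    lattice[frag] = target
                else:
                    lattice[frag] = 0
                changed = True
        if not changed:
            return
    raise RuntimeError("fragment repair did not converge")  # pragma: no cover


def inject_artifacts(
    vol: LabelVolume, art: ArtifactSpec, seed: int = 0
) -> tuple[LabelVolume, ArtifactManifest]:
    """Plant segmentation artifacts into a clean volume.

    Adds exactly ``n_debris`` new labels of 1–4 voxels and ``n_slivers``
    new labels spanning at most two z-planes, both placed in medium
    adjacent to the aggregate surface, and rescales ``n_outliers``
    existing cells out of the valid size band (below 15 % of the mean
    volume, or above mean + 2 SD, by erosion/dilation). Labels absent
    from the returned manifest are voxel-identical before and after,
    except where an outlier grew into medium.
    """
    if not (vol.lattice != 0).any():
        raise ValueError("cannot inject artifacts into an empty volume")
    rng = np.random.default_rng(seed)
    lattice = vol.lattice.copy()
    manifest = ArtifactManifest()
    next_id = int(lattice.max()) + 1

    surface_medium = _surface_medium_voxels(lattice)
    rng.shuffle(surface_medium)
    cursor = 0

    for _ in range(art.n_debris):
        size = int(rng.integers(1, 5))
        cursor = _grow_patch(lattice, surface_medium, cursor, next_id, size, max_z_planes=None, rng=rng)
        manifest.debris_ids.append(next_id)
        next_id += 1

    for _ in range(art.n_slivers):
        size = int(rng.integers(6, 13))
        n_planes = int(rng.integers(1, 3))
        cursor = _grow_patch(lattice, surface_medium, cursor, next_id, size, max_z_planes=n_planes, rng=rng)
        manifest.sliver_ids.append(next_id)
        next_id += 1

    if art.n_outliers:
        _rescale_outliers(lattice, art.n_outliers, manifest, rng)

    return LabelVolume(lattice, vol.spacing), manifest


def _surface_medium_voxels(lattice: np.ndarray) -> np.ndarray:
    fg = lattice != 0
    shell = ndimage.binary_dilation(fg, structure=_FACE_STRUCT, iterations=2) & ~fg
    # keep off the lattice faces so injected labels never touch the boundary
    shell[0, :, :] = shell[-1, :, :] = False
    shell[:, 0, :] = shell[:, -1, :] = False
    shell[:, :, 0] = shell[:, :, -1] = False
    return np.argwhere(shell)


def _grow_patch(lattice, candidates, cursor, new_id, size, max_z_planes, rng) -> int:
    """Grow a ``size``-voxel 6-connected patch of ``new_id`` in medium; returns new cursor."""
    while cursor < len(candidates):
        start = tuple(candidates[cursor])
        cursor += 1
        if lattice[start] != 0:
            continue
        placed = [start]
        lattice[start] = new_id
        frontier = [start]
        while len(placed) < size and frontier:
            x, y, z = frontier.pop(0)
            nbrs = [(x + 1, y, z), (x - 1, y, z), (x, y + 1, z), (x, y - 1, z), (x, y, z + 1), (x, y, z - 1)]
            rng.shuffle(nbrs)
            for nx, ny, nz in nbrs:
                if len(placed) >= size:
                    break
                if not all(1 <= c < s - 1 for c, s in zip((nx, ny, nz), lattice.shape)):
                    continue
                if lattice[nx, ny, nz] != 0:
                    continue
                if max_z_planes is not None:
                    zs = {p[2] for p in placed} | {nz}
                    if max(zs) - min(zs) + 1 > max_z_planes:
                        continue
                lattice[nx, ny, nz] = new_id
                placed.append((nx, ny, nz))
                frontier.append((nx, ny, nz))
        if len(placed) == size:
            return cursor
        for p in placed:  # could not reach target size here; retry elsewhere
            lattice[p] = 0
    raise ValueError("no room to inject artifact label")


def _rescale_outliers(lattice, n_outliers, manifest: ArtifactManifest, rng) -> None:
    ids, counts = np.unique(lattice[lattice > 0], return_counts=True)
    if n_outliers > len(ids):
        raise ValueError(f"cannot make {n_outliers} outliers from {len(ids)} cells")
    mean_v = counts.mean()
    sd_v = counts.std(ddof=1) if len(counts) > 1 else 0.0
    chosen = rng.choice(ids, size=n_outliers, replace=False)
    for k, lab in enumerate(chosen):
        if k % 2 == 0:
            _shrink_below(lattice, int(lab), 0.15 * mean_v)
        else:
            _grow_above(lattice, int(lab), mean_v + 2 * sd_v)
        manifest.outlier_ids.append(int(lab))


def _shrink_below(lattice, lab, threshold) -> None:
    mask = lattice == lab
    while mask.sum() >= max(threshold, 2):
        eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT)
        if not eroded.any():
            # keep a single voxel rather than deleting the cell
            keep = tuple(np.argwhere(mask)[0])
            mask[:] = False
            mask[keep] = True
            break
        mask = eroded
    lattice[(lattice == lab) & ~mask] = 0


def _grow_above(lattice, lab, threshold) -> None:
    mask = lattice == lab
    for _ in range(200):
        if mask.sum() > threshold:
            break
        grown = ndimage.binary_dilation(mask, structure=_FACE_STRUCT)
        room = grown & (lattice == 0) & ~mask
        # never grow onto the lattice faces
        room[0, :, :] = room[-1, :, :] = False
        room[:, 0, :] = room[:, -1, :] = False
        room[:, :, 0] = room[:, :, -1] = False
        if not room.any():
            raise ValueError(f"no medium room to grow outlier cell {lab}")
        mask |= room
        lattice[room] = lab
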