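"""A minimal 3D Cellular Potts engine with Metropolis dynamics.

The energy of a configuration is

    H = sum_i lambda_V (V_i - V_i^target)^2
      + sum_i lambda_A (A_i - A_i^target)^2
      + J_cc * (total cell-cell contact area)
      + J_cm * (total cell-medium contact area)
      + J_cw * (total cell-wall contact area)

where ``V_i`` is cell i's voxel count and ``A_i`` its face-contact surface
(number of lattice faces between a voxel of i and a voxel of anything
else). Contact areas are counted over face neighbors (order 1); copy
attempts draw the candidate from the 26-neighborhood. One Monte Carlo
step (MCS) is one copy attempt per interior lattice site.

A one-voxel frozen "Wall" shell lines the lattice boundary; wall voxels
are never the source nor the target of a copy, which realizes fixed
boundary conditions and keeps cells off the box edge. The medium (ID 0)
is unconstrained: it has no target volume or surface and no lambda terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import LabelVolume

__all__ = [
    "MEDIUM_ID",
    "ModelParams",
    "PottsState",
    "Trajectory",
    "assign_targets",
    "init_state",
    "hamiltonian",
    "delta_H",
    "metropolis_accept",
    "mcs_step",
    "run_simulation",
    "face_contact_surfaces",
]

MEDIUM_ID = 0

# entity kinds used by the kernels
_KIND_MEDIUM = 0
_KIND_CELL = 1
_KIND_WALL = 2


@dataclass(frozen=True)
class ModelParams:
    """Hamiltonian weights, Metropolis temperature and run bookkeeping.

    Energies are in arbitrary units (J/pix^k); no physical conversion is
    applied. ``temperature`` shares the Hamiltonian's units.
    """

    lambda_V: float = 2.0
    lambda_A: float = 0.001
    J_cc: float = 2.0
    J_cm: float = 55.0
    J_cw: float = 100.0
    temperature: float = 10.0
    contact_neighbor_order: int = 1
    copy_neighborhood: int = 26
    n_mcs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_V < 0 or self.lambda_A < 0:
            raise ValueError("lambda_V and lambda_A must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_mcs < 0:
            raise ValueError("n_mcs must be >= 0")
        if self.contact_neighbor_order != 1:
            raise NotImplementedError("only order-1 (face) contact neighborhoods are supported")
        if self.copy_neighborhood not in (6, 26):
            raise ValueError("copy_neighborhood must be 6 or 26")


def _neighbor_offsets(n: int) -> np.ndarray:
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and (n == 26 or abs(dx) + abs(dy) + abs(dz) == 1)
    ]
    return np.array(offs, dtype=np.int64)


@dataclass
class PottsState:
    """Lattice plus per-cell bookkeeping, evolved in place by the engine.

    ``volumes``/``surfaces``/targets are arrays indexed by cell ID
    (index 0 = medium, ``wall_id`` = wall; both carry no energy terms).
    ``kind`` maps IDs to medium/cell/wall.
    """

    lattice: np.ndarray
    spacing: tuple[float, float, float]
    wall_id: int
    kind: np.ndarray
    volumes: np.ndarray
    surfaces: np.ndarray
    target_volumes: np.ndarray
    target_surfaces: np.ndarray
    rng: np.random.Generator
    mcs_counter: int = 0

    @property
    def cell_ids(self) -> np.ndarray:
        return np.nonzero(self.kind == _KIND_CELL)[0]

    def cells(self) -> pd.DataFrame:
        """Per-cell state table (living and vanished cells)."""
        ids = self.cell_ids
        return pd.DataFrame(
            {
                "cell_id": ids,
                "celltype": "Cell",
                "volume": self.volumes[ids],
                "surface": self.surfaces[ids],
                "target_volume": self.target_volumes[ids],
                "target_surface": self.target_surfaces[ids],
            }
        )

    def to_label_volume(self) -> LabelVolume:
        """Current configuration with the wall shell blanked to medium."""
        lattice = self.lattice.copy()
        lattice[lattice == self.wall_id] = MEDIUM_ID
        return LabelVolume(lattice, self.spacing)

    def copy(self) -> "PottsState":
        return PottsState(
            lattice=self.lattice.copy(),
            spacing=self.spacing,
            wall_id=self.wall_id,
            kind=self.kind.copy(),
            volumes=self.volumes.copy(),
            surfaces=self.surfaces.copy(),
            target_volumes=self.target_volumes.copy(),
            target_surfaces=self.target_surfaces.copy(),
            rng=np.random.default_rng(),  # caller reseeds if determinism is needed
            mcs_counter=self.mcs_counter,
        )


def assign_targets(
    table: pd.DataFrame,
    seed: int = 0,
    surfaces: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign per-cell (V_target, A_target) from measured morphology.

    Cells whose volume lies inside ``[0.15 * mean(V), mean(V) + 2 * sd(V)]``
    keep their own measured volume and surface as targets. Cells outside
    the band receive the (V, A) pair of an in-band donor drawn uniformly
    with ``seed`` — pairs are sampled jointly, never mixed across donors.

    ``surfaces`` optionally overrides the table's ``surface`` column (e.g.
    to constrain the engine's face-contact surface instead of the
    border-voxel metric surface).
    """
    if len(table) == 0:
        raise ValueError("cannot assign targets from an empty feature table")
    vols = table["volume"].to_numpy(dtype=float)
    surf = np.asarray(surfaces, dtype=float) if surfaces is not None else table["surface"].to_numpy(dtype=float)
    if len(surf) != len(vols):
        raise ValueError("surfaces length does not match table")
    mean_v = vols.mean()
    sd_v = vols.std(ddof=1) if len(vols) > 1 else 0.0
    lo, hi = 0.15 * mean_v, mean_v + 2.0 * sd_v
    in_band = (vols >= lo) & (vols <= hi)
    if not in_band.any():
        raise ValueError("no cells fall inside the valid size band; cannot draw donor targets")

    rng = np.random.default_rng(seed)
    tv = vols.copy()
    ta = surf.copy()
    donors = np.nonzero(in_band)[0]
    for i in np.nonzero(~in_band)[0]:
        j = donors[rng.integers(len(donors))]
        tv[i], ta[i] = vols[j], surf[j]
    return pd.DataFrame(
        {
            "cell_id": table["cell_id"].to_numpy(dtype=int),
            "target_volume": tv,
            "target_surface": ta,
            "in_band": in_band,
        }
    )


def face_contact_surfaces(lattice: np.ndarray) -> dict[int, int]:
    """Internal lattice faces between each positive ID and any other ID (incl. medium).

    Faces on the lattice boundary (to the outside of the array) are not
    counted, consistent with the engine's incremental bookkeeping.
    """
    max_id = int(lattice.max()) if lattice.size else 0
    out = np.zeros(max_id + 1, dtype=np.int64)
    for axis in range(3):
        a = np.moveaxis(lattice, axis, 0)[:-1].ravel()
        b = np.moveaxis(lattice, axis, 0)[1:].ravel()
        diff = a != b
        out += np.bincount(a[diff], minlength=max_id + 1)
        out += np.bincount(b[diff], minlength=max_id + 1)
    return {int(i): int(out[i]) for i in range(1, max_id + 1) if out[i] or (lattice == i).any()}


def init_state(
    vol: LabelVolume,
    targets: pd.DataFrame | None = None,
    params: ModelParams = ModelParams(),
) -> PottsState:
    """Wrap a label volume in a PottsState with a one-voxel wall shell.

    The wall claims the boundary layer of the lattice; a cell owning a
    boundary voxel is an error. ``targets`` is the frame returned by
    :func:`assign_targets`; omitted, every cell is its own target
    (volume = voxel count, surface = face-contact count).
    """
    lattice = vol.lattice.astype(np.int64).copy()
    boundary = np.zeros(lattice.shape, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    clash = np.unique(lattice[boundary])
    clash = clash[clash > 0]
    if clash.size:
        raise ValueError(f"cells overlap the wall shell: IDs {clash.tolist()}")

    ids = vol.labels()
    wall_id = (int(ids.max()) if ids.size else 0) + 1
    lattice[boundary] = wall_id

    kind = np.zeros(wall_id + 1, dtype=np.int64)
    kind[wall_id] = _KIND_WALL
    for i in ids:
        kind[int(i)] = _KIND_CELL

    volumes = np.bincount(lattice.ravel(), minlength=wall_id + 1).astype(np.int64)
    face = face_contact_surfaces(lattice)
    surfaces = np.zeros(wall_id + 1, dtype=np.int64)
    for i, a in face.items():
        surfaces[i] = a

    tv = volumes.astype(np.float64).copy()
    ta = surfaces.astype(np.float64).copy()
    if targets is not None:
        for cid, v, a in zip(
            targets["cell_id"].to_numpy(dtype=int),
            targets["target_volume"].to_numpy(dtype=float),
            targets["target_surface"].to_numpy(dtype=float),
        ):
            if cid <= 0 or cid >= wall_id or kind[cid] != _KIND_CELL:
                raise ValueError(f"target row for unknown cell ID {cid}")
            tv[cid], ta[cid] = v, a
    tv[MEDIUM_ID] = ta[MEDIUM_ID] = 0.0
    tv[wall_id] = ta[wall_id] = 0.0

    return PottsState(
        lattice=lattice,
        spacing=vol.spacing,
        wall_id=wall_id,
        kind=kind,
        volumes=volumes,
        surfaces=surfaces,
        target_volumes=tv,
        target_surfaces=ta,
        rng=np.random.default_rng(params.seed),
        mcs_counter=0,
    )


def _contact_energy_matrix(params: ModelParams) -> np.ndarray:
    e = np.zeros((3, 3), dtype=np.float64)
    e[_KIND_CELL, _KIND_CELL] = params.J_cc
    e[_KIND_CELL, _KIND_MEDIUM] = e[_KIND_MEDIUM, _KIND_CELL] = params.J_cm
    e[_KIND_CELL, _KIND_WALL] = e[_KIND_WALL, _KIND_CELL] = params.J_cw
    return e


def hamiltonian(state: PottsState, params: ModelParams) -> float:
    """Full energy recomputed from the lattice (independent of bookkeeping)."""
    lattice = state.lattice
    wall_id = state.wall_id
    volumes = np.bincount(lattice.ravel(), minlength=wall_id + 1).astype(np.float64)
    max_id = wall_id
    surfaces = np.zeros(max_id + 1, dtype=np.float64)
    e_contact = 0.0
    emat = _contact_energy_matrix(params)
    for axis in range(3):
        a = np.moveaxis(lattice, axis, 0)[:-1].ravel()
        b = np.moveaxis(lattice, axis, 0)[1:].ravel()
        diff = a != b
        ad, bd = a[diff], b[diff]
        surfaces += np.bincount(ad, minlength=max_id + 1)
        surfaces += np.bincount(bd, minlength=max_id + 1)
        e_contact += emat[state.kind[ad], state.kind[bd]].sum()

    cells = state.cell_ids
    dv = volumes[cells] - state.target_volumes[cells]
    da = surfaces[cells] - state.target_surfaces[cells]
    return float(params.lambda_V * (dv * dv).sum() + params.lambda_A * (da * da).sum() + e_contact)


@njit(cache=True)
def _delta_h_kernel(
    lattice, kind, volumes, surfaces, tv, ta, emat,
    lam_v, lam_a, x, y, z, new_id,
    touched_ids, touched_dv, touched_da,
):
    """Local energy change of copying ``new_id`` onto site (x, y, z).

    ``touched_dv``/``touched_da`` must arrive zeroed; they are filled with
    per-ID volume/surface deltas for reuse by the bookkeeping update.
    Returns (dH, n_touched).
    """
    old_id = lattice[x, y, z]
    n_touched = 0

    def _touch(ids, n, cid):
        for k in range(n):
            if ids[k] == cid:
                return k, n
        ids[n] = cid
        return n, n + 1

    # register old and new owners
    i_old, n_touched = _touch(touched_ids, n_touched, old_id)
    touched_dv[i_old] = -1
    touched_da[i_old] = 0
    i_new, n_touched = _touch(touched_ids, n_touched, new_id)
    touched_dv[i_new] = 1
    touched_da[i_new] = 0

    d_contact = 0.0
    for axis in range(3):
        for s in (-1, 1):
            nx, ny, nz = x, y, z
            if axis == 0:
                nx += s
            elif axis == 1:
                ny += s
            else:
                nz += s
            c = lattice[nx, ny, nz]
            # surface deltas from the face (site, neighbor)
            if c != old_id:
                touched_da[i_old] -= 1
                idx, n_touched = _touch(touched_ids, n_touched, c)
                touched_da[idx] -= 1
                d_contact -= emat[kind[old_id], kind[c]]
            if c != new_id:
                touched_da[i_new] += 1
                idx, n_touched = _touch(touched_ids, n_touched, c)
                touched_da[idx] += 1
                d_contact += emat[kind[new_id], kind[c]]

    dh = d_contact
    for k in range(n_touched):
        cid = touched_ids[k]
        if kind[cid] != 1:  # only cells carry lambda terms
            continue
        dv = touched_dv[k] if (cid == old_id or cid == new_id) else 0
        v0 = volumes[cid]
        a0 = surfaces[cid]
        dvv = v0 + dv - tv[cid]
        dv0 = v0 - tv[cid]
        daa = a0 + touched_da[k] - ta[cid]
        da0 = a0 - ta[cid]
        dh += lam_v * (dvv * dvv - dv0 * dv0) + lam_a * (daa * daa - da0 * da0)
    return dh, n_touched


@njit(cache=True)
def _run_attempts_kernel(
    lattice, kind, volumes, surfaces, tv, ta, emat,
    lam_v, lam_a, temperature,
    sites, neigh_idx, offsets, uniforms,
):
    """One batch of copy attempts (typically one MCS). Returns accepted count."""
    touched_ids = np.empty(10, dtype=np.int64)
    touched_dv = np.empty(10, dtype=np.int64)
    touched_da = np.empty(10, dtype=np.int64)
    accepted = 0
    for t in range(sites.shape[0]):
        x, y, z = sites[t, 0], sites[t, 1], sites[t, 2]
        off = offsets[neigh_idx[t]]
        new_id = lattice[x + off[0], y + off[1], z + off[2]]
        old_id = lattice[x, y, z]
        if new_id == old_id:
            continue
        if kind[new_id] == 2 or kind[old_id] == 2:
            continue
        for k in range(10):
            touched_dv[k] = 0
            touched_da[k] = 0
        dh, n_touched = _delta_h_kernel(
            lattice, kind, volumes, surfaces, tv, ta, emat,
            lam_v, lam_a, x, y, z, new_id,
            touched_ids, touched_dv, touched_da,
        )
        if dh <= 0.0:
            accept = True
        else:
            arg = dh / temperature
            accept = arg < 700.0 and uniforms[t] < math.exp(-arg)
        if accept:
            lattice[x, y, z] = new_id
            volumes[old_id] -= 1
            volumes[new_id] += 1
            for k in range(n_touched):
                surfaces[touched_ids[k]] += touched_da[k]
            accepted += 1
    return accepted


def delta_H(
    state: PottsState, params: ModelParams, site: tuple[int, int, int], candidate_id: int
) -> float:
    """Energy change of copying ``candidate_id`` onto ``site`` (no mutation)."""
    x, y, z = site
    shape = state.lattice.shape
    if not all(1 <= c < s - 1 for c, s in zip(site, shape)):
        raise ValueError(f"site {site} is not an interior lattice site")
    old_id = int(state.lattice[x, y, z])
    if candidate_id == old_id:
        raise ValueError("candidate equals the site's current ID (degenerate attempt)")
    if state.kind[old_id] == _KIND_WALL or state.kind[candidate_id] == _KIND_WALL:
        raise ValueError("wall voxels may not take part in copy attempts")
    touched_ids = np.empty(10, dtype=np.int64)
    touched_dv = np.zeros(10, dtype=np.int64)
    touched_da = np.zeros(10, dtype=np.int64)
    dh, _ = _delta_h_kernel(
        state.lattice, state.kind, state.volumes, state.surfaces,
        state.target_volumes, state.target_surfaces,
        _contact_energy_matrix(params),
        params.lambda_V, params.lambda_A, x, y, z, int(candidate_id),
        touched_ids, touched_dv, touched_da,
    )
    return float(dh)


def metropolis_accept(delta_h: float, temperature: float, u: float) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dH / T))."""
    if delta_h <= 0.0:
        return True
    arg = delta_h / temperature
    return arg < 700.0 and u < math.exp(-arg)


def mcs_step(state: PottsState, params: ModelParams) -> PottsState:
    """One Monte Carlo step: one copy attempt per interior site, in place.

    Attempts whose chosen neighbor shares the site's ID, or that would
    involve the wall, count as attempts but are skipped.
    """
    shape = state.lattice.shape
    n_sites = (shape[0] - 2) * (shape[1] - 2) * (shape[2] - 2)
    rng = state.rng
    sites = np.empty((n_sites, 3), dtype=np.int64)
    sites[:, 0] = rng.integers(1, shape[0] - 1, size=n_sites)
    sites[:, 1] = rng.integers(1, shape[1] - 1, size=n_sites)
    sites[:, 2] = rng.integers(1, shape[2] - 1, size=n_sites)
    offsets = _neighbor_offsets(params.copy_neighborhood)
    neigh_idx = rng.integers(0, len(offsets), size=n_sites)
    uniforms = rng.random(n_sites)
    _run_attempts_kernel(
        state.lattice, state.kind, state.volumes, state.surfaces,
        state.target_volumes, state.target_surfaces,
        _contact_energy_matrix(params),
        params.lambda_V, params.lambda_A, params.temperature,
        sites, neigh_idx, offsets, uniforms,
    )
    state.mcs_counter += 1
    return state


@dataclass
class Trajectory:
    """Collected outputs of one simulation run."""

    reports: list[dict] = field(default_factory=list)
    snapshots: list = field(default_factory=list)  # (mcs, LabelVolume or path)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: v for k, v in r.items() if not isinstance(v, (pd.DataFrame, dict))} for r in self.reports]
        )


def run_simulation(
    state: PottsState,
    params: ModelParams,
    snapshot_interval: int = 50,
    report_interval: int = 10,
    out_dir=None,
) -> Trajectory:
    """Evolve ``state`` for ``params.n_mcs`` steps, recording as it goes.

    At each report interval the mean cell volume/surface, the per-cell
    morphology table, and the similarity metrics against the MCS-0 frame
    are recorded; at each snapshot interval the lattice is stored (and
    written as TIFF when ``out_dir`` is given). The initial frame is always
    both reported and snapshotted.
    """
    from . import morphology, similarity
    from .io_formats import write_label_tiff

    if snapshot_interval < 1 or report_interval < 1:
        raise ValueError("intervals must be >= 1")

    start = state.to_label_volume()
    traj = Trajectory()

    def record(mcs: int) -> None:
        frame = state.to_label_volume()
        feats = morphology.compute_features(frame)
        report = similarity.wip(start, frame, mcs=mcs)
        traj.reports.append(
            {
                "mcs": mcs,
                "energy": hamiltonian(state, params),
                "mean_volume": float(feats["volume"].mean()) if len(feats) else 0.0,
                "mean_surface": float(feats["surface"].mean()) if len(feats) else 0.0,
                "n_cells": int(len(feats)),
                "mean_W": report.mean_W,
                "mean_IoU": report.mean_IoU,
                "wip": report.wip,
                "features": feats,
                "wip_report": report.to_dict(),
            }
        )

    def snapshot(mcs: int) -> None:
        frame = state.to_label_volume()
        if out_dir is not None:
            from pathlib import Path

            path = Path(out_dir) / f"snapshot_mcs{mcs:06d}.tiff"
            write_label_tiff(frame, path)
            traj.snapshots.append((mcs, path))
        else:
            traj.snapshots.append((mcs, frame))

    record(0)
    snapshot(0)
    for _ in range(params.n_mcs):
        mcs_step(state, params)
        mcs = state.mcs_counter
        if mcs % report_interval == 0 or mcs == params.n_mcs:
            record(mcs)
        if mcs % snapshot_interval == 0 or mcs == params.n_mcs:
            snapshot(mcs)
    return traj
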