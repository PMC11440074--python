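"""Grid scans of model parameters ranked by the WIP objective.

A scan enumerates the Cartesian product of candidate values for the four
free Hamiltonian weights (J_cm, J_cc, lambda_V, lambda_A), runs the
simulation from the same preprocessed initial patch for each combination
(and each replicate seed), scores the final frame against the initial one
with :func:`spherosim.similarity.wip`, and ranks ascending by WIP.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cpm, morphology, similarity
from .io_formats import LabelVolume

__all__ = ["ScanGrid", "ScanResult", "build_grid", "drop_boundary_labels", "run_scan", "report_scan"]

logger = logging.getLogger(__name__)

#: Grid axes in enumeration order (outermost first).
GRID_AXES = ("J_cm", "J_cc", "lambda_V", "lambda_A")


@dataclass(frozen=True)
class ScanGrid:
    """Candidate values per scanned parameter plus replicate seeds."""

    J_cm: tuple[float, ...]
    J_cc: tuple[float, ...]
    lambda_V: tuple[float, ...]
    lambda_A: tuple[float, ...]
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        for name in GRID_AXES + ("seeds",):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"scan axis {name!r} is empty")

    def __len__(self) -> int:
        return len(self.J_cm) * len(self.J_cc) * len(self.lambda_V) * len(self.lambda_A) * len(self.seeds)

    def combinations(self):
        """Deterministic enumeration: J_cm, then J_cc, lambda_V, lambda_A, seed."""
        for j_cm, j_cc, lam_v, lam_a in itertools.product(self.J_cm, self.J_cc, self.lambda_V, self.lambda_A):
            for seed in self.seeds:
                yield {"J_cm": j_cm, "J_cc": j_cc, "lambda_V": lam_v, "lambda_A": lam_a, "seed": seed}


def build_grid(config: dict) -> ScanGrid:
    """Build a ScanGrid from a parsed key-value config."""
    def values(key, default=None):
        v = config.get(key, default)
        if v is None:
            raise ValueError(f"scan config missing {key!r}")
        if np.isscalar(v):
            v = [v]
        if len(v) == 0:
            raise ValueError(f"scan axis {key!r} is empty")
        return tuple(v)

    return ScanGrid(
        J_cm=tuple(float(x) for x in values("J_cm")),
        J_cc=tuple(float(x) for x in values("J_cc")),
        lambda_V=tuple(float(x) for x in values("lambda_V")),
        lambda_A=tuple(float(x) for x in values("lambda_A")),
        seeds=tuple(int(x) for x in values("seeds", (0,))),
    )


def drop_boundary_labels(vol: LabelVolume) -> LabelVolume:
    """Delete every label that owns a voxel on any lattice face."""
    lattice = vol.lattice.copy()
    faces = np.concatenate(
        [
            lattice[0].ravel(), lattice[-1].ravel(),
            lattice[:, 0].ravel(), lattice[:, -1].ravel(),
            lattice[:, :, 0].ravel(), lattice[:, :, -1].ravel(),
        ]
    )
    touching = np.unique(faces[faces > 0])
    if touching.size:
        lattice[np.isin(lattice, touching)] = 0
    return LabelVolume(lattice, vol.spacing)


@dataclass
class ScanResult:
    """Outcome of one (parameter combination, seed) run."""

    params: dict
    seed: int
    report: similarity.WipReport | None
    trajectory_summary: pd.DataFrame | None = None
    error: str | None = None

    @property
    def wip(self) -> float:
        return self.report.wip if self.report is not None else float("nan")

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "seed": int(self.seed),
            "wip": None if self.report is None else float(self.report.wip),
            "mean_W": None if self.report is None else float(self.report.mean_W),
            "mean_IoU": None if self.report is None else float(self.report.mean_IoU),
            "W": None if self.report is None else {k: float(v) for k, v in self.report.W.items()},
            "error": self.error,
        }


def run_scan(
    grid: ScanGrid,
    initial: LabelVolume,
    n_mcs: int,
    base_params: cpm.ModelParams = cpm.ModelParams(),
    report_interval: int | None = None,
) -> list[ScanResult]:
    """Run every grid combination from the same initial patch; never raises per-run.

    The initial volume must already be preprocessed (isotropic, cleaned)
    and free of boundary-clipped cells (see :func:`drop_boundary_labels`).
    Targets are assigned once per seed from the initial morphology, using
    the engine's face-contact surfaces so every in-band cell starts exactly
    at its targets. Per-run failures are recorded on the result and the
    scan continues.
    """
    table = morphology.compute_features(initial)
    if len(table) == 0:
        raise ValueError("initial volume holds no cells")
    # face-contact surfaces of the walled initial state, for target assignment
    probe = cpm.init_state(initial, None, base_params)
    face_surf = probe.surfaces[table["cell_id"].to_numpy(dtype=int)]

    results: list[ScanResult] = []
    total = len(grid)
    for idx, combo in enumerate(grid.combinations(), start=1):
        params = replace(
            base_params,
            J_cm=combo["J_cm"],
            J_cc=combo["J_cc"],
            lambda_V=combo["lambda_V"],
            lambda_A=combo["lambda_A"],
            seed=int(combo["seed"]),
            n_mcs=n_mcs,
        )
        logger.info("scan %d/%d: %s", idx, total, combo)
        try:
            targets = cpm.assign_targets(table, seed=int(combo["seed"]), surfaces=face_surf)
            state = cpm.init_state(initial, targets, params)
            interval = report_interval or max(1, n_mcs)
            traj = cpm.run_simulation(state, params, snapshot_interval=max(1, n_mcs), report_interval=interval)
            final_report = similarity.wip(initial, state.to_label_volume(), mcs=n_mcs)
            results.append(
                ScanResult(
                    params={k: combo[k] for k in GRID_AXES},
                    seed=int(combo["seed"]),
                    report=final_report,
                    trajectory_summary=traj.to_frame(),
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-run isolation is the contract
            logger.exception("scan run failed for %s", combo)
            results.append(
                ScanResult(params={k: combo[k] for k in GRID_AXES}, seed=int(combo["seed"]), report=None, error=str(exc))
            )
    return results


def report_scan(results: list[ScanResult]) -> tuple[pd.DataFrame, dict]:
    """Rank results ascending by WIP (ties broken by parameter tuple).

    Returns the ranked table and a JSON-ready dict that also carries the
    per-feature W_k of the best and worst successful runs.
    """
    if not results:
        raise ValueError("no scan results to report")
    rows = []
    for r in results:
        row = {**{k: r.params[k] for k in GRID_AXES}, "seed": r.seed}
        row["wip"] = r.wip
        row["mean_W"] = r.report.mean_W if r.report else float("nan")
        row["mean_IoU"] = r.report.mean_IoU if r.report else float("nan")
        row["error"] = r.error
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["wip"] + list(GRID_AXES) + ["seed"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))

    ok = [r for r in results if r.report is not None]
    best = min(ok, key=lambda r: (r.wip, tuple(r.params[k] for k in GRID_AXES), r.seed)) if ok else None
    worst = max(ok, key=lambda r: (r.wip, tuple(r.params[k] for k in GRID_AXES), r.seed)) if ok else None
    payload = {
        "n_runs": len(results),
        "n_failed": sum(1 for r in results if r.error),
        "ranking": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            for row in table.drop(columns=["error"]).to_dict(orient="records")
        ],
        "best": best.to_dict() if best else None,
        "worst": worst.to_dict() if worst else None,
    }
    return table, payload
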