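"""Similarity scoring between a simulation frame and its starting frame.

Three layers:

* :func:`wasserstein` — distance between two empirical feature
  distributions from their ordered sample values. The default form is the
  root-mean-square of ordered differences,
  ``W = sqrt((1/n) * sum_i (X_(i) - Y_(i))^2)``; the classical L1
  ordered-difference form is available via ``form="l1"``. Unequal sample
  sizes are reconciled by evaluating both samples at ``max(n_x, n_y)``
  common quantile ranks.
* :func:`iou` — voxel-overlap of one cell between two frames,
  ``|A ∩ B| / |A ∪ B|``.
* :func:`wip` — the calibration objective: (mean W over features) ×
  (mean IoU over cells). Minimizing it favors runs whose ensemble feature
  distributions stay put while individual cells still move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LabelVolume
from .morphology import FEATURE_COLUMNS, compute_features

__all__ = ["wasserstein", "iou", "wip", "WipReport"]


def wasserstein(x, y, form: str = "rms") -> float:
    """Distance between two samples from their ordered values.

    ``form="rms"`` (default): sqrt of the mean squared ordered difference.
    ``form="l1"``: mean absolute ordered difference (the classical first
    Wasserstein distance for equal-size samples).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("wasserstein requires nonempty samples")
    if x.size != y.size:
        n = max(x.size, y.size)
        ranks = (np.arange(n) + 0.5) / n
        x = np.quantile(x, ranks)
        y = np.quantile(y, ranks)
    d = x - y
    if form == "rms":
        return float(np.sqrt(np.mean(d * d)))
    if form == "l1":
        return float(np.mean(np.abs(d)))
    raise ValueError(f"unknown form {form!r} (expected 'rms' or 'l1')")


def iou(start: LabelVolume, current: LabelVolume, cell_id: int) -> float:
    """Intersection-over-union of one cell's voxel set between two frames.

    A cell absent from ``current`` scores 0; a cell absent from ``start``
    is an error.
    """
    a = start.lattice == cell_id
    if not a.any():
        raise ValueError(f"cell {cell_id} absent from the start frame")
    b = current.lattice == cell_id
    inter = int(np.count_nonzero(a & b))
    if inter == 0:
        return 0.0
    union = int(np.count_nonzero(a | b))
    return inter / union


@dataclass
class WipReport:
    """Per-feature Wasserstein distances, per-cell IoUs, and their product."""

    W: dict[str, float] = field(default_factory=dict)
    IoU: dict[int, float] = field(default_factory=dict)
    mean_W: float = 0.0
    mean_IoU: float = 0.0
    wip: float = 0.0
    mcs: int | None = None

    def to_dict(self) -> dict:
        return {
            "W": {k: float(v) for k, v in self.W.items()},
            "IoU": {str(k): float(v) for k, v in self.IoU.items()},
            "mean_W": float(self.mean_W),
            "mean_IoU": float(self.mean_IoU),
            "wip": float(self.wip),
            "mcs": self.mcs,
        }


def wip(
    start: LabelVolume,
    current: LabelVolume,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    form: str = "rms",
    normalize: bool = False,
    mcs: int | None = None,
) -> WipReport:
    """Score ``current`` against ``start``: WIP = mean_W * mean_IoU.

    Feature distributions are compared raw by default (``normalize=True``
    divides each W_k by the start sample's standard deviation). Cells that
    vanished by ``current`` contribute IoU 0 and are absent from the
    current frame's feature samples.
    """
    if start.shape != current.shape:
        raise ValueError(f"frames live on different lattices: {start.shape} vs {current.shape}")
    feats_start = compute_features(start)
    if len(feats_start) == 0:
        raise ValueError("start frame holds no cells")
    feats_cur = compute_features(current)
    if len(feats_cur) == 0:
        raise ValueError("current frame holds no cells; cannot form feature distributions")

    report = WipReport(mcs=mcs)
    for k in features:
        w_k = wasserstein(feats_start[k].to_numpy(), feats_cur[k].to_numpy(), form=form)
        if normalize:
            sd = float(feats_start[k].std(ddof=0))
            w_k = w_k / sd if sd > 0 else w_k
        report.W[k] = w_k
    for cid in feats_start["cell_id"].astype(int):
        report.IoU[int(cid)] = iou(start, current, int(cid))

    report.mean_W = float(np.mean(list(report.W.values())))
    report.mean_IoU = float(np.mean(list(report.IoU.values())))
    report.wip = report.mean_W * report.mean_IoU
    return report
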