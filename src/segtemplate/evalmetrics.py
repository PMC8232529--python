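"""Segmentation evaluation: soft Dice, average Hausdorff distance,
apex/midgland/base subvolume Dice, per-image aggregation, paired tests.

Dice is the overlap ratio 2|A∩B| / (|A|+|B|); the soft variant replaces the
hard intersection and set sizes with sums over probabilities.  The average
Hausdorff distance (AHD) between foreground point sets X (reference) and Y
(prediction) is the halved sum of the two directed mean nearest-neighbour
distances,

    AHD(X, Y) = [ mean_x min_y d(x,y) + mean_y min_x d(x,y) ] / 2,

with d Euclidean in millimetres.  Regional Dice splits the reference
foreground slices along the through-plane axis into apex (25%), midgland
(50%) and base (25%) blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import t as t_dist

from .imgio import AxisConvention, SegmentationMask


@dataclass
class MetricRecord:
    """Per-case evaluation result. ``ahd_mm`` is None when undefined (empty mask)."""

    case_id: str
    dice_overall: float
    dice_base: Optional[float]
    dice_mid: Optional[float]
    dice_apex: Optional[float]
    ahd_mm: Optional[float]
    fold: int = -1
    model_tag: str = ""


@dataclass(frozen=True)
class SubvolumePartition:
    """Disjoint slice-index blocks over the reference-foreground slices."""

    apex_slices: tuple[int, ...]
    mid_slices: tuple[int, ...]
    base_slices: tuple[int, ...]


def _check_grids(pred: SegmentationMask, ref: SegmentationMask) -> None:
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: pred {pred.shape} vs ref {ref.shape}")


def soft_dice(pred: SegmentationMask, ref: SegmentationMask) -> float:
    """Soft Dice coefficient; 1.0 when both masks are empty (0/0 convention)."""
    _check_grids(pred, ref)
    p = pred.data.astype(np.float64)
    r = ref.data.astype(np.float64)
    denom = p.sum() + r.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p * r).sum() / denom)


def average_hausdorff(pred: SegmentationMask, ref: SegmentationMask) -> Optional[float]:
    """Average Hausdorff distance in mm between foreground voxel centres.

    Soft predictions are thresholded at 0.5.  Returns None ("undefined")
    when either mask is empty after thresholding — callers record this as
    missing rather than a fabricated distance.
    """
    _check_grids(pred, ref)
    spacing = np.asarray(ref.spacing_mm, dtype=np.float64)
    y_idx = np.argwhere(pred.data > 0.5) * spacing
    x_idx = np.argwhere(ref.data > 0.5) * spacing
    if len(x_idx) == 0 or len(y_idx) == 0:
        return None
    d_xy = cKDTree(y_idx).query(x_idx, k=1)[0]
    d_yx = cKDTree(x_idx).query(y_idx, k=1)[0]
    return float((d_xy.mean() + d_yx.mean()) / 2.0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_subvolumes(
    ref: SegmentationMask, axis_convention: AxisConvention | None = None
) -> SubvolumePartition:
    """Partition reference-foreground slices into apex/mid/base blocks.

    Block sizes are 25% / 50% / 25% of the n foreground slices, the quarter
    blocks rounded half away from zero and the midgland taking the
    remainder, so the three blocks always partition the n slices.  The apex
    block sits at the apex end given by ``axis_convention``.
    """
    conv = axis_convention or ref.axis_convention
    fg = np.where(ref.data.reshape(-1, ref.shape[2]).sum(axis=0) > 0)[0]
    if len(fg) == 0:
        raise ValueError("empty reference mask: no foreground slices to partition")
    n = len(fg)
    quarter = _round_half_away(0.25 * n)
    ordered = fg if conv.apex_low else fg[::-1]  # apex end first
    apex = tuple(int(s) for s in ordered[:quarter])
    base = tuple(int(s) for s in ordered[n - quarter:]) if quarter else ()
    mid = tuple(int(s) for s in ordered[quarter: n - quarter])
    return SubvolumePartition(apex_slices=apex, mid_slices=mid, base_slices=base)


def _slab_dice(pred: SegmentationMask, ref: SegmentationMask, slices) -> Optional[float]:
    if len(slices) == 0:
        return None
    idx = np.asarray(slices, dtype=int)
    p = pred.data[:, :, idx].astype(np.float64)
    r = ref.data[:, :, idx].astype(np.float64)
    denom = p.sum() + r.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p * r).sum() / denom)


def regional_dice(
    pred: SegmentationMask,
    ref: SegmentationMask,
    partition: SubvolumePartition | None = None,
) -> tuple[float, Optional[float], Optional[float], Optional[float]]:
    """(overall, base, mid, apex) Dice; overall is on the full uncropped grid."""
    _check_grids(pred, ref)
    if partition is None:
        partition = split_subvolumes(ref)
    overall = soft_dice(pred, ref)
    return (
        overall,
        _slab_dice(pred, ref, partition.base_slices),
        _slab_dice(pred, ref, partition.mid_slices),
        _slab_dice(pred, ref, partition.apex_slices),
    )


def evaluate_case(
    case_id: str,
    pred: SegmentationMask,
    ref: SegmentationMask,
    fold: int = -1,
    model_tag: str = "",
    soft: bool = True,
) -> MetricRecord:
    """Full per-case metric record: overall/regional Dice plus AHD.

    Dice uses soft probabilities when ``soft`` (the evaluation default);
    AHD and the slice partition always use the 0.5-thresholded prediction.
    """
    pd_mask = pred if soft else pred.binarized()
    try:
        part = split_subvolumes(ref)
    except ValueError:
        part = None
    if part is not None:
        overall, base, mid, apex = regional_dice(pd_mask, ref, part)
    else:
        overall, base, mid, apex = soft_dice(pd_mask, ref), None, None, None
    ahd = average_hausdorff(pred.binarized(), ref)
    return MetricRecord(case_id, overall, base, mid, apex, ahd, fold, model_tag)


def aggregate(records: Sequence[MetricRecord], model_tag: str = "") -> dict:
    """Mean ± sample SD of each metric pooled across all images (not fold means).

    Missing AHDs are excluded with their count reported; SD is None when
    fewer than two values contribute.
    """
    if model_tag:
        records = [r for r in records if r.model_tag == model_tag]
    if len(records) == 0:
        raise ValueError("no records to aggregate")

    def _stat(values):
        vals = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
        if not vals:
            return {"mean": None, "sd": None, "n": 0}
        arr = np.asarray(vals, dtype=np.float64)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
        return {"mean": float(arr.mean()), "sd": sd, "n": len(arr)}

    out = {
        "model_tag": model_tag,
        "n_cases": len(records),
        "dice_overall": _stat([r.dice_overall for r in records]),
        "dice_base": _stat([r.dice_base for r in records]),
        "dice_mid": _stat([r.dice_mid for r in records]),
        "dice_apex": _stat([r.dice_apex for r in records]),
        "ahd_mm": _stat([r.ahd_mm for r in records]),
    }
    out["ahd_missing"] = len(records) - out["ahd_mm"]["n"]
    return out


@dataclass(frozen=True)
class PairedTestResult:
    t: Optional[float]
    df: int
    p: Optional[float]
    superior: bool
    degenerate: bool = False


def paired_onetailed_test(
    scores_a: Sequence[float], scores_b: Sequence[float], alpha: float = 0.001
) -> PairedTestResult:
    """One-tailed paired t-test for the alternative mean(a − b) > 0.

    Zero variance of the differences yields a degenerate-test flag rather
    than a fabricated p-value.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test requires equal-length 1D score vectors")
    n = len(a)
    if n < 2:
        raise ValueError(f"paired test requires n >= 2, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return PairedTestResult(t=None, df=df, p=None, superior=False, degenerate=True)
    t_stat = float(d.mean() / (sd / math.sqrt(n)))
    p = float(t_dist.sf(t_stat, df))
    return PairedTestResult(t=t_stat, df=df, p=p, superior=bool(p < alpha))
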