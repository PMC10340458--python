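"""Training loss and evaluation statistics, stratified by axial offset.

The central quantity is the slice-wise Sørensen–Dice coefficient: the
training loss averages soft Dice over axial slices so every slice weighs
equally, whereas volumetric Dice naturally favors the large central
slices and can hide failures at the tumor's axial edges.  Evaluation
therefore records per-slice metrics keyed by the signed offset from the
tumor-center slice, so accuracy can be compared between tumor center and
edges.

Binary conventions: predictions are thresholded at 0.5; a slice where
both prediction and truth are empty scores Dice 1.0; sensitivity /
specificity with empty denominators and Hausdorff distances with an empty
mask are NaN and excluded from offset averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .nn import Tensor
from .preprocess import GtvMask

DICE_EPS = 1e-6
BINARY_THRESHOLD = 0.5

__all__ = [
    "dice_2d",
    "dice_3d",
    "dice_loss_2d",
    "soft_dice_per_slice",
    "sensitivity_slice",
    "specificity_slice",
    "hausdorff_slice",
    "slice_metrics_table",
    "metrics_by_offset",
    "area_profile",
    "centroid_drift_stats",
    "binarize",
    "plot_offset_curves",
]


def binarize(probs: np.ndarray, threshold: float = BINARY_THRESHOLD) -> np.ndarray:
    return (np.asarray(probs) > threshold).astype(np.uint8)


def _check_binary_pair(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def dice_2d(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap of two binary slices; 1.0 when both are empty."""
    p, t = _check_binary_pair(pred, truth)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, t).sum() / denom


def dice_3d(pred_vol: np.ndarray, truth_vol: np.ndarray) -> float:
    """Single Dice over all voxels of a volume (large slices dominate)."""
    return dice_2d(pred_vol, truth_vol)


def soft_dice_per_slice(pred: Tensor, truth: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice of each slice: (2*sum(p*t)+eps) / (sum(p)+sum(t)+eps).

    ``pred`` is an (S, ...) tensor of probabilities with one row per
    slice; returns an (S,) tensor, differentiable through ``pred``.
    """
    s = pred.shape[0]
    p = pred.reshape(s, -1)
    t = np.asarray(truth, dtype=p.data.dtype).reshape(s, -1)
    inter = (p * Tensor(t)).sum(axis=1)
    return (2.0 * inter + eps) / (p.sum(axis=1) + Tensor(t.sum(axis=1)) + eps)


def dice_loss_2d(
    pred_probs: Tensor | np.ndarray, truth: np.ndarray, valid: np.ndarray | None = None
) -> Tensor:
    """1 - mean soft Dice over valid slices: every slice weighs equally.

    ``pred_probs`` and ``truth`` are (L,H,W) (or any (L, ...) layout);
    ``valid`` marks the unpadded slices of a half-sequence.
    """
    if not isinstance(pred_probs, Tensor):
        pred_probs = Tensor(np.asarray(pred_probs, dtype=np.float32))
    length = pred_probs.shape[0]
    if valid is None:
        valid = np.ones(length, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() == 0:
        raise ValueError("dice_loss_2d: no valid slices")
    if np.any(pred_probs.data < -1e-6) or np.any(pred_probs.data > 1 + 1e-6):
        raise ValueError("dice_loss_2d expects probabilities in [0,1]")
    dice = soft_dice_per_slice(pred_probs, truth)
    mask = Tensor(valid.astype(np.float32))
    return 1.0 - (dice * mask).sum() / float(valid.sum())


def sensitivity_slice(pred: np.ndarray, truth: np.ndarray) -> float:
    """TP / (TP + FN); NaN when the slice has no positive truth."""
    p, t = _check_binary_pair(pred, truth)
    tp = np.logical_and(p, t).sum()
    fn = np.logical_and(~p, t).sum()
    if tp + fn == 0:
        return float("nan")
    return tp / (tp + fn)


def specificity_slice(pred: np.ndarray, truth: np.ndarray) -> float:
    """TN / (TN + FP); NaN when the slice has no negative truth."""
    p, t = _check_binary_pair(pred, truth)
    tn = np.logical_and(~p, ~t).sum()
    fp = np.logical_and(p, ~t).sum()
    if tn + fp == 0:
        return float("nan")
    return tn / (tn + fp)


def hausdorff_slice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric Hausdorff distance between foreground pixel sets, in px.

    NaN (undefined) when either mask is empty; excluded from averages.
    """
    p, t = _check_binary_pair(pred, truth)
    pp = np.argwhere(p)
    tt = np.argwhere(t)
    if pp.size == 0 or tt.size == 0:
        return float("nan")
    return max(directed_hausdorff(pp, tt)[0], directed_hausdorff(tt, pp)[0])


def slice_metrics_table(
    pred_vol: np.ndarray,
    truth: GtvMask | np.ndarray,
    center_z: int | None = None,
    patient: str | int = 0,
) -> pd.DataFrame:
    """Per-slice metric records keyed by signed offset from the center slice.

    Columns: patient, z, offset, dsc, sensitivity, specificity,
    hausdorff_px, gtv_area_px, in_gtv_span.  ``in_gtv_span`` marks slices
    between the first and last non-empty truth slices; offset averages
    are usually restricted to that span.
    """
    if isinstance(truth, GtvMask):
        truth_vol = truth.mask
        center_z = truth.center_z if center_z is None else center_z
    else:
        truth_vol = np.asarray(truth)
        if center_z is None:
            raise ValueError("center_z required when truth is a bare array")
    pred_vol = binarize(pred_vol) if pred_vol.dtype != np.uint8 else pred_vol
    if pred_vol.shape != truth_vol.shape:
        raise ValueError(f"shape mismatch: {pred_vol.shape} vs {truth_vol.shape}")
    areas = truth_vol.reshape(truth_vol.shape[0], -1).sum(axis=1)
    nz = np.nonzero(areas)[0]
    lo, hi = (int(nz[0]), int(nz[-1])) if nz.size else (0, -1)
    rows = []
    for z in range(truth_vol.shape[0]):
        rows.append(
            {
                "patient": patient,
                "z": z,
                "offset": z - center_z,
                "dsc": dice_2d(pred_vol[z], truth_vol[z]),
                "sensitivity": sensitivity_slice(pred_vol[z], truth_vol[z]),
                "specificity": specificity_slice(pred_vol[z], truth_vol[z]),
                "hausdorff_px": hausdorff_slice(pred_vol[z], truth_vol[z]),
                "gtv_area_px": int(areas[z]),
                "in_gtv_span": lo <= z <= hi,
            }
        )
    return pd.DataFrame(rows)


def metrics_by_offset(tables: pd.DataFrame | list[pd.DataFrame], span_only: bool = True) -> pd.DataFrame:
    """Mean metric value per signed offset across a cohort of slice tables.

    NaN entries (undefined Hausdorff/sensitivity rows) are dropped per
    metric; with ``span_only`` only slices within each patient's true GTV
    span contribute.
    """
    if isinstance(tables, list):
        if not tables:
            raise ValueError("metrics_by_offset: empty input")
        tables = pd.concat(tables, ignore_index=True)
    if tables.empty:
        raise ValueError("metrics_by_offset: empty input")
    df = tables[tables["in_gtv_span"]] if span_only and "in_gtv_span" in tables else tables
    cols = ["dsc", "sensitivity", "specificity", "hausdorff_px", "gtv_area_px"]
    return df.groupby("offset")[cols].mean().reset_index()


def area_profile(mask: GtvMask | np.ndarray, center_z: int | None = None) -> pd.DataFrame:
    """Per-slice foreground pixel counts keyed by offset from the center."""
    if isinstance(mask, GtvMask):
        vol, center_z = mask.mask, mask.center_z if center_z is None else center_z
    else:
        vol = np.asarray(mask)
        if center_z is None:
            raise ValueError("center_z required for a bare array")
    if vol.sum() == 0:
        raise ValueError("area_profile: empty mask")
    areas = vol.reshape(vol.shape[0], -1).sum(axis=1)
    return pd.DataFrame(
        {"offset": np.arange(vol.shape[0]) - center_z, "area_px": areas.astype(np.int64)}
    )


def plot_offset_curves(
    curves: dict[str, pd.DataFrame],
    metric: str,
    path,
    ylabel: str | None = None,
) -> None:
    """Plot per-offset mean curves (one line per model) to an image file.

    ``curves`` maps a model name to the output of :func:`metrics_by_offset`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, df in curves.items():
        ax.plot(df["offset"], df[metric], marker="o", markersize=3, label=name)
    ax.set_xlabel("slice offset from tumor center")
    ax.set_ylabel(ylabel or metric)
    ax.axvline(0, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def centroid_drift_stats(mask: GtvMask | np.ndarray) -> tuple[float, float]:
    """Mean absolute per-step centroid displacement (|dy|, |dx|) in pixels.

    Estimated by differencing the centroids of consecutive non-empty
    slices; requires at least one such adjacent pair.
    """
    vol = mask.mask if isinstance(mask, GtvMask) else np.asarray(mask)
    nonempty = [z for z in range(vol.shape[0]) if vol[z].any()]
    cents = {z: np.asarray(ndimage.center_of_mass(vol[z])) for z in nonempty}
    deltas = [
        np.abs(cents[z2] - cents[z1])
        for z1, z2 in zip(nonempty, nonempty[1:])
        if z2 == z1 + 1
    ]
    if not deltas:
        raise ValueError("centroid_drift_stats: need >=2 consecutive non-empty slices")
    mean = np.mean(deltas, axis=0)
    return float(mean[0]), float(mean[1])
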