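"""Training, cross-validation, prediction, and statistical comparison.

Every architecture minimizes the slice-wise soft Dice loss with Adam
(learning rate 3e-4, batch size 10, 100 epochs by default) under k-fold
cross-validation (7 folds by default).  A "batch" is the architecture's
natural unit: 10 slices for the 2D net, 10 volumes for the 3D net, and 10
half-sequences for the recurrent nets.  No data augmentation and no
learning-rate schedule are used.  All randomness (fold assignment,
initialization, shuffling) derives from explicit seeds, so identical
seed + config reproduces identical loss histories and metric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from . import metrics as M
from .models import ModelSpec, RecurrentUNet, UNet2d, UNet3d, build_model
from .nn import Tensor
from .nn.modules import Adam
from .preprocess import (
    GtvMask,
    ScanVolume,
    SEQUENCE_LENGTH,
    merge_halves,
    split_at_center,
    split_mask_at_center,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "kfold_split",
    "train",
    "predict_patient",
    "evaluate_cv",
    "paired_ttest",
    "save_checkpoint",
    "load_checkpoint",
]

Triplet = tuple[ScanVolume, GtvMask, int]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 3e-4
    batch_size: int = 10
    epochs: int = 100
    folds: int = 7
    seed: int = 0
    sequence_length: int = SEQUENCE_LENGTH

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if min(self.learning_rate, self.batch_size, self.epochs, self.folds) <= 0:
            raise ValueError("learning_rate, batch_size, epochs, folds must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple
    test_ids: tuple


def kfold_split(patient_ids: list, k: int = 7, seed: int = 0) -> list[FoldSplit]:
    """Deterministic shuffled partition into k near-equal test folds."""
    ids = list(patient_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds cohort size {len(ids)}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (tr, te) in enumerate(splitter.split(ids)):
        folds.append(
            FoldSplit(
                fold_index=i,
                train_ids=tuple(ids[j] for j in tr),
                test_ids=tuple(ids[j] for j in te),
            )
        )
    return folds


# ---------------------------------------------------------------------------
# training items: each architecture's natural unit
# ---------------------------------------------------------------------------


def _sequence_items(cohort: list[Triplet], length: int):
    """(seq (L,2,H,W), targets (L,H,W), valid (L,)) per half, both halves."""
    items = []
    for scan, gtv, center_z in cohort:
        inf, sup = split_at_center(scan, center_z, length)
        minf, msup = split_mask_at_center(gtv, center_z, length)
        for half, mhalf in ((inf, minf), (sup, msup)):
            valid = np.arange(length) < half.valid_length
            items.append(
                (
                    half.data.transpose(0, 3, 1, 2).astype(np.float32),
                    mhalf.data[..., 0].astype(np.float32),
                    valid,
                )
            )
    return items


def _slice_items(cohort: list[Triplet]):
    items = []
    for scan, gtv, _ in cohort:
        stacked = scan.stacked().transpose(0, 3, 1, 2)  # (Z,2,H,W)
        for z in range(stacked.shape[0]):
            items.append((stacked[z].astype(np.float32), gtv.mask[z].astype(np.float32)))
    return items


def _volume_items(cohort: list[Triplet]):
    return [
        (scan.stacked().transpose(3, 0, 1, 2).astype(np.float32), gtv.mask.astype(np.float32))
        for scan, gtv, _ in cohort
    ]


def _batch_loss(model, batch, kind: str) -> Tensor:
    if kind == "sequence":
        seqs = Tensor(np.stack([b[0] for b in batch]))  # (B,L,2,H,W)
        targets = np.stack([b[1] for b in batch])  # (B,L,H,W)
        valid = np.stack([b[2] for b in batch])  # (B,L)
        probs = model(seqs)  # (B,L,1,H,W)
        b, length = targets.shape[:2]
        flat = probs.reshape(b * length, *probs.shape[2:])
        return M.dice_loss_2d(flat, targets.reshape(b * length, 1, *targets.shape[2:]),
                              valid.reshape(-1))
    if kind == "slice":
        x = Tensor(np.stack([b[0] for b in batch]))  # (B,2,H,W)
        targets = np.stack([b[1] for b in batch])
        probs = model(x)  # (B,1,H,W)
        return M.dice_loss_2d(probs, targets[:, None])
    # volume: per-slice Dice over the full volume's axial slices
    x = Tensor(np.stack([b[0] for b in batch]))  # (B,2,Z,H,W)
    targets = np.stack([b[1] for b in batch])  # (B,Z,H,W)
    probs = model(x)  # (B,1,Z,H,W)
    b, z = targets.shape[:2]
    flat = probs.transpose(0, 2, 1, 3, 4).reshape(b * z, 1, *targets.shape[2:])
    return M.dice_loss_2d(flat, targets.reshape(b * z, 1, *targets.shape[2:]))


def _item_kind(model) -> str:
    if isinstance(model, RecurrentUNet):
        return "sequence"
    if isinstance(model, UNet3d):
        return "volume"
    return "slice"


def train(model, cohort: list[Triplet], config: TrainConfig) -> tuple[object, list[float]]:
    """Fit ``model`` on a cohort by slice-wise Dice loss; returns loss history.

    The history holds one mean training loss per epoch.  A NaN loss
    aborts with a diagnostic rather than silently diverging.
    """
    if not cohort:
        raise ValueError("train: empty cohort")
    kind = _item_kind(model)
    if kind == "sequence":
        items = _sequence_items(cohort, config.sequence_length)
    elif kind == "slice":
        items = _slice_items(cohort)
    else:
        items = _volume_items(cohort)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(items))
        losses, weights = [], []
        for start in range(0, len(items), config.batch_size):
            batch = [items[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            loss = _batch_loss(model, batch, kind)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            loss.backward()
            opt.step()
            losses.append(value)
            weights.append(len(batch))
        history.append(float(np.average(losses, weights=weights)))
        logger.info("epoch %d/%d: loss %.4f", epoch + 1, config.epochs, history[-1])
    return model, history


def predict_patient(
    model,
    scan: ScanVolume,
    center_z: int | None = None,
    pad_length: int = SEQUENCE_LENGTH,
    return_probs: bool = False,
):
    """Predict a binary GTV mask for one preprocessed patient scan.

    Recurrent models run the center-outward halves and reassemble them
    (shared center slice averaged); the 2D/3D baselines run directly.
    Probabilities are thresholded at 0.5.
    """
    z, h, w = scan.shape
    if center_z is None:
        center_z = z // 2
    if isinstance(model, RecurrentUNet):
        inf, sup = split_at_center(scan, center_z, pad_length)
        halves = []
        for half in (inf, sup):
            seq = Tensor(half.data.transpose(0, 3, 1, 2)[None])  # (1,L,2,H,W)
            probs = model(seq).data[0, :, 0]  # (L,H,W)
            halves.append(
                dataclasses.replace(half, data=probs[..., None].astype(np.float32))
            )
        prob_vol = merge_halves(halves[0], halves[1], z)
    elif isinstance(model, UNet3d):
        x = Tensor(scan.stacked().transpose(3, 0, 1, 2)[None])  # (1,2,Z,H,W)
        prob_vol = model(x).data[0, 0]
    else:
        stacked = scan.stacked().transpose(0, 3, 1, 2)  # (Z,2,H,W)
        outs = [model(Tensor(stacked[i : i + 16])).data[:, 0] for i in range(0, z, 16)]
        prob_vol = np.concatenate(outs, axis=0)
    mask = M.binarize(prob_vol)
    return (mask, prob_vol) if return_probs else mask


def evaluate_cv(
    cohort: list[Triplet],
    specs: list[ModelSpec],
    config: TrainConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, np.ndarray]]:
    """Cross-validated training and held-out evaluation for several models.

    Returns ``(summary, tables, patient_dsc)``: a per-model summary of
    slice/volume Dice, sensitivity and specificity (patient-level and
    fold-level means with sd), the concatenated per-slice metric tables,
    and each model's per-patient slice-mean DSC vector (cohort order) for
    paired tests.
    """
    if config.folds < 2:
        raise ValueError("evaluate_cv needs at least 2 folds")
    ids = list(range(len(cohort)))
    folds = kfold_split(ids, k=config.folds, seed=config.seed)
    summary_rows = []
    tables: dict[str, pd.DataFrame] = {}
    patient_dsc: dict[str, np.ndarray] = {}
    for spec in specs:
        per_patient = np.full(len(cohort), np.nan)
        vol_dsc = np.full(len(cohort), np.nan)
        sens = np.full(len(cohort), np.nan)
        spec_ = np.full(len(cohort), np.nan)
        fold_of = np.zeros(len(cohort), dtype=int)
        patient_tables = []
        for fold in folds:
            model = build_model(spec, seed=config.seed * 1000 + fold.fold_index)
            train_cohort = [cohort[i] for i in fold.train_ids]
            model, _ = train(model, train_cohort, config)
            for pid in fold.test_ids:
                scan, gtv, center_z = cohort[pid]
                pred = predict_patient(model, scan, center_z)
                table = M.slice_metrics_table(pred, gtv, patient=pid)
                span = table[table["in_gtv_span"]]
                per_patient[pid] = span["dsc"].mean()
                vol_dsc[pid] = M.dice_3d(pred, gtv.mask)
                sens[pid] = span["sensitivity"].mean()
                spec_[pid] = span["specificity"].mean()
                fold_of[pid] = fold.fold_index
                patient_tables.append(table)
        tables[spec.name] = pd.concat(patient_tables, ignore_index=True)
        patient_dsc[spec.name] = per_patient
        fold_means = pd.DataFrame({"fold": fold_of, "dsc": per_patient}).groupby("fold")["dsc"].mean()
        summary_rows.append(
            {
                "model": spec.name,
                "slice_dsc_mean": np.nanmean(per_patient),
                "slice_dsc_sd": np.nanstd(per_patient),
                "volume_dsc_mean": np.nanmean(vol_dsc),
                "volume_dsc_sd": np.nanstd(vol_dsc),
                "sensitivity_mean": np.nanmean(sens),
                "specificity_mean": np.nanmean(spec_),
                "fold_dsc_mean": fold_means.mean(),
                "fold_dsc_sd": fold_means.std(ddof=0),
            }
        )
    return pd.DataFrame(summary_rows), tables, patient_dsc


def paired_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-patient scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_ttest needs two equal-length vectors of size >= 2")
    if np.var(a - b) == 0:
        raise ValueError("paired_ttest: zero variance of differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# checkpoints and run records
# ---------------------------------------------------------------------------


def save_checkpoint(model, path: str | Path) -> None:
    """Single-file parameter archive with the model spec embedded."""
    state = {k: v for k, v in model.state_dict().items()}
    np.savez(path, __spec__=np.frombuffer(json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path):
    with np.load(path) as archive:
        spec = ModelSpec.from_dict(json.loads(bytes(archive["__spec__"]).decode()))
        state = {k: archive[k] for k in archive.files if k != "__spec__"}
    model = build_model(spec)
    model.load_state_dict(state)
    return model


def write_run_record(path: str | Path, config: TrainConfig, metrics: dict) -> None:
    record = {"seed": config.seed, "config": config.to_dict(), "config_hash": config.config_hash(),
              "metrics": metrics}
    Path(path).write_text(json.dumps(record, indent=2, default=float))
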