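"""Volume normalization, resampling, cropping, and center-outward sequencing.

The recurrent models consume *half-sequences*: runs of axial slices that
start at a designated tumor-center slice and proceed outward, one toward
the skull base (superior) and one toward the thoracic inlet (inferior).
Feeding the tumor from its most salient slice outward is what lets the
recurrence push information to the low-contrast axial edges.

Conventions used throughout: volumes are indexed (Z, H, W), 0-based, with
z increasing superiorly; channels are stacked last as (CT, PET); CT is
clipped to [-200, 200] HU and mapped to [0, 1]; PET is min-max normalized
per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_SPACING = (3.0, 0.977, 0.977)  # mm per voxel along (z, y, x)
SEQUENCE_LENGTH = 32
ROI_EXTENT = (64, 64, 64)

__all__ = [
    "ScanVolume",
    "GtvMask",
    "HalfSequence",
    "RoiCrop",
    "clip_normalize_ct",
    "normalize_pet",
    "resample_to_grid",
    "compute_roi_crop",
    "apply_roi_crop",
    "split_at_center",
    "split_mask_at_center",
    "merge_halves",
]


@dataclass
class ScanVolume:
    """Co-registered CT and PET channels, both (Z,H,W) floats in [0, 1]."""

    ct: np.ndarray
    pet: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.ct = np.asarray(self.ct, dtype=np.float32)
        self.pet = np.asarray(self.pet, dtype=np.float32)
        if self.ct.shape != self.pet.shape:
            raise ValueError(f"CT {self.ct.shape} and PET {self.pet.shape} shapes differ")
        if self.ct.ndim != 3:
            raise ValueError("expected (Z,H,W) volumes")
        for name, vol in (("ct", self.ct), ("pet", self.pet)):
            if vol.min() < -1e-6 or vol.max() > 1 + 1e-6:
                raise ValueError(f"{name} values outside [0,1]; normalize first")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct.shape

    def stacked(self) -> np.ndarray:
        """(Z,H,W,2) array with channel order (CT, PET)."""
        return np.stack([self.ct, self.pet], axis=-1)


@dataclass
class GtvMask:
    """Binary gross-tumor-volume mask aligned with a :class:`ScanVolume`."""

    mask: np.ndarray
    center_z: int | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be strictly binary")
        self.mask = self.mask.astype(np.uint8)
        if self.center_z is None:
            self.center_z = default_center_z(self.mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


def default_center_z(mask: np.ndarray) -> int:
    """Center slice: the slice of largest tumor area, else the middle slice.

    Stands in for the clinician's manual center selection; an explicit
    index can always be supplied instead.
    """
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    if areas.max() > 0:
        return int(np.argmax(areas))
    return mask.shape[0] // 2


@dataclass
class HalfSequence:
    """Slices ordered from the center slice outward in one axial direction.

    ``data`` is (L,H,W,C); steps at or beyond ``valid_length`` are
    zero-padded and must be masked out of losses and metrics.
    """

    data: np.ndarray
    direction: str  # "inferior" | "superior"
    source_indices: np.ndarray
    valid_length: int

    def __post_init__(self):
        if self.direction not in ("inferior", "superior"):
            raise ValueError(f"direction must be inferior/superior, got {self.direction!r}")
        self.source_indices = np.asarray(self.source_indices, dtype=np.int64)
        step = -1 if self.direction == "inferior" else 1
        diffs = np.diff(self.source_indices[: self.valid_length])
        if self.valid_length > 1 and not np.all(diffs == step):
            raise ValueError("source_indices must advance by one slice per step")

    @property
    def center_z(self) -> int:
        return int(self.source_indices[0])


@dataclass(frozen=True)
class RoiCrop:
    """Fixed-extent crop window, 0-based origin (z0, y0, x0)."""

    z0: int
    y0: int
    x0: int
    extent: tuple[int, int, int] = ROI_EXTENT

    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.z0, self.z0 + self.extent[0]),
            slice(self.y0, self.y0 + self.extent[1]),
            slice(self.x0, self.x0 + self.extent[2]),
        )


def clip_normalize_ct(ct_hu: np.ndarray, lo: float = -200.0, hi: float = 200.0) -> np.ndarray:
    """Clip Hounsfield units to [lo, hi] and min-max map onto [0, 1]."""
    ct_hu = np.asarray(ct_hu, dtype=np.float32)
    if not np.all(np.isfinite(ct_hu)):
        raise ValueError("CT volume contains non-finite values")
    return (np.clip(ct_hu, lo, hi) - lo) / (hi - lo)


def normalize_pet(pet: np.ndarray) -> np.ndarray:
    """Min-max normalize a PET volume over the whole patient volume."""
    pet = np.asarray(pet, dtype=np.float32)
    if not np.all(np.isfinite(pet)):
        raise ValueError("PET volume contains non-finite values")
    lo, hi = float(pet.min()), float(pet.max())
    if hi <= lo:
        raise ValueError("constant PET volume: min-max normalization undefined")
    return (pet - lo) / (hi - lo)


def resample_to_grid(
    volume: np.ndarray,
    src_spacing: tuple[float, ...],
    dst_spacing: tuple[float, ...],
    order: int = 1,
) -> np.ndarray:
    """Resample onto a grid with ``dst_spacing`` by linear interpolation.

    Voxel i sits at physical position i * spacing along each axis (origins
    aligned); the output extent is round(src_extent * src/dst) per axis.
    """
    volume = np.asarray(volume, dtype=np.float32)
    src = np.asarray(src_spacing, dtype=np.float64)
    dst = np.asarray(dst_spacing, dtype=np.float64)
    if len(src) != volume.ndim or len(dst) != volume.ndim:
        raise ValueError("spacing length must match volume dimensionality")
    if np.any(src <= 0) or np.any(dst <= 0):
        raise ValueError("spacings must be positive")
    out_shape = tuple(int(round(n * s / d)) for n, s, d in zip(volume.shape, src, dst))
    coords = np.meshgrid(
        *[np.arange(n) * d / s for n, d, s in zip(out_shape, dst, src)], indexing="ij"
    )
    return ndimage.map_coordinates(volume, coords, order=order, mode="nearest").astype(np.float32)


def compute_roi_crop(masks: list[GtvMask | np.ndarray], extent: tuple[int, int, int] = ROI_EXTENT) -> RoiCrop:
    """Fixed-size window centered on the union bounding box of cohort GTVs.

    The window is shifted inside the volume bounds when the centroid sits
    too close to an edge.  All masks must share one grid.
    """
    arrays = [m.mask if isinstance(m, GtvMask) else np.asarray(m) for m in masks]
    if not arrays:
        raise ValueError("compute_roi_crop needs at least one mask")
    shape = arrays[0].shape
    lo = np.array(shape, dtype=np.int64)
    hi = np.full(3, -1, dtype=np.int64)
    for a in arrays:
        if a.shape != shape:
            raise ValueError("cohort masks must share a common grid")
        nz = np.nonzero(a)
        if nz[0].size == 0:
            continue
        lo = np.minimum(lo, [idx.min() for idx in nz])
        hi = np.maximum(hi, [idx.max() for idx in nz])
    if np.any(hi < 0):
        raise ValueError("all cohort masks are empty")
    center = (lo + hi) / 2.0
    origin = np.round(center - np.array(extent) / 2.0 + 0.5).astype(np.int64)
    origin = np.clip(origin, 0, np.array(shape) - np.array(extent))
    if np.any(np.array(shape) < np.array(extent)):
        raise ValueError(f"volume {shape} smaller than crop extent {extent}")
    return RoiCrop(int(origin[0]), int(origin[1]), int(origin[2]), tuple(extent))


def apply_roi_crop(volume: np.ndarray, crop: RoiCrop) -> np.ndarray:
    return volume[crop.slices()]


def split_at_center(
    scan: ScanVolume, center_z: int, pad_length: int = SEQUENCE_LENGTH
) -> tuple[HalfSequence, HalfSequence]:
    """Split a scan into inferior and superior half-sequences at ``center_z``.

    The center slice opens both halves.  Each half is zero-padded (or
    truncated) to ``pad_length`` steps; ``valid_length`` records the
    unpadded run so padded steps can be excluded from loss and metrics.
    """
    z, h, w = scan.shape
    if not 0 <= center_z < z:
        raise ValueError(f"center_z={center_z} outside [0, {z})")
    if pad_length < 1:
        raise ValueError("pad_length must be >= 1")
    stacked = scan.stacked()

    def build(direction: str) -> HalfSequence:
        if direction == "inferior":
            idx = np.arange(center_z, -1, -1)
        else:
            idx = np.arange(center_z, z)
        idx = idx[:pad_length]
        data = np.zeros((pad_length, h, w, 2), dtype=np.float32)
        data[: len(idx)] = stacked[idx]
        src = np.full(pad_length, -1, dtype=np.int64)
        src[: len(idx)] = idx
        return HalfSequence(data=data, direction=direction, source_indices=src, valid_length=len(idx))

    return build("inferior"), build("superior")


def split_mask_at_center(
    mask: GtvMask | np.ndarray, center_z: int, pad_length: int = SEQUENCE_LENGTH
) -> tuple[HalfSequence, HalfSequence]:
    """Sequence a binary mask with the same index bookkeeping as the scan.

    Returns half-sequences whose ``data`` is (L,H,W,1); used to build
    per-step training targets aligned with :func:`split_at_center`.
    """
    vol = mask.mask if isinstance(mask, GtvMask) else np.asarray(mask)
    z, h, w = vol.shape
    if not 0 <= center_z < z:
        raise ValueError(f"center_z={center_z} outside [0, {z})")

    def build(direction: str) -> HalfSequence:
        if direction == "inferior":
            idx = np.arange(center_z, -1, -1)
        else:
            idx = np.arange(center_z, z)
        idx = idx[:pad_length]
        data = np.zeros((pad_length, h, w, 1), dtype=np.float32)
        data[: len(idx), :, :, 0] = vol[idx]
        src = np.full(pad_length, -1, dtype=np.int64)
        src[: len(idx)] = idx
        return HalfSequence(data=data, direction=direction, source_indices=src, valid_length=len(idx))

    return build("inferior"), build("superior")


def merge_halves(pred_inf: HalfSequence, pred_sup: HalfSequence, z: int) -> np.ndarray:
    """Reassemble per-half slice predictions into a (Z,H,W) volume.

    Each valid step lands at its source slice; the center slice, present
    in both halves, becomes the voxel-wise mean of the two predictions.
    Slices never visited (beyond the padded halves) stay zero.
    """
    if pred_inf.center_z != pred_sup.center_z:
        raise ValueError("halves do not share a center slice")
    spatial = pred_inf.data.shape[1:3]
    out = np.zeros((z, *spatial), dtype=np.float32)
    seen = np.zeros(z, dtype=bool)
    center = pred_inf.center_z
    for half in (pred_inf, pred_sup):
        for step in range(half.valid_length):
            zi = int(half.source_indices[step])
            sl = np.asarray(half.data[step], dtype=np.float32).reshape(spatial)
            if zi == center:
                continue
            if seen[zi]:
                raise ValueError(f"conflicting predictions for slice {zi}")
            out[zi] = sl
            seen[zi] = True
    c_inf = np.asarray(pred_inf.data[0], dtype=np.float32).reshape(spatial)
    c_sup = np.asarray(pred_sup.data[0], dtype=np.float32).reshape(spatial)
    out[center] = 0.5 * (c_inf + c_sup)
    return out
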