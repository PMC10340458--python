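"""Seeded CT/PET/mask phantoms with center-peaked area and axial drift.

Each phantom is a two-channel volume containing one simulated tumor whose
per-slice cross-section is a filled, axis-aligned ellipse.  Three
statistical features of head-and-neck gross tumor volumes are emulated,
because they are exactly what the recurrent architectures are designed to
exploit:

* the tumor's per-slice area peaks at a center slice and tapers
  monotonically toward the superior and inferior edges;
* the per-slice centroid drifts from slice to slice (a Gaussian random
  walk, symmetric about the center, with a configurable mean step of
  about 1.5 px in each in-plane direction);
* the PET signal is strongest at the center slice and decays
  multiplicatively toward the axial edges, so edge slices carry little
  slice-local evidence of the tumor.

The background is smoothed noise: no anatomy is simulated, which is
sufficient to exercise sequencing, alignment, and evaluation machinery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import GtvMask, ScanVolume

logger = logging.getLogger(__name__)

__all__ = ["PhantomConfig", "generate_phantom", "make_cohort", "save_phantom", "load_phantom",
           "DEFAULT_CONFIG_RANGES"]


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters for one phantom patient.

    ``taper`` is the fractional radius shrink per slice away from the
    center (radii scale by ``(1 - taper)**|offset|``); ``drift_mean`` is
    the mean per-step centroid displacement (dy, dx) in pixels, applied
    walking outward from the center; ``pet_edge_decay`` scales the PET
    amplitude by ``(1 - pet_edge_decay)**|offset|``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    center_z: int = 32
    base_radii: tuple[float, float] = (10.0, 8.0)
    taper: float = 0.15
    drift_mean: tuple[float, float] = (1.53, 1.5)  # (dy, dx): in-plane px per slice step
    drift_sd: float = 0.5
    pet_peak: float = 0.9
    pet_edge_decay: float = 0.12
    ct_contrast: float = 0.25
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        z = self.grid_shape[0]
        if not 0 <= self.center_z < z:
            raise ValueError(f"center_z={self.center_z} outside [0, {z})")
        if min(self.base_radii) <= 0:
            raise ValueError("base_radii must be positive")
        if not 0 < self.taper < 1:
            raise ValueError("taper must lie in (0, 1)")
        if self.drift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.pet_edge_decay < 1:
            raise ValueError("pet_edge_decay must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("grid_shape", "base_radii", "drift_mean"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for k in ("grid_shape", "base_radii", "drift_mean"):
            d[k] = tuple(d[k])
        return cls(**d)


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0).astype(np.uint8)


def _gaussian_blob(h: int, w: int, cy: float, cx: float, sy: float, sx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)).astype(np.float32)


def generate_phantom(config: PhantomConfig) -> tuple[ScanVolume, GtvMask, int]:
    """Generate one (scan, mask, center_z) triplet; byte-deterministic in config.

    The centroid performs independent outward random walks from the center
    slice toward each axial edge (mean step ``drift_mean``, sd
    ``drift_sd``).  Slices whose tapered radii fall below half a pixel are
    empty; tumors walking off-grid are truncated at the boundary with a
    logged warning.
    """
    rng = np.random.default_rng(config.seed)
    z, h, w = config.grid_shape
    ry0, rx0 = config.base_radii

    # outward random walks of the centroid, symmetric about the center slice
    center_yx = np.array([h / 2.0, w / 2.0]) + rng.normal(0.0, 1.0, size=2)
    centroids = np.zeros((z, 2))
    centroids[config.center_z] = center_yx
    for direction in (-1, 1):
        pos = center_yx.copy()
        zi = config.center_z + direction
        while 0 <= zi < z:
            pos = pos + rng.normal(config.drift_mean, config.drift_sd, size=2)
            centroids[zi] = pos
            zi += direction

    mask = np.zeros((z, h, w), dtype=np.uint8)
    pet = np.zeros((z, h, w), dtype=np.float32)
    truncated = False
    for zi in range(z):
        k = abs(zi - config.center_z)
        scale = (1.0 - config.taper) ** k
        ry, rx = ry0 * scale, rx0 * scale
        if min(ry, rx) < 0.5:
            continue  # degenerate slice: tumor has tapered away
        cy, cx = centroids[zi]
        if not (ry <= cy <= h - 1 - ry and rx <= cx <= w - 1 - rx):
            truncated = True
        sl = _ellipse(h, w, cy, cx, ry, rx)
        if sl.sum() == 0:
            continue
        mask[zi] = sl
        amp = config.pet_peak * (1.0 - config.pet_edge_decay) ** k
        pet[zi] = amp * _gaussian_blob(h, w, cy, cx, ry, rx)
    if truncated:
        logger.warning("phantom seed=%d: tumor reached the grid boundary; ellipse truncated", config.seed)

    # background CT texture: smoothed white noise around mid-intensity
    bg = rng.normal(0.0, 1.0, size=(z, h, w))
    bg = ndimage.gaussian_filter(bg, sigma=3.0)
    bg = 0.45 + 0.05 * bg / max(bg.std(), 1e-8)
    ct = bg + config.ct_contrast * mask

    if config.noise_sd > 0:
        ct = ct + rng.normal(0.0, config.noise_sd, size=ct.shape)
        pet = pet + rng.normal(0.0, config.noise_sd, size=pet.shape).astype(np.float32)
    ct = np.clip(ct, 0.0, 1.0).astype(np.float32)
    pet = np.clip(pet, 0.0, 1.0).astype(np.float32)

    scan = ScanVolume(ct=ct, pet=pet)
    gtv = GtvMask(mask=mask, center_z=config.center_z)
    return scan, gtv, config.center_z


#: Cohort sampling ranges: uniform draws between (lo, hi) per parameter.
DEFAULT_CONFIG_RANGES: dict[str, tuple] = {
    "center_frac": (0.40, 0.60),  # center slice as a fraction of the axial extent
    "base_radii_y": (7.0, 12.0),
    "base_radii_x": (6.0, 11.0),
    "taper": (0.10, 0.22),
    "drift_sd": (0.3, 0.7),
    "pet_peak": (0.75, 0.95),
    "pet_edge_decay": (0.08, 0.16),
    "ct_contrast": (0.15, 0.30),
    "noise_sd": (0.02, 0.05),
}


def make_cohort(
    n_patients: int,
    config_ranges: dict[str, tuple] | None = None,
    seed: int = 0,
    base_config: PhantomConfig | None = None,
) -> list[tuple[ScanVolume, GtvMask, int]]:
    """Draw ``n_patients`` phantom configs from uniform ranges and generate them.

    Ranges not listed fall back to the fields of ``base_config``.  The
    same (ranges, seed) always yields an identical cohort.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ranges = dict(DEFAULT_CONFIG_RANGES if config_ranges is None else config_ranges)
    for key, rng_pair in ranges.items():
        if len(rng_pair) != 2 or rng_pair[1] < rng_pair[0]:
            raise ValueError(f"invalid range for {key!r}: {rng_pair}")
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        fields = {}
        if "center_frac" in draw:
            fields["center_z"] = int(round(draw.pop("center_frac") * (base.grid_shape[0] - 1)))
        if "center_z" in draw:
            fields["center_z"] = int(round(draw.pop("center_z")))
        ry = draw.pop("base_radii_y", base.base_radii[0])
        rx = draw.pop("base_radii_x", base.base_radii[1])
        fields["base_radii"] = (float(ry), float(rx))
        if "drift_magnitude" in draw:
            # per-patient drift direction: magnitude with a random in-plane angle
            mag = draw.pop("drift_magnitude")
            angle = draw.pop("drift_angle", rng.uniform(0.0, 2.0 * np.pi))
            fields["drift_mean"] = (float(mag * np.sin(angle)), float(mag * np.cos(angle)))
        else:
            dy = draw.pop("drift_mean_y", base.drift_mean[0])
            dx = draw.pop("drift_mean_x", base.drift_mean[1])
            fields["drift_mean"] = (float(dy), float(dx))
        fields.update({k: float(v) for k, v in draw.items()})
        cfg = dataclasses.replace(
            base, seed=int(rng.integers(0, 2**31 - 1)), **fields
        )
        cohort.append(generate_phantom(cfg))
    return cohort


def save_phantom(
    out_dir: str | Path, scan: ScanVolume, gtv: GtvMask, config: PhantomConfig | None = None
) -> None:
    """Write ct/pet/mask as NIfTI plus a JSON sidecar with config and center."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*reversed(scan.spacing), 1.0])  # (x,y,z) spacing on the diagonal
    for name, vol in (("ct", scan.ct), ("pet", scan.pet), ("mask", gtv.mask)):
        img = nib.Nifti1Image(np.asarray(vol).transpose(2, 1, 0), affine)
        nib.save(img, out / f"{name}.nii.gz")
    sidecar = {"center_z": int(gtv.center_z)}
    if config is not None:
        sidecar["config"] = config.to_dict()
        sidecar["seed"] = config.seed
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(in_dir: str | Path) -> tuple[ScanVolume, GtvMask, int]:
    """Read a triplet written by :func:`save_phantom`."""
    import nibabel as nib

    src = Path(in_dir)
    vols = {}
    for name in ("ct", "pet", "mask"):
        img = nib.load(src / f"{name}.nii.gz")
        vols[name] = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    sidecar = json.loads((src / "phantom.json").read_text())
    center_z = int(sidecar["center_z"])
    scan = ScanVolume(ct=vols["ct"], pet=vols["pet"])
    gtv = GtvMask(mask=(vols["mask"] > 0.5).astype(np.uint8), center_z=center_z)
    return scan, gtv, center_z
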