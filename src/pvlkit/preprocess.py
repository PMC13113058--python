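"""Image preprocessing and augmentation.

Chain (in order): resample to fixed voxel spacing -> intensity window to
[0, 1] -> crop around the foreground with a voxel margin -> anisotropic
resize to a fixed grid -> (training only) random 3-D patch with random
intensity shift on the CT channel. CT channels are interpolated trilinearly;
mask channels use trilinear-then-threshold interpolation so they stay
exactly binary while conserving volume.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import VolumeSample

__all__ = [
    "PreprocessConfig", "PreprocessedVolume", "Patch", "AugmentConfig",
    "resample", "window_normalize", "crop_foreground", "resize",
    "preprocess_sample", "random_patch", "inference_patches",
]

TARGET_SPACING = (1.0, 1.0, 2.0)
TARGET_SHAPE = (192, 128, 96)
WINDOW = (-79.0, 304.0)
CROP_MARGIN = 30
PATCH_SIZE = 64


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = TARGET_SPACING
    target_shape: tuple[int, int, int] = TARGET_SHAPE
    window: tuple[float, float] = WINDOW
    crop_margin: int = CROP_MARGIN

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessConfig":
        d = json.loads(Path(path).read_text())
        return cls(target_spacing=tuple(d["target_spacing"]),
                   target_shape=tuple(d["target_shape"]),
                   window=tuple(d["window"]),
                   crop_margin=int(d["crop_margin"]))

    #: desk-scale profile: reduced grid sized so a 32^3 patch spans the full
    #: z-extent (keeps the patch-level proxy target informative at small n)
    @classmethod
    def desk_scale(cls) -> "PreprocessConfig":
        return cls(target_shape=(64, 48, 32))


@dataclasses.dataclass
class PreprocessedVolume:
    """3-channel fixed-shape model input: (CT, root mask, calc mask)."""

    channels: np.ndarray            # (3, X, Y, Z), float32
    patient_id: str
    original_spacing: tuple[float, float, float]
    crop_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def validate(self) -> None:
        ct = self.channels[0]
        if ct.min() < 0 or ct.max() > 1:
            raise ValueError("CT channel outside [0, 1]")
        for c in (1, 2):
            if not np.all(np.isin(np.unique(self.channels[c]), [0, 1])):
                raise ValueError(f"channel {c} not binary")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]


@dataclasses.dataclass
class Patch:
    channels: np.ndarray            # (3, s, s, s)
    offset: tuple[int, int, int]


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    crop_size: int = PATCH_SIZE
    intensity_shift_offset: float = 0.40
    intensity_shift_prob: float = 0.50

    def __post_init__(self):
        if self.intensity_shift_offset < 0:
            raise ValueError("offset must be >= 0")
        if not 0.0 <= self.intensity_shift_prob <= 1.0:
            raise ValueError("probability must be in [0, 1]")


def _zoom_mask(mask: np.ndarray, zoom: tuple[float, ...]) -> np.ndarray:
    """Binary-preserving interpolation: trilinear on the indicator followed
    by a 0.5 threshold (conserves volume much better than pure nearest)."""
    soft = ndimage.zoom(mask.astype(np.float32), zoom, order=1,
                        mode="nearest", grid_mode=True)
    return (soft >= 0.5).astype(np.uint8)


def resample(sample: VolumeSample,
             target_spacing: tuple[float, float, float] = TARGET_SPACING,
             ) -> VolumeSample:
    """Resample all three grids to `target_spacing` (CT: trilinear; masks:
    trilinear-then-threshold). Physical extent preserved within one voxel."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    if min(sample.ct.shape) < 2:
        raise ValueError("degenerate single-slice volume cannot be resampled")
    zoom = tuple(s / t for s, t in zip(sample.spacing, target_spacing))
    if all(abs(z - 1.0) < 1e-9 for z in zoom):
        return sample
    ct = ndimage.zoom(sample.ct, zoom, order=1, mode="nearest",
                      grid_mode=True).astype(np.float32)
    root = _zoom_mask(sample.root_mask, zoom)
    calc = _zoom_mask(sample.calc_mask, zoom)
    out = VolumeSample(sample.patient_id, ct, root, calc, target_spacing)
    out.validate()
    return out


def window_normalize(ct: np.ndarray, lo: float = WINDOW[0],
                     hi: float = WINDOW[1]) -> np.ndarray:
    """Clip-and-rescale HU values to [0, 1] over the window [lo, hi]."""
    if lo >= hi:
        raise ValueError("window requires lo < hi")
    ct = np.asarray(ct, dtype=np.float32)
    if not np.all(np.isfinite(ct)):
        raise ValueError("CT contains non-finite values")
    return np.clip((ct - lo) / (hi - lo), 0.0, 1.0)


def crop_foreground(sample: VolumeSample, margin: int = CROP_MARGIN,
                    ) -> tuple[VolumeSample, tuple]:
    """Crop to the bounding box of the foreground (root ∪ calcification)
    dilated by `margin` voxels and clipped to the grid."""
    fg = (sample.root_mask > 0) | (sample.calc_mask > 0)
    if not fg.any():
        raise ValueError(f"{sample.patient_id}: empty root mask, cannot crop")
    box = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        prof = fg.any(axis=other)
        idx = np.where(prof)[0]
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + margin + 1, fg.shape[axis])
        box.append((lo, hi))
    sl = tuple(slice(lo, hi) for lo, hi in box)
    out = VolumeSample(sample.patient_id, sample.ct[sl].copy(),
                       sample.root_mask[sl].copy(),
                       sample.calc_mask[sl].copy(), sample.spacing)
    return out, tuple(box)


def resize(ct: np.ndarray, root: np.ndarray, calc: np.ndarray,
           shape: tuple[int, int, int] = TARGET_SHAPE,
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anisotropic stretch to a fixed grid (trilinear CT, binary-safe masks)."""
    if ct.shape == tuple(shape):
        return (ct.astype(np.float32), root.astype(np.uint8),
                calc.astype(np.uint8))
    zoom = tuple(t / s for t, s in zip(shape, ct.shape))
    ct_r = ndimage.zoom(ct, zoom, order=1, mode="nearest", grid_mode=True)
    root_r = _zoom_mask(root, zoom)
    calc_r = _zoom_mask(calc, zoom)
    # guard against off-by-one from rounding inside zoom
    def fix(a):
        sl = tuple(slice(0, t) for t in shape)
        a = a[sl]
        pad = [(0, t - s) for t, s in zip(shape, a.shape)]
        if any(p[1] for p in pad):
            a = np.pad(a, pad, mode="edge")
        return a
    return (fix(ct_r).astype(np.float32), fix(root_r).astype(np.uint8),
            fix(calc_r).astype(np.uint8))


def preprocess_sample(sample: VolumeSample,
                      config: PreprocessConfig | None = None,
                      ) -> PreprocessedVolume:
    """Run the full deterministic chain on one sample."""
    config = config or PreprocessConfig()
    rs = resample(sample, config.target_spacing)
    ct = window_normalize(rs.ct, *config.window)
    windowed = VolumeSample(rs.patient_id, ct, rs.root_mask, rs.calc_mask,
                            rs.spacing)
    cropped, box = crop_foreground(windowed, config.crop_margin)
    ct_r, root_r, calc_r = resize(cropped.ct, cropped.root_mask,
                                  cropped.calc_mask, config.target_shape)
    ct_r = np.clip(ct_r, 0.0, 1.0)
    vol = PreprocessedVolume(
        channels=np.stack([ct_r, root_r.astype(np.float32),
                           calc_r.astype(np.float32)]),
        patient_id=sample.patient_id,
        original_spacing=sample.spacing,
        crop_box=box,
    )
    vol.validate()
    return vol


def random_patch(vol: PreprocessedVolume, cfg: AugmentConfig,
                 rng: np.random.Generator) -> Patch:
    """Uniformly random patch plus optional uniform intensity shift on CT."""
    s = cfg.crop_size
    shape = vol.shape
    if any(d < s for d in shape):
        raise ValueError(f"volume {shape} smaller than patch size {s}")
    offset = tuple(int(rng.integers(0, d - s + 1)) for d in shape)
    sl = (slice(None),) + tuple(slice(o, o + s) for o in offset)
    channels = vol.channels[sl].copy()
    if rng.uniform() < cfg.intensity_shift_prob:
        shift = rng.uniform(-cfg.intensity_shift_offset,
                            cfg.intensity_shift_offset)
        channels[0] = np.clip(channels[0] + shift, 0.0, 1.0)
    return Patch(channels=channels, offset=offset)


def inference_patches(vol: PreprocessedVolume,
                      patch_size: int = PATCH_SIZE) -> list[Patch]:
    """Deterministic tiling: stride = patch size, with the final tile shifted
    back so it ends exactly at the volume boundary. Covers every voxel."""
    shape = vol.shape
    if any(d < patch_size for d in shape):
        raise ValueError(f"volume {shape} smaller than patch size {patch_size}")
    offsets_per_axis = []
    for d in shape:
        offs = list(range(0, d - patch_size + 1, patch_size))
        if offs[-1] != d - patch_size:
            offs.append(d - patch_size)
        offsets_per_axis.append(offs)
    patches = []
    for ox in offsets_per_axis[0]:
        for oy in offsets_per_axis[1]:
            for oz in offsets_per_axis[2]:
                sl = (slice(None), slice(ox, ox + patch_size),
                      slice(oy, oy + patch_size), slice(oz, oz + patch_size))
                patches.append(Patch(channels=vol.channels[sl].copy(),
                                     offset=(ox, oy, oz)))
    return patches
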