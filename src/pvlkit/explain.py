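"""3-D Grad-CAM over the final convolutional stage of the imaging encoder.

Channel weights are the spatial average of the positive-class logit's
gradient on the final feature map; the map is the ReLU of the weighted
channel sum, trilinearly upsampled to the input frame and max-normalized.
Whole-volume maps are assembled from the deterministic inference tiling by
averaging overlapping patch maps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage

from .nnx import Tensor
from .model_b import FusionModel
from .preprocess import PreprocessedVolume, inference_patches

__all__ = ["gradcam3d", "gradcam_volume", "export_overlay", "select_axial_levels"]


def _patch_cam(model: FusionModel, patch_channels: np.ndarray,
               covariates: np.ndarray, stage: int = -1) -> np.ndarray:
    """CAM for one patch, upsampled to the patch shape, not yet normalized.

    `stage` selects the encoder stage whose feature maps are explained
    (default: the final convolutional stage). Earlier stages give finer
    maps; at desk scale the final stage collapses to one spatial cell per
    32-cube patch, so callers may target stage 1 (index from 0) instead.
    """
    model.eval()
    x = Tensor(patch_channels[None].astype(np.float32))
    c = Tensor(np.asarray(covariates, dtype=np.float32)[None])
    final = model.encoder(x)
    fmap = model.encoder.stage_outputs[stage]
    if fmap.ndim != 5 or min(fmap.shape[2:]) < 1:
        raise ValueError("target layer has no spatial extent")
    img_tokens = model.encoder.tokens(final)
    clin_tokens = model.clinical.token_view(model.clinical(c))
    fused = model.fusion(img_tokens, clin_tokens)
    logit = model.head(fused)               # pre-sigmoid positive-class score
    model.zero_grad()
    fmap.grad = None
    logit.backward(np.ones_like(logit.data))
    if fmap.grad is None:
        grads = np.zeros_like(fmap.data)
    else:
        grads = fmap.grad
    weights = grads.mean(axis=(2, 3, 4))    # (1, C)
    cam = np.maximum(
        np.einsum("c,cdhw->dhw", weights[0], fmap.data[0]), 0.0)
    zoom = tuple(t / s for t, s in zip(patch_channels.shape[1:], cam.shape))
    cam_up = ndimage.zoom(cam, zoom, order=1, mode="nearest", grid_mode=True)
    # guard rounding
    sl = tuple(slice(0, t) for t in patch_channels.shape[1:])
    return cam_up[sl]


def gradcam3d(model: FusionModel, patch_channels: np.ndarray,
              covariates: np.ndarray, stage: int = -1) -> np.ndarray:
    """Max-normalized CAM for a single patch; all-zero when nothing fires."""
    cam = _patch_cam(model, patch_channels, covariates, stage)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def gradcam_volume(model: FusionModel, vol: PreprocessedVolume,
                   covariates: np.ndarray, patch_size: int,
                   stage: int = -1) -> np.ndarray:
    """Whole-volume CAM stitched from the inference tiling (overlap-averaged)."""
    acc = np.zeros(vol.shape, dtype=np.float64)
    weight = np.zeros(vol.shape, dtype=np.float64)
    for patch in inference_patches(vol, patch_size):
        cam = _patch_cam(model, patch.channels, covariates, stage)
        sl = tuple(slice(o, o + patch_size) for o in patch.offset)
        acc[sl] += cam
        weight[sl] += 1.0
    cam = acc / np.maximum(weight, 1.0)
    peak = cam.max()
    return (cam / peak if peak > 0 else cam).astype(np.float32)


def select_axial_levels(root_mask: np.ndarray) -> tuple[int, int, int]:
    """Axial (z) indices at the upper/middle/lower thirds of the root extent,
    emulating ascending-aorta / annulus / outflow-tract panels."""
    zs = np.where(root_mask.any(axis=(0, 1)))[0]
    if len(zs) == 0:
        raise ValueError("empty root mask")
    lo, hi = int(zs[0]), int(zs[-1])
    span = hi - lo
    return (lo + int(span * 5 / 6), lo + int(span * 0.5), lo + int(span * 1 / 6))


def export_overlay(cam: np.ndarray, ct: np.ndarray, levels: list[int],
                   out_dir: str | Path, alpha: float = 0.45,
                   ) -> list[Path]:
    """Write per-level triplets (CT slice, heatmap, overlay) as PNGs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.cm as cm

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nz = ct.shape[2]
    levels = sorted(int(v) for v in levels)
    for lv in levels:
        if not 0 <= lv < nz:
            raise ValueError(f"axial level {lv} outside grid of depth {nz}")
    from matplotlib.image import imsave

    paths = []
    for lv in levels:
        ct_slice = ct[:, :, lv].astype(float)
        span = ct_slice.max() - ct_slice.min()
        ct_norm = (ct_slice - ct_slice.min()) / span if span > 0 \
            else np.zeros_like(ct_slice)
        cam_slice = cam[:, :, lv].astype(float)
        gray = np.stack([ct_norm] * 3, axis=-1)
        heat = cm.jet(cam_slice)[..., :3]
        overlay = (1 - alpha) * gray + alpha * heat if alpha > 0 else gray
        for tag, img in (("ct", gray), ("cam", heat), ("overlay", overlay)):
            path = out_dir / f"level{lv:03d}_{tag}.png"
            imsave(path, np.clip(img, 0, 1))
            paths.append(path)
    return paths
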