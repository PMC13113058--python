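"""Multi-modal fusion network ("Model B").

Imaging branch: a 3-D ResNet-18-style encoder over the 3-channel volumetric
input (CT, root mask, calcification mask). Clinical branch: an MLP embedding
the standardized covariate vector into 64 dimensions. The two are fused by
single-head scaled dot-product cross-attention — image tokens (one per
final-stage spatial location) are the queries; the clinical embedding,
reshaped into m tokens, provides keys and values — and the fused
representation is passed to a sigmoid classification head.

A note on tokenization: with one pooled image vector and one clinical vector
the softmax collapses to a constant 1 and the fusion output would ignore the
image entirely; using spatial image tokens and m > 1 clinical tokens keeps
the published fusion equation intact while making it informative.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nnx
from .nnx import Tensor

__all__ = [
    "EncoderConfig", "FusionConfig", "ResNet3dEncoder", "ClinicalMLP",
    "CrossAttentionFusion", "FusionModel", "bce_loss",
    "save_checkpoint", "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 3
    base_width: int = 64
    width_factor: float = 1.0
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)

    @property
    def stage_widths(self) -> tuple[int, ...]:
        w = max(2, int(round(self.base_width * self.width_factor)))
        return (w, 2 * w, 4 * w, 8 * w)

    @property
    def feature_dim(self) -> int:
        return self.stage_widths[-1]

    @classmethod
    def tiny(cls) -> "EncoderConfig":
        """Desk-scale profile: 1/8 width, trains on one CPU."""
        return cls(width_factor=0.125)


@dataclasses.dataclass(frozen=True)
class FusionConfig:
    n_clinical_features: int = 35
    clinical_embed_dim: int = 64
    n_clinical_tokens: int = 8
    attention_dim: int = 32

    def __post_init__(self):
        if self.clinical_embed_dim % self.n_clinical_tokens != 0:
            raise ValueError("embed dim must be divisible by token count")
        if self.attention_dim <= 0:
            raise ValueError("attention dimension must be positive")


class BasicBlock3d(nnx.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nnx.Conv3d(in_ch, out_ch, 3, stride=stride, padding=1,
                                rng=rng)
        self.bn1 = nnx.BatchNorm3d(out_ch)
        self.conv2 = nnx.Conv3d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.bn2 = nnx.BatchNorm3d(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = nnx.Sequential(
                nnx.Conv3d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng),
                nnx.BatchNorm3d(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.downsample is None else self.downsample(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + identity).relu()


class ResNet3dEncoder(nnx.Module):
    """Four stages of two basic blocks after a strided stem; every stage
    halves the spatial grid, so a 64^3 patch yields a 2x2x2 token grid."""

    def __init__(self, cfg: EncoderConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        widths = cfg.stage_widths
        self.stem = nnx.Sequential(
            nnx.Conv3d(cfg.in_channels, widths[0], 3, stride=2, padding=1,
                       rng=rng),
            nnx.BatchNorm3d(widths[0]),
            nnx.ReLU())
        stages = []
        in_ch = widths[0]
        for w, n_blocks in zip(widths, cfg.blocks_per_stage):
            blocks = [BasicBlock3d(in_ch, w, stride=2, rng=rng)]
            blocks += [BasicBlock3d(w, w, stride=1, rng=rng)
                       for _ in range(n_blocks - 1)]
            stages.append(nnx.Sequential(*blocks))
            in_ch = w
        self.stages = nnx.Sequential(*stages)
        self.last_feature_map: Tensor | None = None   # retained for Grad-CAM
        self.stage_outputs: list[Tensor] = []         # per-stage, ditto

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, D, H, W) -> final feature map (N, d_model, d', h', w')."""
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        out = self.stem(x)
        self.stage_outputs = []
        for stage in self.stages.items:
            out = stage(out)
            self.stage_outputs.append(out)
        self.last_feature_map = out
        return out

    def tokens(self, fmap: Tensor) -> Tensor:
        """Flatten the spatial grid: (N, C, d, h, w) -> (N, T, C)."""
        N, C = fmap.shape[:2]
        T = int(np.prod(fmap.shape[2:]))
        return fmap.reshape(N, C, T).transpose(0, 2, 1)

    def pooled(self, fmap: Tensor) -> Tensor:
        """Global average pooling: (N, C, d, h, w) -> (N, C)."""
        return fmap.mean(axis=(2, 3, 4))


class ClinicalMLP(nnx.Module):
    """Covariate vector -> 64-dim embedding (two-layer perceptron)."""

    def __init__(self, cfg: FusionConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.fc1 = nnx.Linear(cfg.n_clinical_features, cfg.clinical_embed_dim,
                              rng=rng)
        self.fc2 = nnx.Linear(cfg.clinical_embed_dim, cfg.clinical_embed_dim,
                              rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.cfg.n_clinical_features:
            raise ValueError(
                f"expected {self.cfg.n_clinical_features} covariates, "
                f"got {x.shape[-1]}")
        return self.fc2(self.fc1(x).relu())

    def token_view(self, embedding: Tensor) -> Tensor:
        """(N, 64) -> (N, m, 64/m) clinical tokens."""
        m = self.cfg.n_clinical_tokens
        N = embedding.shape[0]
        return embedding.reshape(N, m, self.cfg.clinical_embed_dim // m)


class CrossAttentionFusion(nnx.Module):
    """softmax(Q K^T / sqrt(d)) V with image queries and clinical keys/values;
    the fused token grid is mean-pooled to a single vector."""

    def __init__(self, d_model: int, cfg: FusionConfig, *,
                 rng: np.random.Generator):
        super().__init__()
        d = cfg.attention_dim
        token_dim = cfg.clinical_embed_dim // cfg.n_clinical_tokens
        self.d = d
        self.w_q = nnx.Linear(d_model, d, rng=rng)
        self.w_k = nnx.Linear(token_dim, d, rng=rng)
        self.w_v = nnx.Linear(token_dim, d, rng=rng)
        self.last_weights: np.ndarray | None = None

    def forward(self, image_tokens: Tensor, clinical_tokens: Tensor) -> Tensor:
        q = self.w_q(image_tokens)                       # (N, T, d)
        k = self.w_k(clinical_tokens)                    # (N, m, d)
        v = self.w_v(clinical_tokens)                    # (N, m, d)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d))
        weights = scores.softmax(axis=-1)                # rows sum to 1
        self.last_weights = weights.data.copy()
        fused = weights @ v                              # (N, T, d)
        return fused.mean(axis=1)                        # (N, d)


class FusionModel(nnx.Module):
    """Full Model B: encoder + clinical MLP + cross-attention + sigmoid head."""

    def __init__(self, enc_cfg: EncoderConfig, fus_cfg: FusionConfig,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.enc_cfg = enc_cfg
        self.fus_cfg = fus_cfg
        self.encoder = ResNet3dEncoder(enc_cfg, rng=rng)
        self.clinical = ClinicalMLP(fus_cfg, rng=rng)
        self.fusion = CrossAttentionFusion(enc_cfg.feature_dim, fus_cfg,
                                           rng=rng)
        self.head = nnx.Linear(fus_cfg.attention_dim, 1, rng=rng)

    def forward(self, patches: Tensor, covariates: Tensor) -> Tensor:
        """Returns predicted probabilities, shape (N,)."""
        fmap = self.encoder(patches)
        img_tokens = self.encoder.tokens(fmap)
        clin_tokens = self.clinical.token_view(self.clinical(covariates))
        fused = self.fusion(img_tokens, clin_tokens)
        logit = self.head(fused)
        return logit.sigmoid().reshape(logit.shape[0])

    def predict_volume(self, volume_channels: np.ndarray,
                       covariates: np.ndarray, patch_size: int) -> float:
        """Average patch probabilities over the deterministic inference grid."""
        from .preprocess import PreprocessedVolume, inference_patches

        vol = PreprocessedVolume(volume_channels, "inference", (1, 1, 1),
                                 ((0, 0), (0, 0), (0, 0)))
        patches = inference_patches(vol, patch_size)
        self.eval()
        probs = []
        for p in patches:
            x = Tensor(p.channels[None])
            c = Tensor(np.asarray(covariates, dtype=np.float32)[None])
            probs.append(float(self.forward(x, c).data[0]))
        return float(np.mean(probs))


def bce_loss(p: Tensor, y: np.ndarray, sample_weights: np.ndarray | None = None,
             eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy, optionally weighted per sample.

    Probabilities are clamped to [eps, 1-eps] so the loss is never NaN.
    """
    y = np.asarray(y, dtype=np.float32)
    if y.shape[0] != p.shape[0]:
        raise ValueError("labels and probabilities must have equal length")
    if y.shape[0] < 1:
        raise ValueError("empty batch")
    pc = p.clip(eps, 1.0 - eps)
    terms = Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()
    if sample_weights is not None:
        terms = terms * Tensor(np.asarray(sample_weights, dtype=np.float32))
    return -terms.mean()


def class_balanced_weights(y: np.ndarray) -> np.ndarray:
    """Weights w_c = n / (2 * n_c), so both classes contribute equally."""
    y = np.asarray(y)
    n = len(y)
    w = np.ones(n, dtype=np.float32)
    for cls in (0, 1):
        n_c = max(int((y == cls).sum()), 1)
        w[y == cls] = n / (2.0 * n_c)
    return w


# ----------------------------------------------------------------- checkpoints

def save_checkpoint(model: FusionModel, path: str | Path) -> None:
    """Parameters to one .npz; self-describing config JSON alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    cfg = {
        "encoder": dataclasses.asdict(model.enc_cfg),
        "fusion": dataclasses.asdict(model.fus_cfg),
    }
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> FusionModel:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    enc = cfg["encoder"]
    enc["blocks_per_stage"] = tuple(enc["blocks_per_stage"])
    model = FusionModel(EncoderConfig(**enc), FusionConfig(**cfg["fusion"]))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
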