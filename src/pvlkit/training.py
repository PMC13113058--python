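"""Two-stage training: proxy pretraining and cross-validated fine-tuning.

Stage 1 trains the volumetric encoder to regress (log-standardized)
calcification volume; by construction its input type carries no outcome
labels, so the stage cannot leak outcome information. Stage 2 initializes
the imaging branch from the pretrained encoder and fine-tunes the full
fusion model end-to-end under 5-fold stratified cross-validation, producing
exactly one out-of-fold probability per patient.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import nnx
from .nnx import Tensor
from .model_b import (EncoderConfig, FusionConfig, FusionModel,
                      ResNet3dEncoder, bce_loss, class_balanced_weights)
from .preprocess import AugmentConfig, PreprocessedVolume, random_patch

__all__ = [
    "Stage1Config", "Stage2Config", "FoldPlan", "PredictionSet",
    "PretrainingSet", "LogStandardizer", "standardize_log_target",
    "make_stratified_folds", "stage1_pretrain", "stage2_finetune", "binarize",
]


@dataclasses.dataclass(frozen=True)
class Stage1Config:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 4
    max_epochs: int = 100
    val_fraction: float = 0.10
    patience: int = 10
    patch_size: int = 64
    patches_per_volume: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if min(self.learning_rate, self.weight_decay, self.batch_size,
               self.max_epochs) <= 0:
            raise ValueError("hyperparameters must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "Stage1Config":
        return cls(learning_rate=5e-3, batch_size=8, max_epochs=120,
                   patience=40, patch_size=32, patches_per_volume=2,
                   seed=seed)


@dataclasses.dataclass(frozen=True)
class Stage2Config:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 4
    scheduler_factor: float = 0.35
    scheduler_patience: int = 10
    max_epochs: int = 200
    early_stop_patience: int = 40
    n_folds: int = 5
    patch_size: int = 64
    class_balanced: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.scheduler_factor < 1:
            raise ValueError("scheduler factor must be in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be below max epochs")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "Stage2Config":
        return cls(learning_rate=2e-3, scheduler_patience=4,
                   max_epochs=16, early_stop_patience=15, patch_size=32,
                   seed=seed)


@dataclasses.dataclass
class FoldPlan:
    """Partition of the cohort into k stratified folds."""

    fold_of: np.ndarray            # fold index per patient, in {0..k-1}
    k: int

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of != fold)[0]

    def val_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of == fold)[0]

    def content_hash(self) -> str:
        import hashlib
        return hashlib.sha256(self.fold_of.astype(np.int64).tobytes()
                              ).hexdigest()


@dataclasses.dataclass
class PredictionSet:
    """Out-of-fold probabilities: the substrate for all evaluation."""

    patient_ids: list[str]
    y: np.ndarray
    p: np.ndarray
    fold: np.ndarray
    model_tag: str

    def __post_init__(self):
        n = len(self.patient_ids)
        if not (len(self.y) == len(self.p) == len(self.fold) == n):
            raise ValueError("misaligned prediction set")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate out-of-fold prediction")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("probabilities outside [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"patient_id": self.patient_ids, "fold": self.fold,
                      "y": self.y, "p": self.p}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, model_tag: str = "") -> "PredictionSet":
        df = pd.read_csv(path)
        return cls(list(df["patient_id"]), df["y"].to_numpy(int),
                   df["p"].to_numpy(float), df["fold"].to_numpy(int),
                   model_tag)


class PretrainingSet:
    """Stage-1 input: volumes plus calcification volumes — no outcome field.

    The deliberate absence of any label attribute is the leakage firewall:
    Stage 1 code receives only this type and cannot read what is not there.
    """

    __slots__ = ("volumes", "calc_volumes_mm3")

    def __init__(self, volumes: list[PreprocessedVolume],
                 calc_volumes_mm3: np.ndarray):
        if len(volumes) != len(calc_volumes_mm3):
            raise ValueError("volumes and targets misaligned")
        self.volumes = volumes
        self.calc_volumes_mm3 = np.asarray(calc_volumes_mm3, dtype=float)


# ------------------------------------------------------------- target scaling

class LogStandardizer:
    """log1p then z-score with statistics frozen from a reference set."""

    def __init__(self):
        self.mean_: float | None = None
        self.sd_: float | None = None

    def fit(self, reference: np.ndarray) -> "LogStandardizer":
        reference = np.asarray(reference, dtype=float)
        if np.any(reference < 0):
            raise ValueError("volumes must be non-negative")
        logs = np.log1p(reference)
        sd = float(logs.std())
        if sd == 0:
            raise ValueError("zero variance in reference set")
        self.mean_ = float(logs.mean())
        self.sd_ = sd
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.log1p(np.asarray(values, dtype=float)) - self.mean_) / self.sd_

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.expm1(np.asarray(z, dtype=float) * self.sd_ + self.mean_)


def standardize_log_target(values: np.ndarray,
                           reference: np.ndarray) -> np.ndarray:
    """z-scores of log1p(values) under reference-set statistics."""
    return LogStandardizer().fit(reference).transform(values)


# ---------------------------------------------------------------------- folds

def make_stratified_folds(labels: np.ndarray, k: int = 5,
                          seed: int = 0) -> FoldPlan:
    """Deal each class round-robin after a seeded shuffle, so per-fold
    validation sizes and event counts each differ by at most one."""
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    fold_of = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} members, fewer than k={k}")
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[i] = j % k
    # rotate fold order per class start so fold sizes stay balanced
    return FoldPlan(fold_of=fold_of, k=k)


def binarize(pred: PredictionSet, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff p >= threshold (ties go positive)."""
    return (pred.p >= threshold).astype(int)


# ---------------------------------------------------------------- Stage 1

def _patch_batches(indices: np.ndarray, batch_size: int,
                   rng: np.random.Generator):
    order = indices.copy()
    rng.shuffle(order)
    for i in range(0, len(order), batch_size):
        yield order[i:i + batch_size]


def _tiled_prediction(forward, vol: PreprocessedVolume, patch_size: int):
    """Average `forward` over the deterministic inference tiling."""
    from .preprocess import inference_patches

    vals = [forward(p.channels[None]) for p in inference_patches(vol, patch_size)]
    return float(np.mean(vals))


def stage1_pretrain(data: PretrainingSet, cfg: Stage1Config,
                    enc_cfg: EncoderConfig | None = None,
                    ) -> tuple[dict[str, np.ndarray], dict]:
    """Proxy-task pretraining of the encoder on calcification volume.

    Returns (encoder state dict at the best validation epoch, training log).
    The regression head is trained but not returned.
    """
    if not isinstance(data, PretrainingSet):
        raise TypeError("stage 1 accepts only PretrainingSet (no labels)")
    n = len(data.volumes)
    if n < cfg.batch_size:
        raise ValueError(f"need at least {cfg.batch_size} samples, got {n}")
    enc_cfg = enc_cfg or EncoderConfig.tiny()
    rng = np.random.default_rng(cfg.seed)

    # random (not stratified: no labels exist here) internal validation split
    order = rng.permutation(n)
    n_val = max(1, int(round(n * cfg.val_fraction)))
    val_idx, train_idx = order[:n_val], order[n_val:]

    scaler = LogStandardizer().fit(
        data.calc_volumes_mm3[train_idx])
    z = scaler.transform(data.calc_volumes_mm3)

    encoder = ResNet3dEncoder(enc_cfg, rng=np.random.default_rng(cfg.seed + 1))
    head = nnx.Linear(enc_cfg.feature_dim, 1,
                      rng=np.random.default_rng(cfg.seed + 2))
    params = encoder.parameters() + head.parameters()
    opt = nnx.Adam(params, lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
    aug = AugmentConfig(crop_size=cfg.patch_size)

    def predict_patch(channels: np.ndarray) -> float:
        fmap = encoder(Tensor(channels))
        return float(head(encoder.pooled(fmap)).data[0, 0])

    def val_mse() -> float:
        encoder.eval()
        errs = []
        for i in val_idx:
            pred = _tiled_prediction(predict_patch, data.volumes[i],
                                     cfg.patch_size)
            errs.append((pred - z[i]) ** 2)
        encoder.train()
        return float(np.mean(errs))

    log = {"train_loss": [], "val_mse": [], "best_epoch": -1,
           "head_state": head.state_dict(), "scaler": None}
    best = np.inf
    best_state = encoder.state_dict()
    bad = 0
    for epoch in range(cfg.max_epochs):
        losses = []
        epoch_idx = np.repeat(train_idx, cfg.patches_per_volume)
        for batch in _patch_batches(epoch_idx, cfg.batch_size, rng):
            xs = np.stack([random_patch(data.volumes[i], aug, rng).channels
                           for i in batch])
            targets = z[batch].astype(np.float32)
            fmap = encoder(Tensor(xs))
            pred = head(encoder.pooled(fmap)).reshape(len(batch))
            diff = pred - Tensor(targets)
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mse = val_mse()
        log["train_loss"].append(float(np.mean(losses)))
        log["val_mse"].append(mse)
        if mse < best - 1e-6:
            best = mse
            best_state = encoder.state_dict()
            log["best_epoch"] = epoch
            log["head_state"] = head.state_dict()  # diagnostic only
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    log["scaler"] = {"mean": scaler.mean_, "sd": scaler.sd_}
    return best_state, log


# ---------------------------------------------------------------- Stage 2

def stage2_finetune(volumes: list[PreprocessedVolume],
                    covariates: pd.DataFrame,
                    labels: np.ndarray,
                    folds: FoldPlan,
                    cfg: Stage2Config,
                    enc_cfg: EncoderConfig | None = None,
                    fus_cfg: FusionConfig | None = None,
                    encoder_state: dict[str, np.ndarray] | None = None,
                    run_dir: str | Path | None = None,
                    patient_ids: list[str] | None = None,
                    ) -> tuple[PredictionSet, dict]:
    """Cross-validated end-to-end fine-tuning of the fusion model.

    Covariates are standardized per fold using training-split statistics
    only. Returns the pooled out-of-fold PredictionSet and a log with
    per-fold histories and learning-rate reduction events.
    """
    labels = np.asarray(labels).astype(int)
    n = len(volumes)
    if not (len(covariates) == len(labels) == n):
        raise ValueError("cohort arrays misaligned")
    enc_cfg = enc_cfg or EncoderConfig.tiny()
    fus_cfg = fus_cfg or FusionConfig(
        n_clinical_features=covariates.shape[1])
    if fus_cfg.n_clinical_features != covariates.shape[1]:
        raise ValueError("fusion config covariate count mismatch")

    X = covariates.to_numpy(dtype=float)
    oof_p = np.full(n, np.nan)
    log: dict = {"folds": [], "fold_hash": folds.content_hash()}

    for fold in range(folds.k):
        tr = folds.train_indices(fold)
        va = folds.val_indices(fold)
        if len(np.unique(labels[tr])) < 2:
            raise ValueError(f"fold {fold}: single-class training split")
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (X - mu) / sd       # train-split statistics applied to everyone

        rng = np.random.default_rng(cfg.seed * 1000 + fold)
        model = FusionModel(enc_cfg, fus_cfg, seed=cfg.seed * 1000 + fold)
        if encoder_state is not None:
            model.encoder.load_state_dict(encoder_state)
        opt = nnx.Adam(model.parameters(), lr=cfg.learning_rate,
                       weight_decay=cfg.weight_decay)
        sched = nnx.ReduceLROnPlateau(opt, factor=cfg.scheduler_factor,
                                      patience=cfg.scheduler_patience)
        aug = AugmentConfig(crop_size=cfg.patch_size)
        weights_all = (class_balanced_weights(labels[tr])
                       if cfg.class_balanced else np.ones(len(tr)))
        w_of = dict(zip(tr.tolist(), weights_all))

        def val_loss() -> float:
            model.eval()
            losses = []
            for i in va:
                p = model.predict_volume(volumes[i].channels, Xz[i],
                                         cfg.patch_size)
                p = min(max(p, 1e-7), 1 - 1e-7)
                losses.append(-(labels[i] * np.log(p)
                                + (1 - labels[i]) * np.log(1 - p)))
            model.train()
            return float(np.mean(losses))

        history = {"train_loss": [], "val_loss": [], "lr_events": [],
                   "best_epoch": -1}
        best = np.inf
        best_state = model.state_dict()
        bad = 0
        for epoch in range(cfg.max_epochs):
            losses = []
            for batch in _patch_batches(tr, cfg.batch_size, rng):
                xs = np.stack([random_patch(volumes[i], aug, rng).channels
                               for i in batch])
                cov = Xz[batch].astype(np.float32)
                p = model(Tensor(xs), Tensor(cov))
                w = np.array([w_of[int(i)] for i in batch], dtype=np.float32)
                loss = bce_loss(p, labels[batch], w)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            vl = val_loss()
            sched.step(vl)
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(vl)
            if vl < best - 1e-6:
                best = vl
                best_state = model.state_dict()
                history["best_epoch"] = epoch
                bad = 0
            else:
                bad += 1
                if bad >= cfg.early_stop_patience:
                    break
        history["lr_events"] = list(sched.events)
        model.load_state_dict(best_state)
        model.eval()
        for i in va:
            oof_p[i] = model.predict_volume(volumes[i].channels, Xz[i],
                                            cfg.patch_size)
        log["folds"].append(history)
        if run_dir is not None:
            from .model_b import save_checkpoint
            save_checkpoint(model, Path(run_dir) / f"fold{fold}.npz")

    assert not np.any(np.isnan(oof_p)), "missing out-of-fold prediction"
    if patient_ids is None:
        patient_ids = [f"idx-{i}" for i in range(n)]
    pred = PredictionSet(patient_ids=list(patient_ids), y=labels, p=oof_p,
                         fold=folds.fold_of.copy(), model_tag="B")
    if run_dir is not None:
        Path(run_dir).mkdir(parents=True, exist_ok=True)
        pred.to_csv(Path(run_dir) / "oof_predictions.csv")
    return pred, log
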