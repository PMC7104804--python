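"""Training, fine-tuning, augmentation, and evaluation metrics.

The training protocol: mean squared error loss, Adam (learning rate
0.0005, β1 0.9, β2 0.999), batch size 8, shuffling every epoch,
validation MAE evaluated after each epoch, and the parameter snapshot
from the best-validation epoch restored at the end (earliest epoch wins
on ties).

Fine-tuning runs the identical protocol but starts from pretrained
weights and applies a random rigid augmentation (rotation up to a bound
in degrees about a random grid axis, integer translation up to a bound
in voxels per axis) to every training volume each time it is drawn.
Validation and test volumes are never augmented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from . import nn
from .errors import DomainError, ShapeError, ValidationError
from .model import RegressionNet
from .volume_io import CohortTable, Volume

__all__ = [
    "TrainConfig",
    "AugmentSpec",
    "TrainResult",
    "Metrics",
    "mse_loss",
    "train",
    "fine_tune",
    "augment",
    "evaluate",
    "predict",
]


@dataclass
class AugmentSpec:
    """Bounds for random rigid augmentation."""

    max_rotation_deg: float = 5.0
    max_translation_voxels: int = 10

    def __post_init__(self):
        if self.max_rotation_deg < 0 or self.max_translation_voxels < 0:
            raise DomainError("augmentation bounds must be non-negative")


@dataclass
class TrainConfig:
    learning_rate: float = 0.0005
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    epochs: int = 50
    dropout_rate: float = 0.4
    seed: int = 0
    augmentation: AugmentSpec | None = None
    standardize_covariates: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise DomainError("learning rate must be positive")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DomainError(f"{name} must lie in (0, 1), got {v}")
        if self.batch_size < 1 or self.epochs < 1:
            raise DomainError("batch size and epochs must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DomainError("dropout rate must be in [0, 1)")


@dataclass
class TrainResult:
    best_net: RegressionNet
    history: list[dict]
    best_epoch: int


@dataclass
class Metrics:
    """Standard regression metrics between true and predicted targets."""

    mae: float
    stdae: float
    rmse: float
    r_squared: float
    pearson_r: float

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "stdae": self.stdae,
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "pearson_r": self.pearson_r,
        }


def mse_loss(predicted, target) -> float:
    """Mean squared error."""
    p = np.asarray(predicted, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise DomainError("mse_loss needs at least one pair")
    return float(np.mean((p - t) ** 2))


# --------------------------------------------------------------------------
# data assembly


def _load_arrays(table: CohortTable, require_targets: bool = True):
    """Materialize a cohort as (X, covariates, targets) float32 arrays."""
    if len(table) == 0:
        raise DomainError("empty cohort")
    vols, covs, targets = [], [], []
    for r in table:
        if require_targets and r.bmi_kg_m2 is None:
            raise ValidationError(f"subject {r.subject_id!r} has no target BMI")
        v = r.load_volume(table.base_dir)
        vols.append(np.asarray(v.intensities, dtype=np.float32))
        covs.append([r.age_years, r.sex_code])
        targets.append(np.nan if r.bmi_kg_m2 is None else r.bmi_kg_m2)
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ShapeError(f"cohort volumes have mixed shapes: {sorted(shapes)}")
    x = np.stack(vols)[:, None]  # (n, 1, i, j, k)
    return x, np.asarray(covs, dtype=np.float64), np.asarray(targets, dtype=np.float64)


def _predict_array(net: RegressionNet, x, cov, batch_size: int = 16) -> np.ndarray:
    preds = []
    for lo in range(0, x.shape[0], batch_size):
        hi = lo + batch_size
        c = cov[lo:hi] if net.config.use_covariates else None
        preds.append(net.forward_batch(x[lo:hi], c, training=False))
    return np.concatenate(preds).astype(np.float64)


def predict(net: RegressionNet, table: CohortTable) -> np.ndarray:
    """Evaluation-mode predictions for every record in a cohort."""
    x, cov, _ = _load_arrays(table, require_targets=False)
    return _predict_array(net, x, cov)


# --------------------------------------------------------------------------
# augmentation


def _augment_array(arr: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Random rigid transform of a 3D array: rotation then integer shift, zero fill."""
    out = arr
    if spec.max_rotation_deg > 0:
        angle = rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)
        axis = int(rng.integers(3))
        plane = tuple(a for a in (0, 1, 2) if a != axis)
        out = ndimage.rotate(
            out, angle, axes=plane, reshape=False, order=3, mode="constant", cval=0.0
        )
    t = spec.max_translation_voxels
    if t > 0:
        shifts = rng.integers(-t, t + 1, size=3)
        shifted = np.zeros_like(out)
        src, dst = [], []
        for n, s in zip(out.shape, shifts):
            s = int(s)
            if abs(s) >= n:
                return shifted
            if s >= 0:
                dst.append(slice(s, n))
                src.append(slice(0, n - s))
            else:
                dst.append(slice(0, n + s))
                src.append(slice(-s, n))
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return out if out is not arr else arr.copy()


def augment(volume: Volume, spec: AugmentSpec, seed: int) -> Volume:
    """Apply one seeded random rigid augmentation to a volume."""
    rng = np.random.default_rng(seed)
    data = _augment_array(np.asarray(volume.intensities, dtype=np.float32), spec, rng)
    return replace(volume, intensities=data)


# --------------------------------------------------------------------------
# metrics


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("constant vector in correlation; reporting r = 0", stacklevel=3)
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def compute_metrics(true, predicted) -> Metrics:
    """MAE, STDAE (population SD of |error|), RMSE, R², Pearson r."""
    t = np.asarray(true, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if t.shape != p.shape:
        raise ShapeError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 2:
        raise DomainError("metrics need at least 2 pairs")
    err = p - t
    abs_err = np.abs(err)
    sstot = np.sum((t - t.mean()) ** 2)
    ssres = np.sum(err**2)
    r2 = 1.0 - ssres / sstot if sstot > 0 else (1.0 if ssres == 0 else -np.inf)
    return Metrics(
        mae=float(abs_err.mean()),
        stdae=float(abs_err.std()),
        rmse=float(np.sqrt(np.mean(err**2))),
        r_squared=float(r2),
        pearson_r=_pearson(t, p),
    )


def evaluate(net: RegressionNet, test_set: CohortTable) -> Metrics:
    """Evaluation-mode metrics of a network on a labelled cohort."""
    x, cov, y = _load_arrays(test_set, require_targets=True)
    if y.size < 2:
        raise DomainError("evaluation needs at least 2 subjects")
    preds = _predict_array(net, x, cov)
    return compute_metrics(y, preds)


# --------------------------------------------------------------------------
# training loop


def train(
    net: RegressionNet,
    train_set: CohortTable,
    val_set: CohortTable,
    config: TrainConfig,
) -> TrainResult:
    """Train a network; returns the best-validation-epoch snapshot and history.

    Deterministic given (data, config.seed) on a fixed platform.  Three
    independent random streams are derived from the seed: data order,
    dropout masks, and augmentation draws, so they can be reasoned about
    separately.
    """
    x_tr, cov_tr, y_tr = _load_arrays(train_set)
    x_va, cov_va, y_va = _load_arrays(val_set)

    net.dropout.rate = config.dropout_rate
    if config.standardize_covariates and net.config.use_covariates:
        mean = cov_tr.mean(axis=0)
        sd = cov_tr.std(axis=0)
        sd[sd < 1e-8] = 1.0
        net.covariate_stats = (mean, sd)

    ss = np.random.SeedSequence(config.seed)
    data_rng, dropout_rng, aug_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    optimizer = nn.Adam(
        net.parameters(), config.learning_rate, config.beta1, config.beta2
    )

    n = x_tr.shape[0]
    history: list[dict] = []
    best_epoch = -1
    best_mae = np.inf
    best_state: dict | None = None
    y_tr32 = y_tr.astype(np.float32)

    for epoch in range(1, config.epochs + 1):
        order = data_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = x_tr[idx]
            if config.augmentation is not None:
                xb = np.stack(
                    [_augment_array(xb[i, 0], config.augmentation, aug_rng) for i in range(len(idx))]
                )[:, None]
            cb = cov_tr[idx] if net.config.use_covariates else None
            optimizer.zero_grad()
            preds = net.forward_batch(xb, cb, training=True, rng=dropout_rng)
            resid = preds - y_tr32[idx]
            losses.append(float(np.mean(resid**2)))
            net.backward_batch((2.0 / len(idx)) * resid.astype(np.float32))
            optimizer.step()

        val_pred = _predict_array(net, x_va, cov_va)
        val_abs = np.abs(val_pred - y_va)
        rec = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_mae": float(val_abs.mean()),
            "val_stdae": float(val_abs.std()),
        }
        history.append(rec)
        if rec["val_mae"] < best_mae:
            best_mae = rec["val_mae"]
            best_epoch = epoch
            best_state = net.snapshot()

    assert best_state is not None
    net.load_state_arrays(best_state)
    return TrainResult(best_net=net, history=history, best_epoch=best_epoch)


def fine_tune(
    pretrained: RegressionNet,
    train_set: CohortTable,
    val_set: CohortTable,
    config: TrainConfig,
) -> TrainResult:
    """Fine-tune a pretrained network with training-set augmentation.

    Identical protocol to :func:`train` except the starting weights come
    from ``pretrained`` and every training volume is augmented per
    ``config.augmentation`` each time it is drawn.
    """
    if config.augmentation is None:
        config = replace(config, augmentation=AugmentSpec())
    return train(pretrained, train_set, val_set, config)


def history_to_frame(history: list[dict]):
    import pandas as pd

    return pd.DataFrame(history, columns=["epoch", "train_loss", "val_mae", "val_stdae"])
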