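"""Regression-adapted 3D Grad-CAM localization maps.

For a trained network predicting a scalar y, the gradient of y with
respect to each feature map A^n of the last convolutional block (post
batch-normalization and ReLU) is globally average-pooled into an
importance weight

    α_n = (1/Z) Σ_ijk ∂y/∂A^n_ijk ,        Z = units per feature map,

and the localization map is the weighted combination

    L = Σ_n α_n A^n .

Because the output is a single regression unit, no ReLU is applied to L:
voxels that push the prediction down are as informative as voxels that
push it up, so the signed map is kept.

Per-subject maps are upsampled to input-volume resolution with spline
interpolation, standardized to zero mean / unit variance over the grid,
voxelwise-averaged across subjects, re-standardized, and thresholded at
|Z| > 2 standard deviations to produce a cohort mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateMapError,
    ShapeError,
    StateError,
    ValidationError,
)
from .model import RegressionNet
from .volume_io import CohortTable, Volume, write_volume

__all__ = [
    "FeatureStack",
    "ImportanceWeights",
    "LocalizationMap",
    "GrandAverageMap",
    "capture_features_and_gradients",
    "importance_weights",
    "localization_map",
    "upsample_map",
    "standardize_map",
    "grand_average",
    "subject_map",
    "cohort_maps",
    "save_map",
]


@dataclass
class FeatureStack:
    """n feature maps (or their gradients) of one shared spatial shape."""

    maps: np.ndarray  # (n, u, v, w)

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 4:
            raise ShapeError(f"expected (n, u, v, w) maps, got shape {self.maps.shape}")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def z_units(self) -> int:
        return int(np.prod(self.maps.shape[1:]))


@dataclass
class ImportanceWeights:
    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.alpha.ndim != 1:
            raise ShapeError("importance weights must be a vector")
        if not np.all(np.isfinite(self.alpha)):
            raise ValidationError("importance weights must be finite")


@dataclass
class LocalizationMap:
    """A 3D importance grid at one of the stages raw → upsampled → standardized."""

    values: np.ndarray
    stage: str = "raw"
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ShapeError("localization map must be 3D")
        if self.stage not in ("raw", "upsampled", "standardized"):
            raise ValidationError(f"unknown stage {self.stage!r}")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class GrandAverageMap:
    """Cohort-average standardized map with its suprathreshold mask."""

    values: np.ndarray
    n_subjects: int
    threshold_sd: float
    thresholded_mask: np.ndarray
    affine: np.ndarray | None = None


def capture_features_and_gradients(
    net: RegressionNet, volume: Volume | np.ndarray, covariates=None
) -> tuple[FeatureStack, FeatureStack]:
    """Last-block feature maps and ∂y/∂A^n for one subject, in evaluation mode."""
    arr = volume.intensities if isinstance(volume, Volume) else np.asarray(volume)
    if arr.ndim != 3:
        raise ShapeError(f"expected a 3D volume, got shape {arr.shape}")
    x = arr[None, None].astype(net.dtype, copy=False)
    cov = None
    if net.config.use_covariates:
        if covariates is None:
            raise ValidationError("this network requires covariates")
        cov = np.asarray(covariates, dtype=net.dtype)[None, :]
    a = net.trunk_forward(x, training=False)
    net.head_forward(a, cov, training=False)
    grads = net.head_backward(np.ones(1, dtype=net.dtype))
    for p in net.parameters():
        p.grad[...] = 0  # head_backward accumulates; capture must not leak into training
    features = FeatureStack(a[0].astype(np.float64))
    gradients = FeatureStack(grads[0].astype(np.float64))
    if not np.all(np.isfinite(gradients.maps)):
        raise ValidationError("non-finite gradients captured")
    return features, gradients


def importance_weights(gradients: FeatureStack) -> ImportanceWeights:
    """Global average pooling of the gradients: α_n = mean over spatial units."""
    return ImportanceWeights(gradients.maps.mean(axis=(1, 2, 3)))


def localization_map(features: FeatureStack, weights: ImportanceWeights) -> LocalizationMap:
    """Weighted combination L = Σ_n α_n A^n.  No rectification: the sign is kept."""
    if features.n_maps != weights.alpha.shape[0]:
        raise ShapeError(
            f"{features.n_maps} feature maps but {weights.alpha.shape[0]} weights"
        )
    values = np.tensordot(weights.alpha, features.maps, axes=1)
    return LocalizationMap(values=values, stage="raw")


def receptive_field_geometry(
    input_shape: tuple[int, int, int], n_pools: int
) -> tuple[list[int], list[int]]:
    """Per-axis (step, offset) mapping feature cell c to its receptive-field
    center at input resolution: center = step·c + offset.

    Each SAME max pooling (window 3, stride 2) maps output cell c to the
    input cell 2c+1 when the level's length is even (padding falls on the
    right) and 2c when it is odd (symmetric padding); the odd-extent SAME
    convolutions are center-preserving.  Composing the pools gives the
    exact alignment of the last block's feature grid.
    """
    steps, offsets = [], []
    for length in input_shape:
        s, o, cur = 1, 0, int(length)
        for _ in range(n_pools):
            if cur % 2 == 0:
                o = s + o
            s *= 2
            cur = -(-cur // 2)
        steps.append(s)
        offsets.append(o)
    return steps, offsets


def upsample_map(
    map_: LocalizationMap,
    target_shape: tuple[int, int, int],
    spline_order: int = 3,
    affine: np.ndarray | None = None,
    rf_geometry: tuple[list[int], list[int]] | None = None,
) -> LocalizationMap:
    """Spline-upsample a raw map to input-volume resolution.

    With ``rf_geometry`` (per-axis steps and offsets from
    :func:`receptive_field_geometry`), each feature cell is placed at its
    receptive-field center, so upsampled maps are registered to the input
    volume; without it, a plain corner-aligned zoom is used.
    """
    if map_.stage != "raw":
        raise StateError(f"can only upsample a raw map, got stage {map_.stage!r}")
    if rf_geometry is not None:
        steps, offsets = rf_geometry
        coords = np.meshgrid(
            *[
                (np.arange(t) - o) / s
                for t, s, o in zip(target_shape, steps, offsets)
            ],
            indexing="ij",
        )
        values = ndimage.map_coordinates(
            map_.values, coords, order=spline_order, mode="nearest"
        )
    else:
        factors = [t / s for t, s in zip(target_shape, map_.values.shape)]
        values = ndimage.zoom(map_.values, factors, order=spline_order)
        if values.shape != tuple(target_shape):  # guard against rounding at odd ratios
            pads = [(0, max(0, t - s)) for t, s in zip(target_shape, values.shape)]
            values = np.pad(values, pads, mode="edge")[
                tuple(slice(0, t) for t in target_shape)
            ]
    return LocalizationMap(values=values, stage="upsampled", affine=affine)


def standardize_map(map_: LocalizationMap) -> LocalizationMap:
    """Standardize to zero mean and unit variance over the whole grid."""
    if map_.stage != "upsampled":
        raise StateError(f"can only standardize an upsampled map, got stage {map_.stage!r}")
    sd = map_.values.std()
    if sd < 1e-12:
        raise DegenerateMapError("map has zero variance; cannot standardize")
    values = (map_.values - map_.values.mean()) / sd
    return LocalizationMap(values=values, stage="standardized", affine=map_.affine)


def grand_average(
    maps: list[LocalizationMap], threshold_sd: float = 2.0
) -> GrandAverageMap:
    """Voxelwise mean of standardized maps, re-standardized and thresholded.

    The mask marks voxels with |Z| > ``threshold_sd`` after
    re-standardization of the cohort average.
    """
    if not maps:
        raise ValidationError("grand_average needs at least one map")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValidationError(f"maps have mixed shapes: {sorted(shapes)}")
    for m in maps:
        if m.stage != "standardized":
            raise StateError("grand_average expects standardized maps")
    if threshold_sd <= 0:
        raise ValidationError("threshold must be positive")
    mean_map = np.mean([m.values for m in maps], axis=0)
    sd = mean_map.std()
    if sd < 1e-12:
        raise DegenerateMapError("cohort-average map has zero variance")
    z = (mean_map - mean_map.mean()) / sd
    return GrandAverageMap(
        values=z,
        n_subjects=len(maps),
        threshold_sd=float(threshold_sd),
        thresholded_mask=np.abs(z) > threshold_sd,
        affine=maps[0].affine,
    )


# --------------------------------------------------------------------------
# convenience pipelines


def subject_map(
    net: RegressionNet, volume: Volume | np.ndarray, covariates=None
) -> LocalizationMap:
    """Full per-subject pipeline: capture → weights → combine → upsample → standardize.

    Upsampling is registered to the network's receptive-field geometry so
    feature cells land on the input voxels they actually summarize.
    """
    arr = volume.intensities if isinstance(volume, Volume) else np.asarray(volume)
    affine = volume.affine if isinstance(volume, Volume) else None
    features, gradients = capture_features_and_gradients(net, arr, covariates)
    raw = localization_map(features, importance_weights(gradients))
    n_pools = sum(1 for b in net.config.blocks if b.followed_by_pool)
    geometry = receptive_field_geometry(arr.shape, n_pools)
    up = upsample_map(raw, arr.shape, affine=affine, rf_geometry=geometry)
    return standardize_map(up)


def cohort_maps(
    net: RegressionNet, table: CohortTable, threshold_sd: float = 2.0
) -> tuple[list[LocalizationMap], GrandAverageMap]:
    """Per-subject standardized maps plus the thresholded grand average."""
    maps = []
    for r in table:
        vol = r.load_volume(table.base_dir)
        cov = [r.age_years, r.sex_code] if net.config.use_covariates else None
        maps.append(subject_map(net, vol, cov))
    return maps, grand_average(maps, threshold_sd)


def save_map(map_: LocalizationMap | GrandAverageMap, path, affine=None) -> None:
    """Write a map (or a grand-average mask alongside it) as NIfTI."""
    aff = affine if affine is not None else (map_.affine if map_.affine is not None else np.eye(4))
    write_volume(Volume(intensities=np.asarray(map_.values, dtype=np.float32), affine=aff), path)
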