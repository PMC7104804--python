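"""The separable-convolution regression network.

The reference architecture maps a single-channel 3D volume to one scalar:

* 8 blocks, each = spatially separable convolution (N×1×1, 1×N×1, 1×1×N;
  kernel extent 5 in the first block, 3 afterwards) → batch normalization
  → ReLU.  Channel schedule 1→8→16→16→32→32→64→64→128 (filter count
  doubled at regular intervals).
* 3×3×3 max pooling (stride 2, SAME) after blocks 2, 4 and 6.
* Global average pooling after block 8 gives one scalar per feature map
  (128 values); optional covariates (age in years, sex coded 0/1) are
  concatenated, giving 130 inputs.
* A 128-unit fully connected hidden layer with ReLU and dropout feeds a
  single linear output unit.

With the reference configuration this network has exactly 231,681
parameters, of which 230,961 are trainable; the remaining 720 are batch-
normalization running statistics (2 × 360 channels).  The block-by-block
arithmetic is laid out in ``docs/methods.md``.

Global average pooling makes the trunk shape-agnostic: the same
configuration runs on any input shape large enough to survive the pooling
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError, ValidationError
from .volume_io import Volume

__all__ = [
    "BlockSpec",
    "NetConfig",
    "RegressionNet",
    "reference_config",
    "build_model",
    "count_parameters",
    "load_model",
]

REFERENCE_TOTAL_PARAMS = 231_681
REFERENCE_TRAINABLE_PARAMS = 230_961


@dataclass(frozen=True)
class BlockSpec:
    """One separable-convolution block."""

    kernel_extent: int
    in_channels: int
    out_channels: int
    followed_by_pool: bool = False

    def __post_init__(self):
        if self.kernel_extent < 1 or self.kernel_extent % 2 != 1:
            raise ConfigurationError(f"kernel extent must be odd, got {self.kernel_extent}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")


@dataclass
class NetConfig:
    blocks: list[BlockSpec]
    hidden_units: int = 128
    dropout_rate: float = 0.4
    use_covariates: bool = True
    n_covariates: int = 2
    input_shape: tuple[int, int, int] = (91, 109, 91)

    def validate(self) -> None:
        if not self.blocks:
            raise ConfigurationError("at least one block is required")
        if self.blocks[0].in_channels != 1:
            raise ConfigurationError("first block must take the single-channel image")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.out_channels != b.in_channels:
                raise ConfigurationError(
                    f"channel mismatch: block out {a.out_channels} vs next in {b.in_channels}"
                )
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.use_covariates and self.n_covariates < 0:
            raise ConfigurationError("n_covariates must be non-negative")

    def to_dict(self) -> dict:
        return {
            "blocks": [
                [b.kernel_extent, b.in_channels, b.out_channels, b.followed_by_pool]
                for b in self.blocks
            ],
            "hidden_units": self.hidden_units,
            "dropout_rate": self.dropout_rate,
            "use_covariates": self.use_covariates,
            "n_covariates": self.n_covariates,
            "input_shape": list(self.input_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        return cls(
            blocks=[BlockSpec(*row) for row in d["blocks"]],
            hidden_units=d["hidden_units"],
            dropout_rate=d["dropout_rate"],
            use_covariates=d["use_covariates"],
            n_covariates=d["n_covariates"],
            input_shape=tuple(d["input_shape"]),
        )


def reference_config(
    input_shape: tuple[int, int, int] = (91, 109, 91), use_covariates: bool = True
) -> NetConfig:
    """The reference 8-block schedule.

    Kernel extents [5, 3, 3, 3, 3, 3, 3, 3]; channels 1→8→16→16→32→32→64→64→128;
    max pooling after blocks 2, 4 and 6; 128 hidden units; dropout 0.4;
    two covariates (age, sex).
    """
    extents = [5, 3, 3, 3, 3, 3, 3, 3]
    channels = [1, 8, 16, 16, 32, 32, 64, 64, 128]
    pooled = {1, 3, 5}  # zero-based: after blocks 2, 4, 6
    blocks = [
        BlockSpec(extents[i], channels[i], channels[i + 1], followed_by_pool=i in pooled)
        for i in range(8)
    ]
    return NetConfig(blocks=blocks, input_shape=tuple(input_shape), use_covariates=use_covariates)


class RegressionNet:
    """A configured network with all parameter state.

    Parameters are initialized on construction from ``seed``: Xavier/Glorot
    uniform for convolution and fully connected weights, zero convolution
    biases, 0.01 fully connected biases, batch-norm scale 1 / shift 0,
    running mean 0 / variance 1.
    """

    def __init__(self, config: NetConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        self.covariate_stats: tuple[np.ndarray, np.ndarray] | None = None

        self.convs: list[nn.SepConv3d] = []
        self.bns: list[nn.BatchNorm3d] = []
        self.relus: list[nn.ReLU] = []
        self.pools: list[nn.MaxPool3dSame | None] = []
        for b in config.blocks:
            self.convs.append(nn.SepConv3d(b.kernel_extent, b.in_channels, b.out_channels, dtype))
            self.bns.append(nn.BatchNorm3d(b.out_channels, dtype))
            self.relus.append(nn.ReLU())
            self.pools.append(nn.MaxPool3dSame() if b.followed_by_pool else None)
        self.gap = nn.GlobalAvgPool3d()
        n_feat = config.blocks[-1].out_channels
        n_in = n_feat + (config.n_covariates if config.use_covariates else 0)
        self.fc_hidden = nn.Dense(n_in, config.hidden_units, dtype, bias_init=0.01)
        self.fc_relu = nn.ReLU()
        self.dropout = nn.Dropout(config.dropout_rate)
        self.fc_out = nn.Dense(config.hidden_units, 1, dtype, bias_init=0.01)
        self._head_cov_width = config.n_covariates if config.use_covariates else 0
        self.initialize(seed)

    # ---------------------------------------------------------------- params

    def parameters(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for conv, bn in zip(self.convs, self.bns):
            out.extend(conv.params())
            out.extend(bn.params())
        out.extend(self.fc_hidden.params())
        out.extend(self.fc_out.params())
        return out

    def initialize(self, seed: int) -> "RegressionNet":
        rng = np.random.default_rng(seed)
        for conv, bn in zip(self.convs, self.bns):
            conv.init_params(rng)
            bn.init_params(rng)
        self.fc_hidden.init_params(rng)
        self.fc_out.init_params(rng)
        return self

    def count_parameters(self) -> tuple[int, int]:
        total = sum(p.size for p in self.parameters())
        trainable = sum(p.size for p in self.parameters() if p.trainable)
        return total, trainable

    # --------------------------------------------------------------- forward

    def trunk_forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the convolutional trunk; returns the last block's post-activation maps."""
        for conv, bn, relu, pool in zip(self.convs, self.bns, self.relus, self.pools):
            x = conv.forward(x, training)
            x = bn.forward(x, training)
            x = relu.forward(x, training)
            if pool is not None:
                x = pool.forward(x, training)
        return x

    def _prepare_covariates(self, cov: np.ndarray | None, batch: int) -> np.ndarray | None:
        if not self.config.use_covariates:
            return None
        if cov is None:
            raise ValidationError("this network requires covariates")
        cov = np.asarray(cov, dtype=self.dtype)
        if cov.ndim == 1:
            cov = cov[None, :]
        if cov.shape != (batch, self.config.n_covariates):
            raise ShapeError(
                f"covariates shape {cov.shape} != ({batch}, {self.config.n_covariates})"
            )
        if not np.all(np.isfinite(cov)):
            raise ValidationError("covariates must be finite")
        if self.covariate_stats is not None:
            mean, sd = self.covariate_stats
            cov = (cov - mean.astype(self.dtype)) / sd.astype(self.dtype)
        return cov

    def head_forward(
        self,
        features: np.ndarray,
        cov: np.ndarray | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Prediction head: GAP → concat covariates → hidden FC → linear output."""
        pooled = self.gap.forward(features, training)
        cov = self._prepare_covariates(cov, pooled.shape[0])
        z = pooled if cov is None else np.concatenate([pooled, cov], axis=1)
        h = self.fc_hidden.forward(z, training)
        h = self.fc_relu.forward(h, training)
        h = self.dropout.forward(h, training, rng)
        y = self.fc_out.forward(h, training)
        return y[:, 0]

    def head_backward(self, gy: np.ndarray) -> np.ndarray:
        """Backprop the head; returns the gradient w.r.t. the last feature maps."""
        g = self.fc_out.backward(gy[:, None])
        g = self.dropout.backward(g)
        g = self.fc_relu.backward(g)
        g = self.fc_hidden.backward(g)
        if self._head_cov_width:
            g = g[:, : -self._head_cov_width]
        return self.gap.backward(np.ascontiguousarray(g))

    def forward_batch(
        self,
        x: np.ndarray,
        cov: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Predict for a (B, 1, i, j, k) batch; returns (B,) predictions."""
        if x.ndim != 5 or x.shape[1] != 1:
            raise ShapeError(f"expected (B, 1, i, j, k) input, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValidationError("input volume contains non-finite values")
        a = self.trunk_forward(x.astype(self.dtype, copy=False), training)
        return self.head_forward(a, cov, training, rng)

    def backward_batch(self, gy: np.ndarray) -> None:
        """Backprop ∂loss/∂prediction through head and trunk (after a training forward)."""
        g = self.head_backward(gy)
        for conv, bn, relu, pool in zip(
            reversed(self.convs), reversed(self.bns), reversed(self.relus), reversed(self.pools)
        ):
            if pool is not None:
                g = pool.backward(g)
            g = relu.backward(g)
            g = bn.backward(g)
            g = conv.backward(g)

    def forward(
        self,
        volume: Volume | np.ndarray,
        covariates=None,
        training_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Predict one scalar for a single volume."""
        arr = volume.intensities if isinstance(volume, Volume) else np.asarray(volume)
        if arr.ndim != 3:
            raise ShapeError(f"expected a 3D volume, got shape {arr.shape}")
        if tuple(arr.shape) != tuple(self.config.input_shape):
            raise ShapeError(
                f"volume shape {arr.shape} does not match configured {self.config.input_shape}"
            )
        cov = None
        if self.config.use_covariates:
            if covariates is None:
                raise ValidationError("this network requires covariates (age, sex)")
            cov = np.asarray(covariates, dtype=self.dtype)[None, :]
        x = arr[None, None].astype(self.dtype, copy=False)
        return float(self.forward_batch(x, cov, training=training_mode, rng=rng)[0])

    # ------------------------------------------------------------ checkpoint

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            for p in conv.params():
                out[f"block{i}.conv.{p.name}"] = p.value
            for p in bn.params():
                out[f"block{i}.bn.{p.name}"] = p.value
        for p in self.fc_hidden.params():
            out[f"fc_hidden.{p.name}"] = p.value
        for p in self.fc_out.params():
            out[f"fc_out.{p.name}"] = p.value
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        keyed = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            for p in conv.params():
                keyed[f"block{i}.conv.{p.name}"] = p
            for p in bn.params():
                keyed[f"block{i}.bn.{p.name}"] = p
        for p in self.fc_hidden.params():
            keyed[f"fc_hidden.{p.name}"] = p
        for p in self.fc_out.params():
            keyed[f"fc_out.{p.name}"] = p
        for k, p in keyed.items():
            if k not in arrays:
                raise ValidationError(f"checkpoint missing parameter {k}")
            a = np.asarray(arrays[k])
            if a.shape != p.value.shape:
                raise ShapeError(f"checkpoint shape mismatch for {k}: {a.shape} vs {p.value.shape}")
            p.value = a.astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)

    def snapshot(self) -> dict[str, np.ndarray]:
        """Deep copy of all parameter state (including running statistics)."""
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def save(self, path) -> None:
        meta = {"config": self.config.to_dict(), "dtype": np.dtype(self.dtype).name}
        if self.covariate_stats is not None:
            meta["covariate_stats"] = [
                np.asarray(self.covariate_stats[0]).tolist(),
                np.asarray(self.covariate_stats[1]).tolist(),
            ]
        arrays = dict(self.state_arrays())
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)


def load_model(path) -> RegressionNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    net = RegressionNet(
        NetConfig.from_dict(meta["config"]), dtype=np.dtype(meta.get("dtype", "float32"))
    )
    net.load_state_arrays(arrays)
    if "covariate_stats" in meta:
        mean, sd = meta["covariate_stats"]
        net.covariate_stats = (np.asarray(mean, dtype=np.float64), np.asarray(sd, dtype=np.float64))
    return net


def build_model(config: NetConfig, seed: int = 0, dtype=np.float32) -> RegressionNet:
    """Construct and initialize a network from a configuration."""
    return RegressionNet(config, seed=seed, dtype=dtype)


def count_parameters(net: RegressionNet) -> tuple[int, int]:
    """(total, trainable) parameter counts; non-trainable = running statistics."""
    return net.count_parameters()
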