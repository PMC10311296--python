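"""Cube-based model architectures.

Three models share one convolutional trunk design:

* the self-supervised masked-residue model: trunk + three fully connected
  layers (200, 20, 20) + softmax over the 20 amino-acid types;
* the Siamese mutation-effect model: two weight-sharing branches (trunk +
  FC 200 + FC 20) whose outputs are subtracted, concatenated with the
  9-dim auxiliary vector and mapped by a single linear unit to a scalar
  binding free-energy change (kcal/mol);
* a small dense classifier mapping 200-dim embeddings to categorical
  residue or interface properties.

The trunk is: a 1x1x1 "projector" convolution reducing the per-voxel
channel vector to 20 dimensions, three 3D convolutions (batch-normalized,
ReLU), and a block average pool down to 3x3x3.  Dropout (40/20/10%) is
applied to the input and first two layers of the dense subnetwork.
Weight sharing in the Siamese model is exact: both branches run through
the same layer objects on a stacked batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import (Adam, AvgPool3d, BatchNorm, Conv3d, Dense, Dropout,
                     Flatten, Layer, Param, ReLU, Sequential, softmax)

__all__ = [
    "TrunkConfig",
    "SsdlaModel",
    "DlaMutationModel",
    "EmbeddingClassifier",
    "AUX_DIM",
    "N_AMINO_ACIDS",
    "EMBEDDING_DIM",
]

N_AMINO_ACIDS = 20
EMBEDDING_DIM = 200
AUX_DIM = 9
GRID = 24


@dataclass(frozen=True)
class TrunkConfig:
    """Hyperparameters of the convolutional trunk.

    The projector width (20) and the dense sizes downstream are fixed
    design constants; convolution filter counts, kernel and strides are
    tunable.  Defaults keep every stage divisible down to the 3x3x3
    average pool (24 -> 12 -> 6 -> 6 -> pool 3).
    """

    n_channels_in: int = 167
    projector_dim: int = 20
    conv_filters: tuple[int, ...] = (32, 64, 128)
    conv_strides: tuple[int, ...] = (2, 2, 1)
    kernel: int = 3
    pool_to: int = 3
    dropout_rates: tuple[float, float, float] = (0.40, 0.20, 0.10)

    @classmethod
    def desk(cls, n_channels_in: int = 4) -> "TrunkConfig":
        """Reduced configuration for CPU-scale experiments and tests."""
        return cls(n_channels_in=n_channels_in, conv_filters=(12, 16, 24))

    def spatial_out(self) -> int:
        d = GRID
        for s in self.conv_strides:
            d = (d + 2 * ((self.kernel - 1) // 2) - self.kernel) // s + 1
        return d

    def flat_dim(self) -> int:
        return self.pool_to ** 3 * self.conv_filters[-1]


def _build_trunk(cfg: TrunkConfig, rng: np.random.Generator,
                 dtype=np.float32) -> Sequential:
    layers: list[Layer] = [
        Conv3d(cfg.n_channels_in, cfg.projector_dim, kernel=1, stride=1,
               rng=rng, dtype=dtype)
    ]
    c_prev = cfg.projector_dim
    for f, s in zip(cfg.conv_filters, cfg.conv_strides):
        layers += [
            Conv3d(c_prev, f, kernel=cfg.kernel, stride=s, rng=rng, dtype=dtype),
            BatchNorm(f, dtype=dtype),
            ReLU(),
        ]
        c_prev = f
    if cfg.spatial_out() % cfg.pool_to:
        raise ValueError(
            f"conv output size {cfg.spatial_out()} not divisible by pool "
            f"target {cfg.pool_to}")
    layers += [AvgPool3d(cfg.pool_to), Flatten()]
    return Sequential(layers)


class SsdlaModel:
    """Masked-residue recovery model: P(amino acid | local environment)."""

    def __init__(self, config: TrunkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.trunk = _build_trunk(config, rng, dtype)
        d0, d1, d2 = config.dropout_rates
        flat = config.flat_dim()
        self.drop0 = Dropout(d0, seed=seed + 101)
        self.fc1 = Dense(flat, EMBEDDING_DIM, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.drop1 = Dropout(d1, seed=seed + 102)
        self.fc2 = Dense(EMBEDDING_DIM, 20, rng=rng, dtype=dtype)
        self.relu2 = ReLU()
        self.drop2 = Dropout(d2, seed=seed + 103)
        self.fc3 = Dense(20, N_AMINO_ACIDS, rng=rng, dtype=dtype)
        self.head = Sequential([self.drop0, self.fc1, self.relu1, self.drop1,
                                self.fc2, self.relu2, self.drop2, self.fc3])

    def params(self) -> list[Param]:
        return self.trunk.params() + self.head.params()

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.trunk.forward(x, train), train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability vector(s) over the 20 amino-acid types."""
        return softmax(self.logits(x, train))

    def backward(self, grad: np.ndarray) -> None:
        self.trunk.backward(self.head.backward(grad))

    def embed(self, x: np.ndarray) -> np.ndarray:
        """200-dim embedding: post-activation output of the first dense layer."""
        h = self.trunk.forward(x, False)
        return self.relu1.forward(self.fc1.forward(h, False), False)


class DlaMutationModel:
    """Siamese mutation-effect model.

    prediction = w . (branch(wt) - branch(mu)) + v . aux + c

    Both branches are the *same* layer objects (trunk + dense 200 + dense
    20); a forward pass stacks the wild-type and mutant cubes into one
    batch, so weight sharing is exact by construction.  The final layer
    is linear: identical cubes contribute exactly zero and the prediction
    is odd in the branch difference.
    """

    def __init__(self, config: TrunkConfig, seed: int = 0,
                 aux_dim: int = AUX_DIM, dtype=np.float32):
        self.config = config
        self.aux_dim = aux_dim
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.trunk = _build_trunk(config, rng, dtype)
        d0, d1, _ = config.dropout_rates
        self.drop0 = Dropout(d0, seed=seed + 201)
        self.fc1 = Dense(config.flat_dim(), EMBEDDING_DIM, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.drop1 = Dropout(d1, seed=seed + 202)
        self.fc2 = Dense(EMBEDDING_DIM, 20, rng=rng, dtype=dtype)
        self.branch_head = Sequential([self.drop0, self.fc1, self.relu1,
                                       self.drop1, self.fc2])
        self.head = Dense(20 + aux_dim, 1, rng=rng, dtype=dtype)

    def params(self) -> list[Param]:
        return self.trunk.params() + self.branch_head.params() + self.head.params()

    def branch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.branch_head.forward(self.trunk.forward(x, train), train)

    def embed(self, x: np.ndarray) -> np.ndarray:
        h = self.trunk.forward(x, False)
        return self.relu1.forward(self.fc1.forward(h, False), False)

    def forward(self, wt: np.ndarray, mu: np.ndarray, aux: np.ndarray,
                train: bool = False) -> np.ndarray:
        if wt.shape != mu.shape:
            raise ValueError("wild-type and mutant cube batches differ in shape")
        if wt.shape[-1] != self.config.n_channels_in:
            raise ValueError(
                f"cube has {wt.shape[-1]} channels, model expects "
                f"{self.config.n_channels_in}")
        aux = np.atleast_2d(np.asarray(aux, dtype=wt.dtype))
        if aux.shape[1] != self.aux_dim:
            raise ValueError(
                f"aux vector length {aux.shape[1]} != configured {self.aux_dim}")
        n = wt.shape[0]
        stacked = np.concatenate([wt, mu], axis=0)
        out = self.branch(stacked, train)
        diff = out[:n] - out[n:]
        self._n = n
        z = np.concatenate([diff, aux], axis=1)
        return self.head.forward(z, train).reshape(-1)

    def backward(self, grad: np.ndarray) -> None:
        gz = self.head.backward(grad.reshape(-1, 1))
        gdiff = gz[:, :20]
        gstack = np.concatenate([gdiff, -gdiff], axis=0)
        self.trunk.backward(self.branch_head.backward(gstack))

    def init_from_ssdla(self, ssdla: SsdlaModel) -> None:
        """Transfer pre-trained trunk and first dense layer weights."""
        if ssdla.config.n_channels_in != self.config.n_channels_in or \
                ssdla.config.conv_filters != self.config.conv_filters:
            raise ValueError("trunk configurations are incompatible")
        for src, dst in zip(ssdla.trunk.params(), self.trunk.params()):
            dst.value = src.value.copy()
        for layer_s, layer_d in zip(ssdla.trunk.layers, self.trunk.layers):
            if isinstance(layer_s, BatchNorm):
                layer_d.running_mean = layer_s.running_mean.copy()
                layer_d.running_var = layer_s.running_var.copy()
        self.fc1.w.value = ssdla.fc1.w.value.copy()
        self.fc1.b.value = ssdla.fc1.b.value.copy()


class EmbeddingClassifier:
    """One-hidden-layer dense classifier over 200-dim embeddings.

    For interface-level tasks the input is the arithmetic mean of the
    interface's per-cube embeddings.
    """

    def __init__(self, n_classes: int, hidden: int = 20, seed: int = 0,
                 in_dim: int = EMBEDDING_DIM, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.net = Sequential([
            Dense(in_dim, hidden, rng=rng, dtype=dtype),
            ReLU(),
            Dense(hidden, n_classes, rng=rng, dtype=dtype),
        ])

    def params(self) -> list[Param]:
        return self.net.params()

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(np.atleast_2d(x), train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return softmax(self.logits(x, train))


def _all_state(model) -> dict[str, np.ndarray]:
    state = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    i = 0
    for layer in getattr(model.trunk, "layers", []):
        if isinstance(layer, BatchNorm):
            state[f"bn_mean_{i}"] = layer.running_mean
            state[f"bn_var_{i}"] = layer.running_var
            i += 1
    return state


def save_checkpoint(model, path: str | Path, scheme_mode: str = "") -> None:
    """Persist model weights plus its configuration and channel scheme tag."""
    meta = {
        "class": type(model).__name__,
        "config": asdict(model.config) if hasattr(model, "config") else {},
        "scheme_mode": scheme_mode,
    }
    np.savez(path, __meta__=json.dumps(meta), **_all_state(model))


def load_checkpoint(path: str | Path):
    """Restore a model saved by :func:`save_checkpoint`."""
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg_d = dict(meta["config"])
    for key in ("conv_filters", "conv_strides", "dropout_rates"):
        if key in cfg_d:
            cfg_d[key] = tuple(cfg_d[key])
    cfg = TrunkConfig(**cfg_d)
    cls = {"SsdlaModel": SsdlaModel, "DlaMutationModel": DlaMutationModel}[
        meta["class"]]
    model = cls(cfg)
    for i, p in enumerate(model.params()):
        p.value = data[f"param_{i}"].copy()
    i = 0
    for layer in model.trunk.layers:
        if isinstance(layer, BatchNorm):
            layer.running_mean = data[f"bn_mean_{i}"].copy()
            layer.running_var = data[f"bn_var_{i}"].copy()
            i += 1
    return model, meta["scheme_mode"]
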