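"""Training loops for the cube models.

All loops are plain full-batch/mini-batch gradient descent with Adam,
seeded and deterministic on a single device.  The self-supervised task
minimizes a class-weighted categorical cross-entropy (weights inversely
proportional to amino-acid frequency); the mutation-effect task
minimizes mean squared error against measured binding free-energy
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Adam, BatchNorm, Dropout, mse_loss, softmax_cross_entropy
from .models import DlaMutationModel, EmbeddingClassifier, SsdlaModel, TrunkConfig

__all__ = [
    "class_weights",
    "TrainResult",
    "calibrate_batchnorm",
    "train_ssdla",
    "train_ddg",
    "train_classifier",
]


def calibrate_batchnorm(model, x: np.ndarray, batch_size: int = 32) -> None:
    """Reset batch-norm running statistics to the data's batch statistics.

    With few optimizer steps per epoch the exponentially averaged running
    statistics lag far behind the evolving activations, which corrupts
    eval-mode forward passes.  This pass re-estimates them as a cumulative
    moving average over ``x`` (momentum 1/i on the i-th batch), leaving
    parameters untouched.
    """
    bns = [l for l in model.trunk.layers if isinstance(l, BatchNorm)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    try:
        for i, start in enumerate(range(0, len(x), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            model.trunk.forward(x[start:start + batch_size], True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m


def class_weights(frequencies: np.ndarray) -> np.ndarray:
    """Loss weights inversely proportional to class frequency.

    Normalized to mean 1 so the overall loss scale is unchanged.  A zero
    frequency signals a degenerate training set and raises ``ValueError``.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise ValueError("all class frequencies must be positive")
    w = 1.0 / f
    return w / w.mean()


@dataclass
class TrainResult:
    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _reset_dropout(model, seed: int) -> None:
    for i, attr in enumerate(("drop0", "drop1", "drop2")):
        layer = getattr(model, attr, None)
        if isinstance(layer, Dropout):
            layer.reset(seed + 31 * (i + 1))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_ssdla(
    cubes: np.ndarray,
    labels: np.ndarray,
    model: SsdlaModel,
    epochs: int = 50,
    lr: float = 1e-4,
    batch_size: int = 64,
    seed: int = 0,
    weights: np.ndarray | None = None,
    val_cubes: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    stop_at_train_accuracy: float | None = None,
) -> TrainResult:
    """Train the masked-residue model with weighted cross-entropy + Adam.

    ``cubes`` is ``(N, 24, 24, 24, C)``, ``labels`` integer amino-acid
    indices in [0, 20).  When a validation set is given, the parameters
    from the best-validation epoch are restored at the end.  When
    ``weights`` is None they are derived from the training label
    frequencies.
    """
    if len(cubes) == 0:
        raise ValueError("empty training set")
    labels = np.asarray(labels)
    if weights is None:
        counts = np.bincount(labels, minlength=20)
        present = counts > 0
        freq = np.where(present, counts, 1) / len(labels)
        w = 1.0 / freq
        w[~present] = 0.0
        weights = w / w[present].mean()
    rng = np.random.default_rng(seed)
    _reset_dropout(model, seed)
    opt = Adam(model.params(), lr=lr)
    result = TrainResult()
    best_val = np.inf
    best_state = None
    for epoch in range(epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in _batches(len(cubes), batch_size, rng):
            opt.zero_grad()
            logits = model.logits(cubes[idx], train=True)
            loss, grad = softmax_cross_entropy(logits, labels[idx], weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        result.loss_history.append(epoch_loss / n_seen)
        if stop_at_train_accuracy is not None:
            calibrate_batchnorm(model, cubes)
            acc = float((model.forward(cubes).argmax(axis=1) == labels).mean())
            if acc >= stop_at_train_accuracy:
                break
        if val_cubes is not None:
            calibrate_batchnorm(model, cubes)
            vloss, _ = softmax_cross_entropy(
                model.logits(val_cubes, train=False), val_labels, weights)
            result.val_history.append(vloss)
            if vloss < best_val:
                best_val = vloss
                result.best_epoch = epoch
                best_state = (
                    [p.value.copy() for p in model.params()],
                    [(bn.running_mean.copy(), bn.running_var.copy())
                     for bn in model.trunk.layers if isinstance(bn, BatchNorm)],
                )
    if best_state is not None:
        params, bn_stats = best_state
        for p, v in zip(model.params(), params):
            p.value = v
        bns = [l for l in model.trunk.layers if isinstance(l, BatchNorm)]
        for bn, (rm, rv) in zip(bns, bn_stats):
            bn.running_mean, bn.running_var = rm, rv
    else:
        calibrate_batchnorm(model, cubes)
    return result


def train_ddg(
    wt_cubes: np.ndarray,
    mu_cubes: np.ndarray,
    aux: np.ndarray,
    targets: np.ndarray,
    model: DlaMutationModel | None = None,
    config: TrunkConfig | None = None,
    init: str = "random",
    pretrained: SsdlaModel | None = None,
    epochs: int = 100,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[DlaMutationModel, TrainResult]:
    """Train the Siamese mutation-effect model with MSE + Adam.

    ``init`` is ``"random"`` or ``"pretrained"`` (requires ``pretrained``,
    whose trunk and first dense layer seed the Siamese branches).  A
    non-finite loss aborts with diagnostics.  ``epochs=0`` returns the
    initialized model untouched.
    """
    if model is None:
        if config is None:
            raise ValueError("either a model or a config is required")
        model = DlaMutationModel(config, seed=seed)
    if init == "pretrained":
        if pretrained is None:
            raise ValueError("init='pretrained' requires a pre-trained model")
        model.init_from_ssdla(pretrained)
    elif init != "random":
        raise ValueError(f"unknown init {init!r}")
    targets = np.asarray(targets, dtype=float)
    rng = np.random.default_rng(seed)
    _reset_dropout(model, seed)
    opt = Adam(model.params(), lr=lr)
    result = TrainResult()
    for epoch in range(epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in _batches(len(targets), batch_size, rng):
            opt.zero_grad()
            pred = model.forward(wt_cubes[idx], mu_cubes[idx], aux[idx],
                                 train=True)
            loss, grad = mse_loss(pred, targets[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite ΔΔG training loss at epoch {epoch} "
                    f"(lr={lr}, batch={len(idx)}, pred range "
                    f"[{np.nanmin(pred):.3g}, {np.nanmax(pred):.3g}])")
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        result.loss_history.append(epoch_loss / n_seen)
    if epochs > 0:
        calibrate_batchnorm(
            model, np.concatenate([wt_cubes, mu_cubes], axis=0))
    return model, result


def train_classifier(
    embeddings: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    epochs: int = 200,
    lr: float = 1e-3,
    seed: int = 0,
    hidden: int = 20,
) -> tuple[EmbeddingClassifier, TrainResult]:
    """Train the downstream dense classifier on embedding vectors."""
    clf = EmbeddingClassifier(n_classes, hidden=hidden, seed=seed,
                              in_dim=embeddings.shape[1])
    opt = Adam(clf.params(), lr=lr)
    labels = np.asarray(labels)
    result = TrainResult()
    for epoch in range(epochs):
        opt.zero_grad()
        logits = clf.logits(embeddings, train=True)
        loss, grad = softmax_cross_entropy(logits, labels)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite classifier loss at epoch {epoch}")
        clf.net.backward(grad)
        opt.step()
        result.loss_history.append(loss)
    return clf, result
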