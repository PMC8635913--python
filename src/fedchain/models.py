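"""Local model backends: parameter layout, mini-batch SGD, and evaluation.

All trainable parameters live in a single flat float64 vector with a fixed,
documented order (per layer: weights row-major, then biases). Three
architectures are supported:

* ``logistic`` — binary logistic regression on the 8 clinical features
  (8 weights + 1 bias = 9 parameters); the default training backend.
* ``tabular_mlp`` — one hidden tanh layer (8 -> 16 -> 2 softmax, 178
  parameters) for the tabular task.
* ``mnist_cnn`` — a 28x28x1 LeNet-style CNN (conv 5x5x32, 2x2 pool,
  conv 5x5x64 same-padded, 2x2 pool, dense 512, dense 10 softmax;
  1,663,370 parameters). Only initialization and the parameter-count
  contract are provided — the convolutional forward pass is not part of the
  tabular training path.

Weights are initialized from N(0, 0.02^2) and biases are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import ClinicalDataset, N_FEATURES

INIT_STD = 0.02

#: (name, weight shape, bias length) per layer, flattening order.
_ARCH_LAYERS: dict[str, list[tuple[str, tuple[int, ...], int]]] = {
    "logistic": [("linear", (N_FEATURES, 1), 1)],
    "tabular_mlp": [("hidden", (N_FEATURES, 16), 16), ("output", (16, 2), 2)],
    "mnist_cnn": [
        ("conv1", (5, 5, 1, 32), 32),
        ("conv2", (5, 5, 32, 64), 64),
        ("dense1", (7 * 7 * 64, 512), 512),
        ("dense2", (512, 10), 10),
    ],
}


def _check_arch(arch_id: str) -> None:
    if arch_id not in _ARCH_LAYERS:
        raise ValueError(f"unknown arch_id {arch_id!r}; known: {sorted(_ARCH_LAYERS)}")


def count_params(arch_id: str) -> int:
    """Exact trainable-parameter count for an architecture."""
    _check_arch(arch_id)
    return sum(int(np.prod(w)) + b for _, w, b in _ARCH_LAYERS[arch_id])


@dataclass(frozen=True)
class ModelParams:
    """All trainable parameters as one flat vector, tagged by architecture."""

    values: np.ndarray
    arch_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        expected = count_params(self.arch_id)
        if v.shape != (expected,):
            raise ValueError(
                f"{self.arch_id} expects {expected} parameters, got shape {v.shape}"
            )
        object.__setattr__(self, "values", v)

    def unflatten(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-layer (weights, biases) views in the documented order."""
        out = []
        off = 0
        for _, wshape, blen in _ARCH_LAYERS[self.arch_id]:
            wsize = int(np.prod(wshape))
            w = self.values[off : off + wsize].reshape(wshape)
            off += wsize
            b = self.values[off : off + blen]
            off += blen
            out.append((w, b))
        return out


def flatten(layers: list[tuple[np.ndarray, np.ndarray]], arch_id: str) -> ModelParams:
    parts = []
    for w, b in layers:
        parts.append(np.asarray(w, dtype=np.float64).ravel())
        parts.append(np.asarray(b, dtype=np.float64).ravel())
    return ModelParams(np.concatenate(parts), arch_id)


def init_params(arch_id: str, seed: int) -> ModelParams:
    """Weights ~ N(0, 0.02^2), biases exactly 0; deterministic under seed."""
    _check_arch(arch_id)
    rng = np.random.default_rng(seed)
    values = np.zeros(count_params(arch_id))
    off = 0
    for _, wshape, blen in _ARCH_LAYERS[arch_id]:
        wsize = int(np.prod(wshape))
        values[off : off + wsize] = rng.normal(0.0, INIT_STD, size=wsize)
        off += wsize + blen  # biases stay zero
    return ModelParams(values, arch_id)


@dataclass(frozen=True)
class LocalUpdate:
    """One device's per-round update: the parameter delta w_in - w_out."""

    gradient: np.ndarray
    round: int
    device_id: str


# ---------------------------------------------------------------------------
# forward / backward for the tabular backends


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_proba(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """P(y=1 | x) for each row of X under the tabular backends."""
    if params.arch_id == "logistic":
        (w, b), = params.unflatten()
        return _sigmoid(X @ w[:, 0] + b[0])
    if params.arch_id == "tabular_mlp":
        (w1, b1), (w2, b2) = params.unflatten()
        h = np.tanh(X @ w1 + b1)
        logits = h @ w2 + b2
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        return (e / e.sum(axis=1, keepdims=True))[:, 1]
    raise ValueError(f"{params.arch_id} has no tabular prediction path")


def loss_and_grad(
    params: ModelParams, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its flat gradient."""
    n = X.shape[0]
    if params.arch_id == "logistic":
        (w, b), = params.unflatten()
        z = X @ w[:, 0] + b[0]
        p = _sigmoid(z)
        eps = 1e-12
        loss = -float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        r = (p - y) / n
        gw = X.T @ r
        gb = r.sum()
        return loss, np.concatenate([gw, [gb]])
    if params.arch_id == "tabular_mlp":
        (w1, b1), (w2, b2) = params.unflatten()
        a = X @ w1 + b1
        h = np.tanh(a)
        logits = h @ w2 + b2
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        probs = e / e.sum(axis=1, keepdims=True)
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(n), y] + eps)))
        d_logits = probs.copy()
        d_logits[np.arange(n), y] -= 1.0
        d_logits /= n
        gw2 = h.T @ d_logits
        gb2 = d_logits.sum(axis=0)
        dh = d_logits @ w2.T
        da = dh * (1.0 - h**2)
        gw1 = X.T @ da
        gb1 = da.sum(axis=0)
        return loss, np.concatenate(
            [gw1.ravel(), gb1, gw2.ravel(), gb2]
        )
    raise ValueError(f"{params.arch_id} has no tabular training path")


def local_train(
    params: ModelParams,
    shard: ClinicalDataset,
    batch_size: int,
    iterations: int,
    lr: float,
    seed: int,
    round_index: int = 0,
    device_id: str = "device",
) -> LocalUpdate:
    """Run mini-batch SGD locally and return the parameter delta.

    Batches are sampled without replacement within an epoch (reshuffling when
    the shard is exhausted); a batch size larger than the shard silently falls
    back to full-batch. The returned ``gradient`` is w_in - w_out, i.e. the
    raw accumulated delta: the coordinator applies it with a unit server step.
    """
    if shard.n == 0:
        raise ValueError("cannot train on an empty shard")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X, y = shard.features, shard.labels
    b = min(batch_size, shard.n)
    rng = np.random.default_rng(seed)
    w = params.values.copy()
    order = rng.permutation(shard.n)
    pos = 0
    for _ in range(iterations):
        if pos + b > shard.n:
            order = rng.permutation(shard.n)
            pos = 0
        idx = order[pos : pos + b]
        pos += b
        _, g = loss_and_grad(ModelParams(w, params.arch_id), X[idx], y[idx])
        w = w - lr * g
    return LocalUpdate(params.values - w, round_index, device_id)


def evaluate(params: ModelParams, test: ClinicalDataset) -> tuple[float, float]:
    """(accuracy, attack_success_rate) on a test set; the two sum to 1."""
    if test.n == 0:
        raise ValueError("cannot evaluate on an empty test set")
    p = predict_proba(params, test.features)
    acc = float(np.mean((p >= 0.5).astype(np.int64) == test.labels))
    return acc, 1.0 - acc
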