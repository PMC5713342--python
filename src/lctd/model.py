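"""Feed-forward binary classifier for protein-pair feature vectors.

A fully-connected network with (by default) three hidden layers of widths
2048, 512 and 32, each applying affine -> batch normalisation -> ReLU ->
dropout, followed by a single logistic output unit.  Training minimises the
mean binary cross-entropy over mini-batches with the Adam optimiser.

The implementation is pure numpy: parameters, the forward/backward passes
and the optimiser state are explicit arrays, all randomness (weight
initialisation, shuffling, dropout masks) flows from one seed, and inference
is fully deterministic (dropout off, batch norm using running statistics),
so predictions are invariant to how rows are batched.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["MLPConfig", "TrainedModel", "build", "train", "predict"]

_EPS_BN = 1e-5
_EPS_LOSS = 1e-7


@dataclass
class MLPConfig:
    """Architecture and optimisation hyper-parameters.

    Defaults follow the recommended configuration for 8120-dimensional pair
    features: hidden widths (2048, 512, 32), dropout 0.6, batch
    normalisation on, Adam at learning rate 0.002, batch size 512.  The
    epoch budget is a free choice; training stops early once the epoch-mean
    loss stops improving by ``min_delta`` for ``patience`` epochs.
    """

    input_dim: int
    hidden: tuple[int, ...] = (2048, 512, 32)
    dropout: float = 0.6
    learning_rate: float = 0.002
    batch_size: int = 512
    epochs: int = 100
    patience: int = 10
    min_delta: float = 1e-4
    init: str = "glorot_normal"
    optimizer: str = "adam"
    batch_norm: bool = True
    standardize: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.hidden = tuple(int(w) for w in self.hidden)
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if any(w < 1 for w in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.optimizer.lower() not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.init not in ("glorot_normal", "glorot_uniform", "normal"):
            raise ValueError(f"unknown init scheme {self.init!r}")


def _init_weight(rng: np.random.Generator, fan_in: int, fan_out: int, scheme: str,
                 dtype: np.dtype) -> np.ndarray:
    if scheme == "glorot_normal":
        std = np.sqrt(2.0 / (fan_in + fan_out))
        w = rng.normal(0.0, std, size=(fan_in, fan_out))
    elif scheme == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
    else:  # plain normal
        w = rng.normal(0.0, 0.05, size=(fan_in, fan_out))
    return w.astype(dtype)


class TrainedModel:
    """Parameters, running statistics and training history of the network."""

    def __init__(self, config: MLPConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        dims = (config.input_dim, *config.hidden, 1)
        self.W = [
            _init_weight(rng, dims[i], dims[i + 1], config.init, dtype)
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1], dtype=dtype) for i in range(len(dims) - 1)]
        self.gamma = [np.ones(w, dtype=dtype) for w in config.hidden]
        self.beta = [np.zeros(w, dtype=dtype) for w in config.hidden]
        self.running_mean = [np.zeros(w, dtype=dtype) for w in config.hidden]
        self.running_var = [np.ones(w, dtype=dtype) for w in config.hidden]
        self.history: list[float] = []
        # Input standardisation (z-scoring by training-set statistics); the
        # descriptor blocks mix 0-100 percentage scales with 0-1 triad values,
        # and equalising them markedly improves optimisation.
        self.input_mean = np.zeros(config.input_dim, dtype=dtype)
        self.input_scale = np.ones(config.input_dim, dtype=dtype)
        self._rng = rng  # consumed further during training (shuffling, dropout)

    # ------------------------------------------------------------------ fwd
    def _forward(self, X: np.ndarray, training: bool) -> tuple[np.ndarray, list]:
        cfg = self.config
        cache = []
        A = X
        for layer in range(len(cfg.hidden)):
            Z = A @ self.W[layer] + self.b[layer]
            if cfg.batch_norm:
                if training:
                    mu = Z.mean(axis=0)
                    var = Z.var(axis=0)
                    m = 0.9
                    self.running_mean[layer] = (
                        m * self.running_mean[layer] + (1 - m) * mu
                    ).astype(Z.dtype)
                    self.running_var[layer] = (
                        m * self.running_var[layer] + (1 - m) * var
                    ).astype(Z.dtype)
                else:
                    mu = self.running_mean[layer]
                    var = self.running_var[layer]
                inv_std = 1.0 / np.sqrt(var + _EPS_BN)
                Zhat = (Z - mu) * inv_std
                Zbn = self.gamma[layer] * Zhat + self.beta[layer]
            else:
                Zhat, inv_std, Zbn = None, None, Z
            H = np.maximum(Zbn, 0.0)
            if training and cfg.dropout > 0.0:
                mask = (
                    self._rng.random(H.shape) >= cfg.dropout
                ).astype(H.dtype) / (1.0 - cfg.dropout)
                Hd = H * mask
            else:
                mask = None
                Hd = H
            cache.append((A, Zhat, inv_std, Zbn, mask))
            A = Hd
        logits = A @ self.W[-1] + self.b[-1]
        cache.append((A, None, None, None, None))
        return logits[:, 0], cache

    # ------------------------------------------------------------------ bwd
    def _backward(self, cache: list, dlogits: np.ndarray) -> list[dict]:
        cfg = self.config
        grads: list[dict] = [dict() for _ in self.W]
        A_last = cache[-1][0]
        dlog = dlogits[:, None].astype(A_last.dtype)
        grads[-1]["W"] = A_last.T @ dlog
        grads[-1]["b"] = dlog.sum(axis=0)
        dA = dlog @ self.W[-1].T
        for layer in range(len(cfg.hidden) - 1, -1, -1):
            A_in, Zhat, inv_std, Zbn, mask = cache[layer]
            if mask is not None:
                dA = dA * mask
            dZbn = dA * (Zbn > 0)
            if cfg.batch_norm:
                n = dZbn.shape[0]
                grads[layer]["gamma"] = (dZbn * Zhat).sum(axis=0)
                grads[layer]["beta"] = dZbn.sum(axis=0)
                dZhat = dZbn * self.gamma[layer]
                dZ = (inv_std / n) * (
                    n * dZhat
                    - dZhat.sum(axis=0)
                    - Zhat * (dZhat * Zhat).sum(axis=0)
                )
            else:
                dZ = dZbn
            grads[layer]["W"] = A_in.T @ dZ
            grads[layer]["b"] = dZ.sum(axis=0)
            if layer > 0:
                dA = dZ @ self.W[layer].T
        return grads

    def save(self, path: str | Path) -> None:
        """Serialise config, weights, batch-norm state and history to one file."""
        arrays: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        for i in range(len(self.config.hidden)):
            arrays[f"gamma{i}"] = self.gamma[i]
            arrays[f"beta{i}"] = self.beta[i]
            arrays[f"rmean{i}"] = self.running_mean[i]
            arrays[f"rvar{i}"] = self.running_var[i]
        arrays["history"] = np.asarray(self.history, dtype=np.float64)
        arrays["input_mean"] = self.input_mean
        arrays["input_scale"] = self.input_scale
        meta = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            meta["hidden"] = tuple(meta["hidden"])
            config = MLPConfig(**meta)
            model = cls(config)
            model.W = [data[f"W{i}"] for i in range(len(config.hidden) + 1)]
            model.b = [data[f"b{i}"] for i in range(len(config.hidden) + 1)]
            for i in range(len(config.hidden)):
                model.gamma[i] = data[f"gamma{i}"]
                model.beta[i] = data[f"beta{i}"]
                model.running_mean[i] = data[f"rmean{i}"]
                model.running_var[i] = data[f"rvar{i}"]
            model.history = list(data["history"])
            model.input_mean = data["input_mean"]
            model.input_scale = data["input_scale"]
        return model


def build(config: MLPConfig) -> TrainedModel:
    """Construct an untrained network with seeded initial weights."""
    return TrainedModel(config)


def binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping for stability."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS_LOSS, 1.0 - _EPS_LOSS)
    y = np.asarray(y, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train(
    model: TrainedModel,
    features: np.ndarray,
    labels: np.ndarray,
    config: MLPConfig | None = None,
) -> TrainedModel:
    """Fit the network in place by mini-batch Adam on binary cross-entropy.

    ``labels`` must be 0/1.  Per-epoch mean training loss is appended to
    ``model.history``; training stops early when the loss plateaus.
    """
    cfg = config or model.config
    dtype = np.dtype(cfg.dtype)
    X = np.ascontiguousarray(features, dtype=dtype)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree on the number of rows")
    if X.shape[1] != cfg.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != configured input_dim {cfg.input_dim}"
        )
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if cfg.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        model.input_mean = mu
        model.input_scale = sd
        X = (X - mu) / sd
    if len(np.unique(y)) < 2:
        warnings.warn(
            "training set contains a single class; the fitted model will be "
            "degenerate and AUC will be undefined downstream",
            stacklevel=2,
        )

    params: list[np.ndarray] = []
    for layer in range(len(model.W)):
        params.append(model.W[layer])
        params.append(model.b[layer])
    for layer in range(len(cfg.hidden)):
        params.append(model.gamma[layer])
        params.append(model.beta[layer])
    use_adam = cfg.optimizer.lower() == "adam"
    if use_adam:
        m_state = [np.zeros_like(p, dtype=np.float32) for p in params]
        v_state = [np.zeros_like(p, dtype=np.float32) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

    n = X.shape[0]
    best = np.inf
    stale = 0
    for _epoch in range(cfg.epochs):
        order = model._rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            logits, cache = model._forward(Xb, training=True)
            p = _sigmoid(logits)
            epoch_loss += binary_cross_entropy(yb, p) * idx.size
            dlogits = ((p - yb) / idx.size).astype(dtype)
            grads = model._backward(cache, dlogits)
            flat_grads: list[np.ndarray] = []
            for layer in range(len(model.W)):
                flat_grads.append(grads[layer]["W"])
                flat_grads.append(grads[layer]["b"])
            for layer in range(len(cfg.hidden)):
                flat_grads.append(grads[layer].get("gamma", np.zeros_like(model.gamma[layer])))
                flat_grads.append(grads[layer].get("beta", np.zeros_like(model.beta[layer])))
            if use_adam:
                t += 1
                # bias correction folded into the step size
                step = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for p_arr, g, m_s, v_s in zip(params, flat_grads, m_state, v_state):
                    g32 = g if g.dtype == np.float32 else g.astype(np.float32)
                    m_s *= beta1
                    m_s += (1 - beta1) * g32
                    np.multiply(g32, g32, out=g32)
                    v_s *= beta2
                    v_s += (1 - beta2) * g32
                    np.sqrt(v_s, out=g32)
                    g32 += eps
                    np.divide(m_s, g32, out=g32)
                    g32 *= step
                    p_arr -= g32.astype(p_arr.dtype, copy=False)
            else:
                for p_arr, g in zip(params, flat_grads):
                    p_arr -= (cfg.learning_rate * g).astype(p_arr.dtype)
        epoch_loss /= n
        model.history.append(epoch_loss)
        if best - epoch_loss > cfg.min_delta:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return model


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Interaction probabilities in [0, 1], one per feature row.

    Inference is deterministic: dropout is disabled and batch normalisation
    uses the running statistics accumulated during training, so the output
    for a row does not depend on which other rows are scored with it.
    """
    X = np.asarray(features, dtype=np.dtype(model.config.dtype))
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model input_dim "
            f"{model.config.input_dim}"
        )
    if model.config.standardize:
        X = (X - model.input_mean) / model.input_scale
    logits, _ = model._forward(X, training=False)
    return _sigmoid(logits)
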