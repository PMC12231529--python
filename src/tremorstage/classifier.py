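"""BiLSTM-GRU sequence classifier for tremor-level staging.

Architecture: sequence input (N channels) -> bidirectional LSTM (50 hidden
units per direction, full sequence output, forward/backward states
concatenated) -> dropout 0.5 -> GRU (50 hidden units, final-state readout)
-> dropout 0.5 -> dense (5) -> softmax.  One label per input sequence.

Training uses weighted cross-entropy, Adam, global-gradient-norm clipping,
L2 weight decay on the weight matrices, and a piecewise learning-rate
schedule (x0.1 every 10 epochs).  The whole network — forward pass and
backpropagation through time — is implemented directly on numpy arrays, so
runs are reproducible from a single integer seed on any machine with the
same BLAS arithmetic.

Shapes follow the (batch, time, channels) convention internally; the public
API accepts windows as (batch, channels, time) to match the dataset layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkConfig",
    "TrainedModel",
    "build_network",
    "softmax",
    "weighted_cross_entropy",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_EPS = 1e-12


@dataclass
class NetworkConfig:
    """Hyperparameters of the BiLSTM-GRU network and its training run."""

    n_features: int
    n_classes: int = 5
    bilstm_hidden: int = 50
    gru_hidden: int = 50
    dropout: float = 0.5
    l2_lambda: float = 0.01
    batch_size: int = 64
    max_epochs: int = 30
    lr0: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    grad_threshold: float = 1.0
    seed: int = 0
    class_weights: list[float] | None = None

    def validate(self) -> None:
        if self.n_features <= 0 or self.n_classes <= 0:
            raise ValueError("n_features and n_classes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lr0 < 0:
            raise ValueError("lr0 must be non-negative")
        if self.bilstm_hidden <= 0 or self.gru_hidden <= 0:
            raise ValueError("hidden sizes must be positive")
        if self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.class_weights is not None:
            if len(self.class_weights) != self.n_classes:
                raise ValueError("one class weight per class required")
            if any(w <= 0 for w in self.class_weights):
                raise ValueError("class weights must be positive")

    def weights_vector(self) -> np.ndarray:
        if self.class_weights is None:
            return np.ones(self.n_classes)
        return np.asarray(self.class_weights, dtype=float)

    def iterations_per_run(self, n_train: int) -> int:
        return self.max_epochs * (n_train // self.batch_size)


def parameter_count(config: NetworkConfig) -> int:
    """Closed-form parameter count of the declared architecture.

    Per LSTM direction: 4H(N + H + 1); GRU with single bias: 3G(2H + G + 1);
    dense: C(G + 1).
    """
    n, h = config.n_features, config.bilstm_hidden
    g, c = config.gru_hidden, config.n_classes
    lstm = 2 * 4 * h * (n + h + 1)
    gru = 3 * g * (2 * h + g + 1)
    dense = c * (g + 1)
    return lstm + gru + dense


# ---------------------------------------------------------------------------
# parameters and initialization
# ---------------------------------------------------------------------------

_WEIGHT_KEYS = ("Wx_f", "Wh_f", "Wx_b", "Wh_b", "Wx_g", "Wh_g", "Wd")
_BIAS_KEYS = ("b_f", "b_b", "b_g", "bd")


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _init_params(config: NetworkConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    n, h = config.n_features, config.bilstm_hidden
    g, c = config.gru_hidden, config.n_classes
    p: dict[str, np.ndarray] = {}
    for d in ("f", "b"):                       # forward / backward LSTM
        p[f"Wx_{d}"] = _glorot(rng, (n, 4 * h))
        p[f"Wh_{d}"] = _glorot(rng, (h, 4 * h))
        b = np.zeros(4 * h, dtype=np.float32)
        b[h:2 * h] = 1.0                       # forget-gate bias
        p[f"b_{d}"] = b
    p["Wx_g"] = _glorot(rng, (2 * h, 3 * g))   # GRU input weights (r|z|n)
    p["Wh_g"] = _glorot(rng, (g, 3 * g))
    p["b_g"] = np.zeros(3 * g, dtype=np.float32)
    p["Wd"] = _glorot(rng, (g, c))
    p["bd"] = np.zeros(c, dtype=np.float32)
    return p


@dataclass
class TrainedModel:
    """Network parameters plus the config and per-iteration loss history."""

    config: NetworkConfig
    params: dict[str, np.ndarray]
    history: list[float] = field(default_factory=list)
    channel_names: list[str] | None = None

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def build_network(config: NetworkConfig,
                  channel_names: list[str] | None = None) -> TrainedModel:
    """Deterministically initialize an untrained BiLSTM-GRU network."""
    config.validate()
    return TrainedModel(config=config, params=_init_params(config),
                        channel_names=channel_names)


# ---------------------------------------------------------------------------
# pointwise primitives
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax; invariant to adding a constant to all scores."""
    x = np.asarray(x, dtype=float)
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def weighted_cross_entropy(probs: np.ndarray, targets: np.ndarray,
                           weights: np.ndarray | None = None) -> float:
    """Weighted multiclass cross-entropy loss, averaged over the batch.

    ``probs`` is (L, C) on the simplex; ``targets`` is either one-hot (L, C)
    or integer class indices 0..C-1 of length L.  Probabilities of zero at
    the target class are clamped at a small epsilon.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probs must be (n_samples, n_classes)")
    n, c = probs.shape
    targets = np.asarray(targets)
    if targets.ndim == 2:
        idx = np.argmax(targets, axis=1)
    else:
        idx = targets.astype(int)
    if weights is None:
        weights = np.ones(c)
    w = np.asarray(weights, dtype=float)[idx]
    p = np.clip(probs[np.arange(n), idx], _EPS, None)
    return float(-np.mean(w * np.log(p)))


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------
# Recurrent kernels run time-major -- (T, B, channels) -- so each timestep
# slice is contiguous, and cache full gate arrays so the weight gradients
# reduce to one large GEMM after the loop.  Gate column layout within the
# pre-activation matrices is [sigmoid gates | tanh gates]: LSTM (i, f, o, g),
# GRU (r, z, n).


def _lstm_forward(x: np.ndarray, Wx, Wh, b, reverse: bool):
    """One LSTM direction over time-major (T, B, N); returns (seq, cache)."""
    T, B, _ = x.shape
    H = Wh.shape[0]
    pre = (x.reshape(T * B, -1) @ Wx).reshape(T, B, 4 * H)
    pre += b
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    seq = np.empty((T, B, H), dtype=x.dtype)
    sig_all = np.empty((T, B, 3 * H), dtype=x.dtype)
    g_all = np.empty((T, B, H), dtype=x.dtype)
    c_prev_all = np.empty((T, B, H), dtype=x.dtype)
    tc_all = np.empty((T, B, H), dtype=x.dtype)
    h_prev_all = np.empty((T, B, H), dtype=x.dtype)
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        z = pre[t] + h @ Wh
        sig = _sigmoid(z[:, :3 * H])
        g = np.tanh(z[:, 3 * H:])
        i, f, o = sig[:, :H], sig[:, H:2 * H], sig[:, 2 * H:]
        c_prev_all[t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h_prev_all[t] = h
        h = o * tc
        seq[t] = h
        sig_all[t] = sig
        g_all[t] = g
        tc_all[t] = tc
    cache = (sig_all, g_all, c_prev_all, tc_all, h_prev_all, order)
    return seq, cache


def _gru_forward(x: np.ndarray, Wx, Wh, b):
    """GRU over time-major (T, B, D); returns (final hidden state, cache)."""
    T, B, _ = x.shape
    G = Wh.shape[0]
    pre = (x.reshape(T * B, -1) @ Wx).reshape(T, B, 3 * G)
    pre += b
    h = np.zeros((B, G), dtype=x.dtype)
    rz_all = np.empty((T, B, 2 * G), dtype=x.dtype)
    n_all = np.empty((T, B, G), dtype=x.dtype)
    m_all = np.empty((T, B, G), dtype=x.dtype)
    h_prev_all = np.empty((T, B, G), dtype=x.dtype)
    for t in range(T):
        rec = h @ Wh
        rz = _sigmoid(pre[t, :, :2 * G] + rec[:, :2 * G])
        r, z = rz[:, :G], rz[:, G:]
        m = rec[:, 2 * G:]                 # candidate recurrent term
        n_ = np.tanh(pre[t, :, 2 * G:] + r * m)
        h_prev_all[t] = h
        h = (1.0 - z) * n_ + z * h
        rz_all[t] = rz
        n_all[t] = n_
        m_all[t] = m
    return h, (rz_all, n_all, m_all, h_prev_all)


def _forward(params: dict, config: NetworkConfig, X_tbn: np.ndarray,
             dropout_rng: np.random.Generator | None = None):
    """Full forward pass on time-major input; dropout only when rng given."""
    seq_f, cache_f = _lstm_forward(X_tbn, params["Wx_f"], params["Wh_f"],
                                   params["b_f"], reverse=False)
    seq_b, cache_b = _lstm_forward(X_tbn, params["Wx_b"], params["Wh_b"],
                                   params["b_b"], reverse=True)
    seq = np.concatenate([seq_f, seq_b], axis=2)

    keep = 1.0 - config.dropout
    if dropout_rng is not None and config.dropout > 0:
        mask1 = (dropout_rng.random(seq.shape) < keep).astype(seq.dtype) / keep
        seq_d = seq * mask1
    else:
        mask1 = None
        seq_d = seq

    h_final, cache_g = _gru_forward(seq_d, params["Wx_g"], params["Wh_g"],
                                    params["b_g"])
    if dropout_rng is not None and config.dropout > 0:
        mask2 = (dropout_rng.random(h_final.shape) < keep).astype(seq.dtype) / keep
        h_d = h_final * mask2
    else:
        mask2 = None
        h_d = h_final

    logits = h_d @ params["Wd"] + params["bd"]
    probs = softmax(logits, axis=1)
    fw = {"X": X_tbn, "cache_f": cache_f, "cache_b": cache_b, "seq": seq,
          "mask1": mask1, "seq_d": seq_d, "cache_g": cache_g,
          "h_final": h_final, "mask2": mask2, "h_d": h_d, "probs": probs}
    return probs, fw


# ---------------------------------------------------------------------------
# backward pass (BPTT)
# ---------------------------------------------------------------------------

_FLUSH = 1e-30   # magnitudes below this are zeroed in the BPTT recurrences;
# gradients this small are meaningless at float32 precision, and flushing
# them keeps exponentially decaying recurrent gradients out of the CPU's
# slow denormal path


def _flush_denormals(x: np.ndarray) -> np.ndarray:
    x[np.abs(x) < _FLUSH] = 0.0
    return x


def _lstm_backward(dseq: np.ndarray, x: np.ndarray, cache, Wx, Wh):
    T, B, _ = x.shape
    H = Wh.shape[0]
    sig_all, g_all, c_prev_all, tc_all, h_prev_all, order = cache
    dpre_all = np.empty((T, B, 4 * H), dtype=x.dtype)
    dh_rec = np.zeros((B, H), dtype=x.dtype)
    dc = np.zeros((B, H), dtype=x.dtype)
    for t in reversed(order):
        dh = _flush_denormals(dseq[t] + dh_rec)
        sig = sig_all[t]
        i, f, o = sig[:, :H], sig[:, H:2 * H], sig[:, 2 * H:]
        g = g_all[t]
        tc = tc_all[t]
        dct = dc + dh * o * (1.0 - tc * tc)
        dpre = dpre_all[t]
        dpre[:, :H] = dct * g                 # d input gate
        dpre[:, H:2 * H] = dct * c_prev_all[t]  # d forget gate
        dpre[:, 2 * H:3 * H] = dh * tc        # d output gate
        dpre[:, :3 * H] *= sig * (1.0 - sig)
        dpre[:, 3 * H:] = (dct * i) * (1.0 - g * g)
        dc = _flush_denormals(dct * f)
        dh_rec = dpre @ Wh.T
    flat = dpre_all.reshape(T * B, 4 * H)
    dWx = x.reshape(T * B, -1).T @ flat
    dWh = h_prev_all.reshape(T * B, H).T @ flat
    db = flat.sum(axis=0)
    dx = (flat @ Wx.T).reshape(T, B, -1)
    return dx, dWx, dWh, db


def _gru_backward(dh_final: np.ndarray, x: np.ndarray, cache, Wx, Wh):
    T, B, _ = x.shape
    G = Wh.shape[0]
    rz_all, n_all, m_all, h_prev_all = cache
    dpre_all = np.empty((T, B, 3 * G), dtype=x.dtype)
    # d(recurrent pre-activation): [r|z] blocks equal dpre, the candidate
    # block enters through m = h_prev @ Wh[:, 2G:]
    drec_all = np.empty((T, B, 3 * G), dtype=x.dtype)
    dh = dh_final.astype(x.dtype)
    for t in range(T - 1, -1, -1):
        rz = rz_all[t]
        r, z = rz[:, :G], rz[:, G:]
        n_ = n_all[t]
        dpre = dpre_all[t]
        dpre_n = (dh * (1.0 - z)) * (1.0 - n_ * n_)
        dpre[:, :G] = dpre_n * m_all[t]       # d reset gate
        dpre[:, G:2 * G] = dh * (h_prev_all[t] - n_)  # d update gate
        dpre[:, :2 * G] *= rz * (1.0 - rz)
        dpre[:, 2 * G:] = dpre_n
        drec = drec_all[t]
        drec[:, :2 * G] = dpre[:, :2 * G]
        drec[:, 2 * G:] = dpre_n * r
        dh = _flush_denormals(dh * z + drec @ Wh.T)
    flat = dpre_all.reshape(T * B, 3 * G)
    dWx = x.reshape(T * B, -1).T @ flat
    dWh = h_prev_all.reshape(T * B, G).T @ drec_all.reshape(T * B, 3 * G)
    db = flat.sum(axis=0)
    dx = (flat @ Wx.T).reshape(T, B, -1)
    return dx, dWx, dWh, db


def _backward(params: dict, config: NetworkConfig, fw: dict,
              y_idx: np.ndarray, class_weights: np.ndarray):
    B = y_idx.size
    probs = fw["probs"]
    targets = np.zeros_like(probs)
    targets[np.arange(B), y_idx] = 1.0
    w = class_weights[y_idx][:, None]
    dlogits = (w * (probs - targets) / B).astype(fw["X"].dtype)

    grads: dict[str, np.ndarray] = {}
    grads["Wd"] = fw["h_d"].T @ dlogits
    grads["bd"] = dlogits.sum(axis=0)
    dh_d = dlogits @ params["Wd"].T
    if fw["mask2"] is not None:
        dh_d = dh_d * fw["mask2"]

    dseq_d, grads["Wx_g"], grads["Wh_g"], grads["b_g"] = _gru_backward(
        dh_d, fw["seq_d"], fw["cache_g"], params["Wx_g"], params["Wh_g"])
    if fw["mask1"] is not None:
        dseq_d = dseq_d * fw["mask1"]

    H = config.bilstm_hidden
    _, grads["Wx_f"], grads["Wh_f"], grads["b_f"] = _lstm_backward(
        dseq_d[:, :, :H], fw["X"], fw["cache_f"], params["Wx_f"],
        params["Wh_f"])
    _, grads["Wx_b"], grads["Wh_b"], grads["b_b"] = _lstm_backward(
        dseq_d[:, :, H:], fw["X"], fw["cache_b"], params["Wx_b"],
        params["Wh_b"])
    return grads


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _clip_global_norm(grads: dict[str, np.ndarray], threshold: float) -> None:
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                        for g in grads.values()))
    if total > threshold > 0:
        scale = threshold / total
        for key in grads:
            grads[key] = grads[key] * scale


def train(model: TrainedModel, X: np.ndarray, y: np.ndarray,
          config: NetworkConfig | None = None) -> TrainedModel:
    """Train the network in place on windows ``X`` (n, channels, time) with
    labels ``y`` in 1..C; returns the same model with history filled.

    Mini-batches of ``batch_size`` are drawn from a fresh shuffle each epoch
    (trailing partial batches are dropped, so iterations per run =
    max_epochs * floor(n_train / batch_size)).  Gradients get L2 weight decay
    on the weight matrices, global-norm clipping, and an Adam update with the
    piecewise learning-rate schedule.  The recorded history is the plain
    cross-entropy loss per iteration.
    """
    config = config or model.config
    config.validate()
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3 or X.shape[1] != config.n_features:
        raise ValueError(
            f"expected (n, {config.n_features}, time) windows, got {X.shape}")
    y_idx = np.asarray(y, dtype=int) - 1
    if y_idx.min() < 0 or y_idx.max() >= config.n_classes:
        raise ValueError("labels must lie in 1..n_classes")
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    class_weights = config.weights_vector()

    params = model.params
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rng = np.random.default_rng(config.seed + 1)

    n_batches = n // config.batch_size
    if n_batches == 0:
        n_batches = 1  # degenerate: single undersized batch

    for epoch in range(config.max_epochs):
        lr = config.lr0 * config.lr_drop_factor ** (epoch // config.lr_drop_period)
        perm = rng.permutation(n)
        for bi in range(n_batches):
            sel = perm[bi * config.batch_size:(bi + 1) * config.batch_size]
            xb = np.ascontiguousarray(np.transpose(X[sel], (2, 0, 1)))  # (T, B, N)
            yb = y_idx[sel]
            probs, fw = _forward(params, config, xb, dropout_rng=rng)
            loss = weighted_cross_entropy(probs, yb, class_weights)
            model.history.append(loss)
            grads = _backward(params, config, fw, yb, class_weights)
            if config.l2_lambda > 0:
                for key in _WEIGHT_KEYS:
                    grads[key] = grads[key] + config.l2_lambda * params[key]
            _clip_global_norm(grads, config.grad_threshold)
            step += 1
            if lr > 0:
                for key in params:
                    g = grads[key]
                    adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                    adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                    m_hat = adam_m[key] / (1 - beta1 ** step)
                    v_hat = adam_v[key] / (1 - beta2 ** step)
                    params[key] = (params[key]
                                   - lr * m_hat / (np.sqrt(v_hat) + eps)
                                   ).astype(np.float32)
    return model


def predict(model: TrainedModel, X: np.ndarray,
            batch_size: int = 256):
    """Classify windows (n, channels, time); dropout disabled.

    Returns ``(labels, probs)`` with labels in 1..C.
    """
    config = model.config
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3 or X.shape[1] != config.n_features:
        raise ValueError(
            f"expected (n, {config.n_features}, time) windows, got {X.shape}")
    probs_out = []
    for start in range(0, X.shape[0], batch_size):
        xb = np.ascontiguousarray(
            np.transpose(X[start:start + batch_size], (2, 0, 1)))
        probs, _ = _forward(model.params, config, xb, dropout_rng=None)
        probs_out.append(probs)
    probs = np.concatenate(probs_out, axis=0)
    labels = np.argmax(probs, axis=1) + 1
    return labels, probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Versioned checkpoint: config + channel order as JSON, weights as npz."""
    path = Path(path)
    payload = {
        "format_version": 1,
        "config": asdict(model.config),
        "channel_names": model.channel_names,
        "history": list(map(float, model.history)),
    }
    np.savez(path.with_suffix(".npz"), **model.params)
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    payload = json.loads(path.with_suffix(".json").read_text())
    config = NetworkConfig(**payload["config"])
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k] for k in data.files}
    return TrainedModel(config=config, params=params,
                        history=payload["history"],
                        channel_names=payload["channel_names"])
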