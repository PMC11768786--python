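"""From-scratch LSTM multi-classifier: gated cell, softmax, cross-entropy,
backpropagation through time, plain gradient descent.

The recurrence per layer and time step t is the standard gated cell

    f_t = sigmoid(w_fx x_t + w_fh h_{t-1} + b_f)        (forget gate)
    i_t = sigmoid(w_ix x_t + w_ih h_{t-1} + b_i)        (input gate)
    C'_t = tanh(w_cx x_t + w_ch h_{t-1} + b_c)          (candidate state)
    C_t = f_t * C_{t-1} + i_t * C'_t                    (cell update)
    e_t = sigmoid(w_ex x_t + w_eh h_{t-1} + b_e)        (output gate)
    h_t = e_t * tanh(C_t)                               (hidden state)

Layers are stacked (the lower layer's h-sequence is the upper layer's input
sequence); the final time step's top-layer hidden state feeds an affine
softmax output whose cross-entropy against one-hot labels is minimized by
full-batch gradient descent.  Gradients are exact BPTT, computed by hand and
validated against central finite differences in the test suite.

Everything is float64 NumPy; no deep-learning framework is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

EPS_PROB = 1e-12

GATE_FIELDS = ("w_fx", "w_fh", "b_f", "w_ix", "w_ih", "b_i",
               "w_cx", "w_ch", "b_c", "w_ex", "w_eh", "b_e")


@dataclass
class LayerParams:
    """One LSTM layer's gate weights: w_*x (H,F), w_*h (H,H), b_* (H,)."""

    w_fx: np.ndarray
    w_fh: np.ndarray
    b_f: np.ndarray
    w_ix: np.ndarray
    w_ih: np.ndarray
    b_i: np.ndarray
    w_cx: np.ndarray
    w_ch: np.ndarray
    b_c: np.ndarray
    w_ex: np.ndarray
    w_eh: np.ndarray
    b_e: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.b_f.size

    @property
    def input_size(self) -> int:
        return self.w_fx.shape[1]


@dataclass
class LSTMParams:
    """All trainable parameters: stacked layers plus the softmax output layer."""

    layers: list
    w_y: np.ndarray  # (n_classes, H_top)
    b_y: np.ndarray  # (n_classes,)

    @property
    def n_classes(self) -> int:
        return self.b_y.size

    def named_arrays(self):
        """Yield (path, array) for every parameter, in a fixed order."""
        for li, layer in enumerate(self.layers):
            for name in GATE_FIELDS:
                yield f"layers[{li}].{name}", getattr(layer, name)
        yield "w_y", self.w_y
        yield "b_y", self.b_y

    def copy(self) -> "LSTMParams":
        return LSTMParams([LayerParams(**{f.name: getattr(l, f.name).copy()
                                          for f in fields(l)}) for l in self.layers],
                          self.w_y.copy(), self.b_y.copy())


def init_params(input_size: int, hidden_sizes, n_classes: int, seed: int = 0,
                scale: float = 0.1) -> LSTMParams:
    """Uniform(-scale, scale) initialization from a stated seed."""
    rng = np.random.default_rng(seed)
    layers = []
    f_in = input_size
    for h in hidden_sizes:
        kw = {}
        for name in GATE_FIELDS:
            shape = (h, f_in) if name.endswith("x") else (h, h) if name.endswith("h") else (h,)
            kw[name] = rng.uniform(-scale, scale, shape)
        layers.append(LayerParams(**kw))
        f_in = h
    w_y = rng.uniform(-scale, scale, (n_classes, f_in))
    b_y = rng.uniform(-scale, scale, n_classes)
    return LSTMParams(layers, w_y, b_y)


@dataclass
class LSTMState:
    """Cell/hidden state plus the gate activations of one step."""

    h: np.ndarray
    c: np.ndarray
    f: np.ndarray = None
    i: np.ndarray = None
    c_tilde: np.ndarray = None
    e: np.ndarray = None

    @classmethod
    def zeros(cls, batch: int, hidden: int) -> "LSTMState":
        return cls(np.zeros((batch, hidden)), np.zeros((batch, hidden)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cell_step(layer: LayerParams, x_t: np.ndarray, prev: LSTMState) -> LSTMState:
    """One LSTM cell update.  x_t is (B,F) or (F,); prev holds h,c of (B,H)."""
    x_t = np.atleast_2d(np.asarray(x_t, float))
    h_prev, c_prev = np.atleast_2d(prev.h), np.atleast_2d(prev.c)
    if x_t.shape[1] != layer.input_size or h_prev.shape[1] != layer.hidden_size:
        raise ValueError(
            f"shape mismatch: x_t {x_t.shape}, h {h_prev.shape} vs layer "
            f"(F={layer.input_size}, H={layer.hidden_size})")
    f = _sigmoid(x_t @ layer.w_fx.T + h_prev @ layer.w_fh.T + layer.b_f)
    i = _sigmoid(x_t @ layer.w_ix.T + h_prev @ layer.w_ih.T + layer.b_i)
    c_tilde = np.tanh(x_t @ layer.w_cx.T + h_prev @ layer.w_ch.T + layer.b_c)
    c = f * c_prev + i * c_tilde
    e = _sigmoid(x_t @ layer.w_ex.T + h_prev @ layer.w_eh.T + layer.b_e)
    h = e * np.tanh(c)
    return LSTMState(h, c, f, i, c_tilde, e)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax (max-subtracted)."""
    z = np.atleast_2d(logits)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    return p.reshape(np.shape(logits))


def _unroll(params: LSTMParams, X: np.ndarray):
    """Run the stacked unroll; returns (probs, per-layer caches, logits)."""
    X = np.asarray(X, float)
    if X.ndim == 2:
        X = X[None]
    B, T, _ = X.shape
    caches = []
    inp = X
    for layer in params.layers:
        state = LSTMState.zeros(B, layer.hidden_size)
        states = []
        for t in range(T):
            state = cell_step(layer, inp[:, t, :], state)
            states.append(state)
        caches.append((inp, states))
        inp = np.stack([s.h for s in states], axis=1)
    h_final = inp[:, -1, :]
    logits = h_final @ params.w_y.T + params.b_y
    return softmax(logits), caches, h_final


def forward(params: LSTMParams, X) -> np.ndarray:
    """Class probabilities for X of shape (B,T,F) or a single (T,F) sample."""
    single = np.asarray(X).ndim == 2
    probs, _, _ = _unroll(params, X)
    return probs[0] if single else probs


def cross_entropy(probs: np.ndarray, one_hot: np.ndarray) -> float:
    """Mean cross-entropy -sum(B_i log f(X_i)); probabilities clipped at 1e-12."""
    p = np.atleast_2d(probs)
    y = np.atleast_2d(one_hot)
    if np.any(p[y > 0] < EPS_PROB):
        warnings.warn("true-class probability below 1e-12 clipped in cross-entropy",
                      RuntimeWarning, stacklevel=2)
    return float(-np.mean(np.sum(y * np.log(np.clip(p, EPS_PROB, 1.0)), axis=1)))


def _zero_grads(params: LSTMParams) -> LSTMParams:
    return LSTMParams(
        [LayerParams(**{name: np.zeros_like(getattr(l, name)) for name in GATE_FIELDS})
         for l in params.layers],
        np.zeros_like(params.w_y), np.zeros_like(params.b_y))


def backward(params: LSTMParams, X: np.ndarray, one_hot: np.ndarray) -> LSTMParams:
    """Exact BPTT gradients of the mean cross-entropy w.r.t. every parameter.

    Returns an :class:`LSTMParams` of the same shapes holding gradients.
    """
    X = np.asarray(X, float)
    if X.ndim == 2:
        X = X[None]
    Y = np.atleast_2d(one_hot)
    B, T, _ = X.shape
    probs, caches, h_final = _unroll(params, X)
    grads = _zero_grads(params)

    dlogits = (probs - Y) / B  # softmax + CE composite gradient
    grads.w_y[:] = dlogits.T @ h_final
    grads.b_y[:] = dlogits.sum(axis=0)

    # gradient w.r.t. the top layer's h-sequence: only the final step is read
    H_top = params.layers[-1].hidden_size
    dh_seq = np.zeros((B, T, H_top))
    dh_seq[:, -1, :] = dlogits @ params.w_y

    for li in range(len(params.layers) - 1, -1, -1):
        layer = params.layers[li]
        g = grads.layers[li]
        inp, states = caches[li]
        H = layer.hidden_size
        dx_seq = np.zeros((B, T, layer.input_size))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            s = states[t]
            h_prev = states[t - 1].h if t > 0 else np.zeros((B, H))
            c_prev = states[t - 1].c if t > 0 else np.zeros((B, H))
            tanh_c = np.tanh(s.c)
            dh = dh_seq[:, t, :] + dh_next
            dc = dc_next + dh * s.e * (1.0 - tanh_c ** 2)
            d_e = dh * tanh_c * s.e * (1.0 - s.e)
            d_f = dc * c_prev * s.f * (1.0 - s.f)
            d_i = dc * s.c_tilde * s.i * (1.0 - s.i)
            d_ct = dc * s.i * (1.0 - s.c_tilde ** 2)
            x_t = inp[:, t, :]
            for d, wx, wh, b in ((d_f, "w_fx", "w_fh", "b_f"),
                                 (d_i, "w_ix", "w_ih", "b_i"),
                                 (d_ct, "w_cx", "w_ch", "b_c"),
                                 (d_e, "w_ex", "w_eh", "b_e")):
                getattr(g, wx)[:] += d.T @ x_t
                getattr(g, wh)[:] += d.T @ h_prev
                getattr(g, b)[:] += d.sum(axis=0)
            dx_seq[:, t, :] = (d_f @ layer.w_fx + d_i @ layer.w_ix
                               + d_ct @ layer.w_cx + d_e @ layer.w_ex)
            dh_next = (d_f @ layer.w_fh + d_i @ layer.w_ih
                       + d_ct @ layer.w_ch + d_e @ layer.w_eh)
            dc_next = dc * s.f
        dh_seq = dx_seq  # lower layer's h fed this layer's x at every step

    for path, arr in grads.named_arrays():
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite gradient at {path}")
    return grads


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent settings.

    ``learning_rate`` applies to plain full-batch gradient descent (no
    momentum or adaptivity); ``clip_norm`` caps the global gradient norm for
    stability; ``loss_tolerance`` stops training early once the epoch loss
    falls below it (0 disables early stopping).
    """

    max_epochs: int = 200
    learning_rate: float = 1.0
    hidden_sizes: tuple = (10, 20)
    seed: int = 0
    loss_tolerance: float = 0.0
    clip_norm: float = 5.0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


@dataclass
class TrainResult:
    params: LSTMParams
    losses: np.ndarray  # per-epoch training loss, before each update


def train(params: LSTMParams, X: np.ndarray, labels: np.ndarray,
          config: TrainConfig = TrainConfig()) -> TrainResult:
    """Full-batch gradient descent on mean cross-entropy.

    Deterministic: no randomness is drawn here (initialization carries the
    seed).  Raises on divergence (non-finite loss).
    """
    params = params.copy()
    Y = one_hot(np.asarray(labels), params.n_classes)
    losses = []
    for epoch in range(config.max_epochs):
        probs, _, _ = _unroll(params, X)
        loss = cross_entropy(probs, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}: loss={loss}")
        losses.append(loss)
        if config.loss_tolerance > 0 and loss < config.loss_tolerance:
            break
        grads = backward(params, X, Y)
        if config.clip_norm > 0:
            gnorm = np.sqrt(sum(float(np.sum(a * a)) for _, a in grads.named_arrays()))
            if gnorm > config.clip_norm:
                scale = config.clip_norm / gnorm
                for _, a in grads.named_arrays():
                    a *= scale
        for (_, p), (_, g) in zip(params.named_arrays(), grads.named_arrays()):
            p -= config.learning_rate * g
    return TrainResult(params, np.array(losses))


@dataclass
class EvalResult:
    accuracy: float
    confusion: np.ndarray  # (C,C), rows = true class, cols = predicted
    per_class_recall: np.ndarray


def evaluate(params: LSTMParams, X: np.ndarray, labels: np.ndarray) -> EvalResult:
    """Accuracy, confusion matrix and per-class recalls on a labeled set."""
    probs = forward(params, X)
    pred = np.argmax(np.atleast_2d(probs), axis=1)
    labels = np.asarray(labels)
    C = params.n_classes
    conf = np.zeros((C, C), dtype=int)
    for y, p in zip(labels, pred):
        conf[y, p] += 1
    totals = conf.sum(axis=1)
    recalls = np.divide(np.diag(conf), totals, out=np.full(C, np.nan), where=totals > 0)
    return EvalResult(float(np.trace(conf) / conf.sum()), conf, recalls)


# ---------------------------------------------------------------------------
# Serialization: portable structured-text weight documents
# ---------------------------------------------------------------------------


def save_params(params: LSTMParams, path, extra: dict | None = None) -> None:
    """Write weights as a YAML document of named arrays (lists) + shapes."""
    import yaml

    doc = {"format": "fatiguekit-lstm-v1",
           "hidden_sizes": [l.hidden_size for l in params.layers],
           "n_classes": params.n_classes,
           "arrays": {name: arr.tolist() for name, arr in params.named_arrays()}}
    if extra:
        doc["meta"] = extra
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_params(path) -> LSTMParams:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != "fatiguekit-lstm-v1":
        raise ValueError(f"{path}: not a fatiguekit LSTM weight document")
    arrays = {name: np.asarray(a, float) for name, a in doc["arrays"].items()}
    layers = []
    for li in range(len(doc["hidden_sizes"])):
        layers.append(LayerParams(**{name: arrays[f"layers[{li}].{name}"]
                                     for name in GATE_FIELDS}))
    return LSTMParams(layers, arrays["w_y"], arrays["b_y"])
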