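"""Minimal LSTM sequence classifier in numpy.

Stacked LSTM layers followed by a time-distributed fully-connected layer and
softmax, trained with truncated backpropagation through time, cross-entropy
loss and Adam. Small networks over short feature sequences train comfortably
on a single CPU, and every stochastic step is driven by an explicit
``numpy.random.Generator`` so training is bit-reproducible.

Gate layout in the packed weight matrices is (input, forget, cell, output);
the forget-gate bias is initialized to 1, the standard remedy for early
forgetting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMNetwork", "softmax", "cross_entropy", "train_network"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray,
                  class_weights: np.ndarray | None = None) -> float:
    """Mean negative log-likelihood over all (batch, time) positions."""
    p = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    nll = -np.log(np.maximum(p, 1e-12))
    if class_weights is not None:
        wts = class_weights[targets]
        return float((nll * wts).sum() / wts.sum())
    return float(nll.mean())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class LSTMNetwork:
    """Stacked LSTM + dense softmax head, with explicit forward/backward."""

    def __init__(self, input_size: int, hidden_sizes, n_classes: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.input_size = int(input_size)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.n_classes = int(n_classes)
        self.dtype = dtype
        self.params: dict[str, np.ndarray] = {}
        prev = self.input_size
        for li, h in enumerate(self.hidden_sizes):
            self.params[f"Wx{li}"] = self._glorot(rng, prev, 4 * h)
            self.params[f"Wh{li}"] = self._glorot(rng, h, 4 * h)
            b = np.zeros(4 * h, dtype=dtype)
            b[h:2 * h] = 1.0  # forget gate bias
            self.params[f"b{li}"] = b
            prev = h
        self.params["Wd"] = self._glorot(rng, prev, self.n_classes)
        self.params["bd"] = np.zeros(self.n_classes, dtype=dtype)

    def _glorot(self, rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out)).astype(self.dtype)

    # -- forward ------------------------------------------------------------

    def _layer_forward(self, li: int, X: np.ndarray, h0, c0, cache: bool):
        """Run layer ``li`` over (B, T, D); returns outputs and final state."""
        Wx, Wh, b = self.params[f"Wx{li}"], self.params[f"Wh{li}"], self.params[f"b{li}"]
        B, T, _ = X.shape
        H = Wh.shape[0]
        h = np.zeros((B, H), dtype=self.dtype) if h0 is None else h0
        c = np.zeros((B, H), dtype=self.dtype) if c0 is None else c0
        out = np.empty((B, T, H), dtype=self.dtype)
        steps = [] if cache else None
        Zx = X @ Wx  # precompute input contributions for all timesteps
        for t in range(T):
            z = Zx[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t] = h
            if cache:
                steps.append((i, f, g, o, c_prev, tc))
        return out, h, c, steps

    def forward(self, X: np.ndarray, state=None, cache: bool = False):
        """Logits over classes for every (batch, time) position.

        ``state`` is a list of (h, c) per layer for stateful streaming, or
        None for zero initial state. Returns (logits, new_state, cache).
        """
        X = np.ascontiguousarray(X, dtype=self.dtype)
        layer_inputs = [X]
        new_state = []
        caches = []
        inp = X
        for li in range(len(self.hidden_sizes)):
            h0, c0 = (None, None) if state is None else state[li]
            out, h, c, steps = self._layer_forward(li, inp, h0, c0, cache)
            new_state.append((h, c))
            caches.append(steps)
            layer_inputs.append(out)
            inp = out
        logits = inp @ self.params["Wd"] + self.params["bd"]
        full_cache = {"layer_inputs": layer_inputs, "steps": caches, "state": state} if cache else None
        return logits, new_state, full_cache

    def predict_proba(self, X: np.ndarray, state=None):
        logits, new_state, _ = self.forward(X, state=state, cache=False)
        return softmax(logits.astype(np.float64)), new_state

    # -- backward -----------------------------------------------------------

    def _layer_backward(self, li: int, cache, layer_input, layer_output, dH, grads):
        Wx, Wh = self.params[f"Wx{li}"], self.params[f"Wh{li}"]
        B, T, H = layer_output.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params[f"b{li}"])
        dX = np.empty_like(layer_input)
        dh_next = np.zeros((B, H), dtype=self.dtype)
        dc_next = np.zeros((B, H), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc = cache[t]
            dh = dH[:, t] + dh_next
            do = dh * tc
            dtc = dh * o * (1.0 - tc * tc) + dc_next
            di = dtc * g
            df = dtc * c_prev
            dg = dtc * i
            dc_next = dtc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            h_prev = layer_output[:, t - 1] if t > 0 else np.zeros((B, H), dtype=self.dtype)
            dWx += layer_input[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
        grads[f"Wx{li}"] = dWx
        grads[f"Wh{li}"] = dWh
        grads[f"b{li}"] = db
        return dX

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. all parameters given d(loss)/d(logits)."""
        grads: dict[str, np.ndarray] = {}
        layer_inputs = cache["layer_inputs"]
        top = layer_inputs[-1]  # (B, T, H_last)
        dlogits = dlogits.astype(self.dtype)
        grads["Wd"] = np.einsum("bth,btc->hc", top, dlogits)
        grads["bd"] = dlogits.sum(axis=(0, 1))
        dH = dlogits @ self.params["Wd"].T
        for li in range(len(self.hidden_sizes) - 1, -1, -1):
            dH = self._layer_backward(
                li, cache["steps"][li], layer_inputs[li], layer_inputs[li + 1], dH, grads
            )
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float = 5.0) -> None:
    total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] *= scale


def train_network(
    net: LSTMNetwork,
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray | None, y_val: np.ndarray | None,
    rng: np.random.Generator,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 50,
    patience: int = 10,
    class_weights: np.ndarray | None = None,
) -> dict:
    """Mini-batch Adam training with early stopping on validation loss.

    ``X_*`` are (n_sequences, T, D) and ``y_*`` (n_sequences, T) integer
    targets. The best-validation-loss parameters are restored at the end. If
    no validation sequences are given, training runs for ``max_epochs``.
    """
    opt = _Adam(net.params, lr=learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_params = net.copy_params()
    since_best = 0
    n = X_train.shape[0]
    cw = None if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb, yb = X_train[idx], y_train[idx]
            logits, _, cache = net.forward(Xb, cache=True)
            probs = softmax(logits.astype(np.float64))
            epoch_loss += cross_entropy(probs, yb, cw)
            n_batches += 1
            dlogits = probs.copy()
            np.put_along_axis(
                dlogits, yb[..., None],
                np.take_along_axis(dlogits, yb[..., None], axis=-1) - 1.0, axis=-1,
            )
            if cw is not None:
                wts = cw[yb]
                dlogits *= (wts / wts.sum())[..., None]
            else:
                dlogits /= yb.size
            grads = net.backward(cache, dlogits)
            _clip_global_norm(grads)
            opt.step(net.params, grads)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        if X_val is not None and X_val.shape[0] > 0:
            probs, _ = net.predict_proba(X_val)
            val_loss = cross_entropy(probs, y_val, cw)
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = net.copy_params()
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
    if X_val is not None and X_val.shape[0] > 0:
        net.set_params(best_params)
    return history
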