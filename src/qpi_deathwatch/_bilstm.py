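"""A compact NumPy implementation of a bidirectional LSTM sequence regressor.

Architecture: a stack of BiLSTM layers (forward + backward passes
concatenated per timestep) followed by timestep-wise fully connected
layers with ReLU and dropout, ending in a 1-d linear output per frame.
Training uses masked mean-squared error over the valid (unpadded) part
of each sequence, Adam with decoupled weight decay, and global
gradient-norm clipping.

Sequences are left-aligned: sample ``b`` occupies timesteps
``[0, lengths[b])`` and padding sits at the end, so the forward pass
never crosses padding; the backward direction flips each sequence
within its valid length before and after its pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMNet", "AdamState", "masked_mse", "pad_sequences"]


def pad_sequences(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Left-align variable-length (T_i, D) arrays into (B, T_max, D) + lengths."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    T = int(lengths.max())
    D = seqs[0].shape[1]
    out = np.zeros((len(seqs), T, D), dtype=np.float64)
    for b, s in enumerate(seqs):
        out[b, : len(s)] = s
    return out, lengths


def _flip_valid(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its valid length (padding stays put)."""
    out = x.copy()
    for b, L in enumerate(lengths):
        out[b, :L] = x[b, :L][::-1]
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class _LSTMDirection:
    """Single-direction LSTM over a (B, T, D) batch, with full BPTT."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int):
        H = d_hidden
        self.Wx = _glorot(rng, d_in, 4 * H)
        self.Wh = _glorot(rng, H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.H = H

    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray):
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = {
            "x": x,
            "i": np.empty((T, B, H)), "f": np.empty((T, B, H)),
            "g": np.empty((T, B, H)), "o": np.empty((T, B, H)),
            "c": np.empty((T, B, H)), "tc": np.empty((T, B, H)),
            "hprev": np.empty((T, B, H)), "cprev": np.empty((T, B, H)),
        }
        out = np.empty((B, T, H))
        for t in range(T):
            cache["hprev"][t] = h
            cache["cprev"][t] = c
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t] = i, f, g, o
            cache["c"][t], cache["tc"][t] = c, tc
            out[:, t] = h
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        x = cache["x"]
        B, T, D = x.shape
        H = self.H
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            c, tc = cache["c"][t], cache["tc"][t]
            hprev, cprev = cache["hprev"][t], cache["cprev"][t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * cprev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += hprev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class BiLSTMNet:
    """Stacked BiLSTM + fully connected head, per-frame scalar regression."""

    def __init__(
        self,
        d_in: int,
        hidden_units: int = 100,
        n_lstm_layers: int = 2,
        fc_sizes: tuple[int, ...] = (100, 50, 100),
        dropout: float = 0.5,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.lstm: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        d = d_in
        for _ in range(n_lstm_layers):
            self.lstm.append(
                (_LSTMDirection(rng, d, hidden_units), _LSTMDirection(rng, d, hidden_units))
            )
            d = 2 * hidden_units
        self.fc: list[dict[str, np.ndarray]] = []
        for size in fc_sizes:
            self.fc.append({"W": _glorot(rng, d, size), "b": np.zeros(size)})
            d = size
        self.out = {"W": _glorot(rng, d, 1), "b": np.zeros(1)}

    # -- parameter bookkeeping -------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        params = {}
        for l, (fwd, bwd) in enumerate(self.lstm):
            for tag, d in (("f", fwd), ("b", bwd)):
                for k, v in d.params().items():
                    params[f"lstm{l}{tag}.{k}"] = v
        for j, layer in enumerate(self.fc):
            params[f"fc{j}.W"] = layer["W"]
            params[f"fc{j}.b"] = layer["b"]
        params["out.W"] = self.out["W"]
        params["out.b"] = self.out["b"]
        return params

    def set_params_from(self, flat: dict[str, np.ndarray]) -> None:
        for name, value in self.named_params().items():
            value[...] = flat[name]

    # -- forward / backward ----------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        lengths: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        caches = {"lstm": [], "drop": [], "fc": [], "lengths": lengths}
        h = x
        for l, (fwd, bwd) in enumerate(self.lstm):
            out_f, cache_f = fwd.forward(h)
            flipped = _flip_valid(h, lengths)
            out_b_rev, cache_b = bwd.forward(flipped)
            out_b = _flip_valid(out_b_rev, lengths)
            h = np.concatenate([out_f, out_b], axis=2)
            caches["lstm"].append((cache_f, cache_b))
            if train and self.dropout > 0:
                keep = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * keep
                caches["drop"].append(keep)
            else:
                caches["drop"].append(None)
        B, T, D = h.shape
        a = h.reshape(B * T, D)
        for j, layer in enumerate(self.fc):
            z = a @ layer["W"] + layer["b"]
            relu = np.maximum(z, 0.0)
            if train and self.dropout > 0:
                keep = (rng.random(relu.shape) >= self.dropout) / (1 - self.dropout)
                relu_d = relu * keep
            else:
                keep = None
                relu_d = relu
            caches["fc"].append({"a_in": a, "z": z, "keep": keep})
            a = relu_d
        y = (a @ self.out["W"] + self.out["b"]).reshape(B, T)
        caches["head_in"] = a
        caches["shape"] = (B, T, D)
        return y, caches

    def backward(self, dy: np.ndarray, caches) -> dict[str, np.ndarray]:
        B, T, D = caches["shape"]
        lengths = caches["lengths"]
        grads: dict[str, np.ndarray] = {}
        da = dy.reshape(B * T, 1) @ self.out["W"].T
        grads["out.W"] = caches["head_in"].T @ dy.reshape(B * T, 1)
        grads["out.b"] = dy.reshape(-1, 1).sum(axis=0)
        for j in range(len(self.fc) - 1, -1, -1):
            fc_cache = caches["fc"][j]
            if fc_cache["keep"] is not None:
                da = da * fc_cache["keep"]
            dz = da * (fc_cache["z"] > 0)
            grads[f"fc{j}.W"] = fc_cache["a_in"].T @ dz
            grads[f"fc{j}.b"] = dz.sum(axis=0)
            da = dz @ self.fc[j]["W"].T
        dh = da.reshape(B, T, D)
        for l in range(len(self.lstm) - 1, -1, -1):
            if caches["drop"][l] is not None:
                dh = dh * caches["drop"][l]
            H = self.lstm[l][0].H
            d_f, d_b = dh[:, :, :H], dh[:, :, H:]
            cache_f, cache_b = caches["lstm"][l]
            dx_f, g_f = self.lstm[l][0].backward(d_f, cache_f)
            dx_b_rev, g_b = self.lstm[l][1].backward(_flip_valid(d_b, lengths), cache_b)
            dx_b = _flip_valid(dx_b_rev, lengths)
            for k, v in g_f.items():
                grads[f"lstm{l}f.{k}"] = v
            for k, v in g_b.items():
                grads[f"lstm{l}b.{k}"] = v
            dh = dx_f + dx_b
        return grads


def masked_mse(y_pred: np.ndarray, y_true: np.ndarray, lengths: np.ndarray):
    """Mean squared error over valid timesteps; returns (loss, dloss/dy_pred)."""
    B, T = y_pred.shape
    mask = np.arange(T)[None, :] < lengths[:, None]
    n = mask.sum()
    diff = (y_pred - y_true) * mask
    loss = float((diff**2).sum() / n)
    dy = 2.0 * diff / n
    return loss, dy


class AdamState:
    """Adam with decoupled weight decay and global gradient-norm clipping."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 1e-3,
        clip_norm: float = 1.0,
    ):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm and self.clip_norm > 0:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            p -= self.lr * update
            if self.weight_decay and not k.endswith(".b"):
                p -= self.lr * self.weight_decay * p
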