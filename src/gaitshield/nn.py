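"""LSTM-with-attention binary classifier for multivariate gait sequences.

Architecture: an LSTM layer (32 units), dropout (rate 0.3) on the
hidden-state sequence, a multiplicative (Luong-style) attention layer
whose score function is the bilinear form

    score(h_t, h_s) = h_t^T W h_s

with a trained matrix W (the query is the final hidden state, the keys
are all hidden states, scores are softmax-normalized into a context
vector), a dense layer of 10 rectified-linear units with an L1 weight
penalty of 0.002, and a 2-way softmax output trained with cross-entropy
under the RMSProp optimizer.

The implementation is plain numpy: forward pass and
backpropagation-through-time are written out explicitly (the gradients
are verified against central finite differences in the test suite).
Sequences of unequal length are padded and masked; at padded steps the
recurrent state is carried through unchanged and attention weights are
zeroed, so padding cannot influence the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelConfig", "LSTMAttentionClassifier", "attention_score"]


@dataclass
class ModelConfig:
    lstm_units: int = 32
    dropout_rate: float = 0.3
    dense_units: int = 10
    l1_penalty: float = 0.002
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    rms_rho: float = 0.9
    rms_eps: float = 1e-7
    train_seed: int = 0


def attention_score(h_t: np.ndarray, h_s: np.ndarray, W: np.ndarray) -> float:
    """Multiplicative attention score h_t^T W h_s."""
    h_t = np.asarray(h_t, dtype=float)
    h_s = np.asarray(h_s, dtype=float)
    if W.shape != (h_t.shape[0], h_s.shape[0]):
        raise ValueError("W must be (dim(h_t), dim(h_s))")
    return float(h_t @ W @ h_s)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class LSTMAttentionClassifier:
    """Two-class sequence classifier; inputs are lists of (T_i, d) arrays."""

    def __init__(self, cfg: ModelConfig, n_features: int):
        self.cfg = cfg
        self.d = n_features
        rng = np.random.default_rng(cfg.train_seed)
        H, D = cfg.lstm_units, cfg.dense_units

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        self.params = {
            "Wx": glorot((self.d, 4 * H)),
            "Wh": glorot((H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wa": glorot((H, H)),
            "W1": glorot((H, D)),
            "b1": np.zeros(D),
            "W2": glorot((D, 2)),
            "b2": np.zeros(2),
        }
        # forget-gate bias starts at 1 (standard stabilizer)
        self.params["b"][H : 2 * H] = 1.0
        self._cache: dict = {}
        self._rms = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._rng = rng

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    @staticmethod
    def _pad(X: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        T = max(len(x) for x in X)
        d = X[0].shape[1]
        out = np.zeros((len(X), T, d))
        mask = np.zeros((len(X), T))
        for i, x in enumerate(X):
            out[i, : len(x)] = x
            mask[i, : len(x)] = 1.0
        return out, mask

    # -- forward -------------------------------------------------------

    def _forward(self, x: np.ndarray, mask: np.ndarray, train: bool) -> np.ndarray:
        H = self.cfg.lstm_units
        p = self.params
        B, T, _ = x.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.zeros((B, T, H))
        cache_t = []
        for t in range(T):
            m = mask[:, t][:, None]
            z = x[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            h_next = m * h_new + (1 - m) * h
            c_next = m * c_new + (1 - m) * c
            cache_t.append((h, c, i, f, g, o, c_new, tc, m))
            h, c = h_next, c_next
            Hs[:, t] = h
        if train and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            drop = (self._rng.random(Hs.shape) < keep) / keep
            Hd = Hs * drop
        else:
            drop = None
            Hd = Hs
        h_last = h  # masked carry makes this the last *valid* hidden state
        u = Hd @ p["Wa"].T  # (B, T, H); score_bt = h_last . u_bt
        s = np.einsum("bh,bth->bt", h_last, u)
        s = np.where(mask > 0, s, -1e30)
        alpha = _softmax(s, axis=1)
        context = np.einsum("bt,bth->bh", alpha, Hd)
        a1_pre = context @ p["W1"] + p["b1"]
        a1 = np.maximum(a1_pre, 0.0)
        logits = a1 @ p["W2"] + p["b2"]
        prob = _softmax(logits, axis=1)
        self._cache = dict(
            x=x, mask=mask, cache_t=cache_t, Hs=Hs, Hd=Hd, drop=drop, h_last=h_last,
            u=u, alpha=alpha, context=context, a1_pre=a1_pre, a1=a1, prob=prob,
        )
        return prob

    # -- backward ------------------------------------------------------

    def _backward(self, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        cfg, p, C = self.cfg, self.params, self._cache
        H = cfg.lstm_units
        B, T, _ = C["x"].shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = (C["prob"] - y_onehot) / B
        grads["W2"] = C["a1"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["W2"].T
        da1_pre = da1 * (C["a1_pre"] > 0)
        grads["W1"] = C["context"].T @ da1_pre + cfg.l1_penalty * np.sign(p["W1"])
        grads["b1"] = da1_pre.sum(axis=0)
        dcontext = da1_pre @ p["W1"].T

        alpha, Hd, u, h_last = C["alpha"], C["Hd"], C["u"], C["h_last"]
        dalpha = np.einsum("bh,bth->bt", dcontext, Hd)
        dHd = alpha[:, :, None] * dcontext[:, None, :]
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        ds = ds * C["mask"]
        dh_last = np.einsum("bt,bth->bh", ds, u)
        du = ds[:, :, None] * h_last[:, None, :]
        grads["Wa"] = np.einsum("bth,btk->hk", du, Hd)
        dHd = dHd + du @ p["Wa"]
        if C["drop"] is not None:
            dHs = dHd * C["drop"]
        else:
            dHs = dHd

        dh_next = dh_last.copy()
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc, m = C["cache_t"][t]
            dh = dHs[:, t] + dh_next
            dc = dc_next
            dh_new = m * dh
            dc_new = m * dc
            dh_prev_carry = (1 - m) * dh
            dc_prev_carry = (1 - m) * dc
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc**2)
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev
            dc_prev = dc_new * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += C["x"][:, t].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh_next = dz @ p["Wh"].T + dh_prev_carry
            dc_next = dc_prev + dc_prev_carry
        return grads

    # -- loss / training -----------------------------------------------

    def _loss(self, prob: np.ndarray, y_onehot: np.ndarray) -> float:
        ce = -np.mean(np.sum(y_onehot * np.log(prob + 1e-12), axis=1))
        return float(ce + self.cfg.l1_penalty * np.abs(self.params["W1"]).sum())

    def fit(self, X: list[np.ndarray], y: np.ndarray) -> "LSTMAttentionClassifier":
        """Train with RMSProp on padded mini-batches; y holds labels in {0, 1}."""
        cfg = self.cfg
        x_all, mask_all = self._pad(X)
        y = np.asarray(y, dtype=int)
        onehot = np.eye(2)[y]
        n = len(X)
        order_rng = np.random.default_rng(cfg.train_seed + 1)
        for _ in range(cfg.epochs):
            order = order_rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                prob = self._forward(x_all[idx], mask_all[idx], train=True)
                grads = self._backward(onehot[idx])
                for k, gk in grads.items():
                    cache = self._rms[k]
                    cache *= cfg.rms_rho
                    cache += (1 - cfg.rms_rho) * gk * gk
                    self.params[k] -= cfg.learning_rate * gk / (np.sqrt(cache) + cfg.rms_eps)
        return self

    def predict_proba(self, X: list[np.ndarray]) -> np.ndarray:
        """Class probabilities; dropout disabled, so repeated calls agree exactly."""
        x, mask = self._pad(X)
        return self._forward(x, mask, train=False)

    def predict(self, X: list[np.ndarray]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
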