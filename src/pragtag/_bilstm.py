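"""Minimal one-layer Bi-LSTM sequence tagger in numpy.

Forward/backward passes are written out by hand (no autograd framework is
assumed at runtime), trained with Adam. The output head is C independent
3-way (O/B/I) token classifiers over the concatenated directional hidden
states; the loss is the sum of per-channel cross-entropies averaged over
unmasked tokens. float64 throughout: determinism and gradient-check
accuracy matter more here than speed.

Gate layout in the fused projections is [input, forget, cell, output].
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class BiLSTMTagger:
    def __init__(self, vocab_size: int, embed_dim: int, hidden_dim: int,
                 n_channels: int, rng: np.random.Generator):
        self.V, self.De, self.H, self.C = vocab_size, embed_dim, hidden_dim, n_channels
        s = 0.08
        def u(*shape):
            return rng.uniform(-s, s, size=shape)
        self.params: dict[str, np.ndarray] = {"E": u(self.V, self.De)}
        for d in ("f", "b"):
            self.params[f"Wx_{d}"] = u(self.De, 4 * self.H)
            self.params[f"Wh_{d}"] = u(self.H, 4 * self.H)
            bias = np.zeros(4 * self.H)
            bias[self.H:2 * self.H] = 1.0  # forget-gate bias
            self.params[f"b_{d}"] = bias
        self.params["Wo"] = u(2 * self.H, self.C * 3)
        self.params["bo"] = np.zeros(self.C * 3)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------

    def _run_direction(self, X: np.ndarray, mask: np.ndarray, d: str,
                       reverse: bool) -> tuple[np.ndarray, list]:
        """Run one LSTM direction; returns hidden states (B,T,H) and cache."""
        B, T, _ = X.shape
        Wx, Wh, b = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"]
        h = np.zeros((B, self.H))
        c = np.zeros((B, self.H))
        Hs = np.zeros((B, T, self.H))
        cache = []
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            m = mask[:, t][:, None]
            z = X[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :self.H])
            f = _sigmoid(z[:, self.H:2 * self.H])
            g = np.tanh(z[:, 2 * self.H:3 * self.H])
            o = _sigmoid(z[:, 3 * self.H:])
            c_raw = f * c + i * g
            tc = np.tanh(c_raw)
            h_raw = o * tc
            c_new = m * c_raw + (1 - m) * c
            h_new = m * h_raw + (1 - m) * h
            cache.append((t, m, h, c, i, f, g, o, c_raw, tc))
            h, c = h_new, c_new
            Hs[:, t] = h
        return Hs, cache

    def forward(self, ids: np.ndarray, mask: np.ndarray):
        X = self.params["E"][ids]                     # (B,T,De)
        Hf, cache_f = self._run_direction(X, mask, "f", reverse=False)
        Hb, cache_b = self._run_direction(X, mask, "b", reverse=True)
        H2 = np.concatenate([Hf, Hb], axis=2)         # (B,T,2H)
        B, T, _ = X.shape
        logits = (H2 @ self.params["Wo"] + self.params["bo"]).reshape(B, T, self.C, 3)
        return logits, (X, H2, cache_f, cache_b)

    def predict_labels(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(ids, mask)
        return logits.argmax(axis=3)                  # (B,T,C)

    # ------------------------------------------------------------------

    def loss_and_grads(self, ids: np.ndarray, mask: np.ndarray, y: np.ndarray):
        """Masked summed-channel cross-entropy and full parameter gradients.

        ids, mask: (B,T); y: (B,T,C) int labels in {0,1,2}.
        """
        logits, (X, H2, cache_f, cache_b) = self.forward(ids, mask)
        B, T = ids.shape
        n_tok = max(mask.sum(), 1.0)
        z = logits - logits.max(axis=3, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=3, keepdims=True)
        onehot = np.eye(3)[y]                          # (B,T,C,3)
        logp = z - np.log(ez.sum(axis=3, keepdims=True))
        loss = -(onehot * logp).sum(axis=(2, 3)) * mask
        loss = loss.sum() / n_tok

        dlogits = (probs - onehot) * mask[:, :, None, None] / n_tok
        dflat = dlogits.reshape(B, T, self.C * 3)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wo"] = np.einsum("btk,btc->kc", H2, dflat)
        grads["bo"] = dflat.sum(axis=(0, 1))
        dH2 = dflat @ self.params["Wo"].T              # (B,T,2H)
        dX = np.zeros_like(X)
        self._backward_direction(dH2[:, :, :self.H], X, dX, cache_f, "f", grads)
        self._backward_direction(dH2[:, :, self.H:], X, dX, cache_b, "b", grads)
        np.add.at(grads["E"], ids, dX)
        return loss, grads

    def _backward_direction(self, dHs: np.ndarray, X: np.ndarray, dX: np.ndarray,
                            cache: list, d: str, grads: dict) -> None:
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        B = X.shape[0]
        dh_next = np.zeros((B, self.H))
        dc_next = np.zeros((B, self.H))
        for (t, m, h_prev, c_prev, i, f, g, o, c_raw, tc) in reversed(cache):
            dh = dHs[:, t] + dh_next
            dc = dc_next
            dh_raw = dh * m
            dc_raw = dc * m + dh_raw * o * (1 - tc ** 2)
            do = dh_raw * tc
            di = dc_raw * g
            df = dc_raw * c_prev
            dg = dc_raw * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            grads[f"Wx_{d}"] += X[:, t].T @ dz
            grads[f"Wh_{d}"] += h_prev.T @ dz
            grads[f"b_{d}"] += dz.sum(axis=0)
            dX[:, t] += dz @ Wx.T
            dh_next = dz @ Wh.T + dh * (1 - m)
            dc_next = dc * (1 - m) + dc_raw * f
        # cache order follows processing order, so reversed() walks back in time
        # for the forward direction and forward in time for the backward one;
        # both are correct because each entry stores its own (h_prev, c_prev).

    # ------------------------------------------------------------------

    def adam_step(self, grads: dict, lr: float, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            g = grads[k]
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
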