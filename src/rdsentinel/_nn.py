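"""NumPy building blocks for the intent model: Adam, padding, LSTM+MLP.

The network mirrors the intent-prediction architecture: an LSTM encodes the
per-query feature sequence into its final hidden state, which is
concatenated with the 38-dim session vector and passed through a 1-hidden-
layer MLP with ReLU into a 3-way softmax.  Forward and backward passes are
written out explicitly (backpropagation through time with a padding mask);
the gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "pad_sequences", "LSTMMLPNet"]


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def pad_sequences(seqs):
    """Right-pad a list of (L_i, F) arrays; returns (B, T, F) data and
    (B, T) float mask with 1 at real steps."""
    if not seqs:
        raise ValueError("no sequences")
    n_feat = seqs[0].shape[1]
    t_max = max(len(s) for s in seqs)
    x = np.zeros((len(seqs), t_max, n_feat))
    mask = np.zeros((len(seqs), t_max))
    for i, s in enumerate(seqs):
        if len(s) == 0:
            raise ValueError("empty query sequence")
        x[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return x, mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMMLPNet:
    """LSTM sequence encoder + session-vector MLP head with 3-way softmax.

    Gate layout in the fused weight matrices is [input, forget, cell,
    output]; the forget-gate bias starts at 1 (standard recipe for
    gradient flow on short sequences).
    """

    def __init__(self, input_dim, vec_dim, hidden_size, mlp_hidden,
                 n_classes=3, seed=0):
        self.input_dim = input_dim
        self.vec_dim = vec_dim
        self.hidden_size = hidden_size
        self.mlp_hidden = mlp_hidden
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        H = hidden_size

        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.params = {
            "Wx": glorot(input_dim, 4 * H),
            "Wh": glorot(H, 4 * H),
            "b": b,
            "W1": glorot(H + vec_dim, mlp_hidden),
            "b1": np.zeros(mlp_hidden),
            "W2": glorot(mlp_hidden, n_classes),
            "b2": np.zeros(n_classes),
        }

    def copy_params(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params):
        for k in self.params:
            self.params[k] = params[k].copy()

    # -- forward -----------------------------------------------------------

    def encode(self, x_seq, mask):
        """Final LSTM hidden state for each padded sequence; also returns
        the step cache needed for backprop."""
        p = self.params
        H = self.hidden_size
        B, T, _ = x_seq.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            x_t = x_seq[:, t, :]
            m = mask[:, t : t + 1]
            z = x_t @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x_t, h, c, i, f, g, o, tanh_c, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        return h, cache

    def forward(self, x_seq, mask, x_vec):
        """Class probabilities; returns (probs, cache) for backprop."""
        h_final, lstm_cache = self.encode(x_seq, mask)
        zcat = np.concatenate([h_final, x_vec], axis=1)
        a1 = zcat @ self.params["W1"] + self.params["b1"]
        r = np.maximum(a1, 0.0)
        logits = r @ self.params["W2"] + self.params["b2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (lstm_cache, zcat, a1, r)

    # -- loss and gradients -------------------------------------------------

    def loss_and_grads(self, x_seq, mask, x_vec, y, class_weights=None):
        """Weighted cross-entropy and its gradients for one (mini)batch."""
        p = self.params
        H = self.hidden_size
        B = len(y)
        probs, (lstm_cache, zcat, a1, r) = self.forward(x_seq, mask, x_vec)
        w = np.ones(B) if class_weights is None else np.asarray(class_weights)[y]
        wsum = w.sum()
        eps = 1e-12
        loss = float(-(w * np.log(probs[np.arange(B), y] + eps)).sum() / wsum)

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (w / wsum)[:, None]

        grads = {
            "W2": r.T @ dlogits,
            "b2": dlogits.sum(0),
        }
        dr = dlogits @ p["W2"].T
        da1 = dr * (a1 > 0)
        grads["W1"] = zcat.T @ da1
        grads["b1"] = da1.sum(0)
        dzcat = da1 @ p["W1"].T
        dh = dzcat[:, :H]
        dc = np.zeros_like(dh)

        g_wx = np.zeros_like(p["Wx"])
        g_wh = np.zeros_like(p["Wh"])
        g_b = np.zeros_like(p["b"])
        for x_t, h_prev, c_prev, i, f, g, o, tanh_c, m in reversed(lstm_cache):
            dh_new = dh * m
            dc_new = dc * m + dh_new * o * (1 - tanh_c**2)
            do = dh_new * tanh_c
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            g_wx += x_t.T @ dz
            g_wh += h_prev.T @ dz
            g_b += dz.sum(0)
            dh = dz @ p["Wh"].T + dh * (1 - m)
            dc = dc_new * f + dc * (1 - m)
        grads["Wx"] = g_wx
        grads["Wh"] = g_wh
        grads["b"] = g_b
        return loss, grads, probs
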