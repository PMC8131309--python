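"""A compact NumPy LSTM encoder-decoder for fragment sequences.

One embedding table is shared by encoder and decoder; each side is a
single LSTM layer, and the decoder projects its hidden state onto the
vocabulary.  Training is teacher-forced cross-entropy with hand-written
backpropagation through time and Adam updates.  Everything is dense
NumPy, sized for corpora of a few hundred fragments on one CPU.

All arrays are float64; gate order within the stacked LSTM weights is
input, forget, cell, output.  The forget-gate bias is initialized to 1.
"""

from __future__ import annotations

import numpy as np

PAD, BOS, EOS = 0, 1, 2


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _log_softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


class Seq2Seq:
    """LSTM encoder-decoder over an integer token alphabet."""

    def __init__(self, vocab_size: int, embed_dim: int = 32, hidden_size: int = 128,
                 init_scale: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        V, D, H = vocab_size, embed_dim, hidden_size
        self.vocab_size, self.embed_dim, self.hidden_size = V, D, H

        def u(*shape):
            return rng.uniform(-init_scale, init_scale, shape)

        self.params = {
            "E": u(V, D),
            "Wx_e": u(D, 4 * H), "Wh_e": u(H, 4 * H), "b_e": np.zeros(4 * H),
            "Wx_d": u(D, 4 * H), "Wh_d": u(H, 4 * H), "b_d": np.zeros(4 * H),
            "Wo": u(H, V), "bo": np.zeros(V),
        }
        self.params["b_e"][H: 2 * H] = 1.0  # forget bias
        self.params["b_d"][H: 2 * H] = 1.0
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- LSTM

    def _step(self, prefix, x, h, c, mask):
        """One masked LSTM step; returns (h, c, cache)."""
        p = self.params
        H = self.hidden_size
        z = x @ p[f"Wx_{prefix}"] + h @ p[f"Wh_{prefix}"] + p[f"b_{prefix}"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H: 2 * H])
        g = np.tanh(z[:, 2 * H: 3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        m = mask[:, None]
        h_out = m * h_new + (1 - m) * h
        c_out = m * c_new + (1 - m) * c
        cache = (x, h, c, i, f, g, o, c_new, m)
        return h_out, c_out, cache

    def _step_back(self, prefix, dh, dc, cache, grads):
        """Backward through one masked LSTM step; returns (dx, dh_prev, dc_prev)."""
        p = self.params
        x, h_prev, c_prev, i, f, g, o, c_new, m = cache
        tc = np.tanh(c_new)
        dh_new = dh * m
        dc_new = dc * m + dh_new * o * (1 - tc ** 2)
        do = dh_new * tc
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
            axis=1,
        )
        grads[f"Wx_{prefix}"] += x.T @ dz
        grads[f"Wh_{prefix}"] += h_prev.T @ dz
        grads[f"b_{prefix}"] += dz.sum(axis=0)
        dx = dz @ p[f"Wx_{prefix}"].T
        dh_prev = dz @ p[f"Wh_{prefix}"].T + dh * (1 - m)
        dc_prev = dc_new * f + dc * (1 - m)
        return dx, dh_prev, dc_prev

    def _encode(self, src):
        """Run the encoder; returns final (h, c) and step caches."""
        B, T = src.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        for t in range(T):
            x = self.params["E"][src[:, t]]
            mask = (src[:, t] != PAD).astype(float)
            h, c, cache = self._step("e", x, h, c, mask)
            caches.append((cache, src[:, t]))
        return h, c, caches

    # ------------------------------------------------------------ training

    def loss_and_grads(self, src, dec_in, dec_tgt):
        """Masked CE loss (mean per target token) and parameter gradients.

        src: (B, Ts) encoder tokens, PAD-right.
        dec_in: (B, Td) decoder inputs (BOS + tokens).
        dec_tgt: (B, Td) decoder targets (tokens + EOS), PAD-right.
        """
        p = self.params
        B, Td = dec_in.shape
        h, c, enc_caches = self._encode(src)

        dec_caches = []
        logps = []
        tgt_mask = (dec_tgt != PAD).astype(float)
        n_tok = tgt_mask.sum()
        loss = 0.0
        for t in range(Td):
            x = p["E"][dec_in[:, t]]
            h, c, cache = self._step("d", x, h, c, np.ones(B))
            logits = h @ p["Wo"] + p["bo"]
            lp = _log_softmax(logits)
            loss -= (lp[np.arange(B), dec_tgt[:, t]] * tgt_mask[:, t]).sum()
            dec_caches.append((cache, dec_in[:, t], lp, h))
            logps.append(lp)
        loss /= n_tok

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh = np.zeros_like(h)
        dc = np.zeros_like(c)
        for t in range(Td - 1, -1, -1):
            cache, ids, lp, h_t = dec_caches[t]
            dlogits = np.exp(lp)
            dlogits[np.arange(B), dec_tgt[:, t]] -= 1.0
            dlogits *= tgt_mask[:, t][:, None] / n_tok
            grads["Wo"] += h_t.T @ dlogits
            grads["bo"] += dlogits.sum(axis=0)
            dh = dh + dlogits @ p["Wo"].T
            dx, dh, dc = self._step_back("d", dh, dc, cache, grads)
            np.add.at(grads["E"], ids, dx)
        for t in range(len(enc_caches) - 1, -1, -1):
            cache, ids = enc_caches[t]
            dx, dh, dc = self._step_back("e", dh, dc, cache, grads)
            np.add.at(grads["E"], ids, dx)
        return loss, grads

    def adam_update(self, grads, lr=5e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                    clip=5.0):
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = min(1.0, clip / (norm + 1e-12))
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g * scale
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g ** 2
            m_hat = self._adam_m[k] / (1 - beta1 ** t)
            v_hat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # ----------------------------------------------------------- inference

    def sequence_log_probs(self, src_ids: list[int], tgt_ids: list[int]) -> np.ndarray:
        """Per-token log-probabilities of ``tgt_ids`` + EOS, teacher-forced."""
        src = np.array([src_ids])
        h, c, _ = self._encode(src)
        inputs = [BOS] + list(tgt_ids)
        targets = list(tgt_ids) + [EOS]
        out = np.empty(len(targets))
        for t, (xin, tgt) in enumerate(zip(inputs, targets)):
            x = self.params["E"][np.array([xin])]
            h, c, _ = self._step("d", x, h, c, np.ones(1))
            lp = _log_softmax(h @ self.params["Wo"] + self.params["bo"])
            out[t] = lp[0, tgt]
        return out

    def sample(self, src_ids: list[int], rng: np.random.Generator,
               max_len: int = 80, temperature: float = 1.0,
               top_k: int = 0) -> tuple[list[int], float]:
        """Sample one output sequence; returns (token ids, log-likelihood).

        The log-likelihood is the sum of the *untempered* per-token
        log-probabilities of the sampled tokens (EOS included).
        """
        src = np.array([src_ids])
        h, c, _ = self._encode(src)
        ids: list[int] = []
        ll = 0.0
        prev = BOS
        for _ in range(max_len):
            x = self.params["E"][np.array([prev])]
            h, c, _ = self._step("d", x, h, c, np.ones(1))
            logits = (h @ self.params["Wo"] + self.params["bo"])[0]
            lp = _log_softmax(logits[None, :])[0]  # true model distribution
            samp = logits / max(temperature, 1e-6)
            samp[PAD] = -np.inf  # structural tokens never sampled
            samp[BOS] = -np.inf
            if top_k and top_k < self.vocab_size:
                kth = np.sort(samp)[-top_k]
                samp = np.where(samp >= kth, samp, -np.inf)
            probs = np.exp(samp - samp.max())
            probs /= probs.sum()
            tok = int(rng.choice(self.vocab_size, p=probs))
            ll += float(lp[tok])
            if tok == EOS:
                return ids, ll
            ids.append(tok)
            prev = tok
        return ids, ll  # ran off max_len without EOS; caller may discard

    # --------------------------------------------------------- persistence

    def state_arrays(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "Seq2Seq":
        V, D = arrays["E"].shape
        H = arrays["Wo"].shape[0]
        model = cls(V, embed_dim=D, hidden_size=H, seed=0)
        for k in model.params:
            model.params[k] = np.asarray(arrays[k], dtype=float)
        return model

    def copy(self) -> "Seq2Seq":
        return Seq2Seq.from_arrays({k: v.copy() for k, v in self.params.items()})
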