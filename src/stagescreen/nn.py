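"""NumPy neural-network engine for the stage-attentive sequence classifier.

Implements exactly the pieces the classifier needs — stacked bidirectional
LSTM layers with one independent parameter set per stage, the avg/max-pool
stage-attention bottleneck, a ReLU classification head, weighted softmax
cross-entropy, reverse-mode gradients for all of it, and Adam — with no
framework dependency.  Analytic gradients are validated against central
finite differences in the test suite.

Conventions
-----------
* All 11 stages are advanced in lock step: time-step tensors have shape
  ``(S, N, ...)`` with ``S`` stages and ``N`` subjects, so each LSTM cell
  update is a single batched ``matmul`` over the stage axis.
* Gate blocks are ordered input, forget, cell, output (i, f, g, o).
* Stage ``s`` has a reference length ``lengths[s] <= T``; its final hidden
  state is captured after consuming exactly ``lengths[s]`` frames (padding
  included — zero-filled frames are fed to the recurrence unmasked, which
  is part of the model definition, not an approximation).  Output frames at
  ``t >= lengths[s]`` do not exist for that stage and are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "sigmoid",
    "softmax",
    "init_params",
    "network_forward",
    "network_backward",
    "weighted_ce_and_grad",
    "Adam",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # exp(-logaddexp(0, -x)) is stable for large |x|
    return np.exp(-np.logaddexp(0.0, -x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# Parameter initialisation
# ---------------------------------------------------------------------------

def init_params(
    n_stages: int,
    input_features: int,
    hidden_size: int,
    num_layers: int,
    reduction_ratio: float,
    head_hidden: int,
    num_classes: int,
    rng: np.random.Generator,
    use_attention: bool = True,
) -> dict[str, np.ndarray]:
    """Seeded uniform fan-in initialisation.

    Recurrent weights use U(-k, k) with k = 1/sqrt(hidden); dense weights
    U(-k, k) with k = 1/sqrt(fan_in); attention-bottleneck and head biases
    start at zero so an all-zero feature maps to the sigmoid midpoint 0.5.

    All 11 per-stage encoders start from the *same* draw (they remain
    independent parameters and diverge during training).  With identical
    starting encoders, differences between stage features — and hence the
    stage-attention ranking — reflect differences in the motion content
    rather than in the initialisation draw, which is what the attention
    interpretability analysis relies on.
    """
    S, H = n_stages, hidden_size
    params: dict[str, np.ndarray] = {}

    def uni(shape, k):
        return rng.uniform(-k, k, size=shape)

    def tiled(shape, k):
        one = rng.uniform(-k, k, size=shape[1:])
        return np.broadcast_to(one, shape).copy()

    k_h = 1.0 / np.sqrt(H)
    for layer in range(num_layers):
        d_in = input_features if layer == 0 else 2 * H
        for d in ("fw", "bw"):
            params[f"lstm.{layer}.{d}.Wx"] = tiled((S, d_in, 4 * H), k_h)
            params[f"lstm.{layer}.{d}.Wh"] = tiled((S, H, 4 * H), k_h)
            params[f"lstm.{layer}.{d}.b"] = tiled((S, 4 * H), k_h)

    if use_attention:
        R = max(1, int(S * reduction_ratio))
        params["attn.W1"] = uni((S, R), 1.0 / np.sqrt(S))
        params["attn.b1"] = np.zeros(R)
        params["attn.W2"] = uni((R, S), 1.0 / np.sqrt(R))
        params["attn.b2"] = np.zeros(S)

    d_flat = S * 2 * H
    params["head.W1"] = uni((d_flat, head_hidden), 1.0 / np.sqrt(d_flat))
    params["head.b1"] = np.zeros(head_hidden)
    params["head.W2"] = uni((head_hidden, num_classes), 1.0 / np.sqrt(head_hidden))
    params["head.b2"] = np.zeros(num_classes)
    return params


# ---------------------------------------------------------------------------
# Single-direction LSTM over all stages at once
# ---------------------------------------------------------------------------

def _lstm_dir_forward(X, Wx, Wh, b, lengths):
    """Run one direction over (S, N, T, D) input.

    Returns outputs Y (S, N, T, H) zeroed beyond each stage's length, the
    captured final hidden state Hcap (S, N, H) taken at t = lengths[s]-1,
    and the cache needed for the backward pass.
    """
    S, N, T, D = X.shape
    H = Wh.shape[1]
    i_s = np.empty((T, S, N, H)); f_s = np.empty((T, S, N, H))
    g_s = np.empty((T, S, N, H)); o_s = np.empty((T, S, N, H))
    c_s = np.empty((T, S, N, H)); tc_s = np.empty((T, S, N, H))
    h_s = np.empty((T, S, N, H))
    h = np.zeros((S, N, H))
    c = np.zeros((S, N, H))
    Hcap = np.zeros((S, N, H))
    cap_t = lengths - 1  # (S,)
    for t in range(T):
        z = X[:, :, t, :] @ Wx + h @ Wh + b[:, None, :]
        i = sigmoid(z[..., :H])
        f = sigmoid(z[..., H : 2 * H])
        g = np.tanh(z[..., 2 * H : 3 * H])
        o = sigmoid(z[..., 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        i_s[t], f_s[t], g_s[t], o_s[t] = i, f, g, o
        c_s[t], tc_s[t], h_s[t] = c, tc, h
        sel = cap_t == t
        if sel.any():
            Hcap[sel] = h[sel]
    tmask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)  # (S, T)
    Y = np.moveaxis(h_s, 0, 2) * tmask[:, None, :, None]
    cache = (X, Wx, Wh, lengths, i_s, f_s, g_s, o_s, c_s, tc_s, h_s, tmask)
    return Y, Hcap, cache


def _lstm_dir_backward(dY, dHcap, cache):
    """Backprop one direction; dY may be None (no per-step output grad)."""
    X, Wx, Wh, lengths, i_s, f_s, g_s, o_s, c_s, tc_s, h_s, tmask = cache
    S, N, T, D = X.shape
    H = Wh.shape[1]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros((S, 4 * H))
    dX = np.empty_like(X)
    dh_next = np.zeros((S, N, H))
    dc_next = np.zeros((S, N, H))
    cap_t = lengths - 1
    for t in range(T - 1, -1, -1):
        dh = dh_next.copy()
        if dY is not None:
            dh += dY[:, :, t, :] * tmask[:, None, t, None]
        if dHcap is not None:
            sel = cap_t == t
            if sel.any():
                dh[sel] += dHcap[sel]
        i, f, g, o = i_s[t], f_s[t], g_s[t], o_s[t]
        tc = tc_s[t]
        c_prev = c_s[t - 1] if t > 0 else np.zeros((S, N, H))
        h_prev = h_s[t - 1] if t > 0 else np.zeros((S, N, H))
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=-1,
        )
        dX[:, :, t, :] = dz @ Wx.transpose(0, 2, 1)
        dh_next = dz @ Wh.transpose(0, 2, 1)
        x_t = X[:, :, t, :]
        dWx += x_t.transpose(0, 2, 1) @ dz
        dWh += h_prev.transpose(0, 2, 1) @ dz
        db += dz.sum(axis=1)
    return dX, dWx, dWh, db


def _reverse_within_length(X, lengths):
    """Reverse the first lengths[s] time steps of each stage; rest stays 0."""
    out = np.zeros_like(X)
    for s, L in enumerate(lengths):
        out[s, :, :L] = X[s, :, L - 1 :: -1]
    return out


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

def network_forward(params, X, lengths, num_layers, hidden_size, use_attention):
    """Forward pass: stacked BiLSTM -> stage features -> attention -> head.

    Parameters
    ----------
    X : (S, N, T, D) zero-padded per-stage inputs, all stages stacked.
    lengths : (S,) per-stage reference lengths (same for every subject in a
        padded batch).

    Returns (logits, scores, F, cache) where scores is the (N, S) matrix of
    sigmoid stage-attention scores (all ones when attention is disabled) and
    F the (N, S, 2H) pre-attention stage features.
    """
    S, N, T, _ = X.shape
    H = hidden_size
    layer_caches = []
    inp = X
    Hf = Hb = None
    for layer in range(num_layers):
        Wxf = params[f"lstm.{layer}.fw.Wx"]
        Whf = params[f"lstm.{layer}.fw.Wh"]
        bf = params[f"lstm.{layer}.fw.b"]
        Wxb = params[f"lstm.{layer}.bw.Wx"]
        Whb = params[f"lstm.{layer}.bw.Wh"]
        bb = params[f"lstm.{layer}.bw.b"]
        Yf, Hf, cache_f = _lstm_dir_forward(inp, Wxf, Whf, bf, lengths)
        Xrev = _reverse_within_length(inp, lengths)
        Yb_rev, Hb, cache_b = _lstm_dir_forward(Xrev, Wxb, Whb, bb, lengths)
        Yb = _reverse_within_length(Yb_rev, lengths)
        layer_caches.append((cache_f, cache_b))
        inp = np.concatenate([Yf, Yb], axis=-1)

    # Stage features: [forward final hidden || backward final hidden] of the
    # top layer, rearranged subject-major.
    F = np.concatenate([Hf, Hb], axis=-1).transpose(1, 0, 2)  # (N, S, 2H)

    if use_attention:
        avg = F.mean(axis=2)                      # (N, S)
        mx = F.max(axis=2)                        # (N, S)
        amax = F.argmax(axis=2)                   # (N, S)
        W1, b1 = params["attn.W1"], params["attn.b1"]
        W2, b2 = params["attn.W2"], params["attn.b2"]
        ha_pre = avg @ W1 + b1
        hm_pre = mx @ W1 + b1
        ha = relu(ha_pre)
        hm = relu(hm_pre)
        pre = ha @ W2 + hm @ W2 + 2.0 * b2        # shared MLP on both branches
        scores = sigmoid(pre)                     # (N, S), strictly in (0,1)
        G = F * scores[:, :, None]
        attn_cache = (avg, mx, amax, ha_pre, hm_pre, ha, hm, scores)
    else:
        scores = np.ones((N, S))
        G = F
        attn_cache = None

    flat = G.reshape(N, -1)
    hW1, hb1 = params["head.W1"], params["head.b1"]
    hW2, hb2 = params["head.W2"], params["head.b2"]
    a1 = flat @ hW1 + hb1
    r1 = relu(a1)
    logits = r1 @ hW2 + hb2
    cache = (X, lengths, layer_caches, F, attn_cache, flat, a1, r1)
    return logits, scores, F, cache


def network_backward(params, cache, dlogits, num_layers, hidden_size, use_attention):
    """Reverse-mode gradients of a scalar loss w.r.t. every parameter."""
    X, lengths, layer_caches, F, attn_cache, flat, a1, r1 = cache
    N, S, twoH = F.shape
    grads: dict[str, np.ndarray] = {}

    # Head
    grads["head.W2"] = r1.T @ dlogits
    grads["head.b2"] = dlogits.sum(axis=0)
    dr1 = dlogits @ params["head.W2"].T
    da1 = dr1 * (a1 > 0.0)
    grads["head.W1"] = flat.T @ da1
    grads["head.b1"] = da1.sum(axis=0)
    dflat = da1 @ params["head.W1"].T
    dG = dflat.reshape(N, S, twoH)

    # Attention block
    if use_attention:
        avg, mx, amax, ha_pre, hm_pre, ha, hm, scores = attn_cache
        dF = dG * scores[:, :, None]
        dscores = (dG * F).sum(axis=2)
        dpre = dscores * scores * (1.0 - scores)
        W1, W2 = params["attn.W1"], params["attn.W2"]
        grads["attn.W2"] = ha.T @ dpre + hm.T @ dpre
        grads["attn.b2"] = 2.0 * dpre.sum(axis=0)
        dha = (dpre @ W2.T) * (ha_pre > 0.0)
        dhm = (dpre @ W2.T) * (hm_pre > 0.0)
        grads["attn.W1"] = avg.T @ dha + mx.T @ dhm
        grads["attn.b1"] = dha.sum(axis=0) + dhm.sum(axis=0)
        davg = dha @ W1.T
        dmx = dhm @ W1.T
        dF += davg[:, :, None] / twoH
        np.put_along_axis(
            dF,
            amax[:, :, None],
            np.take_along_axis(dF, amax[:, :, None], axis=2) + dmx[:, :, None],
            axis=2,
        )
    else:
        dF = dG

    # Split into final-hidden gradients of the top layer's two directions.
    H = hidden_size
    dF_sn = dF.transpose(1, 0, 2)  # (S, N, 2H)
    dHf = np.ascontiguousarray(dF_sn[..., :H])
    dHb = np.ascontiguousarray(dF_sn[..., H:])

    dY = None
    for layer in range(num_layers - 1, -1, -1):
        cache_f, cache_b = layer_caches[layer]
        if dY is None:
            dYf = dYb = None
        else:
            dYf = np.ascontiguousarray(dY[..., :H])
            dYb = np.ascontiguousarray(dY[..., H:])
        dXf, dWxf, dWhf, dbf = _lstm_dir_backward(dYf, dHf, cache_f)
        dYb_rev = (
            None if dYb is None else _reverse_within_length(dYb, lengths)
        )
        dXrev, dWxb, dWhb, dbb = _lstm_dir_backward(dYb_rev, dHb, cache_b)
        dXb = _reverse_within_length(dXrev, lengths)
        grads[f"lstm.{layer}.fw.Wx"] = dWxf
        grads[f"lstm.{layer}.fw.Wh"] = dWhf
        grads[f"lstm.{layer}.fw.b"] = dbf
        grads[f"lstm.{layer}.bw.Wx"] = dWxb
        grads[f"lstm.{layer}.bw.Wh"] = dWhb
        grads[f"lstm.{layer}.bw.b"] = dbb
        dY = dXf + dXb
        dHf = dHb = None  # final-hidden grads only enter at the top layer
    return grads


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def weighted_ce_and_grad(
    logits: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray,
    eps: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Mean inverse-frequency-weighted cross-entropy and its logit gradient.

    Per sample: ``-w[y] * log softmax(logits)[y]``; the batch loss is the
    mean over samples.
    """
    N = logits.shape[0]
    p = softmax(logits)
    w = class_weights[y]
    loss = float(np.mean(-w * np.log(np.clip(p[np.arange(N), y], eps, None))))
    dlogits = p.copy()
    dlogits[np.arange(N), y] -= 1.0
    dlogits *= w[:, None] / N
    return loss, dlogits


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction.

    ``lr_multipliers`` maps parameter-name prefixes to per-group factors on
    the base learning rate (e.g. a larger step for the shallow head than
    for the deep recurrent encoders); unmatched parameters use factor 1.
    ``weight_decay`` maps prefixes to decoupled (AdamW-style) decay rates,
    applied as ``p -= lr_group * decay * p`` each step.
    """

    def __init__(
        self,
        params,
        lr=1e-3,
        beta1=0.9,
        beta2=0.999,
        eps=1e-8,
        lr_multipliers: dict[str, float] | None = None,
        weight_decay: dict[str, float] | None = None,
    ):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        multipliers = lr_multipliers or {}
        decays = weight_decay or {}
        self.factor = {}
        self.decay = {}
        for k in params:
            f = 1.0
            for prefix, mult in multipliers.items():
                if k.startswith(prefix):
                    f = mult
                    break
            self.factor[k] = f
            d = 0.0
            for prefix, rate in decays.items():
                if k.startswith(prefix):
                    d = rate
                    break
            self.decay[k] = d

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            lr = self.lr * self.factor[k]
            params[k] -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.decay[k]:
                params[k] -= lr * self.decay[k] * params[k]
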