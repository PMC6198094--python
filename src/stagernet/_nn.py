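"""Minimal numpy neural-network primitives for the CONV/recurrent stager.

Implements exactly what the stager needs — valid-mode 1-D convolution,
max-pooling, ReLU/leaky-ReLU, LSTM and GRU layers with full
backpropagation-through-time, variational (per-sequence mask) dropout, and
Adam — in plain float64 numpy.  Everything is deterministic given the
arrays passed in; random masks are drawn by the caller.

Array conventions:
  conv inputs   (N, T, C)    N windows, T samples, C channels
  conv kernels  (F, K, C)    F filters of width K
  recurrent     (B, T, D)    B sequences, T time steps, D features
  Wx (D, G*U), Wh (U, G*U), b (G*U,)  with G = 4 (LSTM: i,f,g,o)
                                      or G = 3 (GRU: z,r,n)
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Convolution / pooling / activations
# ---------------------------------------------------------------------------


def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid-mode stride-1 convolution (cross-correlation); (N,T,C)->(N,T-K+1,F)."""
    F, K, C = W.shape
    To = x.shape[1] - K + 1
    if To < 1:
        raise ValueError(f"input length {x.shape[1]} shorter than kernel {K}")
    y = np.zeros((x.shape[0], To, F))
    for k in range(K):  # K is small (8); avoids an im2col copy of x
        y += x[:, k : k + To, :] @ W[:, k, :].T
    return y + b


def conv1d_backward(x, W, dY):
    F, K, C = W.shape
    To = dY.shape[1]
    dW = np.empty_like(W)
    for k in range(K):
        dW[:, k, :] = np.einsum("ntf,ntc->fc", dY, x[:, k : k + To, :])
    db = dY.sum(axis=(0, 1))
    dx = np.zeros_like(x)
    for k in range(K):
        dx[:, k : k + To, :] += dY @ W[:, k, :]
    return dx, dW, db


def maxpool_forward(x: np.ndarray, p: int):
    """Floor-mode max pooling over time; drops the remainder."""
    N, T, F = x.shape
    To = T // p
    xr = x[:, : To * p, :].reshape(N, To, p, F)
    idx = xr.argmax(axis=2)
    y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return y, idx


def maxpool_backward(x_shape, p: int, idx: np.ndarray, dY: np.ndarray):
    N, T, F = x_shape
    To = idx.shape[1]
    dxr = np.zeros((N, To, p, F))
    np.put_along_axis(dxr, idx[:, :, None, :], dY[:, :, None, :], axis=2)
    dx = np.zeros(x_shape)
    dx[:, : To * p, :] = dxr.reshape(N, To * p, F)
    return dx


def act_forward(x: np.ndarray, kind: str, slope: float = 0.01) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "leaky_relu":
        return np.where(x > 0.0, x, slope * x)
    raise ValueError(f"unknown activation {kind!r}")


def act_backward(x: np.ndarray, dY: np.ndarray, kind: str, slope: float = 0.01):
    if kind == "relu":
        return dY * (x > 0.0)
    if kind == "leaky_relu":
        return dY * np.where(x > 0.0, 1.0, slope)
    raise ValueError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------


def lstm_forward(X, Wx, Wh, b, h0, c0, mask_x=None, mask_h=None):
    """Run an LSTM over (B,T,D); returns H (B,T,U) and the BPTT cache.

    ``mask_x``/``mask_h`` are variational dropout masks of shape (B,D) and
    (B,U), applied identically at every time step (already inverted-scaled).
    """
    B, T, D = X.shape
    U = Wh.shape[0]
    Xm = X * mask_x[:, None, :] if mask_x is not None else X
    XW = Xm.reshape(B * T, D) @ Wx
    XW = XW.reshape(B, T, 4 * U)
    H = np.empty((B, T, U))
    gates = np.empty((B, T, 4 * U))  # post-nonlinearity i,f,g,o
    Cs = np.empty((B, T, U))
    tanhC = np.empty((B, T, U))
    h, c = h0, c0
    for t in range(T):
        hm = h * mask_h if mask_h is not None else h
        z = XW[:, t, :] + hm @ Wh + b
        i = sigmoid(z[:, :U])
        f = sigmoid(z[:, U : 2 * U])
        g = np.tanh(z[:, 2 * U : 3 * U])
        o = sigmoid(z[:, 3 * U :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[:, t, :U], gates[:, t, U : 2 * U] = i, f
        gates[:, t, 2 * U : 3 * U], gates[:, t, 3 * U :] = g, o
        Cs[:, t, :] = c
        tanhC[:, t, :] = tc
        H[:, t, :] = h
    cache = (X, Xm, gates, Cs, tanhC, H, h0, c0, mask_x, mask_h)
    return H, (h, c), cache


def lstm_backward(dH, Wx, Wh, cache):
    X, Xm, gates, Cs, tanhC, H, h0, c0, mask_x, mask_h = cache
    B, T, D = X.shape
    U = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * U)
    dXm = np.empty_like(Xm)
    dh_next = np.zeros((B, U))
    dc_next = np.zeros((B, U))
    dZ = np.empty((B, T, 4 * U))
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :U]
        f = gates[:, t, U : 2 * U]
        g = gates[:, t, 2 * U : 3 * U]
        o = gates[:, t, 3 * U :]
        c_prev = Cs[:, t - 1, :] if t > 0 else c0
        dh = dH[:, t, :] + dh_next
        do = dh * tanhC[:, t, :]
        dc = dc_next + dh * o * (1.0 - tanhC[:, t, :] ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = dZ[:, t, :]
        dz[:, :U] = di * i * (1.0 - i)
        dz[:, U : 2 * U] = df * f * (1.0 - f)
        dz[:, 2 * U : 3 * U] = dg * (1.0 - g**2)
        dz[:, 3 * U :] = do * o * (1.0 - o)
        h_prev = H[:, t - 1, :] if t > 0 else h0
        hm = h_prev * mask_h if mask_h is not None else h_prev
        dWh += hm.T @ dz
        dh_next = dz @ Wh.T
        if mask_h is not None:
            dh_next = dh_next * mask_h
    dZ2 = dZ.reshape(B * T, 4 * U)
    dWx += Xm.reshape(B * T, D).T @ dZ2
    db += dZ2.sum(axis=0)
    dXm = (dZ2 @ Wx.T).reshape(B, T, D)
    dX = dXm * mask_x[:, None, :] if mask_x is not None else dXm
    return dX, dWx, dWh, db


def lstm_step(x, h, c, Wx, Wh, b):
    """Single LSTM step for streaming inference (no dropout)."""
    U = Wh.shape[0]
    z = x @ Wx + h @ Wh + b
    i = sigmoid(z[..., :U])
    f = sigmoid(z[..., U : 2 * U])
    g = np.tanh(z[..., 2 * U : 3 * U])
    o = sigmoid(z[..., 3 * U :])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new


# ---------------------------------------------------------------------------
# GRU
# ---------------------------------------------------------------------------


def gru_forward(X, Wx, Wh, b, h0, mask_x=None, mask_h=None):
    """GRU with reset-before-matmul candidate: h = z*h_prev + (1-z)*n."""
    B, T, D = X.shape
    U = Wh.shape[0]
    Xm = X * mask_x[:, None, :] if mask_x is not None else X
    XW = (Xm.reshape(B * T, D) @ Wx).reshape(B, T, 3 * U)
    H = np.empty((B, T, U))
    gates = np.empty((B, T, 3 * U))  # z, r, n (post-nonlinearity)
    Hm_prev = np.empty((B, T, U))  # masked h_{t-1} entering the matmuls
    h = h0
    for t in range(T):
        hm = h * mask_h if mask_h is not None else h
        Hm_prev[:, t, :] = hm
        az = XW[:, t, :U] + hm @ Wh[:, :U] + b[:U]
        ar = XW[:, t, U : 2 * U] + hm @ Wh[:, U : 2 * U] + b[U : 2 * U]
        z = sigmoid(az)
        r = sigmoid(ar)
        an = XW[:, t, 2 * U :] + (r * (hm @ Wh[:, 2 * U :])) + b[2 * U :]
        n = np.tanh(an)
        h = z * h + (1.0 - z) * n
        gates[:, t, :U], gates[:, t, U : 2 * U], gates[:, t, 2 * U :] = z, r, n
        H[:, t, :] = h
    cache = (X, Xm, gates, Hm_prev, H, h0, mask_x, mask_h, Wh)
    return H, h, cache


def gru_backward(dH, Wx, Wh, cache):
    X, Xm, gates, Hm_prev, H, h0, mask_x, mask_h, _ = cache
    B, T, D = X.shape
    U = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(3 * U)
    dA = np.empty((B, T, 3 * U))
    dh_next = np.zeros((B, U))
    for t in range(T - 1, -1, -1):
        z = gates[:, t, :U]
        r = gates[:, t, U : 2 * U]
        n = gates[:, t, 2 * U :]
        h_prev = H[:, t - 1, :] if t > 0 else h0
        hm = Hm_prev[:, t, :]
        hWhn = hm @ Wh[:, 2 * U :]
        dh = dH[:, t, :] + dh_next
        dz = dh * (h_prev - n)
        dn = dh * (1.0 - z)
        dh_prev = dh * z
        dan = dn * (1.0 - n**2)
        daz = dz * z * (1.0 - z)
        dhWhn = dan * r
        dr = dan * hWhn
        dar = dr * r * (1.0 - r)
        dA[:, t, :U] = daz
        dA[:, t, U : 2 * U] = dar
        dA[:, t, 2 * U :] = dan
        dWh[:, :U] += hm.T @ daz
        dWh[:, U : 2 * U] += hm.T @ dar
        dWh[:, 2 * U :] += hm.T @ dhWhn
        dhm = daz @ Wh[:, :U].T + dar @ Wh[:, U : 2 * U].T + dhWhn @ Wh[:, 2 * U :].T
        if mask_h is not None:
            dhm = dhm * mask_h
        dh_next = dh_prev + dhm
    dA2 = dA.reshape(B * T, 3 * U)
    dWx += Xm.reshape(B * T, D).T @ dA2
    db += dA2.sum(axis=0)
    dXm = (dA2 @ Wx.T).reshape(B, T, D)
    dX = dXm * mask_x[:, None, :] if mask_x is not None else dXm
    return dX, dWx, dWh, db


def gru_step(x, h, Wx, Wh, b):
    U = Wh.shape[0]
    xz = x @ Wx
    az = xz[..., :U] + h @ Wh[:, :U] + b[:U]
    ar = xz[..., U : 2 * U] + h @ Wh[:, U : 2 * U] + b[U : 2 * U]
    z = sigmoid(az)
    r = sigmoid(ar)
    an = xz[..., 2 * U :] + r * (h @ Wh[:, 2 * U :]) + b[2 * U :]
    n = np.tanh(an)
    return z * h + (1.0 - z) * n


# ---------------------------------------------------------------------------
# Softmax / loss / optimizer
# ---------------------------------------------------------------------------


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_cross_entropy(probs, labels, mask):
    """Mean negative log-likelihood over masked positions.

    ``probs`` (B,T,K), ``labels`` (B,T) int, ``mask`` (B,T) weights in
    {0,1}.  Returns (loss, dlogits-style gradient w.r.t. pre-softmax
    values) -- the gradient is (p - onehot) * mask / mask.sum(), the usual
    softmax+CE shortcut.  If the mask is all-zero the loss and gradient
    are exactly zero.
    """
    B, T, K = probs.shape
    total = mask.sum()
    if total == 0:
        return 0.0, np.zeros_like(probs)
    safe_labels = np.where(mask > 0, labels, 0)
    p_true = np.take_along_axis(probs, safe_labels[:, :, None], axis=2)[:, :, 0]
    loss = -np.sum(mask * np.log(np.maximum(p_true, 1e-300))) / total
    grad = probs.copy()
    np.put_along_axis(
        grad,
        safe_labels[:, :, None],
        np.take_along_axis(grad, safe_labels[:, :, None], axis=2) - 1.0,
        axis=2,
    )
    grad *= (mask / total)[:, :, None]
    return float(loss), grad


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8, decay=0.0):
        self.lr, self.beta1, self.beta2, self.eps, self.decay = lr, beta1, beta2, eps, decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        lr = self.lr / (1.0 + self.decay * (self.t - 1))
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            params[k] -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
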