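"""Minimal neural-net core: GRU forward/backward kernels, Adam, helpers.

A single-layer GRU in the standard formulation (gate order z | r | n):

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)          update gate
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)          reset gate
    n_t = tanh(x_t Wn + r_t * (h_{t-1} Un) + bn)     candidate state
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

Variable-length batches use a packed, time-major layout: sequences are sorted
by length (descending), each time step stores only its still-active prefix of
rows, and per-step recurrences touch contiguous blocks, so padding costs
nothing and every sequence's final state is taken at its own last step. The
backward pass is backpropagation through time with hand-derived gate
gradients, verified against finite differences in the test suite. The
recurrent loops are numba-compiled and dtype-generic: model training runs in
float32, while float64 inputs take a float64 path for high-precision oracle
checks.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

F4 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_gru_params(
    input_dim: int, hidden_dim: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) initialization for W (I,3H), U (H,3H), b (3H,)."""
    bound = 1.0 / np.sqrt(hidden_dim)
    return {
        "W": rng.uniform(-bound, bound, size=(input_dim, 3 * hidden_dim)).astype(F4),
        "U": rng.uniform(-bound, bound, size=(hidden_dim, 3 * hidden_dim)).astype(F4),
        "b": rng.uniform(-bound, bound, size=(3 * hidden_dim,)).astype(F4),
    }


@njit(cache=True)
def _gru_fwd_kernel(Xwp, U, n_active, off):  # pragma: no cover - jitted
    S = Xwp.shape[0]
    H = U.shape[0]
    T = n_active.shape[0]
    B = n_active[0]
    h_p = np.empty((S, H), dtype=Xwp.dtype)
    Z = np.empty((S, H), dtype=Xwp.dtype)
    R = np.empty((S, H), dtype=Xwp.dtype)
    N = np.empty((S, H), dtype=Xwp.dtype)
    HUn = np.empty((S, H), dtype=Xwp.dtype)
    h = np.zeros((B, H), dtype=Xwp.dtype)
    for t in range(T):
        nt = n_active[t]
        if nt == 0:
            break
        o = off[t]
        hU = np.dot(h[:nt], U)
        for i in range(nt):
            p = o + i
            for j in range(H):
                z = 1.0 / (1.0 + math.exp(-float(Xwp[p, j] + hU[i, j])))
                r = 1.0 / (1.0 + math.exp(-float(Xwp[p, H + j] + hU[i, H + j])))
                hun = float(hU[i, 2 * H + j])
                cn = math.tanh(float(Xwp[p, 2 * H + j]) + r * hun)
                hn = (1.0 - z) * cn + z * float(h[i, j])
                Z[p, j] = z
                R[p, j] = r
                N[p, j] = cn
                HUn[p, j] = hun
                h[i, j] = hn
                h_p[p, j] = hn
    return h_p, Z, R, N, HUn


@njit(cache=True)
def _gru_bwd_kernel(dh_inject, h_p, Z, R, N, HUn, U_t, n_active, off):  # pragma: no cover
    S, H = Z.shape
    T = n_active.shape[0]
    B = n_active[0]
    dh = np.zeros((B, H), dtype=Z.dtype)
    dpre = np.zeros((S, 3 * H), dtype=Z.dtype)
    dhU = np.zeros((S, 3 * H), dtype=Z.dtype)
    hprev = np.zeros((S, H), dtype=Z.dtype)
    dg = np.zeros((B, 3 * H), dtype=Z.dtype)
    for t in range(T - 1, -1, -1):
        nt = n_active[t]
        if nt == 0:
            continue
        o = off[t]
        op = off[t - 1] if t > 0 else 0
        for i in range(nt):
            p = o + i
            for j in range(H):
                d = float(dh[i, j] + dh_inject[p, j])
                z = float(Z[p, j])
                r = float(R[p, j])
                cn = float(N[p, j])
                hun = float(HUn[p, j])
                hp = float(h_p[op + i, j]) if t > 0 else 0.0
                dz = d * (hp - cn) * z * (1.0 - z)
                dn = d * (1.0 - z) * (1.0 - cn * cn)
                dr = dn * hun * r * (1.0 - r)
                dg[i, j] = dz
                dg[i, H + j] = dr
                dg[i, 2 * H + j] = dn * r
                dpre[p, j] = dz
                dpre[p, H + j] = dr
                dpre[p, 2 * H + j] = dn
                hprev[p, j] = hp
                dh[i, j] = d * z
        tmp = np.dot(dg[:nt], U_t)
        for i in range(nt):
            p = o + i
            for j in range(H):
                dh[i, j] += tmp[i, j]
            for g in range(3 * H):
                dhU[p, g] = dg[i, g]
    return dpre, dhU, hprev


class GRUForwardCache:
    """Packed activations and index maps needed by the backward pass."""

    __slots__ = (
        "Xp", "perm", "inv", "lengths_sorted", "n_active", "off", "final_pos",
        "h_p", "Z", "R", "N", "HUn", "T",
    )

    def __init__(self, Xp, perm, inv, lengths_sorted, n_active, off, final_pos, h_p, Z, R, N, HUn, T):
        self.Xp = Xp
        self.perm = perm
        self.inv = inv
        self.lengths_sorted = lengths_sorted
        self.n_active = n_active
        self.off = off
        self.final_pos = final_pos
        self.h_p, self.Z, self.R, self.N, self.HUn = h_p, Z, R, N, HUn
        self.T = T

    def pack(self, dense: np.ndarray) -> np.ndarray:
        """Scatter a (B, T, K) array (caller's row order) into packed layout."""
        B, T, K = dense.shape
        ds = dense[self.perm]
        out = np.empty((self.off[-1], K), dtype=dense.dtype)
        for t in range(T):
            nt = self.n_active[t]
            if nt == 0:
                break
            out[self.off[t] : self.off[t] + nt] = ds[:nt, t]
        return out

    def unpack(self, packed: np.ndarray) -> np.ndarray:
        """Gather a packed (S, K) array back to (B, T, K) in the caller's order."""
        B = self.n_active[0]
        K = packed.shape[1]
        dense = np.zeros((B, self.T, K), dtype=packed.dtype)
        for t in range(self.T):
            nt = self.n_active[t]
            if nt == 0:
                break
            dense[:nt, t] = packed[self.off[t] : self.off[t] + nt]
        return dense[self.inv]


def gru_forward(
    X: np.ndarray,
    lengths: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    b: np.ndarray,
    return_sequence: bool = False,
):
    """Run the GRU over a (possibly padded) batch.

    X: (B, T, I); lengths: (B,) ints in [1, T]. Returns
    ``(h_seq, h_final, cache)`` in the caller's row order, where
    ``h_final[i]`` is sequence i's state at its own last step and ``h_seq``
    (only built when ``return_sequence``) holds the per-step states with
    zeros past each sequence's end. Computation dtype follows X/W.
    """
    X = np.asarray(X)
    lengths = np.asarray(lengths, dtype=np.int64)
    B, T, _ = X.shape
    perm = np.argsort(-lengths, kind="stable")
    inv = np.empty_like(perm)
    inv[perm] = np.arange(B)
    ls = lengths[perm]
    n_active = (B - np.searchsorted(ls[::-1], np.arange(T), side="right")).astype(np.int64)
    off = np.zeros(T + 1, dtype=np.int64)
    np.cumsum(n_active, out=off[1:])
    final_pos = off[ls - 1] + np.arange(B)
    Xs = np.ascontiguousarray(X[perm])
    Xp = np.empty((off[-1], X.shape[2]), dtype=X.dtype)
    for t in range(T):
        nt = n_active[t]
        if nt == 0:
            break
        Xp[off[t] : off[t] + nt] = Xs[:nt, t]
    Xwp = np.ascontiguousarray(Xp @ W + b)
    h_p, Z, R, N, HUn = _gru_fwd_kernel(Xwp, np.ascontiguousarray(U), n_active, off)
    cache = GRUForwardCache(Xp, perm, inv, ls, n_active, off, final_pos, h_p, Z, R, N, HUn, T)
    h_final = h_p[final_pos][inv]
    h_seq = cache.unpack(h_p) if return_sequence else None
    return h_seq, h_final, cache


def _bwd_common(dh_p: np.ndarray, cache: GRUForwardCache, U: np.ndarray):
    U_t = np.ascontiguousarray(U.T)
    dpre, dhU, hprev = _gru_bwd_kernel(
        dh_p, cache.h_p, cache.Z, cache.R, cache.N, cache.HUn, U_t, cache.n_active, cache.off
    )
    dW = cache.Xp.T @ dpre
    dU = hprev.T @ dhU
    db = dpre.sum(axis=0)
    dt = cache.Xp.dtype
    return dW.astype(dt), dU.astype(dt), db.astype(dt)


def gru_backward(dh_seq: np.ndarray, cache: GRUForwardCache, U: np.ndarray):
    """BPTT given gradients on h_seq (caller's row order; padded entries ignored).

    Returns (dW, dU, db).
    """
    return _bwd_common(cache.pack(np.asarray(dh_seq)), cache, U)


def gru_backward_final(dh_final: np.ndarray, cache: GRUForwardCache, U: np.ndarray):
    """BPTT when only each sequence's final state receives gradient."""
    dh_p = np.zeros_like(cache.h_p)
    dh_p[cache.final_pos] = dh_final[cache.perm]
    return _bwd_common(dh_p, cache, U)


class Adam:
    """Adam with coupled L2 weight decay (decay added to the gradient)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        weight_decay: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], skip: set[str] | None = None) -> None:
        skip = skip or set()
        if self.clip_norm is not None:
            total = math.sqrt(
                sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values())
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: (g * scale).astype(g.dtype) for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if k in skip:
                continue
            g = grads[k] + np.asarray(self.weight_decay, dtype=p.dtype) * p
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def bce_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy from logits (numerically stable)."""
    z = logits.astype(np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
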