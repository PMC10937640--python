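"""Numba-compiled direct 3D convolution kernels (channels-first, float32).

Written for a single CPU core on memory-bandwidth-limited machines: the
innermost loops run contiguously along the last spatial axis so LLVM can
vectorize them, weights stay in L1, and no im2col buffer is materialized.
The forward/input-gradient kernel blocks output channels by 8 to reuse
each input row across several accumulators.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def _conv3d_fwd_generic(xp, wk, out):
    N, Co, D, H, W = out.shape
    Ci = xp.shape[1]
    K = wk.shape[2]
    row = np.empty(W, dtype=np.float32)
    for n in range(N):
        for co in range(Co):
            for d in range(D):
                for h in range(H):
                    for w in range(W):
                        row[w] = 0.0
                    for ci in range(Ci):
                        for dd in range(K):
                            for dh in range(K):
                                for dw in range(K):
                                    wt = wk[co, ci, dd, dh, dw]
                                    for w in range(W):
                                        row[w] += wt * xp[n, ci, d + dd, h + dh, w + dw]
                    for w in range(W):
                        out[n, co, d, h, w] = row[w]


@njit(fastmath=True, cache=True)
def _conv3d_fwd_cb8(xp, wk, out):
    """Forward conv with output channels processed 8 at a time."""
    N, Co, D, H, W = out.shape
    Ci = xp.shape[1]
    K = wk.shape[2]
    rows = np.empty((8, W), dtype=np.float32)
    for n in range(N):
        for co in range(0, Co, 8):
            for d in range(D):
                for h in range(H):
                    rows[:] = 0.0
                    for ci in range(Ci):
                        for dd in range(K):
                            for dh in range(K):
                                for dw in range(K):
                                    w0 = wk[co, ci, dd, dh, dw]
                                    w1 = wk[co + 1, ci, dd, dh, dw]
                                    w2 = wk[co + 2, ci, dd, dh, dw]
                                    w3 = wk[co + 3, ci, dd, dh, dw]
                                    w4 = wk[co + 4, ci, dd, dh, dw]
                                    w5 = wk[co + 5, ci, dd, dh, dw]
                                    w6 = wk[co + 6, ci, dd, dh, dw]
                                    w7 = wk[co + 7, ci, dd, dh, dw]
                                    for w in range(W):
                                        xv = xp[n, ci, d + dd, h + dh, w + dw]
                                        rows[0, w] += w0 * xv
                                        rows[1, w] += w1 * xv
                                        rows[2, w] += w2 * xv
                                        rows[3, w] += w3 * xv
                                        rows[4, w] += w4 * xv
                                        rows[5, w] += w5 * xv
                                        rows[6, w] += w6 * xv
                                        rows[7, w] += w7 * xv
                    for j in range(8):
                        for w in range(W):
                            out[n, co + j, d, h, w] = rows[j, w]


def conv3d_forward(xp, wk, out):
    """out[n,co] = sum_ci xp[n,ci] (*) wk[co,ci]  (valid conv on padded xp).

    xp: (N, Ci, D+K-1, ...); wk: (Co, Ci, K, K, K); out: (N, Co, D, H, W).
    """
    if out.shape[1] % 8 == 0:
        _conv3d_fwd_cb8(xp, wk, out)
    else:
        _conv3d_fwd_generic(xp, wk, out)


@njit(fastmath=True, cache=True)
def conv3d_wgrad(xp, g, gw):
    """gw[co,ci,dd,dh,dw] = sum_{n,d,h,w} g[n,co,d,h,w] * xp[n,ci,d+dd,h+dh,w+dw]."""
    N, Co, D, H, W = g.shape
    Ci = xp.shape[1]
    K = gw.shape[2]
    for n in range(N):
        for d in range(D):
            for h in range(H):
                for ci in range(Ci):
                    for dd in range(K):
                        for dh in range(K):
                            for dw in range(K):
                                for co in range(Co):
                                    s = np.float32(0.0)
                                    for w in range(W):
                                        s += g[n, co, d, h, w] * xp[n, ci, d + dd, h + dh, w + dw]
                                    gw[co, ci, dd, dh, dw] += s
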