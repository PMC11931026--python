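"""Numba kernels for the multi-resolution hash encoding.

The encoding touches N points x L levels x 8 corners; doing that with numpy
broadcasting materializes hundred-megabyte index temporaries, so the inner
loops are compiled instead. Single-threaded on purpose: the scatter-adds in
the backward pass must not race, and the pipeline targets plain CPU boxes.
"""

from __future__ import annotations

import numba
import numpy as np

P1 = np.int64(2654435761)
P2 = np.int64(805459861)


@numba.njit(fastmath=True)
def encode_fwd(x, res, dense, offs, tmask, table, out, idx, w, frac, need_dx):
    """Trilinear hash-grid features.

    x: (N, 3) clipped to [0, 1]; res/dense/offs: per-level resolution, dense
    flag and packed-table offset; tmask: table_size - 1. Fills out (N, L*F),
    idx (N, L, 8), w (N, L, 8) and, when need_dx, frac (N, L, 3).
    """
    N = x.shape[0]
    L = res.shape[0]
    F = table.shape[1]
    for n in range(N):
        for l in range(L):
            r = res[l]
            px = x[n, 0] * r
            py = x[n, 1] * r
            pz = x[n, 2] * r
            cx = min(np.int64(px), r - 1)
            cy = min(np.int64(py), r - 1)
            cz = min(np.int64(pz), r - 1)
            fx = px - cx
            fy = py - cy
            fz = pz - cz
            if need_dx:
                frac[n, l, 0] = fx
                frac[n, l, 1] = fy
                frac[n, l, 2] = fz
            for corner in range(8):
                bx = (corner >> 2) & 1
                by = (corner >> 1) & 1
                bz = corner & 1
                ccx = cx + bx
                ccy = cy + by
                ccz = cz + bz
                if dense[l]:
                    ident = ccx + (r + 1) * (ccy + (r + 1) * ccz)
                else:
                    ident = (ccx ^ (ccy * P1) ^ (ccz * P2)) & tmask
                ident += offs[l]
                wt = (
                    (fx if bx else 1.0 - fx)
                    * (fy if by else 1.0 - fy)
                    * (fz if bz else 1.0 - fz)
                )
                idx[n, l, corner] = ident
                w[n, l, corner] = wt
                base = l * F
                for f in range(F):
                    out[n, base + f] += wt * table[ident, f]


@numba.njit(fastmath=True)
def encode_bwd(grad_out, idx, w, frac, table, res, tgrad, gx, need_dx):
    """Scatter table gradients and (optionally) point gradients."""
    N = grad_out.shape[0]
    L = res.shape[0]
    F = table.shape[1]
    for n in range(N):
        for l in range(L):
            base = l * F
            if need_dx:
                fx = frac[n, l, 0]
                fy = frac[n, l, 1]
                fz = frac[n, l, 2]
            for corner in range(8):
                ident = idx[n, l, corner]
                wt = w[n, l, corner]
                gw = 0.0
                for f in range(F):
                    g = grad_out[n, base + f]
                    tgrad[ident, f] += wt * g
                    gw += g * table[ident, f]
                if need_dx:
                    bx = (corner >> 2) & 1
                    by = (corner >> 1) & 1
                    bz = corner & 1
                    tx = fx if bx else 1.0 - fx
                    ty = fy if by else 1.0 - fy
                    tz = fz if bz else 1.0 - fz
                    sx = 1.0 if bx else -1.0
                    sy = 1.0 if by else -1.0
                    sz = 1.0 if bz else -1.0
                    r = res[l]
                    gx[n, 0] += r * gw * sx * ty * tz
                    gx[n, 1] += r * gw * sy * tx * tz
                    gx[n, 2] += r * gw * sz * tx * ty
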