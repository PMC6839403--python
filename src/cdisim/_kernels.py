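"""Numba kernels: segment geometry, grid-hash contact search, overlap relaxation.

All kernels operate on flat float64/int64 arrays and are deterministic for a
given input ordering.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True, fastmath=False)
def seg_seg_closest(p1x, p1y, d1x, d1y, p2x, p2y, d2x, d2y):
    """Closest points between segments P1+s*D1 and P2+t*D2, s,t in [0,1].

    Returns (s, t, dist): clamped parameters and the distance between the
    closest points. Standard clamped quadratic minimization.
    """
    rx = p1x - p2x
    ry = p1y - p2y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    if a <= _EPS and e <= _EPS:
        s = 0.0
        t = 0.0
    elif a <= _EPS:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry
        if e <= _EPS:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y
            denom = a * e - b * b
            if denom > _EPS:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    cx = p1x + s * d1x - (p2x + t * d2x)
    cy = p1y + s * d1y - (p2y + t * d2y)
    return s, t, np.sqrt(cx * cx + cy * cy)


@njit(cache=True)
def capsule_pair_separation(cx1, cy1, ux1, uy1, hl1, r1,
                            cx2, cy2, ux2, uy2, hl2, r2):
    """Surface separation of two capsules (negative when overlapping)."""
    p1x = cx1 - hl1 * ux1
    p1y = cy1 - hl1 * uy1
    p2x = cx2 - hl2 * ux2
    p2y = cy2 - hl2 * uy2
    _, _, d = seg_seg_closest(p1x, p1y, 2.0 * hl1 * ux1, 2.0 * hl1 * uy1,
                              p2x, p2y, 2.0 * hl2 * ux2, 2.0 * hl2 * uy2)
    return d - (r1 + r2)


@njit(cache=True)
def _grid_keys(cx, cy, cell_size):
    n = cx.shape[0]
    ix = np.empty(n, dtype=np.int64)
    iy = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix[i] = np.int64(np.floor(cx[i] / cell_size))
        iy[i] = np.int64(np.floor(cy[i] / cell_size))
    return ix, iy


@njit(cache=True)
def contact_pairs(cx, cy, ang, hl, rad, tol, cell_size):
    """All capsule pairs with surface separation <= tol.

    Uniform grid hash with bin width >= the largest capsule extent, so a 3x3
    neighborhood search is exhaustive. Returns (i, j, sep) with i < j, ordered
    deterministically by (i, j).
    """
    n = cx.shape[0]
    ux = np.cos(ang)
    uy = np.sin(ang)
    ix, iy = _grid_keys(cx, cy, cell_size)
    minx = np.int64(0)
    miny = np.int64(0)
    if n > 0:
        minx = ix.min()
        miny = iy.min()
    nx = np.int64(1)
    ny = np.int64(1)
    if n > 0:
        nx = ix.max() - minx + 1
        ny = iy.max() - miny + 1
    key = (ix - minx) * ny + (iy - miny)
    order = np.argsort(key, kind="mergesort")
    skey = key[order]

    cap = 16 * n + 16
    out_i = np.empty(cap, dtype=np.int64)
    out_j = np.empty(cap, dtype=np.int64)
    out_s = np.empty(cap, dtype=np.float64)
    m = 0
    for i in range(n):
        gx = ix[i] - minx
        gy = iy[i] - miny
        for dxc in range(-1, 2):
            bx = gx + dxc
            if bx < 0 or bx >= nx:
                continue
            for dyc in range(-1, 2):
                by = gy + dyc
                if by < 0 or by >= ny:
                    continue
                k = bx * ny + by
                lo = np.searchsorted(skey, k)
                hi = np.searchsorted(skey, k + 1)
                for q in range(lo, hi):
                    j = order[q]
                    if j <= i:
                        continue
                    # cheap circle prefilter
                    dx = cx[i] - cx[j]
                    dy = cy[i] - cy[j]
                    reach = hl[i] + rad[i] + hl[j] + rad[j] + tol
                    if dx * dx + dy * dy > reach * reach:
                        continue
                    sep = capsule_pair_separation(
                        cx[i], cy[i], ux[i], uy[i], hl[i], rad[i],
                        cx[j], cy[j], ux[j], uy[j], hl[j], rad[j])
                    if sep <= tol:
                        if m >= cap:
                            cap = cap * 2
                            tmp_i = np.empty(cap, dtype=np.int64)
                            tmp_j = np.empty(cap, dtype=np.int64)
                            tmp_s = np.empty(cap, dtype=np.float64)
                            tmp_i[:m] = out_i[:m]
                            tmp_j[:m] = out_j[:m]
                            tmp_s[:m] = out_s[:m]
                            out_i = tmp_i
                            out_j = tmp_j
                            out_s = tmp_s
                        out_i[m] = i
                        out_j[m] = j
                        out_s[m] = sep
                        m += 1
    res_i = out_i[:m].copy()
    res_j = out_j[:m].copy()
    res_s = out_s[:m].copy()
    # sort pairs by (i, j) for a canonical deterministic order
    idx = np.argsort(res_i * np.int64(n) + res_j, kind="mergesort")
    return res_i[idx], res_j[idx], res_s[idx]


@njit(cache=True)
def pair_separations(cx, cy, ang, hl, rad, pi, pj):
    """Recompute separations for an explicit pair list."""
    m = pi.shape[0]
    out = np.empty(m, dtype=np.float64)
    ux = np.cos(ang)
    uy = np.sin(ang)
    for k in range(m):
        i = pi[k]
        j = pj[k]
        out[k] = capsule_pair_separation(
            cx[i], cy[i], ux[i], uy[i], hl[i], rad[i],
            cx[j], cy[j], ux[j], uy[j], hl[j], rad[j])
    return out


@njit(cache=True)
def overlap_pressure(sep, pi, pj, n, threshold):
    """Per-cell sum of pairwise overlap depths exceeding ``threshold`` (um).

    Overlaps at or below the relaxation residual tolerance are background
    noise of the pushout scheme, not jamming, and are ignored.
    """
    out = np.zeros(n, dtype=np.float64)
    for k in range(sep.shape[0]):
        ov = -sep[k] - threshold
        if ov > 0.0:
            out[pi[k]] += ov
            out[pj[k]] += ov
    return out


@njit(cache=True)
def relax_overlaps(cx, cy, ang, hl, rad, pi, pj,
                   residual_tol, max_iter, damping, torque_gain):
    """Gauss-Seidel pairwise pushout of overlapping capsules, in place.

    Each sweep visits the pair list in order; overlapping pairs are pushed
    apart along the contact normal by half the overlap (scaled by ``damping``)
    with a small torque-like axis correction. Terminates when the maximum
    overlap over the pair list is at most ``residual_tol`` or after
    ``max_iter`` sweeps. Returns (n_sweeps, final_max_overlap).
    """
    m = pi.shape[0]
    if m == 0:
        return 0, 0.0
    n = cx.shape[0]
    ux = np.cos(ang)
    uy = np.sin(ang)
    dang = np.zeros(n, dtype=np.float64)
    sweeps = 0
    for _ in range(max_iter):
        sweeps += 1
        max_ov = 0.0
        for k in range(m):
            i = pi[k]
            j = pj[k]
            uix = ux[i]
            uiy = uy[i]
            ujx = ux[j]
            ujy = uy[j]
            p1x = cx[i] - hl[i] * uix
            p1y = cy[i] - hl[i] * uiy
            p2x = cx[j] - hl[j] * ujx
            p2y = cy[j] - hl[j] * ujy
            s, t, d = seg_seg_closest(
                p1x, p1y, 2.0 * hl[i] * uix, 2.0 * hl[i] * uiy,
                p2x, p2y, 2.0 * hl[j] * ujx, 2.0 * hl[j] * ujy)
            ov = (rad[i] + rad[j]) - d
            if ov <= 0.0:
                continue
            if ov > max_ov:
                max_ov = ov
            c1x = p1x + s * 2.0 * hl[i] * uix
            c1y = p1y + s * 2.0 * hl[i] * uiy
            c2x = p2x + t * 2.0 * hl[j] * ujx
            c2y = p2y + t * 2.0 * hl[j] * ujy
            if d > 1e-9:
                nx_ = (c1x - c2x) / d
                ny_ = (c1y - c2y) / d
            else:
                # coincident closest points: push perpendicular to i's axis
                nx_ = -uiy
                ny_ = uix
            push = 0.5 * damping * ov
            cx[i] += push * nx_
            cy[i] += push * ny_
            cx[j] -= push * nx_
            cy[j] -= push * ny_
            if torque_gain > 0.0:
                armix = c1x - cx[i]
                armiy = c1y - cy[i]
                armjx = c2x - cx[j]
                armjy = c2y - cy[j]
                levi = hl[i] + rad[i]
                levj = hl[j] + rad[j]
                dang[i] += torque_gain * push * (armix * ny_ - armiy * nx_) / (levi * levi)
                dang[j] += torque_gain * push * (-armjx * ny_ + armjy * nx_) / (levj * levj)
        # axis corrections are applied between sweeps (positions in place)
        if torque_gain > 0.0:
            for i in range(n):
                if dang[i] != 0.0:
                    ang[i] += dang[i]
                    ux[i] = np.cos(ang[i])
                    uy[i] = np.sin(ang[i])
                    dang[i] = 0.0
        if max_ov <= residual_tol:
            break
    # residual measured on final geometry
    final = 0.0
    for k in range(m):
        i = pi[k]
        j = pj[k]
        uix = np.cos(ang[i])
        uiy = np.sin(ang[i])
        ujx = np.cos(ang[j])
        ujy = np.sin(ang[j])
        sep = capsule_pair_separation(
            cx[i], cy[i], uix, uiy, hl[i], rad[i],
            cx[j], cy[j], ujx, ujy, hl[j], rad[j])
        if -sep > final:
            final = -sep
    return sweeps, final
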