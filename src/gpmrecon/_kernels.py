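"""Numba kernels for the hot loops.

Everything here is a plain numeric loop nest: per-pixel robust feature maps,
spherical-ball accumulation into the voxel grid, nearest-known-voxel search,
distance-weighted interpolation, and the SAD patch scans. Python-level
wrappers with validation live in the public modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Tie-breaks throughout use the smallest linearized voxel index with x
# fastest: lin = ix + nx*(iy + ny*iz). Loop nests therefore iterate
# iz (outer), iy, ix (inner) and keep the first strict improvement.


@njit(cache=True)
def feature_maps(pixels, su, sv, max_class):
    """Best-contribution distance map for one slice (Eqs 3-9 pipeline).

    For each pixel: H_k = alpha*MAD + beta*IQRAD over the Chebyshev disc of
    radius k (center excluded, border-clipped) for k = 1..max_class; k* is
    the argmin (ties -> smallest k); d is the largest Euclidean pixel
    distance in the k* disc converted to mm via (su, sv).

    Returns (dmap, kmap, hbest) float64/int64/float64 arrays.
    """
    nv, nu = pixels.shape
    dmap = np.zeros((nv, nu), dtype=np.float64)
    kmap = np.zeros((nv, nu), dtype=np.int64)
    hbest = np.zeros((nv, nu), dtype=np.float64)
    side = 2 * max_class + 1
    buf = np.empty(side * side, dtype=np.float64)
    for v in range(nv):
        for u in range(nu):
            center = pixels[v, u]
            best_h = np.inf
            best_k = 1
            for k in range(1, max_class + 1):
                n_neigh = 0
                for dv in range(-k, k + 1):
                    vv = v + dv
                    if vv < 0 or vv >= nv:
                        continue
                    for du in range(-k, k + 1):
                        if du == 0 and dv == 0:
                            continue
                        uu = u + du
                        if uu < 0 or uu >= nu:
                            continue
                        buf[n_neigh] = pixels[vv, uu]
                        n_neigh += 1
                if n_neigh == 0:
                    continue
                neigh = np.sort(buf[:n_neigh])
                med = neigh[(n_neigh - 1) // 2]  # lower median
                mad = abs(med - center)
                imin = neigh[0]
                imax = neigh[n_neigh - 1]
                lo = imin + 0.25 * (imax - imin)
                hi = imin + 0.75 * (imax - imin)
                n_band = 0
                band_sum = 0.0
                for j in range(n_neigh):
                    if lo <= neigh[j] <= hi:
                        n_band += 1
                        band_sum += neigh[j] - center
                iqr = abs(band_sum) / n_band if n_band > 0 else 0.0
                alpha = 0.75 * (n_neigh + 1) / (n_neigh + n_band + 1)
                beta = 1.0 - alpha
                h = alpha * mad + beta * iqr
                if h < best_h:
                    best_h = h
                    best_k = k
            # best contribution distance over the clipped k* disc
            k = best_k
            dmax = 0.0
            for dv in range(-k, k + 1):
                vv = v + dv
                if vv < 0 or vv >= nv:
                    continue
                for du in range(-k, k + 1):
                    if du == 0 and dv == 0:
                        continue
                    uu = u + du
                    if uu < 0 or uu >= nu:
                        continue
                    dist = np.sqrt((du * su) ** 2 + (dv * sv) ** 2)
                    if dist > dmax:
                        dmax = dist
            dmap[v, u] = dmax
            kmap[v, u] = best_k
            hbest[v, u] = best_h if np.isfinite(best_h) else 0.0
    return dmap, kmap, hbest


@njit(cache=True)
def accumulate_ball(ws, ivals, dvals, ox, oy, oz, spacing, hit_frac,
                    nx, ny, nz,
                    num, den_inv, den_lit, hit_sum, hit_cnt, cmin, cmax):
    """Scatter pixels into the grid accumulators.

    A pixel whose world position lies within hit_frac * spacing of a voxel
    center is a direct hit (running mean, excluded from ball accumulation);
    otherwise it contributes I/d and 1/d (and d, for the literal variant) to
    every voxel center within the spherical ball of its best-contribution
    distance.
    """
    half = hit_frac * spacing
    n = ws.shape[0]
    for i in range(n):
        wx = ws[i, 0]
        wy = ws[i, 1]
        wz = ws[i, 2]
        val = ivals[i]
        cx = (wx - ox) / spacing
        cy = (wy - oy) / spacing
        cz = (wz - oz) / spacing
        jx = int(np.floor(cx + 0.5))
        jy = int(np.floor(cy + 0.5))
        jz = int(np.floor(cz + 0.5))
        if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
            ddx = (cx - jx) * spacing
            ddy = (cy - jy) * spacing
            ddz = (cz - jz) * spacing
            if np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz) < half:
                hit_sum[jx, jy, jz] += val
                hit_cnt[jx, jy, jz] += 1.0
                if val < cmin[jx, jy, jz]:
                    cmin[jx, jy, jz] = val
                if val > cmax[jx, jy, jz]:
                    cmax[jx, jy, jz] = val
                continue
        r = dvals[i]
        x0 = max(0, int(np.ceil((wx - r - ox) / spacing)))
        x1 = min(nx - 1, int(np.floor((wx + r - ox) / spacing)))
        y0 = max(0, int(np.ceil((wy - r - oy) / spacing)))
        y1 = min(ny - 1, int(np.floor((wy + r - oy) / spacing)))
        z0 = max(0, int(np.ceil((wz - r - oz) / spacing)))
        z1 = min(nz - 1, int(np.floor((wz + r - oz) / spacing)))
        r2 = r * r
        for iz in range(z0, z1 + 1):
            pz = oz + iz * spacing - wz
            for iy in range(y0, y1 + 1):
                py = oy + iy * spacing - wy
                for ix in range(x0, x1 + 1):
                    px = ox + ix * spacing - wx
                    d2 = px * px + py * py + pz * pz
                    if d2 <= r2 and d2 > 0.0:
                        d = np.sqrt(d2)
                        num[ix, iy, iz] += val / d
                        den_inv[ix, iy, iz] += 1.0 / d
                        den_lit[ix, iy, iz] += d
                        if val < cmin[ix, iy, iz]:
                            cmin[ix, iy, iz] = val
                        if val > cmax[ix, iy, iz]:
                            cmax[ix, iy, iz] = val


@njit(cache=True)
def vnn_search(known, intensity, out):
    """Euclidean nearest known voxel per vacant voxel, expanding-shell scan.

    Ties on distance go to the smallest linearized index (x fastest). The
    shell search stops once the shell radius exceeds the best distance found.
    """
    nx, ny, nz = known.shape
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                if known[ix, iy, iz]:
                    continue
                best_d2 = 1.0e30
                best_lin = -1
                best_val = 0.0
                rmax = max(nx, ny, nz)
                for r in range(1, rmax + 1):
                    if best_lin >= 0 and (r - 1) * (r - 1) >= best_d2:
                        break
                    z0 = max(0, iz - r)
                    z1 = min(nz - 1, iz + r)
                    y0 = max(0, iy - r)
                    y1 = min(ny - 1, iy + r)
                    x0 = max(0, ix - r)
                    x1 = min(nx - 1, ix + r)
                    for jz in range(z0, z1 + 1):
                        dz = jz - iz
                        adz = dz if dz >= 0 else -dz
                        for jy in range(y0, y1 + 1):
                            dy = jy - iy
                            ady = dy if dy >= 0 else -dy
                            for jx in range(x0, x1 + 1):
                                dx = jx - ix
                                adx = dx if dx >= 0 else -dx
                                # only the Chebyshev shell at radius r
                                if adx != r and ady != r and adz != r:
                                    continue
                                if not known[jx, jy, jz]:
                                    continue
                                d2 = float(dx * dx + dy * dy + dz * dz)
                                lin = jx + nx * (jy + ny * jz)
                                if d2 < best_d2 or (d2 == best_d2 and lin < best_lin):
                                    best_d2 = d2
                                    best_lin = lin
                                    best_val = intensity[jx, jy, jz]
                out[ix, iy, iz] = best_val


@njit(cache=True)
def dw_interp(known, intensity, radius, out):
    """Inverse-distance interpolation of vacant voxels from known voxels
    within a Euclidean radius; the radius grows by 1 until a contributor is
    found."""
    nx, ny, nz = known.shape
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                if known[ix, iy, iz]:
                    out[ix, iy, iz] = intensity[ix, iy, iz]
                    continue
                r = radius
                while True:
                    num = 0.0
                    den = 0.0
                    r2 = float(r * r)
                    z0 = max(0, iz - r)
                    z1 = min(nz - 1, iz + r)
                    y0 = max(0, iy - r)
                    y1 = min(ny - 1, iy + r)
                    x0 = max(0, ix - r)
                    x1 = min(nx - 1, ix + r)
                    for jz in range(z0, z1 + 1):
                        for jy in range(y0, y1 + 1):
                            for jx in range(x0, x1 + 1):
                                if not known[jx, jy, jz]:
                                    continue
                                d2 = float((jx - ix) ** 2 + (jy - iy) ** 2
                                           + (jz - iz) ** 2)
                                if d2 <= r2:
                                    d = np.sqrt(d2)
                                    num += intensity[jx, jy, jz] / d
                                    den += 1.0 / d
                    if den > 0.0:
                        out[ix, iy, iz] = num / den
                        break
                    r += 1
                    if r > nx + ny + nz:
                        out[ix, iy, iz] = 0.0
                        break


@njit(cache=True)
def sad_scan_full(vol, valid, t_off, t_val,
                  x0, x1, y0, y1, z0, z1):
    """Minimum-SAD scan over fully-known candidate patches.

    ``valid[c]`` marks candidate centers whose whole patch extent is inside
    the grid and contains no vacant voxel. SAD is summed over the target's
    known support ``t_off``/``t_val``. First strict improvement in
    x-fastest order implements the linearized-index tie-break. Returns
    (bx, by, bz, best_sad); bx == -1 when no candidate exists.
    """
    m = t_off.shape[0]
    best = np.inf
    bx = -1
    by = -1
    bz = -1
    for cz in range(z0, z1 + 1):
        for cy in range(y0, y1 + 1):
            for cx in range(x0, x1 + 1):
                if not valid[cx, cy, cz]:
                    continue
                s = 0.0
                for t in range(m):
                    s += abs(vol[cx + t_off[t, 0], cy + t_off[t, 1],
                                 cz + t_off[t, 2]] - t_val[t])
                    if s >= best:
                        break
                if s < best:
                    best = s
                    bx = cx
                    by = cy
                    bz = cz
    return bx, by, bz, best


@njit(cache=True)
def sad_scan_masked(vol, known, t_off, t_val, forbid,
                    x0, x1, y0, y1, z0, z1):
    """Fallback scan when no fully-known candidate exists.

    Candidates maximize the jointly-known overlap with the target support,
    then minimize SAD normalized by that count; ``forbid`` masks centers
    (e.g. the target itself). Returns (bx, by, bz, normalized sad)."""
    m = t_off.shape[0]
    best_cnt = 0
    best_sad = np.inf
    bx = -1
    by = -1
    bz = -1
    for cz in range(z0, z1 + 1):
        for cy in range(y0, y1 + 1):
            for cx in range(x0, x1 + 1):
                if forbid[cx, cy, cz]:
                    continue
                cnt = 0
                s = 0.0
                for t in range(m):
                    jx = cx + t_off[t, 0]
                    jy = cy + t_off[t, 1]
                    jz = cz + t_off[t, 2]
                    if known[jx, jy, jz]:
                        cnt += 1
                        s += abs(vol[jx, jy, jz] - t_val[t])
                if cnt == 0:
                    continue
                nsad = s / cnt
                if cnt > best_cnt or (cnt == best_cnt and nsad < best_sad):
                    best_cnt = cnt
                    best_sad = nsad
                    bx = cx
                    by = cy
                    bz = cz
    return bx, by, bz, best_sad


@njit(cache=True, inline="always")
def _masked_grad(intensity, known, x, y, z, nx, ny, nz):
    """Intensity gradient using known voxels only.

    Per axis: central difference when both neighbors are known, one-sided
    when the center and one neighbor are known, else 0 (out-of-bounds
    neighbors count as vacant)."""
    g = np.zeros(3)
    kc = known[x, y, z]
    for a in range(3):
        if a == 0:
            xp, yp, zp, xm, ym, zm = x + 1, y, z, x - 1, y, z
        elif a == 1:
            xp, yp, zp, xm, ym, zm = x, y + 1, z, x, y - 1, z
        else:
            xp, yp, zp, xm, ym, zm = x, y, z + 1, x, y, z - 1
        kp = 0 <= xp < nx and 0 <= yp < ny and 0 <= zp < nz and known[xp, yp, zp]
        km = 0 <= xm < nx and 0 <= ym < ny and 0 <= zm < nz and known[xm, ym, zm]
        if kp and km:
            g[a] = 0.5 * (intensity[xp, yp, zp] - intensity[xm, ym, zm])
        elif kc and kp:
            g[a] = intensity[xp, yp, zp] - intensity[x, y, z]
        elif kc and km:
            g[a] = intensity[x, y, z] - intensity[xm, ym, zm]
    return g


@njit(cache=True, inline="always")
def _smooth_vacancy(known, x, y, z, nx, ny, nz):
    """Mean of the vacancy indicator over the clipped 3x3x3 neighborhood."""
    s = 0.0
    c = 0
    for jx in range(max(0, x - 1), min(nx, x + 2)):
        for jy in range(max(0, y - 1), min(ny, y + 2)):
            for jz in range(max(0, z - 1), min(nz, z + 2)):
                c += 1
                if not known[jx, jy, jz]:
                    s += 1.0
    return s / c


@njit(cache=True)
def front_normals(known, pts):
    """Unit front normals: gradient (central differences, one-sided at the
    volume border) of the 1-voxel-smoothed vacancy indicator; a zero
    gradient defaults to +x."""
    nx, ny, nz = known.shape
    m = pts.shape[0]
    out = np.empty((m, 3))
    for i in range(m):
        x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
        g = np.zeros(3)
        for a in range(3):
            if a == 0:
                hi, lo = min(nx - 1, x + 1), max(0, x - 1)
                sp = _smooth_vacancy(known, hi, y, z, nx, ny, nz)
                sm = _smooth_vacancy(known, lo, y, z, nx, ny, nz)
            elif a == 1:
                hi, lo = min(ny - 1, y + 1), max(0, y - 1)
                sp = _smooth_vacancy(known, x, hi, z, nx, ny, nz)
                sm = _smooth_vacancy(known, x, lo, z, nx, ny, nz)
            else:
                hi, lo = min(nz - 1, z + 1), max(0, z - 1)
                sp = _smooth_vacancy(known, x, y, hi, nx, ny, nz)
                sm = _smooth_vacancy(known, x, y, lo, nx, ny, nz)
            if hi > lo:
                g[a] = (sp - sm) / (hi - lo)
        norm = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
        if norm > 0.0:
            out[i, 0] = g[0] / norm
            out[i, 1] = g[1] / norm
            out[i, 2] = g[2] / norm
        else:
            out[i, 0] = 1.0
            out[i, 1] = 0.0
            out[i, 2] = 0.0
    return out


@njit(cache=True)
def priority_terms(intensity, known, conf, pts, half, alpha_norm, floor):
    """Confidence, data, and gradient terms for a batch of front voxels.

    Every quantity is computed by direct local summation (no running sums),
    so results are bitwise reproducible from the local patch content alone.
    """
    nx, ny, nz = intensity.shape
    m = pts.shape[0]
    C = np.empty(m)
    D = np.empty(m)
    G = np.empty(m)
    normals = front_normals(known, pts)
    for i in range(m):
        x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
        x0, x1 = max(0, x - half), min(nx - 1, x + half)
        y0, y1 = max(0, y - half), min(ny - 1, y + half)
        z0, z1 = max(0, z - half), min(nz - 1, z + half)
        csum = 0.0
        gsum = 0.0
        kcnt = 0
        tot = 0
        for jx in range(x0, x1 + 1):
            for jy in range(y0, y1 + 1):
                for jz in range(z0, z1 + 1):
                    tot += 1
                    if known[jx, jy, jz]:
                        kcnt += 1
                        csum += conf[jx, jy, jz]
                        g = _masked_grad(intensity, known, jx, jy, jz, nx, ny, nz)
                        gsum += np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
        C[i] = csum / tot
        G[i] = gsum / kcnt if kcnt > 0 else 0.0
        gp = _masked_grad(intensity, known, x, y, z, nx, ny, nz)
        nvec = normals[i]
        cx = gp[1] * nvec[2] - gp[2] * nvec[1]
        cy = gp[2] * nvec[0] - gp[0] * nvec[2]
        cz = gp[0] * nvec[1] - gp[1] * nvec[0]
        d = np.sqrt(cx * cx + cy * cy + cz * cz) / alpha_norm
        D[i] = d if d > floor else floor
    return C, D, G
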