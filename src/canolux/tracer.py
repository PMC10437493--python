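"""Uniform-grid ray casting with lateral periodic wrapping (numba kernels).

The tracer answers one question for batches of rays launched from facet
sample points: which facet (if any) does the ray hit first?  Rays leaving the
lateral domain re-enter on the opposite side when periodic boundaries are on
(emulating an infinite canopy); triangles overhanging the domain are handled
by ghost copies shifted by one domain period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_T_MIN = 1e-5       # minimum hit distance (m): skips the launching surface
_BARY_EPS = 1e-9    # barycentric tolerance: no leaks through shared edges
_MAX_WRAPS = 512  # lateral wraps per ray; small tiles wrap grazing rays often


@njit(cache=True, fastmath=True)
def _trace_kernel(orig, dirs, src, v0, e1, e2, ghost_src,
                  cell_start, cell_tris,
                  nx, ny, nz, gx0, gy0, gz0, csx, csy, csz,
                  periodic, lx, ly, out_hit):
    n_rays = orig.shape[0]
    for r in range(n_rays):
        ox, oy, oz = orig[r, 0], orig[r, 1], orig[r, 2]
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        s = src[r]
        out_hit[r] = -1
        # shift applied to the ray origin to account for periodic wraps
        sx = 0.0
        sy = 0.0
        if periodic:
            # wrap the origin into the domain (a pure translation by whole
            # periods: valid because the scene is periodic)
            ox = gx0 + (ox - gx0) % lx
            oy = gy0 + (oy - gy0) % ly
        # advance to the grid z-slab if starting outside it
        t0 = 0.0
        if oz < gz0:
            if dz <= 0.0:
                continue
            t0 = (gz0 - oz) / dz + 1e-12
        elif oz > gz0 + nz * csz:
            if dz >= 0.0:
                continue
            t0 = (gz0 + nz * csz - oz) / dz + 1e-12
        px = ox + t0 * dx
        py = oy + t0 * dy
        pz = oz + t0 * dz
        if periodic:
            wx = (px - gx0) % lx
            wy = (py - gy0) % ly
            sx += (gx0 + wx) - px
            sy += (gy0 + wy) - py
            px = gx0 + wx
            py = gy0 + wy
        elif (px < gx0 or px > gx0 + nx * csx or
              py < gy0 or py > gy0 + ny * csy):
            # non-periodic: entering laterally outside the grid = escape
            # (canopy grids cover the full scene, so this is a clean miss)
            continue
        ix = int((px - gx0) / csx)
        iy = int((py - gy0) / csy)
        iz = int((pz - gz0) / csz)
        if ix < 0:
            ix = 0
        if ix >= nx:
            ix = nx - 1
        if iy < 0:
            iy = 0
        if iy >= ny:
            iy = ny - 1
        if iz < 0:
            iz = 0
        if iz >= nz:
            iz = nz - 1

        stepx = 1 if dx > 0 else (-1 if dx < 0 else 0)
        stepy = 1 if dy > 0 else (-1 if dy < 0 else 0)
        stepz = 1 if dz > 0 else (-1 if dz < 0 else 0)
        big = 1e30
        if dx != 0.0:
            nxt = gx0 + (ix + (1 if stepx > 0 else 0)) * csx
            tmaxx = t0 + (nxt - px) / dx
            tdx = csx / abs(dx)
        else:
            tmaxx = big
            tdx = big
        if dy != 0.0:
            nxt = gy0 + (iy + (1 if stepy > 0 else 0)) * csy
            tmaxy = t0 + (nxt - py) / dy
            tdy = csy / abs(dy)
        else:
            tmaxy = big
            tdy = big
        if dz != 0.0:
            nxt = gz0 + (iz + (1 if stepz > 0 else 0)) * csz
            tmaxz = t0 + (nxt - pz) / dz
            tdz = csz / abs(dz)
        else:
            tmaxz = big
            tdz = big

        best_t = big
        best_tri = -1
        wraps = 0
        # effective origin for triangle tests (accounts for wraps)
        while True:
            c = (ix * ny + iy) * nz + iz
            k0 = cell_start[c]
            k1 = cell_start[c + 1]
            eox = ox + sx
            eoy = oy + sy
            for k in range(k0, k1):
                ti = cell_tris[k]
                if ghost_src[ti] == s:
                    continue
                ax = v0[ti, 0]
                ay = v0[ti, 1]
                az = v0[ti, 2]
                e1x = e1[ti, 0]
                e1y = e1[ti, 1]
                e1z = e1[ti, 2]
                e2x = e2[ti, 0]
                e2y = e2[ti, 1]
                e2z = e2[ti, 2]
                pvx = dy * e2z - dz * e2y
                pvy = dz * e2x - dx * e2z
                pvz = dx * e2y - dy * e2x
                det = e1x * pvx + e1y * pvy + e1z * pvz
                if -1e-14 < det < 1e-14:
                    continue
                inv = 1.0 / det
                tvx = eox - ax
                tvy = eoy - ay
                tvz = oz - az
                u = (tvx * pvx + tvy * pvy + tvz * pvz) * inv
                if u < -_BARY_EPS or u > 1.0 + _BARY_EPS:
                    continue
                qvx = tvy * e1z - tvz * e1y
                qvy = tvz * e1x - tvx * e1z
                qvz = tvx * e1y - tvy * e1x
                v = (dx * qvx + dy * qvy + dz * qvz) * inv
                if v < -_BARY_EPS or u + v > 1.0 + _BARY_EPS:
                    continue
                t = (e2x * qvx + e2y * qvy + e2z * qvz) * inv
                if t > _T_MIN and t < best_t:
                    best_t = t
                    best_tri = ti
            # current cell exit time
            t_exit = tmaxx
            if tmaxy < t_exit:
                t_exit = tmaxy
            if tmaxz < t_exit:
                t_exit = tmaxz
            if best_tri >= 0 and best_t <= t_exit + 1e-9:
                out_hit[r] = ghost_src[best_tri]
                break
            # step to the next cell
            if tmaxx <= tmaxy and tmaxx <= tmaxz:
                ix += stepx
                tmaxx += tdx
                if ix < 0 or ix >= nx:
                    if periodic:
                        wraps += 1
                        if wraps > _MAX_WRAPS:
                            break
                        if ix < 0:
                            ix = nx - 1
                            sx += lx
                        else:
                            ix = 0
                            sx -= lx
                    else:
                        break
            elif tmaxy <= tmaxz:
                iy += stepy
                tmaxy += tdy
                if iy < 0 or iy >= ny:
                    if periodic:
                        wraps += 1
                        if wraps > _MAX_WRAPS:
                            break
                        if iy < 0:
                            iy = ny - 1
                            sy += ly
                        else:
                            iy = 0
                            sy -= ly
                    else:
                        break
            else:
                iz += stepz
                tmaxz += tdz
                if iz < 0 or iz >= nz:
                    break


@njit(cache=True)
def _fill_cells(ix0, ix1, iy0, iy1, iz0, iz1, ny, nz, cell_of, tri_of):
    pos = 0
    for t in range(len(ix0)):
        for ix in range(ix0[t], ix1[t] + 1):
            for iy in range(iy0[t], iy1[t] + 1):
                base = (ix * ny + iy) * nz
                for iz in range(iz0[t], iz1[t] + 1):
                    cell_of[pos] = base + iz
                    tri_of[pos] = t
                    pos += 1


@dataclass
class TracerGrid:
    """Prebuilt acceleration structure over one scene geometry."""

    v0: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    ghost_src: np.ndarray
    cell_start: np.ndarray
    cell_tris: np.ndarray
    dims: tuple[int, int, int]
    origin: tuple[float, float, float]
    cell_size: tuple[float, float, float]
    periodic: bool
    domain: tuple[float, float, float, float]  # x0, x1, y0, y1

    def trace(self, origins: np.ndarray, dirs: np.ndarray,
              src: np.ndarray) -> np.ndarray:
        """First-hit facet index per ray (-1 = escaped)."""
        n = len(origins)
        out = np.full(n, -1, dtype=np.int64)
        if n == 0 or len(self.v0) == 0:
            return out
        nx, ny, nz = self.dims
        x0, y0, z0 = self.origin
        csx, csy, csz = self.cell_size
        lx = self.domain[1] - self.domain[0]
        ly = self.domain[3] - self.domain[2]
        _trace_kernel(
            np.ascontiguousarray(origins, dtype=np.float64),
            np.ascontiguousarray(dirs, dtype=np.float64),
            np.ascontiguousarray(src, dtype=np.int64),
            self.v0, self.e1, self.e2, self.ghost_src,
            self.cell_start, self.cell_tris,
            nx, ny, nz, x0, y0, z0, csx, csy, csz,
            self.periodic, lx, ly, out)
        return out


def build_grid(triangles: np.ndarray,
               domain: tuple[float, float, float, float],
               periodic: bool = True,
               target_cell: float | None = None) -> TracerGrid:
    """Bin triangles (plus periodic ghosts) into a uniform grid.

    ``triangles`` is (T, 3, 3); ``domain`` the lateral periodic bounds
    (x0, x1, y0, y1).  In periodic mode the grid covers exactly the domain in
    x/y; otherwise it covers the triangle bounding box.
    """
    tris = np.asarray(triangles, dtype=np.float64)
    T = len(tris)
    x0, x1, y0, y1 = map(float, domain)
    lx, ly = x1 - x0, y1 - y0
    if T == 0:
        empty = np.zeros((0, 3))
        return TracerGrid(empty, empty, empty, np.zeros(0, np.int64),
                          np.zeros(2, np.int64), np.zeros(0, np.int64),
                          (1, 1, 1), (x0, y0, 0.0), (max(lx, 1e-6), max(ly, 1e-6), 1.0),
                          periodic, (x0, x1, y0, y1))

    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    z_lo = float(lo[:, 2].min()) - 1e-6
    z_hi = float(hi[:, 2].max()) + 1e-6

    # ghost copies for periodic overhang
    all_tris = [tris]
    src_ids = [np.arange(T, dtype=np.int64)]
    if periodic and lx > 0 and ly > 0:
        # geometry may overhang the domain by several periods (a plant crown
        # on a small tile); ghost every shift whose copy touches the domain
        ext_xp = max(float(hi[:, 0].max()) - x1, 0.0)
        ext_xm = max(x0 - float(lo[:, 0].min()), 0.0)
        ext_yp = max(float(hi[:, 1].max()) - y1, 0.0)
        ext_ym = max(y0 - float(lo[:, 1].min()), 0.0)
        mx_range = range(-int(np.ceil(ext_xp / lx)), int(np.ceil(ext_xm / lx)) + 1)
        my_range = range(-int(np.ceil(ext_yp / ly)), int(np.ceil(ext_ym / ly)) + 1)
        for mx in mx_range:
            for my in my_range:
                if mx == 0 and my == 0:
                    continue
                shift = np.array([mx * lx, my * ly, 0.0])
                slo = lo[:, :2] + shift[:2]
                shi = hi[:, :2] + shift[:2]
                inside = ((shi[:, 0] >= x0) & (slo[:, 0] <= x1)
                          & (shi[:, 1] >= y0) & (slo[:, 1] <= y1))
                if inside.any():
                    idx = np.nonzero(inside)[0]
                    all_tris.append(tris[idx] + shift)
                    src_ids.append(idx.astype(np.int64))
    tris_g = np.concatenate(all_tris)
    ghost_src = np.concatenate(src_ids)

    if periodic:
        gx0, gx1, gy0, gy1 = x0, x1, y0, y1
    else:
        gx0 = float(lo[:, 0].min()) - 1e-6
        gx1 = float(hi[:, 0].max()) + 1e-6
        gy0 = float(lo[:, 1].min()) - 1e-6
        gy1 = float(hi[:, 1].max()) + 1e-6

    if target_cell is None:
        diag = np.linalg.norm(hi - lo, axis=1)
        target_cell = max(0.75 * float(np.median(diag)), 0.02)
    nx = int(np.clip(round((gx1 - gx0) / target_cell), 1, 160))
    ny = int(np.clip(round((gy1 - gy0) / target_cell), 1, 160))
    nz = int(np.clip(round((z_hi - z_lo) / target_cell), 1, 160))
    csx = (gx1 - gx0) / nx
    csy = (gy1 - gy0) / ny
    csz = (z_hi - z_lo) / nz

    glo = tris_g.min(axis=1)
    ghi = tris_g.max(axis=1)
    ix0 = np.clip(np.floor((glo[:, 0] - gx0) / csx).astype(np.int64), 0, nx - 1)
    ix1 = np.clip(np.floor((ghi[:, 0] - gx0) / csx).astype(np.int64), 0, nx - 1)
    iy0 = np.clip(np.floor((glo[:, 1] - gy0) / csy).astype(np.int64), 0, ny - 1)
    iy1 = np.clip(np.floor((ghi[:, 1] - gy0) / csy).astype(np.int64), 0, ny - 1)
    iz0 = np.clip(np.floor((glo[:, 2] - z_lo) / csz).astype(np.int64), 0, nz - 1)
    iz1 = np.clip(np.floor((ghi[:, 2] - z_lo) / csz).astype(np.int64), 0, nz - 1)

    counts = (ix1 - ix0 + 1) * (iy1 - iy0 + 1) * (iz1 - iz0 + 1)
    total = int(counts.sum())
    cell_of = np.empty(total, dtype=np.int64)
    tri_of = np.empty(total, dtype=np.int64)
    _fill_cells(ix0, ix1, iy0, iy1, iz0, iz1, ny, nz, cell_of, tri_of)
    order = np.argsort(cell_of, kind="stable")
    cell_of = cell_of[order]
    cell_tris = tri_of[order]
    n_cells = nx * ny * nz
    cell_start = np.zeros(n_cells + 1, dtype=np.int64)
    np.add.at(cell_start, cell_of + 1, 1)
    cell_start = np.cumsum(cell_start)

    v0 = np.ascontiguousarray(tris_g[:, 0])
    e1 = np.ascontiguousarray(tris_g[:, 1] - tris_g[:, 0])
    e2 = np.ascontiguousarray(tris_g[:, 2] - tris_g[:, 0])
    return TracerGrid(v0, e1, e2, ghost_src, cell_start, cell_tris,
                      (nx, ny, nz), (gx0, gy0, z_lo), (csx, csy, csz),
                      periodic, (x0, x1, y0, y1))
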