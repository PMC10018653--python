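"""Numba-compiled ray-driven forward projection and voxel-driven backprojection.

Geometry convention (circular cone-beam trajectory in the x-y plane):

* source at gantry angle b: ``S = sid * (cos b, sin b, 0)``
* central-axis direction ``w = -(cos b, sin b, 0)`` (source -> isocenter)
* detector column axis ``u = (-sin b, cos b, 0)``, row axis ``v = (0, 0, 1)``
* flat detector centred on the axis at distance ``sdd`` from the source.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _trilinear(vol, fx, fy, fz):
    nx, ny, nz = vol.shape
    if fx < 0.0 or fy < 0.0 or fz < 0.0:
        return 0.0
    if fx > nx - 1 or fy > ny - 1 or fz > nz - 1:
        return 0.0
    ix = int(fx)
    iy = int(fy)
    iz = int(fz)
    if ix == nx - 1:
        ix -= 1
    if iy == ny - 1:
        iy -= 1
    if iz == nz - 1:
        iz -= 1
    dx = fx - ix
    dy = fy - iy
    dz = fz - iz
    c000 = vol[ix, iy, iz]
    c100 = vol[ix + 1, iy, iz]
    c010 = vol[ix, iy + 1, iz]
    c110 = vol[ix + 1, iy + 1, iz]
    c001 = vol[ix, iy, iz + 1]
    c101 = vol[ix + 1, iy, iz + 1]
    c011 = vol[ix, iy + 1, iz + 1]
    c111 = vol[ix + 1, iy + 1, iz + 1]
    c00 = c000 * (1 - dx) + c100 * dx
    c10 = c010 * (1 - dx) + c110 * dx
    c01 = c001 * (1 - dx) + c101 * dx
    c11 = c011 * (1 - dx) + c111 * dx
    c0 = c00 * (1 - dy) + c10 * dy
    c1 = c01 * (1 - dy) + c11 * dy
    return c0 * (1 - dz) + c1 * dz


@njit(cache=True, fastmath=True)
def forward_kernel(vol, ox, oy, oz, sx, sy, sz,
                   src, det_c, u_hat, v_hat,
                   n_rows, n_cols, pitch, step, out):
    """Line integrals (attenuation * mm) by fixed-step trilinear sampling."""
    nx, ny, nz = vol.shape
    x0, x1 = ox, ox + (nx - 1) * sx
    y0, y1 = oy, oy + (ny - 1) * sy
    z0, z1 = oz, oz + (nz - 1) * sz
    cu = (n_cols - 1) / 2.0
    cv = (n_rows - 1) / 2.0
    for iv in range(n_rows):
        v = (iv - cv) * pitch
        for iu in range(n_cols):
            u = (iu - cu) * pitch
            px = det_c[0] + u * u_hat[0] + v * v_hat[0]
            py = det_c[1] + u * u_hat[1] + v * v_hat[1]
            pz = det_c[2] + u * u_hat[2] + v * v_hat[2]
            dx = px - src[0]
            dy = py - src[1]
            dz = pz - src[2]
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= norm
            dy /= norm
            dz /= norm
            tmin = 0.0
            tmax = norm
            # slab clipping against the interpolation domain
            for axis in range(3):
                if axis == 0:
                    d, s0, a0, a1 = dx, src[0], x0, x1
                elif axis == 1:
                    d, s0, a0, a1 = dy, src[1], y0, y1
                else:
                    d, s0, a0, a1 = dz, src[2], z0, z1
                if abs(d) < 1e-12:
                    if s0 < a0 or s0 > a1:
                        tmin = 1.0
                        tmax = 0.0
                        break
                else:
                    t0 = (a0 - s0) / d
                    t1 = (a1 - s0) / d
                    if t0 > t1:
                        t0, t1 = t1, t0
                    if t0 > tmin:
                        tmin = t0
                    if t1 < tmax:
                        tmax = t1
            if tmax <= tmin:
                out[iv, iu] = 0.0
                continue
            n_steps = int((tmax - tmin) / step) + 1
            dt = (tmax - tmin) / n_steps
            acc = 0.0
            for k in range(n_steps):
                t = tmin + (k + 0.5) * dt
                fx = (src[0] + t * dx - ox) / sx
                fy = (src[1] + t * dy - oy) / sy
                fz = (src[2] + t * dz - oz) / sz
                acc += _trilinear(vol, fx, fy, fz)
            out[iv, iu] = acc * dt


@njit(cache=True, fastmath=True)
def backproject_kernel(filtered, srcs, u_hats, v_hats, w_hats,
                       sid, sdd, pitch,
                       ox, oy, oz, sx, sy, sz, out):
    """Accumulate FDK backprojection: sum_i (sid/U)^2 * p_filtered(u(x), v(x)).

    ``filtered`` must already include cosine pre-weighting, redundancy
    weights, ramp filtering and the per-projection angular step (rad).
    """
    n_proj, n_rows, n_cols = filtered.shape
    nx, ny, nz = out.shape
    cu = (n_cols - 1) / 2.0
    cv = (n_rows - 1) / 2.0
    for a in range(n_proj):
        proj = filtered[a]
        s0 = srcs[a, 0]
        s1 = srcs[a, 1]
        s2 = srcs[a, 2]
        u0, u1, u2 = u_hats[a, 0], u_hats[a, 1], u_hats[a, 2]
        v0, v1, v2 = v_hats[a, 0], v_hats[a, 1], v_hats[a, 2]
        w0, w1, w2 = w_hats[a, 0], w_hats[a, 1], w_hats[a, 2]
        for i in range(nx):
            rx = ox + i * sx - s0
            for j in range(ny):
                ry = oy + j * sy - s1
                for k in range(nz):
                    rz = oz + k * sz - s2
                    U = rx * w0 + ry * w1 + rz * w2
                    if U <= 1e-6:
                        continue
                    inv = 1.0 / U
                    fu = (sdd * (rx * u0 + ry * u1 + rz * u2) * inv) / pitch + cu
                    fv = (sdd * (rx * v0 + ry * v1 + rz * v2) * inv) / pitch + cv
                    if fu < 0.0 or fu > n_cols - 1 or fv < 0.0 or fv > n_rows - 1:
                        continue
                    iu = int(fu)
                    iv = int(fv)
                    if iu == n_cols - 1:
                        iu -= 1
                    if iv == n_rows - 1:
                        iv -= 1
                    du = fu - iu
                    dv = fv - iv
                    val = (
                        proj[iv, iu] * (1 - du) * (1 - dv)
                        + proj[iv, iu + 1] * du * (1 - dv)
                        + proj[iv + 1, iu] * (1 - du) * dv
                        + proj[iv + 1, iu + 1] * du * dv
                    )
                    out[i, j, k] += (sid * inv) ** 2 * val
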