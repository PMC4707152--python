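"""Low-level numba kernels shared by the geometry/projection/reconstruction code.

Conventions used by every kernel in this module:

* arrays are indexed ``[z, y, x]`` (MRC order); world coordinates are
  ``(x, y, z)`` vectors relative to the box centre, which sits at voxel
  ``N // 2`` on each axis (0-based).
* rotation matrices act on ``(x, y, z)`` column vectors.
* interpolation is trilinear (volumes) / bilinear (images) with samples
  outside the grid treated as zero, matching the package-wide resampling
  convention.
"""

from __future__ import annotations

import numba
import numpy as np

_jit = numba.njit(cache=True, fastmath=True)


@_jit
def affine3d(vol, A, b):
    """Resample ``vol`` at xyz coordinates ``A @ p + b`` (p centre-relative).

    Single interpolation pass: the caller composes all rotations/shifts
    into (A, b).
    """
    nz, ny, nx = vol.shape
    cx = nx // 2
    cy = ny // 2
    cz = nz // 2
    out = np.zeros_like(vol)
    for iz in range(nz):
        pz = iz - cz
        for iy in range(ny):
            py = iy - cy
            for ix in range(nx):
                px = ix - cx
                qx = A[0, 0] * px + A[0, 1] * py + A[0, 2] * pz + b[0] + cx
                qy = A[1, 0] * px + A[1, 1] * py + A[1, 2] * pz + b[1] + cy
                qz = A[2, 0] * px + A[2, 1] * py + A[2, 2] * pz + b[2] + cz
                x0 = int(np.floor(qx))
                y0 = int(np.floor(qy))
                z0 = int(np.floor(qz))
                fx = qx - x0
                fy = qy - y0
                fz = qz - z0
                acc = 0.0
                for dz in range(2):
                    z = z0 + dz
                    if z < 0 or z >= nz:
                        continue
                    wz = fz if dz == 1 else 1.0 - fz
                    for dy in range(2):
                        y = y0 + dy
                        if y < 0 or y >= ny:
                            continue
                        wy = fy if dy == 1 else 1.0 - fy
                        for dx in range(2):
                            x = x0 + dx
                            if x < 0 or x >= nx:
                                continue
                            wx = fx if dx == 1 else 1.0 - fx
                            acc += wz * wy * wx * vol[z, y, x]
                out[iz, iy, ix] = acc
    return out


@_jit
def project3d(vol, A):
    """Line integral along z of the volume resampled at ``A @ p``.

    ``A`` is the transpose of the particle rotation matrix, so the result is
    the projection of the rotated volume along the viewing axis.
    """
    nz, ny, nx = vol.shape
    cx = nx // 2
    cy = ny // 2
    cz = nz // 2
    img = np.zeros((ny, nx), dtype=vol.dtype)
    for iy in range(ny):
        py = iy - cy
        for ix in range(nx):
            px = ix - cx
            acc = 0.0
            for iz in range(nz):
                pz = iz - cz
                qx = A[0, 0] * px + A[0, 1] * py + A[0, 2] * pz + cx
                qy = A[1, 0] * px + A[1, 1] * py + A[1, 2] * pz + cy
                qz = A[2, 0] * px + A[2, 1] * py + A[2, 2] * pz + cz
                x0 = int(np.floor(qx))
                y0 = int(np.floor(qy))
                z0 = int(np.floor(qz))
                fx = qx - x0
                fy = qy - y0
                fz = qz - z0
                for dz in range(2):
                    z = z0 + dz
                    if z < 0 or z >= nz:
                        continue
                    wz = fz if dz == 1 else 1.0 - fz
                    for dy in range(2):
                        y = y0 + dy
                        if y < 0 or y >= ny:
                            continue
                        wy = fy if dy == 1 else 1.0 - fy
                        for dx in range(2):
                            x = x0 + dx
                            if x < 0 or x >= nx:
                                continue
                            wx = fx if dx == 1 else 1.0 - fx
                            acc += wz * wy * wx * vol[z, y, x]
            img[iy, ix] = acc
    return img


@_jit
def shift2d(img, dx, dy):
    """Bilinear in-plane shift; the imaged object moves by (+dx, +dy) pixels."""
    ny, nx = img.shape
    out = np.zeros_like(img)
    for iy in range(ny):
        for ix in range(nx):
            qx = ix - dx
            qy = iy - dy
            x0 = int(np.floor(qx))
            y0 = int(np.floor(qy))
            fx = qx - x0
            fy = qy - y0
            acc = 0.0
            for dyy in range(2):
                y = y0 + dyy
                if y < 0 or y >= ny:
                    continue
                wy = fy if dyy == 1 else 1.0 - fy
                for dxx in range(2):
                    x = x0 + dxx
                    if x < 0 or x >= nx:
                        continue
                    wx = fx if dxx == 1 else 1.0 - fx
                    acc += wy * wx * img[y, x]
            out[iy, ix] = acc
    return out


@_jit
def backproject3d(out, img, R, dx, dy):
    """Smear ``img`` along its viewing axis into ``out`` (adjoint of project3d).

    ``R`` is the particle rotation (world -> camera); ``(dx, dy)`` is the
    in-plane shift recorded for the particle, undone here by sampling the
    image at the shifted position.
    """
    nz, ny, nx = out.shape
    cx = nx // 2
    cy = ny // 2
    cz = nz // 2
    for iz in range(nz):
        pz = iz - cz
        for iy in range(ny):
            py = iy - cy
            for ix in range(nx):
                px = ix - cx
                # camera-frame coordinates of this voxel
                ux = R[0, 0] * px + R[0, 1] * py + R[0, 2] * pz + dx + cx
                uy = R[1, 0] * px + R[1, 1] * py + R[1, 2] * pz + dy + cy
                x0 = int(np.floor(ux))
                y0 = int(np.floor(uy))
                fx = ux - x0
                fy = uy - y0
                acc = 0.0
                for dyy in range(2):
                    y = y0 + dyy
                    if y < 0 or y >= ny:
                        continue
                    wy = fy if dyy == 1 else 1.0 - fy
                    for dxx in range(2):
                        x = x0 + dxx
                        if x < 0 or x >= nx:
                            continue
                        wx = fx if dxx == 1 else 1.0 - fx
                        acc += wy * wx * img[y, x]
                out[iz, iy, ix] += acc


@_jit
def rotate_shift2d_batch(bases, base_idx, deltas, dx, dy):
    """Batch of in-plane rotations (+ a common bilinear shift) of base images.

    ``out[k]`` is ``bases[base_idx[k]]`` rotated in-plane by ``deltas[k]``
    radians about the box centre and then shifted so the imaged object moves
    by ``(+dx, +dy)`` pixels — the image a camera rotated by ``deltas[k]``
    about its own viewing axis would record.  Single bilinear pass, zero fill.
    """
    na = base_idx.shape[0]
    ny, nx = bases.shape[1], bases.shape[2]
    cx = nx // 2
    cy = ny // 2
    out = np.zeros((na, ny, nx), dtype=bases.dtype)
    for k in range(na):
        img = bases[base_idx[k]]
        c = np.cos(deltas[k])
        s = np.sin(deltas[k])
        for iy in range(ny):
            py = iy - cy - dy
            for ix in range(nx):
                px = ix - cx - dx
                qx = c * px - s * py + cx
                qy = s * px + c * py + cy
                x0 = int(np.floor(qx))
                y0 = int(np.floor(qy))
                fx = qx - x0
                fy = qy - y0
                acc = 0.0
                for dyy in range(2):
                    y = y0 + dyy
                    if y < 0 or y >= ny:
                        continue
                    wy = fy if dyy == 1 else 1.0 - fy
                    for dxx in range(2):
                        x = x0 + dxx
                        if x < 0 or x >= nx:
                            continue
                        wx = fx if dxx == 1 else 1.0 - fx
                        acc += wy * wx * img[y, x]
                out[k, iy, ix] = acc
    return out


@_jit
def extract_slices(f_re, f_im, mats, n, scale):
    """Central-slice extraction from an oversampled 3D Fourier transform.

    ``f_re``/``f_im``: FFT of the (origin-rolled) zero-padded volume, side P.
    ``mats``: (na, 3, 3) transposed rotation matrices (same matrices as fed
    to :func:`project3d`).  ``n``: output image side.  ``scale``: P / n.
    Interpolation is trilinear with periodic wrap (the discrete-time Fourier
    transform is periodic, so wrapping is exact in that sense).

    Returns (na, n, n) complex128 image spectra in fft index order.
    """
    npad = f_re.shape[0]
    na = mats.shape[0]
    out = np.empty((na, n, n), dtype=np.complex128)
    half = n // 2
    for a in range(na):
        A = mats[a]
        for v in range(n):
            kv = v - n if v >= half else v
            for u in range(n):
                ku = u - n if u >= half else u
                gx = (A[0, 0] * ku + A[0, 1] * kv) * scale
                gy = (A[1, 0] * ku + A[1, 1] * kv) * scale
                gz = (A[2, 0] * ku + A[2, 1] * kv) * scale
                x0 = int(np.floor(gx))
                y0 = int(np.floor(gy))
                z0 = int(np.floor(gz))
                fx = gx - x0
                fy = gy - y0
                fz = gz - z0
                re = 0.0
                im = 0.0
                for dz in range(2):
                    z = (z0 + dz) % npad
                    wz = fz if dz == 1 else 1.0 - fz
                    for dy in range(2):
                        y = (y0 + dy) % npad
                        wy = fy if dy == 1 else 1.0 - fy
                        for dx in range(2):
                            x = (x0 + dx) % npad
                            w = wz * wy * (fx if dx == 1 else 1.0 - fx)
                            re += w * f_re[z, y, x]
                            im += w * f_im[z, y, x]
                out[a, v, u] = complex(re, im)
    return out
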