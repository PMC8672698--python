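"""Low-level threshold-free cluster enhancement kernel.

TFCE integrates, over an ascending ladder of thresholds h, the quantity
e_h(v)^E * h^H * dh for every voxel v, where e_h(v) is the voxel count of
the connected suprathreshold component containing v at height h.  The
kernel below sweeps the ladder once per map, flood-filling components with
an explicit stack; it is compiled with numba so that permutation nulls
(thousands of maps) stay cheap.
"""

from __future__ import annotations

import numba
import numpy as np


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """Voxel-neighbourhood offsets for 6 (faces), 18 (faces+edges) or 26
    (full cube) connectivity."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                n_nonzero = (dx != 0) + (dy != 0) + (dz != 0)
                if n_nonzero == 0:
                    continue
                if connectivity == 6 and n_nonzero > 1:
                    continue
                if connectivity == 18 and n_nonzero > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=np.int64)


@numba.njit(cache=True)
def tfce_kernel(stat, E, H, n_steps, offsets):  # pragma: no cover - jitted
    """Sweep thresholds from the top down.  Positive voxels, pre-sorted by
    descending height, form a growing prefix of the suprathreshold set, so
    each threshold touches only its own supra voxels; a per-threshold
    generation marker replaces clearing the visited map."""
    nx, ny, nz = stat.shape
    out = np.zeros(stat.shape, dtype=np.float64)
    vmax = stat.max()
    if vmax <= 0.0:
        return out
    dh = vmax / n_steps

    flat = stat.ravel()
    order = np.argsort(flat)[::-1]
    npos = 0
    for m in range(order.shape[0]):
        if flat[order[m]] > 0.0:
            npos += 1
        else:
            break
    ox = np.empty(npos, dtype=np.int64)
    oy = np.empty(npos, dtype=np.int64)
    oz = np.empty(npos, dtype=np.int64)
    for m in range(npos):
        idx = order[m]
        ox[m] = idx // (ny * nz)
        oy[m] = (idx // nz) % ny
        oz[m] = idx % nz

    visited = np.zeros(stat.shape, dtype=np.int64)
    sx = np.empty(npos, dtype=np.int64)
    sy = np.empty(npos, dtype=np.int64)
    sz = np.empty(npos, dtype=np.int64)
    mx = np.empty(npos, dtype=np.int64)
    my = np.empty(npos, dtype=np.int64)
    mz = np.empty(npos, dtype=np.int64)
    n_off = offsets.shape[0]
    prefix = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        height_term = h**H * dh
        while prefix < npos and flat[order[prefix]] >= h:
            prefix += 1
        for m in range(prefix):
            i, j, l = ox[m], oy[m], oz[m]
            if visited[i, j, l] == k:
                continue
            # flood-fill the component containing (i, j, l) at height h
            n_stack = 1
            n_mem = 0
            sx[0], sy[0], sz[0] = i, j, l
            visited[i, j, l] = k
            while n_stack > 0:
                n_stack -= 1
                ci, cj, cl = sx[n_stack], sy[n_stack], sz[n_stack]
                mx[n_mem], my[n_mem], mz[n_mem] = ci, cj, cl
                n_mem += 1
                for o in range(n_off):
                    ni = ci + offsets[o, 0]
                    nj = cj + offsets[o, 1]
                    nl = cl + offsets[o, 2]
                    if (
                        0 <= ni < nx
                        and 0 <= nj < ny
                        and 0 <= nl < nz
                        and visited[ni, nj, nl] != k
                        and stat[ni, nj, nl] >= h
                    ):
                        visited[ni, nj, nl] = k
                        sx[n_stack], sy[n_stack], sz[n_stack] = ni, nj, nl
                        n_stack += 1
            increment = float(n_mem) ** E * height_term
            for m2 in range(n_mem):
                out[mx[m2], my[m2], mz[m2]] += increment
    return out
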