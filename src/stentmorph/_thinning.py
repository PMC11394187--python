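"""3D curve thinning by directional simple-point peeling.

Boundary voxels are peeled layer by layer in six directional
subiterations (up/down/north/south/east/west borders) until a fixed
point.  A voxel may be deleted only when it is *simple* — its removal
changes neither the foreground nor the background topology in its
3x3x3 neighbourhood — and not a curve endpoint (exactly one foreground
26-neighbour).  Simplicity uses the standard two-condition
characterization: the foreground 26-neighbours form exactly one
26-connected component, and the background 6-neighbours form exactly
one 6-connected component within the 18-neighbourhood.  Deletions are
sequential (each checked against the current image), so topology
preservation holds unconditionally; the six alternating directions keep
the residual curve close to the medial axis.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["thin"]

# 26-neighbour offsets, and the 6 face directions used for border passes
_OFF26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)
_DIRS = np.array(
    [(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0), (1, 0, 0), (-1, 0, 0)],
    dtype=np.int64,
)


@njit(cache=True)
def _neighborhood(img, x, y, z, out):
    """Copy the 3x3x3 neighbourhood of (x,y,z) into out (27 uint8, zero-padded)."""
    nx, ny, nz = img.shape
    k = 0
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                ax, ay, az = x + dx, y + dy, z + dz
                if 0 <= ax < nx and 0 <= ay < ny and 0 <= az < nz:
                    out[k] = img[ax, ay, az]
                else:
                    out[k] = 0
                k += 1


@njit(cache=True)
def _idx(dx, dy, dz):
    return (dx + 1) * 9 + (dy + 1) * 3 + (dz + 1)


@njit(cache=True)
def _fg_one_component(nb) -> tuple[int, int]:
    """(count, n_components) of the foreground 26-neighbours (centre excluded)."""
    visited = np.zeros(27, dtype=np.uint8)
    count = 0
    for k in range(27):
        if k != 13 and nb[k] == 1:
            count += 1
    ncomp = 0
    stack = np.empty(27, dtype=np.int64)
    for k in range(27):
        if k == 13 or nb[k] == 0 or visited[k]:
            continue
        ncomp += 1
        top = 0
        stack[top] = k
        top += 1
        visited[k] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            cx, cy, cz = cur // 9 - 1, (cur // 3) % 3 - 1, cur % 3 - 1
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        ax, ay, az = cx + dx, cy + dy, cz + dz
                        if ax < -1 or ax > 1 or ay < -1 or ay > 1 or az < -1 or az > 1:
                            continue
                        j = _idx(ax, ay, az)
                        if j == 13 or nb[j] == 0 or visited[j]:
                            continue
                        visited[j] = 1
                        stack[top] = j
                        top += 1
    return count, ncomp


@njit(cache=True)
def _bg_one_component(nb) -> bool:
    """True iff background 6-neighbours of the centre form one 6-connected
    component within the 18-neighbourhood (diagonal corners excluded)."""
    # collect background cells of the 18-neighbourhood
    in18 = np.zeros(27, dtype=np.uint8)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                s = abs(dx) + abs(dy) + abs(dz)
                if 1 <= s <= 2:
                    j = _idx(dx, dy, dz)
                    if nb[j] == 0:
                        in18[j] = 1
    # seeds: background 6-neighbours of the centre
    seeds = np.empty(6, dtype=np.int64)
    n_seeds = 0
    for d in range(6):
        j = _idx(_DIRS[d, 0], _DIRS[d, 1], _DIRS[d, 2])
        if in18[j]:
            seeds[n_seeds] = j
            n_seeds += 1
    if n_seeds == 0:
        return False  # interior voxel: not simple by this condition
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(18, dtype=np.int64)
    top = 0
    stack[top] = seeds[0]
    top += 1
    visited[seeds[0]] = 1
    while top > 0:
        top -= 1
        cur = stack[top]
        cx, cy, cz = cur // 9 - 1, (cur // 3) % 3 - 1, cur % 3 - 1
        for d in range(6):
            ax, ay, az = cx + _DIRS[d, 0], cy + _DIRS[d, 1], cz + _DIRS[d, 2]
            if ax < -1 or ax > 1 or ay < -1 or ay > 1 or az < -1 or az > 1:
                continue
            j = _idx(ax, ay, az)
            if in18[j] and not visited[j]:
                visited[j] = 1
                stack[top] = j
                top += 1
    for s in range(n_seeds):
        if not visited[seeds[s]]:
            return False
    return True


@njit(cache=True)
def _is_deletable(img, x, y, z, nb) -> bool:
    _neighborhood(img, x, y, z, nb)
    count, ncomp = _fg_one_component(nb)
    if count <= 1:  # isolated voxel or curve endpoint: keep
        return False
    if ncomp != 1:
        return False
    return _bg_one_component(nb)


@njit(cache=True)
def _thin_inplace(img) -> int:
    nx, ny, nz = img.shape
    nb = np.empty(27, dtype=np.uint8)
    removed_total = 0
    cand = np.empty((nx * ny * nz, 3), dtype=np.int64)
    changed = True
    while changed:
        changed = False
        for d in range(6):
            ox, oy, oz = _DIRS[d, 0], _DIRS[d, 1], _DIRS[d, 2]
            # mark this direction's border layer first, so one pass never
            # peels more than one voxel layer (keeps the skeleton centred)
            n_cand = 0
            for x in range(nx):
                for y in range(ny):
                    for z in range(nz):
                        if img[x, y, z] != 1:
                            continue
                        ax, ay, az = x + ox, y + oy, z + oz
                        if 0 <= ax < nx and 0 <= ay < ny and 0 <= az < nz and img[ax, ay, az] == 1:
                            continue
                        cand[n_cand, 0] = x
                        cand[n_cand, 1] = y
                        cand[n_cand, 2] = z
                        n_cand += 1
            # delete sequentially, rechecking against the current image so
            # topology preservation holds unconditionally
            for i in range(n_cand):
                x, y, z = cand[i, 0], cand[i, 1], cand[i, 2]
                if img[x, y, z] == 1 and _is_deletable(img, x, y, z, nb):
                    img[x, y, z] = 0
                    removed_total += 1
                    changed = True
    return removed_total


def thin(mask: np.ndarray) -> np.ndarray:
    """Thin a boolean 3D volume to a curve skeleton (same shape, bool)."""
    if mask.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not mask.any():
        return mask.astype(bool).copy()
    # crop to the bounding box for speed, restore afterwards
    idx = np.nonzero(mask)
    lo = [int(v.min()) for v in idx]
    hi = [int(v.max()) + 1 for v in idx]
    sub = np.ascontiguousarray(mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(np.uint8))
    _thin_inplace(sub)
    out = np.zeros_like(mask, dtype=bool)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub.astype(bool)
    return out
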