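"""Independent brute-force oracles used to verify the package.

Everything here is deliberately naive (python loops, recursion, BFS) and
shares no code with the package implementation.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def count_classes(labels, mask):
    """Per-class pixel counts within a mask, by explicit iteration."""
    counts = {}
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                counts[int(labels[r, c])] = counts.get(int(labels[r, c]), 0) + 1
    return counts


def components_8(mask):
    """8-connected components of a boolean image, as a list of pixel sets."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    y, x = q.popleft()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < h
                                and 0 <= nx < w
                                and mask[ny, nx]
                                and not seen[ny, nx]
                            ):
                                seen[ny, nx] = True
                                q.append((ny, nx))
                comps.append(comp)
    return comps


def reachable_8(mask, seeds):
    """Pixels of ``mask`` reachable (8-connected) from any seed pixel."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    q = deque()
    for r, c in seeds:
        if mask[r, c] and not seen[r, c]:
            seen[r, c] = True
            q.append((r, c))
    while q:
        y, x = q.popleft()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                    seen[ny, nx] = True
                    q.append((ny, nx))
    return seen


def quadtree_leaves_bruteforce(image, tol):
    """Recursive reference quadtree: list of half-open leaf rectangles."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    side = 1
    while side < max(h, w):
        side *= 2

    leaves = []

    def var_max(r0, r1, c0, c1):
        block = image[r0:r1, c0:c1].reshape(-1, image.shape[2])
        return float(block.var(axis=0).max())

    def recurse(sr0, sr1, sc0, sc1):
        r0, r1 = max(sr0, 0), min(sr1, h)
        c0, c1 = max(sc0, 0), min(sc1, w)
        if r1 <= r0 or c1 <= c0:
            return
        if var_max(r0, r1, c0, c1) <= tol or (sr1 - sr0 <= 1 and sc1 - sc0 <= 1):
            leaves.append((r0, r1, c0, c1))
            return
        rm, cm = (sr0 + sr1) // 2, (sc0 + sc1) // 2
        recurse(sr0, rm, sc0, cm)
        recurse(sr0, rm, cm, sc1)
        recurse(rm, sr1, sc0, cm)
        recurse(rm, sr1, cm, sc1)

    recurse(0, side, 0, side)
    return leaves


def leaf_bone_neighbour_counts(rectangles, bone_flags):
    """For each rectangle, how many bone rectangles share an edge segment."""
    counts = []
    for i, (r0, r1, c0, c1) in enumerate(rectangles):
        n = 0
        for j, (s0, s1, d0, d1) in enumerate(rectangles):
            if i == j or not bone_flags[j]:
                continue
            vert = (c1 == d0 or d1 == c0) and min(r1, s1) > max(r0, s0)
            horiz = (r1 == s0 or s1 == r0) and min(c1, d1) > max(c0, d0)
            if vert or horiz:
                n += 1
        counts.append(n)
    return counts


def volume_connected_faces(void, connectivity=26):
    """Brute-force 3D flood fill from the top face; True iff it reaches the
    bottom face through ``void`` voxels."""
    nz, ny, nx = void.shape
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros_like(void, dtype=bool)
    q = deque()
    for y in range(ny):
        for x in range(nx):
            if void[0, y, x]:
                seen[0, y, x] = True
                q.append((0, y, x))
    while q:
        z, y, x = q.popleft()
        if z == nz - 1:
            return True
        for dz, dy, dx in offsets:
            nz_, ny_, nx_ = z + dz, y + dy, x + dx
            if (
                0 <= nz_ < nz
                and 0 <= ny_ < ny
                and 0 <= nx_ < nx
                and void[nz_, ny_, nx_]
                and not seen[nz_, ny_, nx_]
            ):
                seen[nz_, ny_, nx_] = True
                q.append((nz_, ny_, nx_))
    return bool(seen[-1].any())
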