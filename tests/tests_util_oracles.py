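"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library code paths they check: per-pixel loops
for morphology and an all-pairs union-find for Euclidean clustering.
"""

import numpy as np


def brute_force_dilate(mask, k):
    """Per-pixel windowed max with border clipping."""
    h, w = mask.shape
    half = k // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            window = mask[max(0, i - half): i + half + 1,
                          max(0, j - half): j + half + 1]
            out[i, j] = 1 if window.any() else 0
    return out


def brute_force_components(mask):
    """8-connected flood fill returning lists of (row, col) pixels."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def union_find_partition(points, t):
    """Set-of-frozensets partition of the <= t proximity graph."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= t:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}
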