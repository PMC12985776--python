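"""Union-find kernels for persistent homology of 2D images.

Superlevel-set filtration on the pixel grid: degree-0 classes are tracked
directly (8-connected foreground); degree-1 classes (holes) are obtained by
Alexander duality as degree-0 classes of the growing complement
(4-connected background on a padded grid).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# neighbour offsets: orthogonal first, then diagonal
_DR = np.array([-1, 1, 0, 0, -1, -1, 1, 1], dtype=np.int64)
_DC = np.array([0, 0, -1, 1, -1, 1, -1, 1], dtype=np.int64)


@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _uf_merge_pairs(order, vals, nrows, ncols, use8, keep_essential):
    """Run the union-find filtration defined by ``order``.

    Pixels are activated one by one in ``order``; whenever two components
    merge at the current pixel value ``v`` the younger component (activated
    later) dies and the pair ``(birth_value_of_young_root, v)`` is emitted.
    If ``keep_essential`` the surviving roots are emitted as
    ``(birth_value, value_of_last_pixel)``.
    """
    n = nrows * ncols
    parent = np.full(n, -1, dtype=np.int64)
    birth = np.empty(n, dtype=np.float64)
    when = np.empty(n, dtype=np.int64)  # activation rank, for the elder rule
    nnb = 8 if use8 else 4

    out_b = np.empty(n, dtype=np.float64)
    out_d = np.empty(n, dtype=np.float64)
    m = 0

    for pos in range(order.shape[0]):
        idx = order[pos]
        parent[idx] = idx
        birth[idx] = vals[idx]
        when[idx] = pos
        r = idx // ncols
        c = idx % ncols
        v = vals[idx]
        for k in range(nnb):
            rr = r + _DR[k]
            cc = c + _DC[k]
            if rr < 0 or rr >= nrows or cc < 0 or cc >= ncols:
                continue
            q = rr * ncols + cc
            if parent[q] < 0:
                continue
            ra = _find(parent, idx)
            rb = _find(parent, q)
            if ra == rb:
                continue
            # elder rule: the root activated earlier survives
            if when[ra] < when[rb]:
                elder, young = ra, rb
            else:
                elder, young = rb, ra
            out_b[m] = birth[young]
            out_d[m] = v
            m += 1
            parent[young] = elder

    n_merge = m
    if keep_essential:
        last_v = vals[order[order.shape[0] - 1]]
        for pos in range(order.shape[0]):
            idx = order[pos]
            if parent[idx] == idx:
                out_b[m] = birth[idx]
                out_d[m] = last_v
                m += 1

    return out_b[:m].copy(), out_d[:m].copy(), n_merge


def superlevel_pairs(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Persistence pairs of the superlevel-set filtration of ``image``.

    Returns ``(pts0, pts1)``, each an ``(n, 2)`` array of (birth, death) in
    sign-flipped intensity units so that ``death >= birth``; the persistence
    ``death - birth`` equals the intensity range over which the feature
    lives.  Degree 0 includes one essential class per connected component of
    the full image (death at the global minimum).  Zero-persistence
    non-essential pairs are dropped.
    """
    img = np.ascontiguousarray(image, dtype=np.float64)
    nr, nc = img.shape
    flat = img.ravel()

    # --- degree 0: activate pixels from high to low intensity, 8-connected
    order0 = np.argsort(-flat, kind="stable").astype(np.int64)
    b0, d0, n_merge = _uf_merge_pairs(order0, flat, nr, nc, True, True)
    # b0 = birth intensity (high), d0 = death intensity (low); flip sign.
    # Merge pairs with zero persistence are diagonal points and dropped;
    # essential classes (one per component, at the tail) are always kept.
    pers0 = b0[:n_merge] - d0[:n_merge]
    keep = np.concatenate((pers0 > 0, np.ones(b0.shape[0] - n_merge, dtype=bool)))
    pts0 = np.column_stack((-b0[keep], -d0[keep]))

    # --- degree 1 by duality: grow the complement from low to high
    # intensity, 4-connected, on a padded grid whose border is the eldest
    # component (below the global minimum).
    pad_val = flat.min() - 1.0
    padded = np.full((nr + 2, nc + 2), pad_val, dtype=np.float64)
    padded[1:-1, 1:-1] = img
    pflat = padded.ravel()
    order1 = np.argsort(pflat, kind="stable").astype(np.int64)
    m1, v1, _ = _uf_merge_pairs(order1, pflat, nr + 2, nc + 2, False, False)
    # a merge at value v of a component with minimum m corresponds to a hole
    # of the superlevel set born at level v and dying at level m
    keep = v1 > m1
    hole_birth = v1[keep]
    hole_death = m1[keep]
    pts1 = np.column_stack((-hole_birth, -hole_death))
    return pts0, pts1
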