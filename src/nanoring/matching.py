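"""Greedy mutual-nearest-neighbor matching between two point sets.

Shared by ring–ring pairing and cluster–cluster alignment.  Pairs are
accepted in increasing distance order, each point used at most once, which
is equivalent to iterated mutual-nearest-neighbor matching.  Deterministic:
distance ties are broken by lexicographic index order.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def greedy_mutual_match(
    a_xy: np.ndarray,
    b_xy: np.ndarray,
    max_dist: float | None = None,
) -> list[tuple[int, int, float]]:
    """Match rows of ``a_xy`` to rows of ``b_xy`` (each shape (n, 2), nm).

    Returns ``[(i_a, i_b, distance), ...]`` sorted by increasing distance.
    If ``max_dist`` is given, pairs farther than it are not formed.
    """
    a_xy = np.asarray(a_xy, float).reshape(-1, 2)
    b_xy = np.asarray(b_xy, float).reshape(-1, 2)
    if len(a_xy) == 0 or len(b_xy) == 0:
        return []
    d = cdist(a_xy, b_xy)
    ii, jj = np.meshgrid(np.arange(len(a_xy)), np.arange(len(b_xy)), indexing="ij")
    order = np.lexsort((jj.ravel(), ii.ravel(), d.ravel()))
    used_a = np.zeros(len(a_xy), bool)
    used_b = np.zeros(len(b_xy), bool)
    out: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(ii.ravel()[k]), int(jj.ravel()[k])
        dist = float(d[i, j])
        if max_dist is not None and dist > max_dist:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        out.append((i, j, dist))
        if used_a.all() or used_b.all():
            break
    return out
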