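"""Shared independent oracles and hand-built fixtures for the test suite.

Everything here is deliberately written as plain loops, independent of the
vectorised library code it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from trcmgene.refsel import ZONE_AI, ZONE_AII, ZONE_B, ZonePartition


def loop_distance(a, b, missing_code=None) -> float:
    """Term-by-term scaled Euclidean distance (reference implementation)."""
    assert len(a) == len(b)
    ss = 0.0
    n_shared = 0
    for x, y in zip(a, b):
        if missing_code is not None and (x == missing_code or y == missing_code):
            continue
        ss += (float(x) - float(y)) ** 2
        n_shared += 1
    if missing_code is None:
        return math.sqrt(ss)
    if n_shared == 0:
        return 0.0
    return math.sqrt(ss * len(a) / n_shared)


def brute_force_wcss(points: np.ndarray, k: int) -> float:
    """Globally optimal k-means WCSS by exhaustive partition enumeration."""
    n = points.shape[0]
    best = math.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        w = 0.0
        for c in range(k):
            rows = [i for i in range(n) if assign[i] == c]
            mu = points[rows].mean(axis=0)
            w += float(((points[rows] - mu) ** 2).sum())
        best = min(best, w)
    return best


def brute_force_references(partition: ZonePartition, members: np.ndarray,
                           delta_d: float | None = None,
                           missing_code=None) -> dict:
    """Loop-based re-derivation of the peer search: for each B member, grow
    the block radius from the ring width by delta_d until an eligible
    zone-A candidate appears (A(II) only before the first growth), pick the
    nearest (ties by lower global row), and share the reference with
    unassigned B members inside the final block.

    Returns {local index: (ref_global_row, radius, hops, shared_from)}.
    """
    labels = partition.labels
    rows = partition.member_rows
    m = len(rows)
    b_idx = [i for i in range(m) if labels[i] == ZONE_B]
    a_idx = [i for i in range(m) if labels[i] != ZONE_B]
    a_outer = [i for i in range(m) if labels[i] == ZONE_AII]
    out: dict = {}
    if not b_idx or not a_idx:
        return out
    r0 = partition.ring_width
    if r0 <= 0:
        r0 = max(max(partition.distances[i] for i in b_idx) - partition.t1, 0.0)
    dd = delta_d if delta_d is not None else (r0 / 4 if r0 > 0 else partition.t1 / 4)
    eps = 1e-12

    def d(i, j):
        return loop_distance(members[i], members[j], missing_code)

    order = sorted(b_idx, key=lambda i: (partition.distances[i], i))
    assigned = set()
    for bi in order:
        if bi in assigned:
            continue
        r = r0
        hops = 0
        pool = a_outer
        while True:
            cands = [j for j in pool if d(bi, j) <= r + eps]
            if cands:
                break
            hops += 1
            r += dd
            pool = a_idx
        best = min(cands, key=lambda j: (d(bi, j), rows[j]))
        out[bi] = (int(rows[best]), r, hops, -1)
        assigned.add(bi)
        for bj in b_idx:
            if bj not in assigned and d(bi, bj) <= r + eps:
                out[bj] = (int(rows[best]), r, hops, int(rows[bi]))
                assigned.add(bj)
    return out


def fig_style_cluster():
    """An 11-point 2-D cluster mimicking the toy two-zone topology.

    Point indices 0..10 stand for P1..P11.  With t1=4, t2=2 the zones are
    A(I) = {P1, P2, P3, P9}, A(II) = {P5, P6, P7, P11}, B = {P4, P8, P10};
    the ring width is R_K - t1 = 1.5.  By construction P4 finds P5 in its
    initial block and P10 shares it, while P8 needs several radius growths
    before reaching P11.
    """
    pts = np.array([
        [0.0, 0.0],     # P1
        [0.5, 0.0],     # P2
        [-1.0, 0.5],    # P3
        [4.5, 0.0],     # P4  (zone B)
        [3.0, 0.0],     # P5  (zone A_II)
        [-3.0, 0.5],    # P6
        [2.5, -1.5],    # P7
        [0.0, 5.5],     # P8  (zone B, needs radius growth)
        [-0.5, 1.0],    # P9
        [5.0, 0.5],     # P10 (zone B, shares P4's block)
        [0.0, 2.6],     # P11 (zone A_II, P8's eventual reference)
    ])
    dist = np.sqrt((pts ** 2).sum(axis=1))
    t1, t2 = 4.0, 2.0
    labels = np.full(11, ZONE_B, dtype=np.int8)
    labels[dist <= t1] = ZONE_AII
    labels[dist <= t2] = ZONE_AI
    part = ZonePartition(cluster=0, member_rows=np.arange(11),
                         distances=dist, labels=labels, t1=t1, t2=t2,
                         ring_width=float(dist.max() - t1))
    return pts, part
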