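"""Two-step reference selection: zone partitioning and kNN peer search.

Each converged cluster is split by two distance thresholds T1 > T2 into an
inner disc A(I) (distance to centre <= T2), an outer near-annulus A(II)
(T2 < distance <= T1) and a far ring B (distance > T1) of width
R = R_K - T1.  Zone-A sequences compress well against the cluster core and
are encoded against it (one-step mode).  Zone-B sequences are poorly
predicted by the core; each gets a peer reference instead: a search block S
— a sphere of radius R centred on the B sequence — is scanned for A(II)
candidates, the radius growing by increments of delta_d whenever the block
is empty (eligibility widening to all of zone A after the first growth), and
the nearest candidate becomes the reference.  Other still-unassigned B
sequences inside the same final block share that reference, which both
bounds the kNN training set and keeps the reference graph a two-level
forest: cores -> centre-encoded rows -> peer-encoded rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .clustering import ClusterModel
from .genotype_io import (
    MISSING_CODE,
    GenotypeMatrix,
    pairwise_row_sq_distances,
    pairwise_sq_distances,
)

logger = logging.getLogger(__name__)

# zone labels
ZONE_AI, ZONE_AII, ZONE_B = 0, 1, 2
# reference kinds
KIND_CENTRE, KIND_PEER = 0, 1



@dataclass
class ZonePartition:
    """Zone labels and distances for the members of one cluster."""

    cluster: int
    member_rows: np.ndarray      # global row indices, ascending
    distances: np.ndarray        # distance to the cluster centre
    labels: np.ndarray           # ZONE_AI / ZONE_AII / ZONE_B per member
    t1: float
    t2: float
    ring_width: float


@dataclass
class ReferenceAssignment:
    """Per-sequence reference choice for the whole panel.

    ``kind`` is KIND_CENTRE or KIND_PEER; ``ref`` is the cluster index for
    centre-encoded rows and the global row index of the peer otherwise.
    ``shared_from`` is -1 for directly searched rows, else the row whose
    search block this row inherited its reference from.
    """

    kind: np.ndarray
    ref: np.ndarray
    zone: np.ndarray
    radius: np.ndarray
    hops: np.ndarray
    shared_from: np.ndarray
    cluster_params: list[dict] = field(default_factory=list)

    @property
    def peer_fraction(self) -> float:
        n = self.kind.shape[0]
        return float((self.kind == KIND_PEER).sum() / n) if n else 0.0


def _member_distances(matrix, model: ClusterModel, cluster: int) -> tuple[np.ndarray, np.ndarray]:
    rows = model.members(cluster)
    if isinstance(matrix, GenotypeMatrix):
        x = matrix.codes.astype(np.float64)
        observed = matrix.codes != MISSING_CODE
    else:
        x = np.asarray(matrix, dtype=np.float64)
        observed = np.ones(x.shape, dtype=bool)
    d2 = pairwise_sq_distances(x[rows], model.centres[cluster][None, :],
                               observed[rows])[:, 0]
    return rows, np.sqrt(d2)


def partition_cluster(matrix, model: ClusterModel, cluster: int,
                      t1: float, t2: float) -> ZonePartition:
    """Label each member of ``cluster`` as A(I), A(II) or B by T1 > T2 > 0."""
    if not (t1 > t2 > 0):
        raise ParameterError(f"thresholds must satisfy t1 > t2 > 0, got "
                             f"t1={t1}, t2={t2}")
    rows, dist = _member_distances(matrix, model, cluster)
    labels = np.full(rows.shape[0], ZONE_B, dtype=np.int8)
    labels[dist <= t1] = ZONE_AII
    labels[dist <= t2] = ZONE_AI
    ring = max(float(model.radii[cluster]) - t1, 0.0)
    return ZonePartition(cluster=cluster, member_rows=rows, distances=dist,
                         labels=labels, t1=float(t1), t2=float(t2),
                         ring_width=ring)


def auto_thresholds(matrix, model: ClusterModel, cluster: int,
                    q1: float = 0.8, q2: float = 0.5) -> tuple[float, float]:
    """Pick (T1, T2) as the q1- and q2-quantiles of member distances.

    Linear-interpolation quantiles; coinciding quantiles are nudged apart so
    T1 > T2 > 0 always holds.  Clusters with fewer than two members fall back
    to (R_K, R_K / 2).
    """
    if not (0 < q2 < q1 < 1):
        raise ParameterError(f"quantiles must satisfy 0 < q2 < q1 < 1, got "
                             f"q1={q1}, q2={q2}")
    rows, dist = _member_distances(matrix, model, cluster)
    r_k = float(model.radii[cluster])
    if rows.size < 2:
        r_k = r_k if r_k > 0 else 1.0
        return r_k, r_k / 2
    t1 = float(np.quantile(dist, q1))
    t2 = float(np.quantile(dist, q2))
    if t2 <= 0:
        t2 = max(t1 / 2, 1e-9)
    if t1 <= t2:
        t1 = t2 + max(1e-9, 1e-9 * t2)
    return t1, t2


@dataclass
class ClusterReferences:
    """Per-member reference choices for one cluster (aligned with the
    partition's ``member_rows``)."""

    kind: np.ndarray
    ref: np.ndarray
    radius: np.ndarray
    hops: np.ndarray
    shared_from: np.ndarray


def select_references(partition: ZonePartition, members, *,
                      delta_d: float | None = None, knn_k: int = 1,
                      missing_code: int | None = MISSING_CODE) -> ClusterReferences:
    """Choose a reference for every member of one partitioned cluster.

    ``members`` are the member rows (genotype codes or plain points), aligned
    with ``partition.member_rows``.  Zone-A members are centre-encoded.  Each
    zone-B member, processed in increasing distance-to-centre order, searches
    its block S (initial radius = ring width) for A(II) candidates, growing
    the radius by ``delta_d`` (default ring width / 4) and widening
    eligibility to all of zone A after the first growth; the nearest
    candidate wins, distance ties broken by lower global row index.  Other
    unassigned B members inside the final block share the reference.
    """
    if knn_k < 1:
        raise ParameterError(f"knn_k must be >= 1, got {knn_k}")
    members = np.atleast_2d(np.asarray(members))
    m = partition.member_rows.shape[0]
    if members.shape[0] != m:
        raise ParameterError(
            f"{members.shape[0]} member rows for a partition of {m}")
    labels = partition.labels
    kind = np.zeros(m, dtype=np.int8)
    ref = np.full(m, partition.cluster, dtype=np.int64)
    radius = np.zeros(m, dtype=np.float64)
    hops = np.zeros(m, dtype=np.int64)
    shared_from = np.full(m, -1, dtype=np.int64)

    b_local = np.nonzero(labels == ZONE_B)[0]
    if b_local.size == 0:
        return ClusterReferences(kind, ref, radius, hops, shared_from)

    a_all = np.nonzero(labels != ZONE_B)[0]
    a_outer = np.nonzero(labels == ZONE_AII)[0]
    if a_all.size == 0:
        logger.warning(
            "cluster %d: zone A empty (all %d members beyond t1=%.4g); "
            "falling back to centre encoding", partition.cluster, m,
            partition.t1)
        return ClusterReferences(kind, ref, radius, hops, shared_from)

    r0 = partition.ring_width
    if r0 <= 0:
        r0 = max(float(partition.distances.max()) - partition.t1, 0.0)
    if delta_d is None:
        delta_d = r0 / 4 if r0 > 0 else max(partition.t1 / 4, 1e-9)
    if delta_d <= 0:
        raise ParameterError(f"delta_d must be positive, got {delta_d}")

    # distances of every B member to every A member, and among B members
    d_ba = np.sqrt(pairwise_row_sq_distances(members[b_local], members[a_all],
                                             missing_code))
    d_bb = np.sqrt(pairwise_row_sq_distances(members[b_local], members[b_local],
                                             missing_code))
    outer_mask = np.isin(a_all, a_outer)

    order = np.argsort(partition.distances[b_local], kind="stable")
    assigned = np.zeros(b_local.size, dtype=bool)
    eps = 1e-12
    for bi in order:
        if assigned[bi]:
            continue
        r = r0
        n_hops = 0
        eligible = outer_mask.copy()
        while True:
            cand = np.nonzero(eligible & (d_ba[bi] <= r + eps))[0]
            if cand.size:
                break
            if n_hops == 0:
                n_hops = 1
                r += delta_d
                eligible = np.ones(a_all.size, dtype=bool)  # widen to all of A
            else:
                # eligibility already covers all of zone A, so the number of
                # remaining delta_d growths needed to reach the nearest
                # candidate is known in closed form; jumping there keeps the
                # grown radius on the r0 + n * delta_d grid while bounding
                # the loop even when delta_d is tiny (degenerate ring width)
                d_min = float(d_ba[bi][eligible].min())
                steps = max(int(math.ceil((d_min - eps - r) / delta_d)), 1)
                n_hops += steps
                r += steps * delta_d
        # knn_k nearest candidates, then the single nearest; distance ties
        # broken by lower global row index
        cd = d_ba[bi][cand]
        grows = partition.member_rows[a_all[cand]]
        pick = cand[np.lexsort((grows, cd))[:knn_k]][0] if cand.size > 1 else cand[0]
        chosen_row = int(partition.member_rows[a_all[pick]])

        li = int(b_local[bi])
        kind[li] = KIND_PEER
        ref[li] = chosen_row
        radius[li] = r
        hops[li] = n_hops
        assigned[bi] = True
        # unassigned B members inside the same block share the reference
        inside = np.nonzero(~assigned & (d_bb[bi] <= r + eps))[0]
        for bj in inside:
            lj = int(b_local[bj])
            kind[lj] = KIND_PEER
            ref[lj] = chosen_row
            radius[lj] = r
            hops[lj] = n_hops
            shared_from[lj] = partition.member_rows[li]
            assigned[bj] = True
    return ClusterReferences(kind, ref, radius, hops, shared_from)


def assign_references(matrix, model: ClusterModel, *, mode: str = "trcm",
                      thresholds: list[tuple[float, float]] | None = None,
                      q1: float = 0.8, q2: float = 0.5,
                      delta_d: float | None = None, knn_k: int = 1) -> ReferenceAssignment:
    """Run partition + peer search over every cluster of the panel.

    ``mode="orcm"`` forces centre encoding for every sequence (T1 = inf
    semantics).  ``thresholds`` optionally supplies explicit (t1, t2) per
    cluster; otherwise quantile-based thresholds are derived per cluster.
    """
    if mode not in ("trcm", "orcm"):
        raise ParameterError(f"mode must be 'trcm' or 'orcm', got {mode!r}")
    if isinstance(matrix, GenotypeMatrix):
        data = matrix.codes
        n = matrix.n_individuals
        missing_code: int | None = MISSING_CODE
    else:
        data = np.atleast_2d(np.asarray(matrix))
        n = data.shape[0]
        missing_code = None

    kind = np.zeros(n, dtype=np.int8)
    ref = np.zeros(n, dtype=np.int64)
    zone = np.zeros(n, dtype=np.int8)
    radius = np.zeros(n, dtype=np.float64)
    hops = np.zeros(n, dtype=np.int64)
    shared_from = np.full(n, -1, dtype=np.int64)
    params: list[dict] = []

    for cluster in range(model.n_clusters):
        if mode == "orcm":
            rows, dist = _member_distances(matrix, model, cluster)
            t2 = max(float(model.radii[cluster]) / 2, 1e-9)
            part = ZonePartition(cluster=cluster, member_rows=rows,
                                 distances=dist,
                                 labels=np.where(dist <= t2, ZONE_AI,
                                                 ZONE_AII).astype(np.int8),
                                 t1=math.inf, t2=t2, ring_width=0.0)
        else:
            if thresholds is not None:
                t1, t2 = thresholds[cluster]
            else:
                t1, t2 = auto_thresholds(matrix, model, cluster, q1, q2)
            part = partition_cluster(matrix, model, cluster, t1, t2)
        refs = select_references(part, data[part.member_rows],
                                 delta_d=delta_d, knn_k=knn_k,
                                 missing_code=missing_code)
        rows = part.member_rows
        kind[rows] = refs.kind
        ref[rows] = np.where(refs.kind == KIND_CENTRE, cluster, refs.ref)
        zone[rows] = part.labels
        radius[rows] = refs.radius
        hops[rows] = refs.hops
        shared_from[rows] = refs.shared_from
        params.append({"cluster": cluster, "t1": part.t1, "t2": part.t2,
                       "ring_width": part.ring_width,
                       "n_members": int(rows.size),
                       "n_peer": int((refs.kind == KIND_PEER).sum())})
    return ReferenceAssignment(kind=kind, ref=ref, zone=zone, radius=radius,
                               hops=hops, shared_from=shared_from,
                               cluster_params=params)
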