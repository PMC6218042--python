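"""Lloyd-style K-means over digitized genotype sequences.

The cluster centres ("core sequences") are the references for one-step
referential compression: every member of cluster K is later delta-encoded
against that cluster's core.  The algorithm is deliberately pinned down for
bit-for-bit reproducibility:

* initial centres are k distinct rows sampled uniformly by the seed;
* assignment ties and near-ties (within 1e-12) keep the current membership,
  so duplicated points cannot oscillate;
* a cluster emptied by an iteration is repaired by reseeding its centre to
  the point currently farthest from its own centre (that point is moved to
  the repaired cluster);
* iteration stops at a membership fixed point, at ``max_iter``, or when no
  centre moves more than ``tol``.

Distances are the same missing-aware scaled Euclidean distances used
throughout the package.  Real-valued means are used for assignment; the
integer "core sequence" stored in the container is the coordinate-wise mean
rounded half-up into {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .genotype_io import MISSING_CODE, GenotypeMatrix, pairwise_sq_distances

_TIE_TOL = 1e-12


@dataclass
class ClusterModel:
    """Converged K-means state: centres, cores, assignment, radii, WCSS."""

    n_clusters: int
    centres: np.ndarray          # (K, E) real-valued means
    cores: np.ndarray            # (K, E) integer core sequences in {0,1,2}
    assignment: np.ndarray       # (N,) cluster index per sequence
    radii: np.ndarray            # (K,) max member distance to centre
    wcss: float
    wcss_history: list[float] = field(default_factory=list)
    seed: int = 0
    n_iterations: int = 0

    @property
    def n_sequences(self) -> int:
        return self.assignment.shape[0]

    def members(self, cluster: int) -> np.ndarray:
        """Row indices assigned to ``cluster``."""
        if not 0 <= cluster < self.n_clusters:
            raise ParameterError(f"cluster index {cluster} out of range")
        return np.nonzero(self.assignment == cluster)[0]


def _as_data(data) -> tuple[np.ndarray, np.ndarray]:
    """Return (float matrix, observed mask) for a GenotypeMatrix or ndarray."""
    if isinstance(data, GenotypeMatrix):
        x = data.codes.astype(np.float64)
        observed = data.codes != MISSING_CODE
    else:
        x = np.asarray(data, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        observed = np.ones(x.shape, dtype=bool)
    return x, observed


def _column_means(x: np.ndarray, observed: np.ndarray, rows: np.ndarray,
                  fallback: np.ndarray) -> np.ndarray:
    """Mean of each column over observed entries of ``rows``; ``fallback``
    supplies columns with no observed member value."""
    sub = x[rows]
    obs = observed[rows]
    counts = obs.sum(axis=0)
    sums = np.where(obs, sub, 0.0).sum(axis=0)
    mean = np.divide(sums, counts, out=fallback.astype(np.float64).copy(),
                     where=counts > 0)
    return mean


def kmeans_cluster(data, k: int, seed: int, max_iter: int = 100,
                   tol: float = 1e-9, n_init: int = 4) -> ClusterModel:
    """Cluster sequences into ``k`` groups; returns a converged model.

    ``data`` is a :class:`GenotypeMatrix` (missing-aware) or a plain 2-D
    array of points.  ``n_init`` independent seeded restarts are run and the
    model with the lowest WCSS kept (restarts escape the merged-cluster
    local optima a single random row init falls into).  Identical
    (data, k, seed) always yields an identical model.
    """
    if n_init < 1:
        raise ParameterError(f"n_init must be >= 1, got {n_init}")
    x, observed = _as_data(data)
    n, e = x.shape
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if k > n:
        raise ParameterError(f"k={k} exceeds number of sequences N={n}")
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(n_init):
        init_rows = np.sort(rng.choice(n, size=k, replace=False))
        model = _kmeans_once(x, observed, k, init_rows, max_iter, tol, seed)
        if best is None or model.wcss < best.wcss:
            best = model
    return best


def _kmeans_once(x: np.ndarray, observed: np.ndarray, k: int,
                 init_rows: np.ndarray, max_iter: int, tol: float,
                 seed: int) -> ClusterModel:
    n, e = x.shape
    # global column means fill missing entries when a row seeds a centre
    global_mean = _column_means(x, observed, np.arange(n),
                                np.zeros(e)) if e else np.zeros(0)
    centres = np.where(observed[init_rows], x[init_rows], global_mean[None, :]) \
        if e else np.zeros((k, 0))

    assign = np.full(n, -1, dtype=np.int64)
    wcss_history: list[float] = []
    n_iterations = 0
    stop_next = False
    for iteration in range(1, max_iter + 1):
        n_iterations = iteration
        d2 = pairwise_sq_distances(x, centres, observed)
        new = np.argmin(d2, axis=1)
        if assign[0] != -1:
            # sticky ties: keep current membership when distances (near-)tie
            cur_d = d2[np.arange(n), assign]
            best_d = d2[np.arange(n), new]
            keep = np.abs(cur_d - best_d) <= _TIE_TOL
            new = np.where(keep, assign, new)

        # repair clusters emptied by this assignment
        empty = np.setdiff1d(np.arange(k), np.unique(new))
        for cluster in empty:
            own = d2[np.arange(n), new]
            far = int(np.argmax(own))
            centres[cluster] = np.where(observed[far], x[far], global_mean) \
                if e else centres[cluster]
            d2[:, cluster] = pairwise_sq_distances(x, centres[cluster][None, :],
                                                   observed)[:, 0]
            new[far] = cluster

        wcss_history.append(float(d2[np.arange(n), new].sum()))
        if np.array_equal(new, assign):
            break
        assign = new
        if stop_next:
            break
        old_centres = centres.copy()
        for cluster in range(k):
            rows = np.nonzero(assign == cluster)[0]
            if rows.size:
                centres[cluster] = _column_means(x, observed, rows,
                                                 centres[cluster])
        if np.max(np.abs(centres - old_centres), initial=0.0) <= tol:
            stop_next = True  # one more assignment pass, then stop

    d2 = pairwise_sq_distances(x, centres, observed)
    dist = np.sqrt(d2[np.arange(n), assign]) if n else np.zeros(0)
    radii = np.zeros(k)
    cores = np.zeros((k, e), dtype=np.int8)
    for cluster in range(k):
        rows = np.nonzero(assign == cluster)[0]
        if rows.size:
            radii[cluster] = float(dist[rows].max())
            mean = _column_means(x, observed, rows, centres[cluster]) if e else centres[cluster]
        else:  # unreachable after repair; defensive
            mean = centres[cluster]
        cores[cluster] = np.clip(np.floor(mean + 0.5), 0, 2).astype(np.int8) \
            if e else cores[cluster]

    return ClusterModel(
        n_clusters=k, centres=centres, cores=cores, assignment=assign,
        radii=radii, wcss=wcss_history[-1] if wcss_history else 0.0,
        wcss_history=wcss_history, seed=seed, n_iterations=n_iterations,
    )


def core_sequence(model: ClusterModel, cluster: int) -> np.ndarray:
    """Integer core sequence (rounded mean in {0,1,2}) for one cluster."""
    if not 0 <= cluster < model.n_clusters:
        raise ParameterError(
            f"cluster index {cluster} out of range [0, {model.n_clusters})"
        )
    return model.cores[cluster]
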