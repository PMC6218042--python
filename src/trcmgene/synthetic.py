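"""Synthetic genotype panels with controllable cluster structure.

The generator emulates a panel of N individuals typed at E bi-allelic
markers, organised into founder clusters:

* each cluster has a founder genotype drawn uniformly from {0,1,2}^E;
* a *core* member copies its founder and mutates each marker independently
  with probability ``mu_in`` (to a different value in {0,1,2});
* a *ring* fraction ``rho`` of each cluster's members instead lies on a
  shared per-cluster drift path: the cluster owns an ordered list of
  ``mu_ring * E`` drift mutations, and a ring member at depth t in (0, 1]
  carries the first ``t * mu_ring * E`` of them (plus its own ``mu_in``
  noise).  Ring members are therefore poorly predicted by the cluster
  centre but well predicted by slightly shallower ring members — the
  low-centre-correlation / high-peer-correlation regime that the two-step
  peer-reference search exploits;
* missing genotypes are sprinkled uniformly at ``missing_rate`` (at least
  one observed genotype is kept per marker so allele inference stays
  well-posed).

Codes are canonicalised so that code = minor-allele count holds marker-wise
(columns where 2 outnumbers 0 are flipped), making
write -> read -> digitize reproduce the codes exactly.  Alleles are A
(major) and C (minor) at every marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .genotype_io import (
    MISSING_CODE,
    GenotypeMatrix,
    MarkerInfo,
    RawPanel,
    undigitize,
)
from .genotype_io import write_ped as _write_ped_raw


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of one synthetic panel."""

    n_individuals: int = 300
    n_markers: int = 1000
    n_clusters: int = 3
    mu_in: float = 0.02          # per-marker core mutation rate
    rho: float = 0.1             # ring fraction per cluster
    mu_ring: float = 0.2         # maximal drift fraction of ring members
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_in", "rho", "mu_ring", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.mu_ring < self.mu_in:
            raise ParameterError(
                f"mu_ring={self.mu_ring} must be >= mu_in={self.mu_in}")
        if not self.n_individuals >= self.n_clusters >= 1:
            if self.n_individuals == 0:
                return  # empty panel allowed
            raise ParameterError(
                f"need N >= n_clusters >= 1, got N={self.n_individuals}, "
                f"n_clusters={self.n_clusters}")


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> None:
    """Mutate each entry independently with ``rate`` to a different value."""
    if rate <= 0 or codes.size == 0:
        return
    hit = rng.random(codes.shape) < rate
    shift = rng.integers(1, 3, size=codes.shape)  # +1 or +2 mod 3 != identity
    codes[hit] = (codes[hit] + shift[hit]) % 3


def generate_panel(spec: PanelSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Generate a panel; returns (matrix, true founder labels).

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, e, c = spec.n_individuals, spec.n_markers, spec.n_clusters
    if n == 0:
        markers = [_marker(i, 0.0) for i in range(e)]
        return GenotypeMatrix([], markers, np.zeros((0, e), dtype=np.int8)), \
            np.zeros(0, dtype=np.int64)

    founders = rng.integers(0, 3, size=(c, e)).astype(np.int8)
    labels = np.sort(np.arange(n) % c)  # near-equal cluster sizes
    codes = founders[labels].copy()

    # drift paths: per cluster an ordered list of positions and new values
    n_drift = int(round(spec.mu_ring * e))
    drift_pos = np.array([rng.permutation(e)[:n_drift] for _ in range(c)],
                         dtype=np.int64).reshape(c, n_drift)
    drift_shift = rng.integers(1, 3, size=(c, n_drift))

    ring = np.zeros(n, dtype=bool)
    for cluster in range(c):
        members = np.nonzero(labels == cluster)[0]
        n_ring = int(round(spec.rho * members.size))
        if n_ring == 0:
            continue
        chosen = rng.choice(members, size=n_ring, replace=False)
        ring[chosen] = True
        depth = rng.uniform(0.0, 1.0, size=n_ring)
        for member, t in zip(chosen, depth):
            m = int(np.ceil(t * n_drift))
            pos = drift_pos[cluster, :m]
            codes[member, pos] = (codes[member, pos]
                                  + drift_shift[cluster, :m]) % 3

    _mutate(rng, codes, spec.mu_in)

    if spec.missing_rate > 0 and n and e:
        miss = rng.random(codes.shape) < spec.missing_rate
        # keep at least one observed genotype per marker
        all_missing = miss.all(axis=0)
        miss[0, all_missing] = False
        codes[miss] = MISSING_CODE

    # canonicalise on *observed* genotypes: code must equal minor-allele
    # count per marker, ties keeping A (the lexicographically smaller
    # allele) as major — exactly the rule allele inference applies on read
    if n and e:
        obs = codes != MISSING_CODE
        allele_c = np.where(obs, codes, 0).sum(axis=0)
        flip = allele_c * 2 > obs.sum(axis=0) * 2  # C strictly the majority
        if flip.any():
            sub = codes[:, flip]
            sub_obs = sub != MISSING_CODE
            sub[sub_obs] = 2 - sub[sub_obs]
            codes[:, flip] = sub

    markers = []
    for i in range(e):
        col = codes[:, i]
        obs = col[col != MISSING_CODE]
        maf = float(obs.sum() / (2 * obs.size)) if obs.size else 0.0
        markers.append(_marker(i, maf))
    ids = [f"IND{i:06d}" for i in range(n)]
    return GenotypeMatrix(ids, markers, codes), labels


def _marker(i: int, maf: float) -> MarkerInfo:
    return MarkerInfo(marker_id=f"SNP{i:06d}", allele_a="A", allele_b="C",
                      maf=maf, position_index=i)


def write_ped(matrix: GenotypeMatrix, ped_path, map_path=None, *,
              dialect: str = "ped") -> None:
    """Write a generated (or decoded) panel to PED/MAP files."""
    raw: RawPanel = undigitize(matrix)
    _write_ped_raw(raw, ped_path, map_path, dialect=dialect)
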