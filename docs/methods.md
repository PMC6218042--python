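# Methods

This note records the model, the default parameters and their rationale,
the numerical conventions, and known limitations. The container byte layout
is specified separately in [FORMAT.md](FORMAT.md).

## Digitization

Each biallelic marker is digitized to the count of its minor allele:
`0` = homozygous major, `1` = heterozygous, `2` = homozygous minor,
`3` = missing. Major/minor are decided from observed allele counts over the
panel (missing genotypes, written `0 0` in PED, are excluded); an exact
50/50 tie takes the lexicographically smaller allele character as major, so
digitization is deterministic. Monomorphic markers get a placeholder minor
allele (`N`) with MAF 0. Because the marker table (both alleles, in order)
is stored in the container, digitization is exactly invertible, including
heterozygote allele order (always written major-then-minor) and the six
leading PED columns, which are carried verbatim.

## Distance

All distances are the scaled Euclidean distance on code vectors,

d(g_i, g_j) = sqrt( (E / |S_ij|) * sum_{e in S_ij} (g_ie − g_je)^2 ),

where S_ij is the set of markers observed in both rows and E the total
marker count. The E/|S_ij| factor makes rows with different missingness
comparable on a common scale. Two rows sharing no observed marker get
distance 0 (they are unconstrained; any reference works and losslessness
never depends on distances). Distances to cluster centres use the same
scaling with the row's own observed set.

## Clustering (step 1)

Lloyd K-means on the digitized rows, `k = 5` by default (clamped to N):

- Initialization: k distinct rows drawn uniformly with the run's seed.
  `n_init = 4` restarts are run and the lowest-WCSS model kept; a single
  uniform draw frequently places two seeds in one true subpopulation and
  converges to a split/merged local optimum, while four restarts make
  recovery of well-separated structure the overwhelmingly common outcome
  at negligible cost.
- Assignment ties are sticky (a row keeps its current cluster when the
  improvement is below 1e-12), which guarantees termination on degenerate
  inputs such as equidistant duplicate points.
- Empty clusters are reseeded to the row farthest from its centre.
- The integer core of each cluster is the coordinate-wise mean rounded
  half-up and clipped to {0, 1, 2}; cores are stored verbatim (2-bit
  packed) and are the roots of the reference forest.

WCSS is recorded after every assignment step and is non-increasing; on
small instances the converged WCSS is checked in the tests against
exhaustive partition enumeration.

## Zone partition and reference selection (step 2)

Within each cluster, thresholds `T1 > T2 > 0` split members by distance to
the centre into A(I) (`d <= T2`), A(II) (`T2 < d <= T1`) and B (`d > T1`);
the ring width is `R = R_K − T1` (clamped at 0), with `R_K` the cluster
radius. By default T1 and T2 are the 0.8- and 0.5-quantiles of member
distances: the quantiles adapt to each cluster's scale, keep a majority of
rows on the cheap centre path, and leave a meaningful A(II) band of
candidate peers. Coinciding quantiles are nudged apart; clusters with
fewer than two members fall back to `(R_K, R_K/2)`.

Zone-A rows are delta-encoded against the core ("ORCM" one-step mode
applies this to every row, via T1 = infinity). Zone-B rows are processed
in increasing distance-to-centre order; each searches a block of initial
radius R around itself for A(II) candidates. If the block is empty the
radius grows by `Δd` (default `R/4`) and after the first growth
eligibility widens to all of zone A; the nearest candidate becomes the
reference, distance ties broken by lower global row index. Still-unassigned
B rows inside the final block share the winner's reference, which bounds
the number of searches and keeps the graph a two-level forest
(cores → centre-encoded → peer-encoded), so decoding any row takes at most
two hops. When the radius grid is pathologically fine (near-degenerate
ring width), the number of remaining Δd growths to the nearest candidate
is computed in closed form instead of looped — the final radius stays on
the `R + n·Δd` grid and hop counts are unchanged, but termination is
bounded. If a cluster's zone A is empty (every member beyond T1), all
members fall back to centre encoding and a warning is logged.

## Difference coding

A row is stored as its differing positions against its reference: varint
count D, then D varints of `(position_gap << 2) | mode`, positions
strictly increasing. The payload for a row at Hamming distance D is at
most `5·D + 2` bytes and is empty-diff-compact (one byte) for exact
duplicates. Blocks of 64 records are deflated (zlib level 6) to squeeze
residual redundancy between neighbouring records.

## Synthetic panels

The generator produces cluster-structured panels: per cluster a uniform
founder in {0,1,2}^E; a fraction `rho` of members ("ring" members) lie on
a shared per-cluster drift path — a member at depth t carries the first
⌈t·mu_ring·E⌉ mutations of an ordered per-cluster mutation list — and all
members additionally receive independent noise at rate `mu_in`. The shared
path makes deep members similar to intermediate ones, which is the regime
where peer references beat centre references; fully independent ring
mutations would make zone-B rows mutually dissimilar and peer selection
pointless, contradicting the premise of two-step selection. Missingness is
applied uniformly at rate `missing_rate` (at least one observed genotype
per marker), and codes are then canonicalised so the minor code is the
less frequent one among *observed* genotypes, matching what digitization
of the written PED file would infer.

## Numerical conventions

- Deterministic JSON (sorted keys, no whitespace) and fixed zlib level 6
  everywhere: identical inputs give byte-identical containers.
- All RNG use goes through `numpy.random.default_rng` seeded from the
  user-supplied seed; no global state.
- Distance comparisons in the block search use an absolute epsilon of
  1e-12 (coordinates are small integers, distances O(sqrt(E)); boundary
  candidates at exactly the grown radius must be included despite float
  rounding).
- Rounding of core coordinates is half-up via `floor(x + 0.5)`, not
  banker's rounding, so cores are independent of platform rounding mode.

## Problem sizes

Default test and benchmark sizes (hundreds of individuals, thousands of
markers, K around 3–10) were chosen to exercise every code path — multiple
blocks, both zones, grown radii, missing data — while keeping the full test
suite around a minute. The implementation itself is vectorized and has no
hard size limits; memory is the practical bound, since compression holds
the N×E code matrix and the per-cluster pairwise B-to-A distance matrices
in memory.

## Limitations

- Markers must be biallelic; more than two observed alleles per marker is
  rejected at digitization.
- Reference selection is per-cluster and in-memory; panels whose code
  matrix does not fit in RAM would need an out-of-core variant.
- Peer references are chosen greedily (nearest at the final radius) with
  block sharing; this is the method's design, not a global minimum of
  total diff size.
- The container stores one panel per file and version 1 has no appending
  or partial update; recompression is the update path.
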