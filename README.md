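# trcmgene

Lossless referential compression of SNP genotype panels with clustered,
two-step reference selection — a re-implementation of the TRCMGene method.

## The problem

A genotype panel stores, for each of N individuals, the genotype at each of E
biallelic SNP markers (PLINK PED/MAP text being a common interchange format).
Individuals in a panel are highly similar to each other — they differ at a
small fraction of markers — so storing each row in full is wasteful.
Referential compression stores a small set of *reference* sequences verbatim
and every other sequence as a sparse list of differences from its reference.
The catch is reference choice: a sequence far from its reference needs a long
difference list, so compression lives or dies by how well references are
matched to sequences.

## The method

Genotypes are digitized per marker to minor-allele counts: `0` = homozygous
major, `1` = heterozygous, `2` = homozygous minor, `3` = missing. The codes
are chosen from observed allele frequencies, so digitization is lossless and
self-inverting.

1. **Clustering.** Lloyd K-means (with a missing-aware, scaled Euclidean
   distance) groups the N sequences into K clusters. Each cluster's
   coordinate-wise rounded mean becomes an integer *core* sequence, stored
   verbatim (2-bit packed).
2. **Zone partition.** Within each cluster, two distance thresholds
   `T1 > T2` (by default the 0.8- and 0.5-quantiles of member distances to
   the centre) split members into an inner disc A(I), an outer annulus
   A(II), and a far ring B of width `R = R_K − T1`, where `R_K` is the
   cluster radius.
3. **Reference selection.** Zone-A sequences are well predicted by the core
   and are delta-encoded against it (the one-step, "ORCM" scheme). Zone-B
   sequences are not; each gets a *peer* reference instead: a search block
   of initial radius R around the B sequence is scanned for A(II)
   candidates, the radius growing by `Δd` (default `R/4`, eligibility
   widening to all of zone A after the first growth) until a candidate
   appears; the nearest candidate wins. Unassigned B sequences inside the
   final block share the reference. This two-step scheme is the "TRCM"
   mode. References form a two-level forest (cores → centre-encoded rows →
   peer-encoded rows), so decoding any row needs at most two hops.
4. **Container.** Differences are stored as varint-packed (position-delta,
   mode) streams in fixed-size record blocks inside an indexed `.trcm`
   container. Every byte is covered by a CRC-32, so any single-byte
   corruption is detected on read. The sorted index enables random access:
   extracting one individual reads only the header, the index, and at most
   two blocks.

## Worked example

```console
$ trcmgene simulate panel -n 200 -e 1000 -c 3 --seed 42
wrote 200 x 1000 panel to panel.ped / panel.map

$ trcmgene compress panel.ped panel.trcm --map panel.map -k 3 --seed 0
individuals      200
markers          1000
clusters (k)     3
mode             trcm
zone counts      A(I)=101 A(II)=58 B=41
peer fraction    0.2050
container bytes  18706
compression factor 44.03

$ trcmgene extract panel.trcm IND000007 | cut -c1-30
IND000007	CC	AA	AC	AC	AC	AA	AA

$ trcmgene decompress panel.trcm back.ped && cmp panel.ped back.ped && echo IDENTICAL
wrote 200 individuals x 1000 markers to back.ped
IDENTICAL
```

`trcmgene info CONTAINER` prints the stored header; `--mode orcm` forces pure
centre encoding for comparison. The same pipeline is available as a library:

```python
from trcmgene import PanelSpec, RunConfig, generate_panel, roundtrip_matrix

matrix, labels = generate_panel(PanelSpec(n_individuals=200, seed=42))
decoded = roundtrip_matrix(matrix, RunConfig(k=3, seed=0))
assert (decoded.codes == matrix.codes).all()
```

## Layout

- `src/trcmgene/genotype_io.py` — PED/MAP parsing, MAF digitization, distances
- `src/trcmgene/clustering.py` — K-means, integer cores
- `src/trcmgene/refsel.py` — zone partition and block-search reference selection
- `src/trcmgene/diffcodec.py` — delta records and varint packing
- `src/trcmgene/container.py` — `.trcm` container, random access, checksums
- `src/trcmgene/synthetic.py` — cluster-structured panel generator
- `src/trcmgene/pipeline.py`, `cli.py` — end-to-end pipeline and CLI
- `docs/methods.md` — method details and parameter rationale
- `docs/FORMAT.md` — exact byte layout of the container
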