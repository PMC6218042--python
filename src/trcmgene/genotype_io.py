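"""PED/MAP genotype I/O and minor-allele-frequency digitization.

A panel of N individuals typed at E bi-allelic markers is read from PLINK
text PED/MAP files (or a genotype-only TSV dialect) and digitized to integer
codes per marker: 0 = homozygous major, 1 = heterozygous, 2 = homozygous
minor, i.e. the count of the minor allele in the genotype.  The coding
direction is decided by each marker's minor allele frequency (MAF), so the
code 0 is always the most common homozygote and reference-based delta
encoding downstream sees mostly zeros of difference.

Digitization is lossless up to heterozygote ordering: the code 1 cannot
distinguish "A C" from "C A", so heterozygotes are written back in canonical
(major, minor) order.  Missing genotypes ("0 0" in PED convention) map to
``MISSING_CODE`` and survive the round trip verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ParameterError

#: Internal code for a missing genotype; outside the {0,1,2} genotype alphabet.
MISSING_CODE = 3

#: PED convention for a missing allele.
MISSING_ALLELE = "0"

#: Number of leading metadata columns in a PED row
#: (family id, individual id, paternal id, maternal id, sex, phenotype).
PED_META_COLUMNS = 6

#: Placeholder minor allele recorded for monomorphic markers.
MONOMORPHIC_PLACEHOLDER = "N"


@dataclass(frozen=True)
class MarkerInfo:
    """Per-marker allele metadata driving the 0/1/2 coding.

    ``allele_a`` is the major (more frequent) allele, ``allele_b`` the minor
    one; ``maf`` is the minor allele frequency in [0, 0.5].
    """

    marker_id: str
    allele_a: str
    allele_b: str
    maf: float
    position_index: int


@dataclass
class RawPanel:
    """Un-digitized panel: individual ids plus N×E allele pairs.

    ``pairs`` has shape (N, E, 2) with single-character allele strings;
    ``metadata`` holds the six leading PED columns per individual (or None
    for the TSV dialect), preserved verbatim for exact file round trips.
    """

    individual_ids: list[str]
    pairs: np.ndarray
    metadata: list[tuple[str, ...]] | None = None
    marker_ids: list[str] | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return 0 if self.pairs.size == 0 and self.pairs.ndim < 3 else self.pairs.shape[1]


@dataclass
class GenotypeMatrix:
    """Digitized panel: N×E integer codes plus the metadata to invert them."""

    individual_ids: list[str]
    markers: list[MarkerInfo]
    codes: np.ndarray
    metadata: list[tuple[str, ...]] | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            self.codes = self.codes.reshape(len(self.individual_ids), len(self.markers))
        n, e = self.codes.shape
        if n != len(self.individual_ids) or e != len(self.markers):
            raise ParameterError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.markers)} markers"
            )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_ped(ped_path, map_path=None, *, dialect: str = "ped") -> RawPanel:
    """Read a PED (or genotype-only TSV) file into a :class:`RawPanel`.

    Parameters
    ----------
    ped_path : path
        PED file: whitespace-separated, six metadata columns then 2·E
        single-character allele fields per row.  With ``dialect="tsv"`` each
        row is ``individual_id`` followed by E two-character genotype fields.
    map_path : path, optional
        MAP file supplying marker ids (second column); row count must equal E.
    """
    if dialect not in ("ped", "tsv"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    with open(ped_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{ped_path}: no records")

    ids: list[str] = []
    metadata: list[tuple[str, ...]] | None = [] if dialect == "ped" else None
    rows: list[list[str]] = []
    expected_fields: int | None = None
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t") if dialect == "tsv" else line.split()
        if expected_fields is None:
            expected_fields = len(fields)
        elif len(fields) != expected_fields:
            raise FormatError(
                f"{ped_path}: row {lineno} has {len(fields)} fields, "
                f"expected {expected_fields} (ragged file)"
            )
        if dialect == "ped":
            if len(fields) < PED_META_COLUMNS:
                raise FormatError(f"{ped_path}: row {lineno} has fewer than "
                                  f"{PED_META_COLUMNS} metadata columns")
            meta, allele_fields = fields[:PED_META_COLUMNS], fields[PED_META_COLUMNS:]
            if len(allele_fields) % 2:
                raise FormatError(
                    f"{ped_path}: row {lineno} has an odd number of allele fields"
                )
            for a in allele_fields:
                if len(a) != 1:
                    raise FormatError(
                        f"{ped_path}: row {lineno}: allele field {a!r} is not a "
                        "single character"
                    )
            ids.append(meta[1])
            metadata.append(tuple(meta))  # type: ignore[union-attr]
            rows.append(allele_fields)
        else:
            ident, geno_fields = fields[0], fields[1:]
            flat: list[str] = []
            for g in geno_fields:
                if len(g) != 2:
                    raise FormatError(
                        f"{ped_path}: row {lineno}: genotype field {g!r} is not "
                        "two characters"
                    )
                flat.extend((g[0], g[1]))
            ids.append(ident)
            rows.append(flat)

    n_markers = len(rows[0]) // 2
    pairs = np.array(rows, dtype="U1").reshape(len(rows), n_markers, 2)

    marker_ids = None
    if map_path is not None:
        marker_ids = read_map(map_path)
        if len(marker_ids) != n_markers:
            raise FormatError(
                f"{map_path}: {len(marker_ids)} markers but PED has {n_markers}"
            )
    return RawPanel(individual_ids=ids, pairs=pairs, metadata=metadata,
                    marker_ids=marker_ids)


def read_map(map_path) -> list[str]:
    """Read marker ids (second column) from a PLINK MAP file."""
    marker_ids = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{map_path}: row {lineno} has fewer than 2 columns")
            marker_ids.append(fields[1])
    return marker_ids


# ---------------------------------------------------------------------------
# Marker inference and digitization
# ---------------------------------------------------------------------------

def infer_marker_info(raw: RawPanel) -> list[MarkerInfo]:
    """Infer per-marker major/minor alleles and MAF from observed genotypes.

    A genotype pair containing the missing allele sentinel is excluded from
    the counts.  Frequency ties are broken lexicographically (the smaller
    character becomes the major allele).  Markers with more than two distinct
    non-missing alleles violate the bi-allelic assumption and raise; an
    all-missing marker also raises.
    """
    markers: list[MarkerInfo] = []
    pairs = raw.pairs
    for e in range(raw.n_markers):
        col = pairs[:, e, :]
        observed = col[~np.any(col == MISSING_ALLELE, axis=1)]
        if observed.size == 0:
            raise FormatError(f"marker {e}: all genotypes missing, cannot infer alleles")
        alleles, counts = np.unique(observed.ravel(), return_counts=True)
        if len(alleles) > 2:
            raise FormatError(
                f"marker {e}: {len(alleles)} distinct alleles "
                f"{[str(a) for a in alleles]}; bi-allelic markers required"
            )
        if len(alleles) == 1:
            major = str(alleles[0])
            minor = MONOMORPHIC_PLACEHOLDER if major != MONOMORPHIC_PLACEHOLDER else "A"
            maf = 0.0
        else:
            # tie -> lexicographically smaller character is the major allele
            if counts[0] > counts[1] or (counts[0] == counts[1] and alleles[0] < alleles[1]):
                major, minor = str(alleles[0]), str(alleles[1])
                maf = counts[1] / counts.sum()
            else:
                major, minor = str(alleles[1]), str(alleles[0])
                maf = counts[0] / counts.sum()
        marker_id = raw.marker_ids[e] if raw.marker_ids else f"SNP{e:06d}"
        markers.append(MarkerInfo(marker_id=marker_id, allele_a=major,
                                  allele_b=minor, maf=float(maf), position_index=e))
    return markers


def digitize(raw: RawPanel, markers: list[MarkerInfo]) -> GenotypeMatrix:
    """Digitize allele pairs to minor-allele counts per marker.

    The code at (i, e) is the number of copies of marker e's minor allele in
    individual i's genotype; heterozygote order is irrelevant.  Missing pairs
    become ``MISSING_CODE``.  A pair using an allele absent from the marker's
    :class:`MarkerInfo` raises, naming individual and marker.
    """
    n, e_count = raw.n_individuals, raw.n_markers
    if len(markers) != e_count:
        raise ParameterError(f"{len(markers)} MarkerInfo for {e_count} marker columns")
    if n == 0 or e_count == 0:
        return GenotypeMatrix(raw.individual_ids, markers,
                              np.zeros((n, e_count), dtype=np.int8), raw.metadata)

    majors = np.array([m.allele_a for m in markers], dtype="U1")
    minors = np.array([m.allele_b for m in markers], dtype="U1")
    pairs = raw.pairs
    missing = np.any(pairs == MISSING_ALLELE, axis=2)
    is_minor = pairs == minors[None, :, None]
    is_major = pairs == majors[None, :, None]
    valid = is_minor | is_major | (pairs == MISSING_ALLELE)
    if not valid.all():
        i, e, _ = np.argwhere(~valid)[0]
        raise FormatError(
            f"individual {raw.individual_ids[i]!r}, marker "
            f"{markers[e].marker_id!r}: allele {pairs[i, e].tolist()} not in "
            f"({markers[e].allele_a!r}, {markers[e].allele_b!r})"
        )
    codes = is_minor.sum(axis=2).astype(np.int8)
    codes[missing] = MISSING_CODE
    return GenotypeMatrix(raw.individual_ids, markers, codes, raw.metadata)


def undigitize(matrix: GenotypeMatrix) -> RawPanel:
    """Invert :func:`digitize`: codes back to allele pairs.

    Heterozygotes are emitted in canonical (major, minor) order; missing codes
    emit the "0 0" sentinel pair.
    """
    n, e_count = matrix.n_individuals, matrix.n_markers
    codes = matrix.codes
    majors = np.array([m.allele_a for m in matrix.markers], dtype="U1")
    minors = np.array([m.allele_b for m in matrix.markers], dtype="U1")
    pairs = np.empty((n, e_count, 2), dtype="U1")
    if n and e_count:
        missing = codes == MISSING_CODE
        pairs[:, :, 0] = np.where(codes <= 1, majors[None, :], minors[None, :])
        pairs[:, :, 1] = np.where(codes == 0, majors[None, :], minors[None, :])
        pairs[:, :, 0][missing] = MISSING_ALLELE
        pairs[:, :, 1][missing] = MISSING_ALLELE
    return RawPanel(individual_ids=list(matrix.individual_ids), pairs=pairs,
                    metadata=matrix.metadata,
                    marker_ids=[m.marker_id for m in matrix.markers])


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_ped(raw: RawPanel, ped_path, map_path=None, *, dialect: str = "ped") -> None:
    """Write a :class:`RawPanel` to PED (+ optional MAP) or TSV files."""
    if dialect not in ("ped", "tsv"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    n, e_count = raw.n_individuals, raw.n_markers
    flat = raw.pairs.reshape(n, 2 * e_count) if n else np.empty((0, 0), dtype="U1")
    with open(ped_path, "w") as fh:
        for i in range(n):
            if dialect == "ped":
                if raw.metadata is not None:
                    meta = raw.metadata[i]
                else:
                    meta = (f"FAM{i:06d}", raw.individual_ids[i], "0", "0", "0", "-9")
                fh.write(" ".join(meta))
                if e_count:
                    fh.write(" " + " ".join(flat[i]))
                fh.write("\n")
            else:
                genos = ["".join(raw.pairs[i, e]) for e in range(e_count)]
                fh.write("\t".join([raw.individual_ids[i], *genos]) + "\n")
    if map_path is not None:
        marker_ids = raw.marker_ids or [f"SNP{e:06d}" for e in range(e_count)]
        with open(map_path, "w") as fh:
            for e, mid in enumerate(marker_ids):
                fh.write(f"1 {mid} 0 {e + 1}\n")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def euclidean_distance(g_i, g_j, *, missing_code: int | None = MISSING_CODE) -> float:
    """Euclidean distance between two digitized sequences.

    sqrt(sum_e (g_ie - g_je)^2) over coordinates where both values are
    observed.  With missing values present, the sum is rescaled by
    E / n_shared so distances stay comparable across pairs with different
    amounts of missingness.  Pass ``missing_code=None`` for plain Euclidean
    distance on fully observed (possibly real-valued) vectors.
    """
    a = np.asarray(g_i, dtype=np.float64)
    b = np.asarray(g_j, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    if missing_code is None:
        return float(math.sqrt(np.sum((a - b) ** 2)))
    shared = (np.asarray(g_i) != missing_code) & (np.asarray(g_j) != missing_code)
    n_shared = int(shared.sum())
    if n_shared == 0:
        return 0.0
    ss = float(np.sum((a[shared] - b[shared]) ** 2))
    return math.sqrt(ss * a.size / n_shared)


def pairwise_sq_distances(x: np.ndarray, centres: np.ndarray,
                          observed: np.ndarray | None = None) -> np.ndarray:
    """Squared scaled Euclidean distances from each row of ``x`` to each centre.

    ``observed`` is a boolean mask of x's non-missing entries (centres are
    assumed fully observed, as cluster means are).  Missing coordinates are
    dropped from the sum and the result rescaled by E / n_observed, matching
    :func:`euclidean_distance`.  Returns an (n_rows, n_centres) float array.
    """
    x = np.asarray(x, dtype=np.float64)
    centres = np.atleast_2d(np.asarray(centres, dtype=np.float64))
    if x.ndim == 1:
        x = x[None, :]
    n, e = x.shape
    if e == 0:
        return np.zeros((n, centres.shape[0]))
    if observed is None or observed.all():
        # ||x||^2 - 2 x.c + ||c||^2
        d2 = (
            np.sum(x * x, axis=1)[:, None]
            - 2.0 * x @ centres.T
            + np.sum(centres * centres, axis=1)[None, :]
        )
        return np.maximum(d2, 0.0)
    m = observed.astype(np.float64)
    xt = np.where(observed, x, 0.0)
    d2 = (
        np.sum(xt * xt, axis=1)[:, None]
        - 2.0 * xt @ centres.T
        + m @ (centres * centres).T
    )
    n_obs = m.sum(axis=1)
    scale = np.divide(e, n_obs, out=np.zeros_like(n_obs), where=n_obs > 0)
    return np.maximum(d2, 0.0) * scale[:, None]


def pairwise_row_sq_distances(x: np.ndarray, y: np.ndarray,
                              missing_code: int | None = MISSING_CODE) -> np.ndarray:
    """Squared scaled distances between all rows of ``x`` and all rows of ``y``.

    Both sides may contain missing codes; per-pair shared-coordinate scaling
    matches :func:`euclidean_distance` exactly.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    e = x.shape[1]
    xf = x.astype(np.float64)
    yf = y.astype(np.float64)
    if missing_code is None:
        return pairwise_sq_distances(xf, yf)
    mx = (x != missing_code)
    my = (y != missing_code)
    if mx.all() and my.all():
        return pairwise_sq_distances(xf, yf)
    xt = np.where(mx, xf, 0.0)
    yt = np.where(my, yf, 0.0)
    mxf = mx.astype(np.float64)
    myf = my.astype(np.float64)
    # sum over shared coords of (x - y)^2 = x^2 my + y^2 mx - 2 x y
    ss = (xt * xt) @ myf.T + mxf @ (yt * yt).T - 2.0 * xt @ yt.T
    n_shared = mxf @ myf.T
    scale = np.divide(e, n_shared, out=np.zeros_like(n_shared), where=n_shared > 0)
    return np.maximum(ss, 0.0) * scale
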