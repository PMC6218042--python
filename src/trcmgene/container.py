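"""The .trcm container: an indexed, random-access compressed genotype file.

Layout (all integers little-endian; byte offsets 64-bit; see docs/FORMAT.md
for the exact byte layout):

* **preamble** — magic ``TRCM``, version, fixed-length name and description
  strings, a deflated JSON metadata blob (N, E, K, marker table, individual
  ids, preserved PED metadata columns, run parameters, the static mode
  dictionary), the index offset, and a CRC-32 over everything before it;
* **core section** — the K core sequences, 2-bit packed, with a CRC-32;
* **blocks** — the N per-sequence diff records grouped into blocks of
  ``block_size`` records, each block optionally deflated as a unit and
  guarded by its own CRC-32, so one random access inflates one block in RAM;
* **index section** — a deflated, alphabetically sorted table mapping each
  individual id to (row, group id, hierarchy id, reference id, block,
  offset-in-block) plus the absolute block offsets, with a CRC-32.

Every byte of the file is covered by a checksum or a structural check, so
any single corrupted byte is detected on read — the format doubles as a
firewall against silent data corruption.  The index is fully regenerable
from a linear scan of the blocks.
"""

from __future__ import annotations

import bisect
import io
import json
import os
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AssemblyError,
    CorruptionError,
    NotFoundError,
    ParameterError,
    UnsupportedVersionError,
)
from .clustering import ClusterModel
from .diffcodec import (
    DiffRecord,
    decode_diff,
    decode_varint,
    encode_diff,
    encode_varint,
    pack_diffs,
    unpack_diffs,
)
from .genotype_io import GenotypeMatrix, MarkerInfo
from .refsel import KIND_CENTRE, KIND_PEER, ReferenceAssignment

MAGIC = b"TRCM"
VERSION = 1
_NAME_LEN = 64
_DESC_LEN = 128
_ZLEVEL = 6

#: Static data dictionary stored in every header (self-description of the
#: diff alphabet and wire encoding).
MODE_DICTIONARY = {
    "modes": {
        "0": "homozygous major difference",
        "1": "heterozygous difference",
        "2": "homozygous minor difference",
        "3": "missing genotype",
    },
    "positions": "varint gap deltas, mode in low 2 bits",
}

HIER_CENTRE = 1  # centre-encoded sequence (level 1 of the reference forest)
HIER_PEER = 2    # peer-encoded sequence (level 2)


@dataclass
class ContainerHeader:
    """Parsed preamble of a .trcm file; suffices to undigitize any row."""

    name: str
    description: str
    version: int
    n_individuals: int
    n_markers: int
    n_clusters: int
    block_size: int
    deflate: bool
    mode: str
    params: dict
    markers: list[MarkerInfo]
    individual_ids: list[str]
    ped_metadata: list[tuple[str, ...]] | None
    dictionary: dict
    index_offset: int
    preamble_len: int

    @property
    def n_blocks(self) -> int:
        if self.n_individuals == 0:
            return 0
        return (self.n_individuals + self.block_size - 1) // self.block_size


@dataclass
class IndexEntry:
    """One individual's locator inside the container."""

    individual_id: str
    row: int
    group: int          # cluster id
    hierarchy: int      # HIER_CENTRE or HIER_PEER
    reference: int      # cluster id (centre) or reference row (peer)
    block: int
    offset_in_block: int


@dataclass
class ContainerIndex:
    entries: list[IndexEntry]            # sorted by individual id
    block_offsets: list[int]             # absolute file offset per block
    _ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._ids = [e.individual_id for e in self.entries]

    def lookup(self, individual_id: str) -> IndexEntry:
        i = bisect.bisect_left(self._ids, individual_id)
        if i < len(self._ids) and self._ids[i] == individual_id:
            return self.entries[i]
        lo, hi = max(0, i - 2), min(len(self._ids), i + 2)
        near = ", ".join(repr(s) for s in self._ids[lo:hi]) or "none"
        raise NotFoundError(
            f"individual id {individual_id!r} not in container index "
            f"(nearest ids: {near})")


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------

def _open_read(path_or_file):
    if hasattr(path_or_file, "read"):
        path_or_file.seek(0)
        return path_or_file, False
    return open(path_or_file, "rb"), True


def _read_exact(fh, n: int) -> bytes:
    try:
        data = fh.read(n)
    except (OSError, ValueError, OverflowError) as exc:
        raise CorruptionError(f"read failed: {exc}") from exc
    if len(data) != n:
        raise CorruptionError(
            f"truncated container: wanted {n} bytes, got {len(data)}")
    return data


def _fixed_str(text: str, length: int) -> bytes:
    raw = text.encode("utf-8")[:length]
    return raw + b"\x00" * (length - len(raw))


def _json_blob(obj) -> bytes:
    return zlib.compress(
        json.dumps(obj, sort_keys=True, separators=(",", ":")).encode("utf-8"),
        _ZLEVEL)


def _json_unblob(blob: bytes):
    try:
        return json.loads(zlib.decompress(blob).decode("utf-8"))
    except (zlib.error, ValueError) as exc:
        raise CorruptionError(f"corrupt metadata blob: {exc}") from exc


def _pack_2bit(arr: np.ndarray) -> bytes:
    arr = np.asarray(arr, dtype=np.uint8)
    pad = (-arr.size) % 4
    if pad:
        arr = np.concatenate([arr, np.zeros(pad, dtype=np.uint8)])
    q = arr.reshape(-1, 4)
    return (q[:, 0] | (q[:, 1] << 2) | (q[:, 2] << 4) | (q[:, 3] << 6)).tobytes()


def _unpack_2bit(buf: bytes, count: int) -> np.ndarray:
    b = np.frombuffer(buf, dtype=np.uint8)
    out = np.empty(b.size * 4, dtype=np.uint8)
    out[0::4] = b & 3
    out[1::4] = (b >> 2) & 3
    out[2::4] = (b >> 4) & 3
    out[3::4] = (b >> 6) & 3
    if count > out.size:
        raise CorruptionError("core section shorter than expected")
    return out[:count].astype(np.int8)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _sequence_record(kind: int, ref: int, payload: bytes) -> bytes:
    return bytes([kind]) + encode_varint(ref) + payload


def write_container(matrix: GenotypeMatrix, model: ClusterModel | None,
                    assignment: ReferenceAssignment | None, path, *,
                    block_size: int = 64, deflate: bool = True,
                    name: str = "", description: str = "",
                    mode: str = "trcm", params: dict | None = None) -> int:
    """Assemble and write a container; returns the number of bytes written.

    Identical inputs and parameters always produce a byte-identical file.
    Inconsistent inputs raise :class:`AssemblyError` before any byte is
    written.
    """
    n, e = matrix.n_individuals, matrix.n_markers
    if block_size < 1:
        raise ParameterError(f"block_size must be >= 1, got {block_size}")
    if len(set(matrix.individual_ids)) != n:
        raise AssemblyError("individual ids must be unique for indexing")
    if n == 0:
        model = None
        assignment = None
    else:
        if model is None or assignment is None:
            raise AssemblyError("non-empty panel requires model and assignment")
        if model.assignment.shape[0] != n or assignment.kind.shape[0] != n:
            raise AssemblyError(
                f"model/assignment cover {model.assignment.shape[0]}/"
                f"{assignment.kind.shape[0]} sequences, panel has {n}")
        if model.cores.shape[1] != e:
            raise AssemblyError(
                f"cores have {model.cores.shape[1]} markers, panel has {e}")
        peer_rows = np.nonzero(assignment.kind == KIND_PEER)[0]
        if peer_rows.size and (assignment.kind[assignment.ref[peer_rows]]
                               != KIND_CENTRE).any():
            raise AssemblyError("peer references must point at centre-encoded "
                                "sequences (two-level forest)")

    k = model.n_clusters if model is not None else 0
    codes = matrix.codes

    # per-sequence records, grouped into blocks in row order
    entries: list[IndexEntry] = []
    raw_blocks: list[bytes] = []
    buf = bytearray()
    block_id = 0
    for row in range(n):
        kind = int(assignment.kind[row])
        ref = int(assignment.ref[row])
        cluster = int(model.assignment[row])
        reference_row = model.cores[cluster] if kind == KIND_CENTRE \
            else codes[ref]
        record = encode_diff(codes[row], reference_row, ref_kind=kind,
                             ref_id=ref)
        entries.append(IndexEntry(
            individual_id=matrix.individual_ids[row], row=row, group=cluster,
            hierarchy=HIER_CENTRE if kind == KIND_CENTRE else HIER_PEER,
            reference=ref, block=block_id, offset_in_block=len(buf)))
        buf += _sequence_record(kind, ref, pack_diffs(record))
        if (row + 1) % block_size == 0:
            raw_blocks.append(bytes(buf))
            buf = bytearray()
            block_id += 1
    if buf:
        raw_blocks.append(bytes(buf))

    meta = {
        "n": n, "e": e, "k": k, "block_size": block_size,
        "deflate": bool(deflate), "mode": mode, "params": params or {},
        "markers": [[m.marker_id, m.allele_a, m.allele_b, m.maf,
                     m.position_index] for m in matrix.markers],
        "individual_ids": list(matrix.individual_ids),
        "ped_metadata": [list(t) for t in matrix.metadata]
        if matrix.metadata is not None else None,
        "dictionary": MODE_DICTIONARY,
    }
    meta_blob = _json_blob(meta)

    # core section
    core_payload = b"".join(_pack_2bit(model.cores[j]) for j in range(k)) \
        if model is not None else b""
    core_section = (struct.pack("<I", len(core_payload)) + core_payload
                    + struct.pack("<I", zlib.crc32(core_payload)))

    # block sections
    block_sections: list[bytes] = []
    for raw in raw_blocks:
        stored = zlib.compress(raw, _ZLEVEL) if deflate else raw
        flag = 1 if deflate else 0
        head = struct.pack("<BII", flag, len(raw), len(stored))
        crc = zlib.crc32(head + stored)
        block_sections.append(head + stored + struct.pack("<I", crc))

    preamble_len = (len(MAGIC) + 1 + _NAME_LEN + _DESC_LEN + 4
                    + len(meta_blob) + 8 + 4)
    blocks_start = preamble_len + len(core_section)
    offsets: list[int] = []
    pos = blocks_start
    for section in block_sections:
        offsets.append(pos)
        pos += len(section)
    index_offset = pos

    entries_sorted = sorted(entries, key=lambda en: (en.individual_id, en.row))
    idx_obj = {
        "block_offsets": offsets,
        "entries": [[en.individual_id, en.row, en.group, en.hierarchy,
                     en.reference, en.block, en.offset_in_block]
                    for en in entries_sorted],
    }
    idx_blob = _json_blob(idx_obj)
    index_section = (struct.pack("<I", len(idx_blob)) + idx_blob
                     + struct.pack("<I", zlib.crc32(idx_blob)))

    head = bytearray()
    head += MAGIC
    head.append(VERSION)
    head += _fixed_str(name, _NAME_LEN)
    head += _fixed_str(description, _DESC_LEN)
    head += struct.pack("<I", len(meta_blob))
    head += meta_blob
    head += struct.pack("<Q", index_offset)
    head += struct.pack("<I", zlib.crc32(bytes(head)))
    assert len(head) == preamble_len

    payload = bytes(head) + core_section + b"".join(block_sections) + index_section
    if hasattr(path, "write"):
        path.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)
    return len(payload)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_preamble(fh) -> ContainerHeader:
    magic = _read_exact(fh, 4)
    if magic != MAGIC:
        raise CorruptionError("not a TRCM container (bad magic bytes)")
    crc = zlib.crc32(magic)
    version_b = _read_exact(fh, 1)
    crc = zlib.crc32(version_b, crc)
    version = version_b[0]
    if version > VERSION:
        raise UnsupportedVersionError(
            f"container version {version} newer than supported ({VERSION})")
    name_b = _read_exact(fh, _NAME_LEN)
    desc_b = _read_exact(fh, _DESC_LEN)
    meta_len_b = _read_exact(fh, 4)
    crc = zlib.crc32(name_b + desc_b + meta_len_b, crc)
    (meta_len,) = struct.unpack("<I", meta_len_b)
    meta_blob = _read_exact(fh, meta_len)
    idx_off_b = _read_exact(fh, 8)
    crc = zlib.crc32(meta_blob + idx_off_b, crc)
    (stored_crc,) = struct.unpack("<I", _read_exact(fh, 4))
    if stored_crc != crc:
        raise CorruptionError("header checksum mismatch")
    meta = _json_unblob(meta_blob)
    try:
        markers = [MarkerInfo(marker_id=m[0], allele_a=m[1], allele_b=m[2],
                              maf=float(m[3]), position_index=int(m[4]))
                   for m in meta["markers"]]
        header = ContainerHeader(
            name=name_b.rstrip(b"\x00").decode("utf-8"),
            description=desc_b.rstrip(b"\x00").decode("utf-8"),
            version=version,
            n_individuals=int(meta["n"]), n_markers=int(meta["e"]),
            n_clusters=int(meta["k"]), block_size=int(meta["block_size"]),
            deflate=bool(meta["deflate"]), mode=meta["mode"],
            params=meta["params"], markers=markers,
            individual_ids=list(meta["individual_ids"]),
            ped_metadata=[tuple(t) for t in meta["ped_metadata"]]
            if meta["ped_metadata"] is not None else None,
            dictionary=meta["dictionary"],
            index_offset=struct.unpack("<Q", idx_off_b)[0],
            preamble_len=4 + 1 + _NAME_LEN + _DESC_LEN + 4 + meta_len + 8 + 4,
        )
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise CorruptionError(f"malformed header metadata: {exc}") from exc
    return header


def read_header(path) -> ContainerHeader:
    """Parse and checksum-validate the header without touching records."""
    fh, close = _open_read(path)
    try:
        return _parse_preamble(fh)
    finally:
        if close:
            fh.close()


def _read_cores(fh, header: ContainerHeader) -> np.ndarray:
    (core_len,) = struct.unpack("<I", _read_exact(fh, 4))
    payload = _read_exact(fh, core_len)
    (crc,) = struct.unpack("<I", _read_exact(fh, 4))
    if crc != zlib.crc32(payload):
        raise CorruptionError("core section checksum mismatch")
    k, e = header.n_clusters, header.n_markers
    per = (e + 3) // 4
    if core_len != k * per:
        raise CorruptionError(
            f"core section is {core_len} bytes, expected {k * per}")
    cores = np.zeros((k, e), dtype=np.int8)
    for j in range(k):
        cores[j] = _unpack_2bit(payload[j * per:(j + 1) * per], e)
    return cores


def _read_block(fh) -> bytes:
    head = _read_exact(fh, 9)
    flag, raw_len, stored_len = struct.unpack("<BII", head)
    stored = _read_exact(fh, stored_len)
    (crc,) = struct.unpack("<I", _read_exact(fh, 4))
    if crc != zlib.crc32(head + stored):
        raise CorruptionError("block checksum mismatch")
    if flag == 1:
        try:
            raw = zlib.decompress(stored)
        except zlib.error as exc:
            raise CorruptionError(f"block inflate failed: {exc}") from exc
    elif flag == 0:
        raw = stored
    else:
        raise CorruptionError(f"unknown block flag {flag}")
    if len(raw) != raw_len:
        raise CorruptionError("block raw length mismatch")
    return raw


def _read_index_section(fh, header: ContainerHeader) -> ContainerIndex:
    fh.seek(header.index_offset)
    (idx_len,) = struct.unpack("<I", _read_exact(fh, 4))
    blob = _read_exact(fh, idx_len)
    (crc,) = struct.unpack("<I", _read_exact(fh, 4))
    if crc != zlib.crc32(blob):
        raise CorruptionError("index checksum mismatch")
    obj = _json_unblob(blob)
    try:
        entries = [IndexEntry(individual_id=t[0], row=int(t[1]),
                              group=int(t[2]), hierarchy=int(t[3]),
                              reference=int(t[4]), block=int(t[5]),
                              offset_in_block=int(t[6]))
                   for t in obj["entries"]]
        offsets = [int(o) for o in obj["block_offsets"]]
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise CorruptionError(f"malformed index: {exc}") from exc
    return ContainerIndex(entries=entries, block_offsets=offsets)


def _parse_record(raw: bytes, offset: int, n_markers: int) -> tuple[int, int, DiffRecord, int]:
    """Parse one sequence record at ``offset`` in an inflated block."""
    if offset >= len(raw):
        raise CorruptionError("record offset beyond block")
    kind = raw[offset]
    if kind not in (KIND_CENTRE, KIND_PEER):
        raise CorruptionError(f"unknown record kind {kind}")
    ref, pos = decode_varint(raw, offset + 1)
    record, pos = unpack_diffs(raw, pos, n_markers=n_markers,
                               ref_kind=kind, ref_id=ref)
    return kind, ref, record, pos


def read_container(path, *, validate_index: bool = True
                   ) -> tuple[GenotypeMatrix, ContainerHeader]:
    """Fully decode a container, validating every checksum on the way."""
    fh, close = _open_read(path)
    try:
        header = _parse_preamble(fh)
        cores = _read_cores(fh, header)
        n, e = header.n_individuals, header.n_markers
        kinds = np.zeros(n, dtype=np.int8)
        refs = np.zeros(n, dtype=np.int64)
        records: list[DiffRecord] = []
        row = 0
        for _ in range(header.n_blocks):
            raw = _read_block(fh)
            pos = 0
            while pos < len(raw):
                if row >= n:
                    raise CorruptionError("more records than individuals")
                kind, ref, record, pos = _parse_record(raw, pos, e)
                kinds[row], refs[row] = kind, ref
                records.append(record)
                row += 1
        if row != n:
            raise CorruptionError(f"decoded {row} records, header says {n}")
        if fh.tell() != header.index_offset:
            raise CorruptionError("index offset inconsistent with blocks")
        if validate_index:
            _read_index_section(fh, header)

        codes = np.zeros((n, e), dtype=np.int8)
        for i in range(n):
            if kinds[i] == KIND_CENTRE:
                if not 0 <= refs[i] < max(header.n_clusters, 1):
                    raise CorruptionError(f"record {i}: cluster {refs[i]} "
                                          "out of range")
                codes[i] = decode_diff(cores[refs[i]], records[i])
        for i in range(n):
            if kinds[i] == KIND_PEER:
                if not 0 <= refs[i] < n or kinds[refs[i]] != KIND_CENTRE:
                    raise CorruptionError(
                        f"record {i}: invalid peer reference {refs[i]}")
                codes[i] = decode_diff(codes[refs[i]], records[i])
        matrix = GenotypeMatrix(individual_ids=list(header.individual_ids),
                                markers=header.markers, codes=codes,
                                metadata=header.ped_metadata)
        return matrix, header
    finally:
        if close:
            fh.close()


def rebuild_index(path) -> bytes:
    """Regenerate the index section from a linear scan of the blocks.

    Returns the serialized index section bytes; a healthy file's stored
    index section is byte-identical.
    """
    fh, close = _open_read(path)
    try:
        header = _parse_preamble(fh)
        _read_cores(fh, header)
        n, e = header.n_individuals, header.n_markers
        offsets: list[int] = []
        raw_entries: list[list] = []
        kinds: dict[int, int] = {}
        groups: dict[int, int] = {}
        row = 0
        for block_id in range(header.n_blocks):
            offsets.append(fh.tell())
            raw = _read_block(fh)
            pos = 0
            while pos < len(raw):
                start = pos
                kind, ref, _, pos = _parse_record(raw, pos, e)
                kinds[row] = kind
                if kind == KIND_CENTRE:
                    groups[row] = ref
                raw_entries.append([header.individual_ids[row], row, kind,
                                    ref, block_id, start])
                row += 1
        entries = []
        for ident, r, kind, ref, block_id, start in raw_entries:
            group = groups[r] if kind == KIND_CENTRE else groups[ref]
            hier = HIER_CENTRE if kind == KIND_CENTRE else HIER_PEER
            entries.append([ident, r, group, hier, ref, block_id, start])
        entries.sort(key=lambda t: (t[0], t[1]))
        blob = _json_blob({"block_offsets": offsets, "entries": entries})
        return (struct.pack("<I", len(blob)) + blob
                + struct.pack("<I", zlib.crc32(blob)))
    finally:
        if close:
            fh.close()


def stored_index_section(path) -> bytes:
    """Raw bytes of the index section as stored in the file."""
    fh, close = _open_read(path)
    try:
        header = _parse_preamble(fh)
        fh.seek(header.index_offset)
        return fh.read()
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Random access
# ---------------------------------------------------------------------------

class _CountingFile:
    """Wraps a binary file, counting bytes actually read."""

    def __init__(self, fh):
        self._fh = fh
        self.bytes_read = 0

    def read(self, n=-1):
        data = self._fh.read(n)
        self.bytes_read += len(data)
        return data

    def seek(self, *args):
        return self._fh.seek(*args)

    def tell(self):
        return self._fh.tell()

    def close(self):
        self._fh.close()


class RandomAccessReader:
    """Constant-time access to single individuals without full decompression.

    Construction reads only the preamble, core section and index; each
    :meth:`extract` then reads (and caches) at most two blocks — the target's
    block and, for a peer-encoded row, its reference's block.
    """

    def __init__(self, path):
        fh, self._close = _open_read(path)
        self._fh = _CountingFile(fh)
        self.header = _parse_preamble(self._fh)
        self._cores = _read_cores(self._fh, self.header)
        self.index = _read_index_section(self._fh, self.header)
        self._blocks: dict[int, bytes] = {}
        self._row_pos = {en.row: en for en in self.index.entries}

    @property
    def bytes_read(self) -> int:
        return self._fh.bytes_read

    def close(self) -> None:
        if self._close:
            self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _block(self, block_id: int) -> bytes:
        if block_id not in self._blocks:
            if not 0 <= block_id < len(self.index.block_offsets):
                raise CorruptionError(f"block id {block_id} out of range")
            self._fh.seek(self.index.block_offsets[block_id])
            self._blocks[block_id] = _read_block(self._fh)
        return self._blocks[block_id]

    def _decode_entry(self, entry: IndexEntry) -> np.ndarray:
        raw = self._block(entry.block)
        kind, ref, record, _ = _parse_record(raw, entry.offset_in_block,
                                             self.header.n_markers)
        if kind == KIND_CENTRE:
            if not 0 <= ref < self.header.n_clusters:
                raise CorruptionError(f"cluster {ref} out of range")
            return decode_diff(self._cores[ref], record)
        ref_entry = self._row_pos.get(ref)
        if ref_entry is None or ref_entry.hierarchy != HIER_CENTRE:
            raise CorruptionError(f"invalid peer reference row {ref}")
        reference = self._decode_entry(ref_entry)
        return decode_diff(reference, record)

    def extract(self, individual_id: str) -> np.ndarray:
        """Digitized genotype row for one individual."""
        return self._decode_entry(self.index.lookup(individual_id))

    def extract_alleles(self, individual_id: str) -> list[str]:
        """Genotypes as two-character allele strings (canonical order)."""
        from .genotype_io import GenotypeMatrix, undigitize

        row = self.extract(individual_id)
        one = GenotypeMatrix(individual_ids=[individual_id],
                             markers=self.header.markers,
                             codes=row[None, :])
        pairs = undigitize(one).pairs[0]
        return ["".join(p) for p in pairs]


def random_access(path, individual_id: str) -> np.ndarray:
    """One-shot convenience wrapper around :class:`RandomAccessReader`."""
    with RandomAccessReader(path) as reader:
        return reader.extract(individual_id)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compression_factor(original_paths, container_path) -> float:
    """Uncompressed size divided by container size (higher is better)."""
    if isinstance(original_paths, (str, bytes, os.PathLike)):
        original_paths = [original_paths]
    original = sum(os.path.getsize(p) for p in original_paths)
    compressed = os.path.getsize(container_path)
    return original / compressed
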