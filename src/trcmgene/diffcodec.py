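"""Referential diff encoding of digitized sequences.

A sequence is stored as the ordered list of (position, mode) pairs where it
differs from its reference; the mode is simply the sequence's own value at
that position — 0 or 2 for a homozygous difference, 1 for a heterozygous
difference, and ``MISSING_MARK`` for a missing genotype — so decoding is
plain value replacement over a copy of the reference.  A sequence identical
to its reference costs a single byte, which is the whole mechanism behind
the referential scheme's win on high-similarity panels.

Wire format (packed record)
---------------------------
``varint(D)`` followed by D varints, each ``(delta << 2) | mode`` where
``delta`` is the gap to the previous diff position (the first delta is the
absolute position) and ``mode`` occupies the low 2 bits.  Varints are
little-endian base-128 with a continuation high bit.  An empty record is
the single byte 0x00.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorruptionError, ParameterError

#: Mode symbol for a missing genotype (outside the genotype 0/1/2 alphabet,
#: required for losslessness).  Equals genotype MISSING_CODE by design.
MISSING_MARK = 3

_SMALL = 64  # below this many values, pure-Python varint paths are faster


@dataclass
class DiffRecord:
    """Differences of one sequence from its reference."""

    positions: np.ndarray   # strictly increasing, each < n_markers
    modes: np.ndarray       # values in {0, 1, 2, MISSING_MARK}
    n_markers: int
    ref_kind: int = 0       # KIND_CENTRE / KIND_PEER (refsel constants)
    ref_id: int = 0

    @property
    def n_diffs(self) -> int:
        return int(self.positions.shape[0])


# ---------------------------------------------------------------------------
# Varints
# ---------------------------------------------------------------------------

def encode_varint(value: int) -> bytes:
    """Little-endian base-128 varint of a single non-negative integer."""
    if value < 0:
        raise ParameterError("varints encode non-negative integers only")
    out = bytearray()
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def decode_varint(buf: bytes, offset: int = 0) -> tuple[int, int]:
    """Decode one varint at ``offset``; returns (value, next offset)."""
    value = 0
    shift = 0
    pos = offset
    while True:
        if pos >= len(buf):
            raise CorruptionError("truncated varint")
        byte = buf[pos]
        value |= (byte & 0x7F) << shift
        pos += 1
        if not byte & 0x80:
            return value, pos
        shift += 7
        if shift > 63:
            raise CorruptionError("varint overflow")


def encode_varints(values) -> bytes:
    """Concatenated varints of a sequence of non-negative integers."""
    values = np.asarray(values, dtype=np.uint64)
    n = values.shape[0]
    if n == 0:
        return b""
    if n < _SMALL:
        out = bytearray()
        for v in values.tolist():
            while True:
                byte = v & 0x7F
                v >>= 7
                if v:
                    out.append(byte | 0x80)
                else:
                    out.append(byte)
                    break
        return bytes(out)
    # vectorized: byte j of value i exists iff nbytes[i] > j
    nbytes = np.ones(n, dtype=np.int64)
    rest = values >> np.uint64(7)
    while rest.any():
        nbytes += (rest > 0)
        rest >>= np.uint64(7)
    total = int(nbytes.sum())
    out = np.zeros(total, dtype=np.uint8)
    starts = np.concatenate(([0], np.cumsum(nbytes)[:-1]))
    for j in range(int(nbytes.max())):
        mask = nbytes > j
        chunk = (values[mask] >> np.uint64(7 * j)) & np.uint64(0x7F)
        cont = np.where(nbytes[mask] > j + 1, 0x80, 0).astype(np.uint64)
        out[starts[mask] + j] = (chunk | cont).astype(np.uint8)
    return out.tobytes()


def decode_varints(buf: bytes, count: int, offset: int = 0) -> tuple[np.ndarray, int]:
    """Decode ``count`` varints starting at ``offset``; returns (values, next)."""
    if count == 0:
        return np.zeros(0, dtype=np.int64), offset
    if count < _SMALL:
        values = np.empty(count, dtype=np.int64)
        pos = offset
        for i in range(count):
            values[i], pos = decode_varint(buf, pos)
        return values, pos
    arr = np.frombuffer(buf, dtype=np.uint8, count=len(buf) - offset,
                        offset=offset)
    last = np.nonzero((arr & 0x80) == 0)[0]
    if last.shape[0] < count:
        raise CorruptionError("truncated varint stream")
    ends = last[:count]
    span = int(ends[-1]) + 1
    arr = arr[:span]
    starts = np.concatenate(([0], ends[:-1] + 1))
    lengths = ends - starts + 1
    if int(lengths.max()) * 7 > 63:
        raise CorruptionError("varint overflow")
    grp = np.repeat(np.arange(count), lengths)
    pos_in_grp = np.arange(span) - np.repeat(starts, lengths)
    contrib = (arr & 0x7F).astype(np.float64) * np.exp2(7.0 * pos_in_grp)
    values = np.bincount(grp, weights=contrib, minlength=count)
    if (values >= 2.0 ** 53).any():
        raise CorruptionError("varint value too large")
    return values.astype(np.int64), offset + span


# ---------------------------------------------------------------------------
# Encode / decode
# ---------------------------------------------------------------------------

def encode_diff(seq, ref, *, ref_kind: int = 0, ref_id: int = 0) -> DiffRecord:
    """Record every position where ``seq`` differs from ``ref``.

    Missing values participate as ordinary symbols (MISSING_MARK), so the
    encoding is lossless for them too.
    """
    seq = np.asarray(seq)
    ref = np.asarray(ref)
    if seq.shape != ref.shape:
        raise ParameterError(f"length mismatch: {seq.shape} vs {ref.shape}")
    positions = np.nonzero(seq != ref)[0].astype(np.int64)
    modes = seq[positions].astype(np.uint8)
    return DiffRecord(positions=positions, modes=modes,
                      n_markers=int(seq.shape[0]),
                      ref_kind=ref_kind, ref_id=ref_id)


def decode_diff(ref, record: DiffRecord) -> np.ndarray:
    """Invert :func:`encode_diff`: copy ``ref`` and replace listed positions."""
    ref = np.asarray(ref)
    if record.n_markers != ref.shape[0]:
        raise CorruptionError(
            f"record encodes {record.n_markers} markers, reference has "
            f"{ref.shape[0]}")
    if record.n_diffs and (int(record.positions[-1]) >= ref.shape[0]
                           or int(record.positions[0]) < 0):
        raise CorruptionError("diff position out of range")
    out = ref.copy()
    out[record.positions] = record.modes.astype(out.dtype)
    return out


def pack_diffs(record: DiffRecord) -> bytes:
    """Deterministic byte encoding of a record's (position, mode) pairs."""
    d = record.n_diffs
    if d == 0:
        return b"\x00"
    deltas = np.diff(record.positions, prepend=np.int64(0))
    deltas[0] = record.positions[0]
    values = (deltas.astype(np.uint64) << np.uint64(2)) | record.modes.astype(np.uint64)
    return encode_varint(d) + encode_varints(values)


def unpack_diffs(buf: bytes, offset: int = 0, *, n_markers: int,
                 ref_kind: int = 0, ref_id: int = 0) -> tuple[DiffRecord, int]:
    """Inverse of :func:`pack_diffs`; returns (record, next offset)."""
    d, pos = decode_varint(buf, offset)
    values, pos = decode_varints(buf, d, pos)
    modes = (values & 3).astype(np.uint8)
    positions = np.cumsum(values >> 2).astype(np.int64)
    if d and (positions[0] < 0 or np.any(np.diff(positions) <= 0)):
        raise CorruptionError("diff positions not strictly increasing")
    if d and positions[-1] >= n_markers:
        raise CorruptionError("diff position beyond sequence length")
    record = DiffRecord(positions=positions, modes=modes, n_markers=n_markers,
                        ref_kind=ref_kind, ref_id=ref_id)
    return record, pos
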