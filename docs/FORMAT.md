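# The `.trcm` container format (version 1)

All integers are little-endian. "varint" is the LEB128-style unsigned
encoding: 7 payload bits per byte, high bit set on every byte except the
last. "JSON blob" is a UTF-8 JSON document with sorted keys and no
whitespace, deflated with zlib level 6 — so identical logical content always
produces identical bytes, and the whole file is deterministic for identical
inputs and parameters.

A file is four consecutive regions: preamble, core section, record blocks,
index section. Every byte of the file is covered by exactly one CRC-32, so
any single-byte corruption is detected on read.

## 1. Preamble

| offset | size | field |
|---|---|---|
| 0 | 4 | magic `"TRCM"` |
| 4 | 1 | format version (`1`) |
| 5 | 64 | container name, UTF-8, NUL-padded |
| 69 | 128 | description, UTF-8, NUL-padded |
| 197 | 4 | `meta_len` (u32) |
| 201 | `meta_len` | metadata JSON blob |
| … | 8 | `index_offset` (u64): absolute offset of the index section |
| … | 4 | CRC-32 of every preceding preamble byte |

Readers validate in this order: magic, version, CRC. An unknown version is
reported as such (not as generic corruption) before the CRC is checked.

The metadata blob is an object with keys:

- `n`, `e`, `k` — individuals, markers, clusters
- `block_size`, `deflate`, `mode` (`"trcm"` or `"orcm"`), `params`
  (the full parameter set of the compression run)
- `markers` — list of `[marker_id, major_allele, minor_allele, maf,
  position_index]`
- `individual_ids` — list of N ids in row order
- `ped_metadata` — list of the six leading PED columns per row, or `null`
- `dictionary` — static self-description of the diff alphabet
  (mode 0 = homozygous major, 1 = heterozygous, 2 = homozygous minor,
  3 = missing; positions stored as varint gap deltas with the mode in the
  low 2 bits)

## 2. Core section

```
u32  core_len
core_len bytes: K cores, each 2-bit packed (4 codes per byte, first code in
                the low bits; each core padded separately to ceil(E/4) bytes)
u32  CRC-32 of the core payload
```

An empty panel stores `core_len = 0`.

## 3. Record blocks

Sequences are grouped in row order into blocks of `block_size` records
(default 64; the last block may be short). Each block is:

```
u8   flag        1 = payload deflated, 0 = raw
u32  raw_len     size of the decoded payload
u32  stored_len  size of the stored payload
stored_len bytes of payload
u32  CRC-32 over flag + raw_len + stored_len + stored payload
```

The decoded payload is a concatenation of per-sequence records:

```
u8      kind      0 = centre-encoded, 1 = peer-encoded
varint  ref       cluster index (kind 0) or global row of the peer (kind 1)
varint  D         number of differing positions
D x varint        (position_gap << 2) | mode
```

`position_gap` is the gap from the previous differing position (the first
gap is the absolute position), so positions are strictly increasing; a
sequence identical to its reference stores the single byte `0x00` for its
diff part. Decoding applies `mode` at each position over the reference row:
for a centre-encoded sequence the reference is core `ref`; for a
peer-encoded one it is the decoded row `ref`, which is always
centre-encoded (two-level forest), so any row decodes in at most two hops.

## 4. Index section

Starts at `index_offset`:

```
u32  idx_len
idx_len bytes: index JSON blob
u32  CRC-32 of the index blob
```

The index object has:

- `block_offsets` — absolute file offset of each block, in block order
- `entries` — one `[individual_id, row, group, hierarchy, reference, block,
  offset_in_block]` per sequence, sorted by id (`hierarchy` is 1 for
  centre-encoded, 2 for peer-encoded; `offset_in_block` addresses the
  record inside the decoded block payload)

The index is fully derivable from a linear scan of the blocks plus the
header metadata; regenerating it reproduces the stored section
byte-for-byte. Random access to one individual therefore needs only the
preamble, the core section, the index, and at most two blocks (the target
record's block and, for a peer-encoded row, its reference's block).
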