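import io

import numpy as np
import pytest

from trcmgene import (
    AssemblyError,
    CorruptionError,
    NotFoundError,
    PanelSpec,
    RandomAccessReader,
    RunConfig,
    UnsupportedVersionError,
    compress_matrix,
    compression_factor,
    generate_panel,
    read_container,
    read_header,
    write_container,
)
from trcmgene.container import rebuild_index, stored_index_section
from trcmgene.genotype_io import GenotypeMatrix


def _compress_bytes(matrix, config=None) -> bytes:
    buf = io.BytesIO()
    compress_matrix(matrix, buf, config or RunConfig(seed=0))
    return buf.getvalue()


@pytest.fixture
def container_bytes(small_panel):
    matrix, _ = small_panel
    return matrix, _compress_bytes(matrix)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_decode_reproduces_panel(self, seed):
        spec = PanelSpec(n_individuals=40, n_markers=120, n_clusters=2,
                         mu_in=0.05, rho=0.3, mu_ring=0.4, missing_rate=0.03,
                         seed=seed)
        matrix, _ = generate_panel(spec)
        data = _compress_bytes(matrix, RunConfig(seed=seed, block_size=7))
        decoded, header = read_container(io.BytesIO(data))
        assert np.array_equal(decoded.codes, matrix.codes)
        assert decoded.individual_ids == matrix.individual_ids
        assert [m.marker_id for m in decoded.markers] == \
            [m.marker_id for m in matrix.markers]

    def test_deterministic_bytes(self, small_panel):
        matrix, _ = small_panel
        assert _compress_bytes(matrix) == _compress_bytes(matrix)

    def test_empty_panel_container(self):
        matrix = GenotypeMatrix([], [], np.zeros((0, 0), dtype=np.int8))
        data = _compress_bytes(matrix)
        decoded, header = read_container(io.BytesIO(data))
        assert header.n_individuals == 0 and header.n_markers == 0
        assert decoded.codes.shape == (0, 0)

    def test_ped_metadata_preserved(self, tmp_path):
        from trcmgene import compress_files, decompress_file

        ped = tmp_path / "p.ped"
        ped.write_text("FAM1 I1 0 0 1 2 A A A C\nFAM2 I2 I1 0 2 1 C C A A\n")
        out = tmp_path / "p.trcm"
        compress_files(ped, out, config=RunConfig(k=1, seed=0))
        back = tmp_path / "back.ped"
        decompress_file(out, back)
        assert back.read_text() == ped.read_text()

    def test_inconsistent_inputs_rejected_before_writing(self, small_panel, tmp_path):
        from trcmgene import kmeans_cluster, assign_references

        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 3, seed=0)
        assignment = assign_references(matrix, model)
        clipped = GenotypeMatrix(matrix.individual_ids[:10],
                                 matrix.markers, matrix.codes[:10])
        target = tmp_path / "bad.trcm"
        with pytest.raises(AssemblyError):
            write_container(clipped, model, assignment, target)
        assert not target.exists()

    def test_duplicate_ids_rejected(self, small_panel):
        from trcmgene import kmeans_cluster, assign_references

        matrix, _ = small_panel
        dup = GenotypeMatrix(["X"] * matrix.n_individuals, matrix.markers,
                             matrix.codes)
        model = kmeans_cluster(dup, 2, seed=0)
        assignment = assign_references(dup, model)
        with pytest.raises(AssemblyError, match="unique"):
            write_container(dup, model, assignment, io.BytesIO())


class TestHeader:
    def test_header_reports_panel_shape(self, container_bytes):
        matrix, data = container_bytes
        header = read_header(io.BytesIO(data))
        assert header.n_individuals == matrix.n_individuals
        assert header.n_markers == matrix.n_markers
        assert header.mode == "trcm"
        assert header.params["seed"] == 0

    def test_bad_magic(self):
        with pytest.raises(CorruptionError, match="not a TRCM container"):
            read_header(io.BytesIO(b"GZIP" + b"\x00" * 64))

    def test_truncated_header_is_corruption_not_crash(self, container_bytes):
        _, data = container_bytes
        with pytest.raises(CorruptionError):
            read_header(io.BytesIO(data[:50]))

    def test_future_version_rejected(self, container_bytes):
        _, data = container_bytes
        bumped = data[:4] + bytes([99]) + data[5:]
        with pytest.raises(UnsupportedVersionError):
            read_header(io.BytesIO(bumped))

    def test_empty_panel_header(self):
        matrix = GenotypeMatrix([], [], np.zeros((0, 0), dtype=np.int8))
        header = read_header(io.BytesIO(_compress_bytes(matrix)))
        assert header.n_individuals == 0
        assert header.n_blocks == 0


class TestRandomAccess:
    def test_every_id_matches_full_decode(self, container_bytes):
        matrix, data = container_bytes
        full, _ = read_container(io.BytesIO(data))
        with RandomAccessReader(io.BytesIO(data)) as reader:
            for i, ident in enumerate(matrix.individual_ids):
                assert np.array_equal(reader.extract(ident), full.codes[i])

    def test_unknown_id_lists_nearest(self, container_bytes):
        _, data = container_bytes
        with RandomAccessReader(io.BytesIO(data)) as reader:
            with pytest.raises(NotFoundError, match="nearest"):
                reader.extract("NOSUCH")

    def test_bytes_read_bounded_by_two_blocks(self, small_panel):
        matrix, _ = small_panel
        data = _compress_bytes(matrix, RunConfig(seed=0, block_size=4))
        header = read_header(io.BytesIO(data))
        index_len = len(data) - header.index_offset
        # blocks region bounds: preamble+core ends where block 0 starts
        with RandomAccessReader(io.BytesIO(data)) as probe:
            blocks_start = probe.index.block_offsets[0]
            offs = probe.index.block_offsets + [header.index_offset]
            max_block = max(b - a for a, b in zip(offs, offs[1:]))
        budget = blocks_start + index_len + 2 * max_block
        for ident in matrix.individual_ids:
            with RandomAccessReader(io.BytesIO(data)) as reader:
                reader.extract(ident)
                assert reader.bytes_read <= budget

    def test_extract_alleles_matches_undigitize(self, container_bytes):
        from trcmgene import undigitize

        matrix, data = container_bytes
        raw = undigitize(matrix)
        with RandomAccessReader(io.BytesIO(data)) as reader:
            genos = reader.extract_alleles(matrix.individual_ids[3])
        assert genos == ["".join(p) for p in raw.pairs[3]]


class TestIndex:
    def test_index_regenerable_from_linear_scan(self, container_bytes):
        _, data = container_bytes
        assert rebuild_index(io.BytesIO(data)) == \
            stored_index_section(io.BytesIO(data))

    def test_index_sorted_alphabetically(self, container_bytes):
        with RandomAccessReader(io.BytesIO(container_bytes[1])) as reader:
            ids = [e.individual_id for e in reader.index.entries]
        assert ids == sorted(ids)


class TestCorruptionFirewall:
    def test_sampled_byte_flips_detected(self, container_bytes):
        _, data = container_bytes
        rng = np.random.default_rng(0)
        for pos in rng.choice(len(data), size=120, replace=False):
            bad = bytearray(data)
            bad[pos] ^= 0xFF
            with pytest.raises(CorruptionError):
                read_container(io.BytesIO(bytes(bad)))

    def test_truncated_file_detected(self, container_bytes):
        _, data = container_bytes
        with pytest.raises(CorruptionError):
            read_container(io.BytesIO(data[:-10]))


class TestCompressionFactor:
    def test_identical_sizes_give_one(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        a.write_bytes(b"x" * 100)
        b.write_bytes(b"y" * 100)
        assert compression_factor(a, b) == 1.0

    def test_deterministic(self, tmp_path, small_panel):
        from trcmgene.synthetic import write_ped

        matrix, _ = small_panel
        ped = tmp_path / "p.ped"
        write_ped(matrix, ped)
        out = tmp_path / "p.trcm"
        compress_matrix(matrix, out, RunConfig(seed=0))
        assert compression_factor(ped, out) == compression_factor(ped, out)
        assert compression_factor(ped, out) > 1.0
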