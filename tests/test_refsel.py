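import numpy as np
import pytest

from helpers import brute_force_references, fig_style_cluster
from trcmgene import (
    KIND_CENTRE,
    KIND_PEER,
    ParameterError,
    ZONE_AI,
    ZONE_AII,
    ZONE_B,
    assign_references,
    auto_thresholds,
    kmeans_cluster,
    partition_cluster,
    select_references,
)
from trcmgene.refsel import ZonePartition


class TestPartitionCluster:
    def test_thresholds_beyond_radius_give_pure_centre_encoding(self, small_panel):
        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 3, seed=0)
        r = float(model.radii[0])
        part = partition_cluster(matrix, model, 0, t1=r + 1, t2=r / 2)
        assert not (part.labels == ZONE_B).any()
        assert part.ring_width == 0.0

    def test_t2_beyond_radius_puts_all_in_inner_disc(self, small_panel):
        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 3, seed=0)
        r = float(model.radii[0])
        part = partition_cluster(matrix, model, 0, t1=r + 2, t2=r + 1)
        assert (part.labels == ZONE_AI).all()

    def test_invalid_threshold_order_rejected(self, small_panel):
        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 2, seed=0)
        with pytest.raises(ParameterError):
            partition_cluster(matrix, model, 0, t1=1.0, t2=2.0)

    def test_fig_style_zone_labels_match_hand_labels(self):
        _, part = fig_style_cluster()
        zones = part.labels
        assert [i for i in range(11) if zones[i] == ZONE_AI] == [0, 1, 2, 8]
        assert [i for i in range(11) if zones[i] == ZONE_AII] == [4, 5, 6, 10]
        assert [i for i in range(11) if zones[i] == ZONE_B] == [3, 7, 9]
        assert part.ring_width == pytest.approx(1.5)


class TestAutoThresholds:
    def test_quantiles_of_uniform_distances(self):
        """q1=0.8 / q2=0.5 on member distances 1..10 give 8.2 and 5.5
        (linear-interpolation quantiles, hand-computed)."""
        from trcmgene.clustering import ClusterModel

        pts = np.arange(1.0, 11.0)[:, None]  # distances to origin are 1..10
        model = ClusterModel(
            n_clusters=1, centres=np.array([[0.0]]),
            cores=np.zeros((1, 1), dtype=np.int8),
            assignment=np.zeros(10, dtype=np.int64),
            radii=np.array([10.0]), wcss=0.0)
        t1, t2 = auto_thresholds(pts, model, 0)
        assert t1 == pytest.approx(8.2)
        assert t2 == pytest.approx(5.5)

    def test_thresholds_strictly_ordered_even_when_equidistant(self):
        pts = np.array([[1.0, 0], [0, 1.0], [-1.0, 0], [0, -1.0]])
        model = kmeans_cluster(pts, 1, seed=0)
        t1, t2 = auto_thresholds(pts, model, 0)
        assert t1 > t2 > 0

    def test_single_member_cluster_fallback(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        model = kmeans_cluster(pts, 2, seed=0)
        t1, t2 = auto_thresholds(pts, model, 0)
        assert t1 > t2 > 0
        assert t2 == pytest.approx(t1 / 2)

    def test_invalid_quantiles_rejected(self, small_panel):
        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 2, seed=0)
        with pytest.raises(ParameterError):
            auto_thresholds(matrix, model, 0, q1=0.5, q2=0.8)


class TestSelectReferences:
    def test_empty_b_zone_keeps_centre_encoding(self):
        pts, part = fig_style_cluster()
        inner = part.labels != ZONE_B
        sub = ZonePartition(cluster=0, member_rows=part.member_rows[inner],
                            distances=part.distances[inner],
                            labels=part.labels[inner], t1=part.t1,
                            t2=part.t2, ring_width=0.0)
        refs = select_references(sub, pts[inner], missing_code=None)
        assert (refs.kind == KIND_CENTRE).all()

    def test_fig_style_topology(self):
        """P4 and P10 share reference P5; P8 reaches P11 only after radius
        growth (indices are 0-based: P4=3, P5=4, P8=7, P10=9, P11=10)."""
        pts, part = fig_style_cluster()
        refs = select_references(part, pts, missing_code=None)
        assert refs.kind[3] == KIND_PEER and refs.ref[3] == 4
        assert refs.kind[9] == KIND_PEER and refs.ref[9] == 4
        assert refs.shared_from[9] == 3        # P10 inherits P4's block
        assert refs.hops[3] == 0
        assert refs.kind[7] == KIND_PEER and refs.ref[7] == 10
        assert refs.hops[7] >= 1               # grown radius was needed
        # everyone in zone A stays on the centre
        for i in (0, 1, 2, 4, 5, 6, 8, 10):
            assert refs.kind[i] == KIND_CENTRE

    def test_matches_brute_force_oracle_on_fig_fixture(self):
        pts, part = fig_style_cluster()
        refs = select_references(part, pts, missing_code=None)
        oracle = brute_force_references(part, pts, missing_code=None)
        for i, (ref, radius, hops, shared) in oracle.items():
            assert refs.ref[i] == ref
            assert refs.radius[i] == pytest.approx(radius)
            assert refs.hops[i] == hops
            assert refs.shared_from[i] == shared

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_clusters(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        pts = rng.normal(size=(n, 2)) * rng.uniform(0.5, 3.0)
        dist = np.sqrt((pts ** 2).sum(axis=1))
        t1 = float(np.quantile(dist, 0.7))
        t2 = float(np.quantile(dist, 0.4))
        if not t1 > t2 > 0:
            pytest.skip("degenerate draw")
        labels = np.full(n, ZONE_B, dtype=np.int8)
        labels[dist <= t1] = ZONE_AII
        labels[dist <= t2] = ZONE_AI
        part = ZonePartition(cluster=0, member_rows=np.arange(n),
                             distances=dist, labels=labels, t1=t1, t2=t2,
                             ring_width=max(float(dist.max()) - t1, 0.0))
        refs = select_references(part, pts, missing_code=None)
        oracle = brute_force_references(part, pts, missing_code=None)
        for i in range(n):
            if labels[i] != ZONE_B:
                assert refs.kind[i] == KIND_CENTRE
                continue
            ref, radius, hops, shared = oracle[i]
            assert refs.ref[i] == ref
            assert refs.radius[i] == pytest.approx(radius)
            assert refs.hops[i] == hops
            assert refs.shared_from[i] == shared

    def test_all_b_points_of_block_share_reference(self):
        pts, part = fig_style_cluster()
        refs = select_references(part, pts, missing_code=None)
        shared = refs.shared_from[9]
        assert refs.ref[9] == refs.ref[shared]

    def test_empty_a_zone_falls_back_to_centre(self, caplog):
        # every member beyond t1: zone A empty
        pts = np.array([[5.0, 0.0], [0.0, 5.0], [-5.0, 0.0]])
        dist = np.sqrt((pts ** 2).sum(axis=1))
        part = ZonePartition(cluster=0, member_rows=np.arange(3),
                             distances=dist,
                             labels=np.full(3, ZONE_B, dtype=np.int8),
                             t1=2.0, t2=1.0, ring_width=3.0)
        import logging
        with caplog.at_level(logging.WARNING, logger="trcmgene.refsel"):
            refs = select_references(part, pts, missing_code=None)
        assert (refs.kind == KIND_CENTRE).all()
        assert any("zone A empty" in r.message for r in caplog.records)


class TestAssignReferences:
    def test_two_level_forest(self, small_panel):
        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 3, seed=1)
        assignment = assign_references(matrix, model)
        peers = np.nonzero(assignment.kind == KIND_PEER)[0]
        if peers.size:
            assert (assignment.kind[assignment.ref[peers]] == KIND_CENTRE).all()
        centres = np.nonzero(assignment.kind == KIND_CENTRE)[0]
        assert (assignment.ref[centres] == model.assignment[centres]).all()

    def test_orcm_mode_forces_centre_encoding(self, small_panel):
        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 3, seed=1)
        assignment = assign_references(matrix, model, mode="orcm")
        assert (assignment.kind == KIND_CENTRE).all()
        assert assignment.peer_fraction == 0.0

    def test_lowering_t1_never_decreases_peer_count(self, small_panel):
        matrix, _ = small_panel
        model = kmeans_cluster(matrix, 3, seed=1)
        counts = []
        for q1 in (0.95, 0.8, 0.6, 0.4):
            a = assign_references(matrix, model, q1=q1, q2=0.2)
            counts.append(int((a.kind == KIND_PEER).sum()))
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))
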