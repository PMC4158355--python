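"""Distance matrices, threshold derivation, and region clustering."""

from __future__ import annotations

import itertools
import random

import pytest

from cactaintrons.io import BoundaryRecord
from cactaintrons.regions import (
    REGION_MEMBER,
    SINGLETON,
    SMALL_CLUSTER,
    ClusterConfig,
    call_regions,
    classify_boundaries,
    cluster_boundaries,
    derive_threshold,
    pairwise_distances,
    region_gap_stats,
)


def records_at(columns):
    """One single-boundary transposase per column (names keep input order)."""
    return [
        BoundaryRecord(name=f"t{i}", index=1, protein_pos=100 + i, msa_col=col)
        for i, col in enumerate(columns)
    ]


def replay_agglomeration(columns, threshold):
    """Independent by-hand replay of the merge schedule on frozen label sets.

    Merges the closest pair of groups (minimum member distance) whose
    union stays within *threshold*, smallest leftmost column first on
    ties; returns the final partition as a set of frozensets of columns'
    input indices.
    """
    groups = {frozenset([i]): [c] for i, c in enumerate(columns)}
    while True:
        candidates = []
        for ga, gb in itertools.combinations(groups, 2):
            cols = groups[ga] + groups[gb]
            if max(cols) - min(cols) > threshold:
                continue
            link = min(abs(a - b) for a in groups[ga] for b in groups[gb])
            candidates.append((link, min(cols), tuple(sorted(ga | gb)), ga, gb))
        if not candidates:
            return set(groups)
        _, _, _, ga, gb = min(candidates, key=lambda t: t[:3])
        merged = ga | gb
        cols = groups.pop(ga) + groups.pop(gb)
        groups[merged] = cols


class TestDistances:
    def test_distance_matrix_values(self):
        recs = records_at([568, 563, 782, 782])
        d = pairwise_distances(recs)
        assert d.loc["t0_1", "t1_1"] == 5
        assert d.loc["t2_1", "t3_1"] == 0
        assert (d.values == d.values.T).all()
        assert (d.values.diagonal() == 0).all()

    def test_paper_spot_distances(self, table1):
        cols = {r.label: r.msa_col for r in table1.projected()}
        assert abs(cols["Baron_1"] - cols["Chester_1"]) == 5
        assert abs(cols["Baldur_1"] - cols["C_1"]) == 11
        assert abs(cols["Baldur_1"] - cols["EnSpm2_Mdom_1"]) == 0

    def test_removed_boundary_rejected(self):
        recs = [BoundaryRecord("a", 1, 10, None)]
        with pytest.raises(ValueError, match="REMOVED"):
            pairwise_distances(recs)


class TestThreshold:
    @pytest.mark.parametrize("lengths,expected", [([33], 16), ([2], 1), ([34], 17), ([33, 45, 204], 16)])
    def test_half_shortest_intron(self, lengths, expected):
        assert derive_threshold(lengths) == expected

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError, match="explicitly"):
            derive_threshold([])


class TestClustering:
    def test_single_boundary_is_a_singleton_cluster(self):
        clusters = cluster_boundaries(records_at([100]), ClusterConfig())
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_fixture_region_g_membership(self, table1):
        clusters = cluster_boundaries(table1.projected(), ClusterConfig(threshold=16))
        g = next(c for c in clusters if 564 in c.columns)
        assert sorted(g.labels) == ["Baron_1", "Chester_1", "EnSpm12_Fves_1", "Korbin_1"]
        assert g.span == (563, 568)

    def test_fixture_column_910_stays_unclustered(self, table1):
        """The boundary between the 879-895 and 920-936 regions joins neither."""
        clusters = cluster_boundaries(table1.projected(), ClusterConfig(threshold=16))
        c910 = next(c for c in clusters if 910 in c.columns)
        assert c910.labels == ("I_2",)

    def test_cluster_diameters_respect_threshold(self, table1):
        config = ClusterConfig(threshold=16)
        for c in cluster_boundaries(table1.projected(), config):
            assert c.diameter <= config.threshold

    def test_maximality_no_two_clusters_mergeable(self, table1):
        config = ClusterConfig(threshold=16)
        clusters = cluster_boundaries(table1.projected(), config)
        for a, b in itertools.combinations(clusters, 2):
            lo = min(a.span[0], b.span[0])
            hi = max(a.span[1], b.span[1])
            assert hi - lo > config.threshold

    def test_invariant_under_input_permutation(self):
        rng = random.Random(99)
        for trial in range(200):
            n = rng.randint(1, 12)
            columns = [rng.randint(0, 60) for _ in range(n)]
            recs = records_at(columns)
            config = ClusterConfig(threshold=rng.randint(0, 20))
            reference = {
                frozenset(c.labels) for c in cluster_boundaries(recs, config)
            }
            shuffled = recs[:]
            rng.shuffle(shuffled)
            assert {
                frozenset(c.labels) for c in cluster_boundaries(shuffled, config)
            } == reference

    def test_random_instances_feasible_and_maximal(self):
        rng = random.Random(7)
        for trial in range(1000):
            n = rng.randint(1, 10)
            columns = [rng.randint(0, 80) for _ in range(n)]
            threshold = rng.randint(0, 25)
            clusters = cluster_boundaries(records_at(columns), ClusterConfig(threshold=threshold))
            assert sum(c.size for c in clusters) == n
            for c in clusters:
                assert c.diameter <= threshold
            for a, b in itertools.combinations(clusters, 2):
                lo = min(a.span[0], b.span[0])
                hi = max(a.span[1], b.span[1])
                assert hi - lo > threshold

    def test_agrees_with_hand_replayed_agglomeration(self):
        rng = random.Random(17)
        for trial in range(300):
            n = rng.randint(1, 8)
            columns = [rng.randint(0, 50) for _ in range(n)]
            threshold = rng.randint(0, 20)
            got = {
                frozenset(int(lab.split("_")[0][1:]) for lab in c.labels)
                for c in cluster_boundaries(records_at(columns), ClusterConfig(threshold=threshold))
            }
            assert got == replay_agglomeration(columns, threshold)


class TestRegions:
    def test_fixture_yields_exactly_four_regions(self, fixture_regions):
        assert len(fixture_regions.regions) == 4
        spans = [r.span for r in fixture_regions.regions]
        assert spans == [(563, 568), (771, 783), (879, 895), (920, 936)]

    def test_min_region_size_one_promotes_every_cluster(self):
        recs = records_at([10, 11, 40])
        config = ClusterConfig(threshold=5, min_region_size=1)
        rs = call_regions(cluster_boundaries(recs, config), config)
        assert len(rs.regions) == len(rs.clusters) == 2

    def test_min_region_size_three_adds_the_833_846_chain(self, table1):
        config = ClusterConfig(threshold=16, min_region_size=3)
        rs = call_regions(cluster_boundaries(table1.projected(), config), config)
        extra = [r for r in rs.regions if r.span == (833, 846)]
        assert len(extra) == 1
        assert sorted(extra[0].cluster.labels) == ["Aron_1", "Dario_2", "EnSpm10_Fves_1"]
        assert len(rs.regions) == 5

    def test_gap_stats_on_fixture(self, fixture_regions, table1):
        gaps = region_gap_stats(fixture_regions, table1)
        assert gaps["R2"][0] == 60  # upstream of the 771-783 region
        assert gaps["R4"][1] == 36  # downstream of the 920-936 region

    def test_gap_none_when_no_outside_boundary(self):
        recs = records_at([10, 11, 12, 13])
        config = ClusterConfig(threshold=5, min_region_size=4)
        rs = call_regions(cluster_boundaries(recs, config), config)
        assert region_gap_stats(rs, recs)["R1"] == (None, None)


class TestClassification:
    def test_region_member(self, fixture_regions, table1):
        cls = classify_boundaries(fixture_regions, table1)
        assert cls["Seamus_3"] == REGION_MEMBER
        assert fixture_regions.cluster_of("Seamus_3").span == (920, 936)

    def test_small_cluster_pair(self, fixture_regions, table1):
        cls = classify_boundaries(fixture_regions, table1)
        assert cls["Horace_1"] == SMALL_CLUSTER
        assert cls["Dario_1"] == SMALL_CLUSTER
        assert fixture_regions.cluster_of("Horace_1").labels == ("Dario_1", "Horace_1")

    def test_singletons_and_removed(self, fixture_regions, table1):
        cls = classify_boundaries(fixture_regions, table1)
        assert cls["ATENSPM6_Athal_1"] == SINGLETON
        assert cls["I_2"] == SINGLETON
        assert cls["EnSpm8_Sbic_2"] == "not_evaluated"
        assert len(cls) == 86  # every boundary labelled
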