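"""Interval algebra: intersection, SRO, clustering, catalog assignment.

Independent oracles: a per-base boolean bitmap for intersection/SRO, and
an explicit union-find over the pairwise overlap matrix for clustering.
"""

import numpy as np
import pytest

from cnvcohort.core import GenomicInterval
from cnvcohort.intervals import (
    assign_to_catalog,
    cluster_by_overlap,
    intersect,
    recurrent_loci,
    shortest_region_of_overlap,
)
from cnvcohort.core import LocusCatalogEntry

from conftest import make_call


# -- oracles -----------------------------------------------------------------

def bitmap_intersection(intervals, domain=10_000):
    """Per-base occupancy oracle: AND of boolean masks."""
    mask = np.ones(domain, dtype=bool)
    for iv in intervals:
        m = np.zeros(domain, dtype=bool)
        m[iv.start:iv.end] = True
        mask &= m
    hits = np.flatnonzero(mask)
    if hits.size == 0:
        return None
    # oracle valid only when the intersection is one contiguous run
    assert hits[-1] - hits[0] + 1 == hits.size
    return int(hits[0]), int(hits[-1] + 1)


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def random_intervals(rng, n, domain=10_000, chrom="chr1"):
    starts = rng.integers(0, domain - 2, size=n)
    lengths = rng.integers(1, domain // 4, size=n)
    return [
        GenomicInterval(chrom, int(s), int(min(s + l, domain)))
        for s, l in zip(starts, lengths)
    ]


# -- intersect ---------------------------------------------------------------

class TestIntersect:
    def test_printed_13q_duplications_overlap(self):
        # the two 13q duplications shared by unrelated carriers
        a = GenomicInterval("chr13", 23_706_634, 24_910_765)
        b = GenomicInterval("chr13", 19_440_913, 31_031_907)
        result = intersect(a, b)
        assert result == GenomicInterval("chr13", 23_706_634, 24_910_765)
        assert result.length == 1_204_131
        assert intersect(b, a) == result

    def test_self_intersection_is_identity(self):
        a = GenomicInterval("chr5", 10, 99)
        assert intersect(a, a) == a

    def test_disjoint_distal_22q_calls_do_not_intersect(self):
        a = GenomicInterval("chr22", 21_468_437, 22_959_609)
        b = GenomicInterval("chr22", 23_012_069, 23_648_827)
        assert intersect(a, b) is None

    def test_different_chromosomes_empty_not_error(self):
        assert intersect(
            GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)
        ) is None

    def test_matches_bitmap_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(400):
            a, b = random_intervals(rng, 2)
            got = intersect(a, b)
            expected = bitmap_intersection([a, b])
            if expected is None:
                assert got is None
            else:
                assert (got.start, got.end) == expected


class TestShortestRegionOfOverlap:
    def test_five_2q37_deletions(self, calls_by_patient):
        dels = [
            c
            for pid in ("P10", "P11", "P12", "P13", "P14")
            for c in calls_by_patient[pid]
            if c.cnv_type.value == "del" and c.interval.start > 230_000_000
        ]
        assert len(dels) == 5
        sro = shortest_region_of_overlap(dels)
        assert sro == GenomicInterval("chr2", 240_880_562, 242_948_060)
        assert sro.length == 2_067_498

    def test_three_9p_deletions(self, calls_by_patient):
        dels = [c for pid in ("P20", "P21", "P22") for c in calls_by_patient[pid]]
        sro = shortest_region_of_overlap(dels)
        assert sro == GenomicInterval("chr9", 204_149, 8_807_593)
        assert sro.length == 8_603_444

    def test_single_call_returns_itself(self):
        call = make_call("X", "chr3", 100, 500)
        assert shortest_region_of_overlap([call]) == call.interval

    def test_mixed_chromosomes_error(self):
        with pytest.raises(ValueError, match="chromosome"):
            shortest_region_of_overlap(
                [make_call("A", "chr1", 0, 10), make_call("B", "chr2", 0, 10)]
            )

    def test_order_invariant_and_contained_in_every_input(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ivs = random_intervals(rng, int(rng.integers(2, 6)))
            sro = shortest_region_of_overlap(ivs)
            perm = [ivs[i] for i in rng.permutation(len(ivs))]
            assert shortest_region_of_overlap(perm) == sro
            expected = bitmap_intersection(ivs)
            if sro is None:
                assert expected is None
            else:
                assert (sro.start, sro.end) == expected
                assert all(iv.contains(sro) for iv in ivs)


class TestClusterByOverlap:
    def test_four_distal_22q_deletions_link_transitively(self, calls_by_patient):
        calls = [
            c
            for pid in ("P44", "P45", "P46", "P47")
            for c in calls_by_patient[pid]
            if c.interval.chrom == "chr22"
        ]
        clusters = cluster_by_overlap(calls)
        assert len(clusters) == 1
        assert clusters[0].n_patients == 4
        # transitive only: the two proximal-distal pairs do not all overlap
        assert clusters[0].sro is None

    def test_identical_breakpoints_cluster_separate_from_neighbour(
        self, calls_by_patient
    ):
        calls = [
            c
            for pid in ("P28", "P29", "P30")
            for c in calls_by_patient[pid]
        ]
        clusters = cluster_by_overlap(calls, ignore_type=True)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]
        pair = next(c for c in clusters if len(c.members) == 2)
        assert pair.members[0].interval == pair.members[1].interval
        assert pair.sro == pair.members[0].interval

    def test_del_dup_pooling_toggle(self):
        calls = [
            make_call("A", "chr1", 100, 200, "del"),
            make_call("B", "chr1", 150, 250, "dup"),
        ]
        assert len(cluster_by_overlap(calls, ignore_type=True)) == 1
        assert len(cluster_by_overlap(calls, ignore_type=False)) == 2

    def test_disjoint_chromosomes_all_singletons(self):
        calls = [make_call(f"P{i}", f"chr{i + 1}", 0, 100) for i in range(4)]
        clusters = cluster_by_overlap(calls)
        assert [len(c.members) for c in clusters] == [1, 1, 1, 1]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(150):
            n = int(rng.integers(2, 12))
            ivs = random_intervals(rng, n, domain=2_000)
            calls = [make_call(f"P{i}", iv.chrom, iv.start, iv.end)
                     for i, iv in enumerate(ivs)]
            uf = UnionFind(n)
            for i in range(n):
                for j in range(i + 1, n):
                    if ivs[i].overlaps(ivs[j]):
                        uf.union(i, j)
            expected = {}
            for i in range(n):
                expected.setdefault(uf.find(i), set()).add(f"P{i}")
            got = {
                frozenset(m.patient_id for m in c.members)
                for c in cluster_by_overlap(calls)
            }
            assert got == {frozenset(s) for s in expected.values()}

    def test_membership_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        ivs = random_intervals(rng, 10, domain=3_000)
        calls = [make_call(f"P{i}", iv.chrom, iv.start, iv.end)
                 for i, iv in enumerate(ivs)]
        base = {frozenset(m.patient_id for m in c.members)
                for c in cluster_by_overlap(calls)}
        for _ in range(5):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            got = {frozenset(m.patient_id for m in c.members)
                   for c in cluster_by_overlap(perm)}
            assert got == base


class TestCatalogAssignment:
    def test_interstitial_deletion_assigned_to_broad_region(self, calls_by_patient,
                                                            catalog):
        p5 = calls_by_patient["P5"][0]
        assignments, unassigned = assign_to_catalog([p5], catalog)
        assert unassigned == []
        assert {a.locus_id for a in assignments} == {"1p36"}

    def test_contained_call_has_fraction_one(self):
        entry = LocusCatalogEntry(
            "toy", GenomicInterval("chr1", 0, 1_000_000)
        )
        call = make_call("A", "chr1", 100, 200)
        assignments, _ = assign_to_catalog([call], [entry])
        assert assignments[0].overlap_fraction_of_call == 1.0
        assert assignments[0].overlap_bp == 100

    def test_min_overlap_boundary(self):
        entry = LocusCatalogEntry("toy", GenomicInterval("chr1", 1000, 2000))
        call = make_call("A", "chr1", 0, 1050)  # 50 bp of overlap
        hit, _ = assign_to_catalog([call], [entry], min_overlap_bp=50)
        assert len(hit) == 1
        miss, unassigned = assign_to_catalog([call], [entry], min_overlap_bp=51)
        assert miss == [] and unassigned == [call]

    def test_empty_catalog_all_unassigned_with_warning(self, caplog):
        import logging

        call = make_call("A", "chr1", 0, 100)
        with caplog.at_level(logging.WARNING, logger="cnvcohort"):
            assignments, unassigned = assign_to_catalog([call], [])
        assert assignments == [] and unassigned == [call]
        assert any("empty" in r.message for r in caplog.records)


class TestRecurrentLoci:
    def _assignments(self, fixture_calls, catalog):
        pathogenic = [c for c in fixture_calls if c.is_pathogenic]
        known = [e for e in catalog if e.known_genomic_disorder]
        assignments, _ = assign_to_catalog(pathogenic, known)
        return assignments

    def test_fixture_recurrence_structure(self, fixture_calls, catalog):
        loci = recurrent_loci(self._assignments(fixture_calls, catalog), 2)
        assert dict(loci) == {
            "1p36": 5, "1p21.3": 2, "2q37": 5, "7q11.23": 2,
            "9p_terminal": 3, "16p13.11": 2, "16p11.2_BP4_5": 2,
            "17p11.2": 5, "22q11.2_proximal": 5, "22q11.2_distal": 4,
        }

    def test_min_patients_one_returns_every_assigned_locus(
        self, fixture_calls, catalog
    ):
        assignments = self._assignments(fixture_calls, catalog)
        all_loci = recurrent_loci(assignments, 1)
        assert {l for l, _ in all_loci} == {a.locus_id for a in assignments}

    def test_min_patients_above_cohort_empty(self, fixture_calls, catalog):
        assert recurrent_loci(self._assignments(fixture_calls, catalog), 1000) == []
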