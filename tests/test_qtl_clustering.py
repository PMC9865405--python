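"""QTL overlap clustering against a brute-force connected-components oracle."""

import numpy as np
import pytest

from kernel_hotspots import (
    GenomicInterval,
    QTLRecord,
    find_qtl_clusters,
    merge_overlapping,
    name_clusters,
)
from kernel_hotspots.core_io import ValidationError
from kernel_hotspots.projection import ProjectedQTL

from conftest import random_intervals


def oracle_components(intervals):
    """O(n^2) pairwise-overlap graph + union-find connected components."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            if intervals[i].overlaps(intervals[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(i)
    out = set()
    for members in groups.values():
        span = (
            intervals[members[0]].chrom,
            min(intervals[i].start for i in members),
            max(intervals[i].end for i in members),
        )
        out.add((span, frozenset(members)))
    return out


def as_projected(intervals, trait="KL"):
    return [
        ProjectedQTL(QTLRecord(f"q{i}", trait), iv) for i, iv in enumerate(intervals)
    ]


class TestMergeOverlapping:
    def test_disjoint_intervals_stay_separate(self):
        comps = merge_overlapping(
            [GenomicInterval("chr1", 1, 10), GenomicInterval("chr1", 20, 30)]
        )
        assert len(comps) == 2

    def test_touching_intervals_are_not_merged(self):
        comps = merge_overlapping(
            [GenomicInterval("chr1", 1, 10), GenomicInterval("chr1", 11, 30)]
        )
        assert len(comps) == 2

    def test_transitive_chain_merges_even_without_mutual_overlap(self):
        comps = merge_overlapping(
            [
                GenomicInterval("chr1", 1, 10),
                GenomicInterval("chr1", 8, 20),
                GenomicInterval("chr1", 18, 30),
            ]
        )
        assert len(comps) == 1
        assert comps[0].interval == GenomicInterval("chr1", 1, 30)
        assert set(comps[0].member_indices) == {0, 1, 2}

    @pytest.mark.parametrize("seed", range(10))
    def test_sweep_line_equals_brute_force_on_random_intervals(self, seed):
        rng = np.random.default_rng(seed)
        intervals = random_intervals(rng, 200)
        got = {
            ((c.interval.chrom, c.interval.start, c.interval.end),
             frozenset(c.member_indices))
            for c in merge_overlapping(intervals)
        }
        assert got == oracle_components(intervals)

    @pytest.mark.parametrize("seed", range(3))
    def test_idempotence_on_merged_spans(self, seed):
        rng = np.random.default_rng(100 + seed)
        spans = [c.interval for c in merge_overlapping(random_intervals(rng, 100))]
        again = [c.interval for c in merge_overlapping(spans)]
        assert sorted(again) == sorted(spans)

    def test_monotonicity_adding_interval_never_shrinks_its_component(self):
        rng = np.random.default_rng(7)
        intervals = random_intervals(rng, 80, chroms=("1",))
        base = merge_overlapping(intervals)
        extra = GenomicInterval("1", 4000, 6000)
        grown = merge_overlapping(intervals + [extra])
        comp_with_extra = next(
            c for c in grown if len(intervals) in c.member_indices
        )
        absorbed = [
            c for c in base if c.interval.overlaps(extra)
        ]
        assert len(comp_with_extra.member_indices) >= 1 + sum(
            len(c.member_indices) for c in absorbed
        )


class TestFindQtlClusters:
    def test_two_overlapping_qtls_are_below_threshold(self):
        projected = as_projected(
            [GenomicInterval("1", 100, 300), GenomicInterval("1", 200, 500)]
        )
        assert find_qtl_clusters(projected, "KL") == []

    def test_three_mutually_overlapping_qtls_form_one_cluster(self):
        projected = as_projected(
            [
                GenomicInterval("1", 100, 300),
                GenomicInterval("1", 200, 500),
                GenomicInterval("1", 150, 400),
            ]
        )
        (cluster,) = find_qtl_clusters(projected, "KL")
        assert cluster.interval == GenomicInterval("1", 100, 500)
        assert set(cluster.member_ids) == {"q0", "q1", "q2"}

    def test_two_separated_components_give_two_clusters(self):
        projected = as_projected(
            [GenomicInterval("1", i, i + 50) for i in (100, 120, 140)]
            + [GenomicInterval("1", i, i + 50) for i in (1000, 1010, 1020, 1030)]
        )
        clusters = find_qtl_clusters(projected, "KL")
        assert [c.n_members for c in clusters] == [3, 4]

    def test_members_all_overlap_cluster_span_and_join_one_cluster(self):
        rng = np.random.default_rng(11)
        projected = as_projected(random_intervals(rng, 150))
        clusters = find_qtl_clusters(projected, "KL", min_members=3)
        seen = []
        for c in clusters:
            seen.extend(c.member_ids)
            for qid in c.member_ids:
                iv = projected[int(qid[1:])].interval
                assert iv.overlaps(c.interval)
        assert len(seen) == len(set(seen))  # at most one cluster per QTL

    def test_mixed_traits_rejected(self):
        projected = as_projected([GenomicInterval("1", 1, 2)], trait="KW")
        with pytest.raises(ValidationError):
            find_qtl_clusters(projected, "KL")


class TestNaming:
    def test_indices_restart_per_chromosome_in_genome_order(self, build):
        projected = as_projected(
            [GenomicInterval("1", i, i + 10) for i in (100, 101, 102)]      # cluster 1
            + [GenomicInterval("1", i, i + 10) for i in (900, 901, 902)]    # cluster 2
            + [GenomicInterval("2", i, i + 10) for i in (50, 51, 52)],      # chr2 cluster 1
            trait="KW",
        )
        named = name_clusters(find_qtl_clusters(projected, "KW"), "KW", "QTL", build)
        assert [c.name for c in named] == ["KW-qCL1-1", "KW-qCL1-2", "KW-qCL2-1"]

    def test_qtn_kind_uses_gcl_tag(self, build):
        projected = as_projected([GenomicInterval("1", i, i + 10) for i in (1, 2, 3)])
        named = name_clusters(find_qtl_clusters(projected, "KL"), "KL", "QTN", build)
        assert named[0].name == "KL-gCL1-1"

    def test_naming_is_deterministic_under_rerun(self, build):
        rng = np.random.default_rng(3)
        projected = as_projected(random_intervals(rng, 120))
        runs = [
            [c.name for c in name_clusters(
                find_qtl_clusters(projected, "KL"), "KL", "QTL", build)]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_empty_input_gives_no_names(self, build):
        assert name_clusters([], "KL", "QTL", build) == []
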