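"""Simulator determinism, planted-truth recovery, and recovery scoring."""

import filecmp

import pytest

from kernel_hotspots import (
    GenomicInterval,
    SimulationConfig,
    TRAITS,
    recovery_report,
    simulate_dataset,
)
from kernel_hotspots.core_io import ValidationError
from kernel_hotspots.hotspots import Hotspot, integrate_hotspots
from kernel_hotspots.projection import project_batch
from kernel_hotspots.qtl_clustering import Cluster, find_qtl_clusters, name_clusters
from kernel_hotspots.qtn_clustering import QTNClusterConfig, find_qtn_clusters
from kernel_hotspots.synthetic_data import GroundTruth


def noise_free(seed, **overrides):
    kwargs = dict(
        seed=seed, missing_marker_rate=0.0, background_qtls=0, background_qtns=0
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def run_inference(dataset):
    cfg = dataset.config
    report = project_batch(dataset.qtls, dataset.markers)
    clusters = []
    for trait in TRAITS:
        per_trait = [p for p in report.projected if p.record.trait == trait]
        clusters += name_clusters(
            find_qtl_clusters(per_trait, trait), trait, "QTL", cfg.genome
        )
        qtns = [q for q in dataset.qtns if q.trait == trait]
        clusters += name_clusters(
            find_qtn_clusters(qtns, QTNClusterConfig(cfg.qtn_window, 5)),
            trait, "QTN", cfg.genome,
        )
    hotspots = integrate_hotspots(clusters, 3, cfg.genome)
    return clusters, hotspots


class TestSimulateDataset:
    def test_zero_loci_and_background_give_empty_tables(self):
        ds = simulate_dataset(noise_free(0, n_hotspot_loci=0, n_genes=0, n_go_terms=0))
        assert ds.qtls == [] and ds.qtns == [] and ds.genes == []
        assert ds.truth.expected_hotspots == []

    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        for d in ("a", "b"):
            simulate_dataset(SimulationConfig(seed=5)).write(tmp_path / d)
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert sorted(match) == sorted(names) and not mismatch and not errors

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimulationConfig(seed=1))
        b = simulate_dataset(SimulationConfig(seed=2))
        assert a.truth.loci != b.truth.loci

    def test_single_locus_recovers_one_hotspot_with_all_clusters(self):
        ds = simulate_dataset(
            noise_free(3, n_hotspot_loci=1, clusters_per_locus=4,
                       qtls_per_cluster=3, qtns_per_cluster=5)
        )
        clusters, hotspots = run_inference(ds)
        assert len(clusters) == 4
        assert len(hotspots) == 1
        assert hotspots[0].n_clusters == 4
        (locus,) = ds.truth.loci
        assert hotspots[0].interval.overlaps(locus)

    @pytest.mark.parametrize("seed", range(6))
    def test_noise_free_recovery_is_perfect(self, seed):
        ds = simulate_dataset(noise_free(seed))
        clusters, hotspots = run_inference(ds)
        rr = recovery_report(clusters, hotspots, ds.truth)
        assert rr.cluster_precision == rr.cluster_recall == 1.0
        assert rr.hotspot_precision == rr.hotspot_recall == 1.0

    def test_planted_recall_survives_sparse_background(self):
        ds = simulate_dataset(
            SimulationConfig(seed=9, missing_marker_rate=0.0,
                             background_qtls=20, background_qtns=40)
        )
        clusters, hotspots = run_inference(ds)
        rr = recovery_report(clusters, hotspots, ds.truth)
        assert rr.cluster_recall == 1.0
        assert rr.hotspot_recall == 1.0

    def test_missing_marker_fraction_converges_to_rate(self):
        rate = 0.25
        ds = simulate_dataset(
            SimulationConfig(seed=11, missing_marker_rate=rate,
                             n_hotspot_loci=8, clusters_per_locus=8,
                             qtls_per_cluster=10, background_qtls=200)
        )
        n = len(ds.qtls)
        blanked = sum(
            1 for q in ds.qtls if q.left_marker is None or q.right_marker is None
        )
        se = (rate * (1 - rate) / n) ** 0.5
        assert abs(blanked / n - rate) <= 3 * se

    def test_planted_qtls_at_a_locus_pairwise_overlap(self):
        ds = simulate_dataset(noise_free(13, n_hotspot_loci=2))
        report = project_batch(ds.qtls, ds.markers)
        for core in ds.truth.loci:
            spans = [
                p.interval for p in report.projected
                if p.interval.chrom == core.chrom and p.interval.overlaps(core)
            ]
            for a in spans:
                for b in spans:
                    assert a.overlaps(b)

    def test_expression_labels_are_honoured_by_the_filter(self):
        from kernel_hotspots import ExpressionProfile, expression_summary, filter_candidates

        ds = simulate_dataset(SimulationConfig(seed=17, n_genes=100))
        summaries = {
            gid: expression_summary(
                ExpressionProfile(gid, fpkm, ds.kernel_tissues)
            )
            for gid, fpkm in ds.expression.items()
        }
        result = filter_candidates(summaries)
        assert set(result.passing) == ds.truth.expression_pass
        assert set(result.failing) == ds.truth.expression_fail

    def test_infeasible_separation_raises_configuration_error(self):
        from kernel_hotspots import GenomeBuild

        tiny = GenomeBuild("tiny", {"1": 1_000_000})
        with pytest.raises(ValidationError):
            simulate_dataset(SimulationConfig(seed=0, genome=tiny, n_hotspot_loci=2))


class TestRecoveryReport:
    TRUTH_IV = [GenomicInterval("1", 100, 200) for _ in range(4)]

    def _truth(self):
        t = GroundTruth()
        t.expected_clusters = {
            ("KL", "QTL"): [GenomicInterval("1", 100 + 500 * i, 200 + 500 * i)
                            for i in range(4)]
        }
        return t

    def _clusters(self, intervals):
        return [
            Cluster(f"c{i}", "KL", "QTL", iv, ("m",)) for i, iv in enumerate(intervals)
        ]

    def test_one_spurious_cluster_gives_precision_point_eight(self):
        truth = self._truth()
        predicted = self._clusters(
            truth.expected_clusters[("KL", "QTL")]
            + [GenomicInterval("5", 1, 100)]
        )
        rr = recovery_report(predicted, [], truth)
        assert rr.cluster_precision == 0.8
        assert rr.cluster_recall == 1.0

    def test_empty_output_vs_nonempty_truth_gives_zero_recall(self):
        truth = self._truth()
        rr = recovery_report([], [], truth)
        assert rr.cluster_recall == 0.0

    def test_reciprocal_overlap_threshold_rejects_loose_matches(self):
        truth = self._truth()
        # 10x wider than the planted span: overlap fraction < 0.5 on one side
        predicted = self._clusters([GenomicInterval("1", 1, 1000)])
        rr = recovery_report(predicted, [], truth)
        assert rr.cluster_matches == 0

    def test_trait_kind_mismatch_never_matches(self):
        truth = self._truth()
        wrong_kind = [
            Cluster("x", "KL", "QTN", GenomicInterval("1", 100, 200), ("m",))
        ]
        rr = recovery_report(wrong_kind, [], truth)
        assert rr.cluster_matches == 0
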