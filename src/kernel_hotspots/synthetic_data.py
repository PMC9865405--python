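"""Synthetic inputs with planted cluster/hotspot structure.

The generator emulates the statistical shape the meta-analysis assumes: a few
dense loci where QTL intervals and QTN points of several traits co-localize,
over a sparse genome-wide background. Each planted locus carries a small core
region; every cluster planted there overlaps the core, so the locus is
recoverable as one hotspot. Clusters at one locus get distinct (trait, kind)
combinations — same-trait clusters would merge under per-trait clustering.

All randomness flows from one integer seed through per-table substreams, so
adding genes does not perturb QTL placement and identical configs give
byte-identical tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    GenomeBuild,
    GeneRecord,
    GenomicInterval,
    MarkerMap,
    QTLRecord,
    QTNRecord,
    TRAITS,
    ValidationError,
    write_expression_table,
    write_gene_table,
    write_go_annotations,
    write_marker_map,
    write_qtl_table,
    write_qtn_table,
)
from .hotspots import Hotspot
from .qtl_clustering import Cluster

#: Tissue panel of the simulated expression matrix; the first four are the
#: kernel tissues (whole kernel at two stages, embryo, endosperm).
KERNEL_TISSUES = ("kernel_12DAP", "kernel_20DAP", "embryo", "endosperm")
OTHER_TISSUES = ("root", "leaf", "tassel", "silk", "stem")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the curated-literature setting: QTL spans with a median
    of ~5 Mb, a 5 Mb QTN window, planted loci separated by at least 20 Mb so
    they cannot merge, and about a quarter of QTLs with incomplete flanking
    markers (the unprojectable fraction seen in curation).
    """

    seed: int = 0
    genome: GenomeBuild = field(default_factory=GenomeBuild)
    n_hotspot_loci: int = 5
    clusters_per_locus: int = 4
    qtls_per_cluster: int = 6
    qtns_per_cluster: int = 8
    qtl_width_median: float = 5_000_000.0
    qtl_width_sigma: float = 0.5
    qtl_width_max: float = 9_000_000.0  # cap keeps loci separable at 20 Mb spacing
    qtn_window: int = 5_000_000
    locus_core_width: int = 1_000_000
    locus_separation_min: int = 20_000_000
    background_qtls: int = 60
    background_qtns: int = 100
    missing_marker_rate: float = 0.25
    n_genes: int = 200
    kernel_gene_fraction: float = 0.5
    genes_per_locus: int = 2
    n_go_terms: int = 20

    def __post_init__(self) -> None:
        if not (0 <= self.clusters_per_locus <= 2 * len(TRAITS)):
            raise ValidationError(
                f"clusters_per_locus must be in [0, {2 * len(TRAITS)}] "
                "(distinct trait x kind combinations per locus)"
            )
        if self.n_hotspot_loci > 0 and self.clusters_per_locus > 0:
            if self.qtls_per_cluster < 0 or self.qtns_per_cluster < 0:
                raise ValidationError("per-cluster counts must be >= 0")
        if not (0.0 <= self.missing_marker_rate <= 1.0):
            raise ValidationError("missing_marker_rate must be a fraction")


@dataclass
class GroundTruth:
    """What the pipeline should recover, derivable from config + seed."""

    loci: list[GenomicInterval] = field(default_factory=list)
    expected_clusters: dict[tuple[str, str], list[GenomicInterval]] = field(default_factory=dict)
    expected_hotspots: list[GenomicInterval] = field(default_factory=list)
    genes_in_hotspots: list[str] = field(default_factory=list)
    expression_pass: set[str] = field(default_factory=set)
    expression_fail: set[str] = field(default_factory=set)
    enriched_term: str | None = None


@dataclass
class SyntheticDataset:
    """All pipeline inputs plus the planted truth."""

    config: SimulationConfig
    qtls: list[QTLRecord]
    markers: MarkerMap
    qtns: list[QTNRecord]
    genes: list[GeneRecord]
    expression: dict[str, dict[str, float]]
    kernel_tissues: tuple[str, ...]
    go_annotations: dict[str, set[str]]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_qtl_table(self.qtls, out / "qtl.tsv")
        write_marker_map(self.markers, out / "markers.tsv")
        write_qtn_table(self.qtns, out / "qtn.tsv")
        write_gene_table(self.genes, out / "genes.tsv")
        write_expression_table(self.expression, out / "expression.tsv")
        write_go_annotations(self.go_annotations, out / "go_annotations.tsv")
        (out / "kernel_tissues.txt").write_text("\n".join(self.kernel_tissues) + "\n")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("kind\ttrait\tchrom\tstart\tend\n")
            for (trait, kind), spans in sorted(self.truth.expected_clusters.items()):
                for iv in spans:
                    fh.write(f"cluster-{kind}\t{trait}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
            for iv in self.truth.expected_hotspots:
                fh.write(f"hotspot\t\t{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _place_loci(config: SimulationConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    """Rejection-sample locus core regions, pairwise separated by at least
    ``locus_separation_min`` (edge distance) and clear of chromosome ends."""
    genome = config.genome
    margin = config.locus_separation_min
    chroms = [c for c, ln in genome.chromosomes.items() if ln > 2 * margin + config.locus_core_width]
    if config.n_hotspot_loci > 0 and not chroms:
        raise ValidationError("genome too small for the requested locus separation")
    weights = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    loci: list[GenomicInterval] = []
    for _ in range(config.n_hotspot_loci):
        for _attempt in range(1000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            lo = margin
            hi = genome.chromosomes[chrom] - margin - config.locus_core_width
            start = int(rng.integers(lo, hi + 1))
            core = GenomicInterval(chrom, start, start + config.locus_core_width - 1)
            if all(
                other.chrom != chrom
                or min(abs(core.start - other.end), abs(other.start - core.end))
                > config.locus_separation_min
                for other in loci
            ):
                loci.append(core)
                break
        else:
            raise ValidationError(
                "could not place loci with the requested separation (genome too crowded)"
            )
    return loci


def _qtl_interval_over_core(
    core: GenomicInterval,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenomicInterval:
    """A QTL interval guaranteed to contain the locus core."""
    width = int(rng.lognormal(np.log(config.qtl_width_median), config.qtl_width_sigma))
    width = min(width, int(config.qtl_width_max))
    width = max(width, core.length() + 2)
    slack = width - core.length()
    start = core.start - int(rng.integers(0, slack + 1))
    end = start + width - 1
    chrom_len = config.genome.chromosomes[core.chrom]
    start = max(1, start)
    end = min(chrom_len, end)
    return GenomicInterval(core.chrom, min(start, core.start), max(end, core.end))


def _away_from_loci(iv: GenomicInterval, loci: Sequence[GenomicInterval], min_dist: int) -> bool:
    for core in loci:
        if core.chrom != iv.chrom:
            continue
        if iv.overlaps(core):
            return False
        if min(abs(iv.start - core.end), abs(core.start - iv.end)) <= min_dist:
            return False
    return True


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate all input tables plus the planted ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_loci, rng_qtl, rng_qtn, rng_gene, rng_expr, rng_go = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    genome = config.genome
    truth = GroundTruth()
    truth.loci = _place_loci(config, rng_loci)

    combos = list(itertools.product(TRAITS, ("QTL", "QTN")))
    qtls: list[QTLRecord] = []
    markers = MarkerMap()
    qtns: list[QTNRecord] = []
    marker_idx = itertools.count(1)
    qtl_idx = itertools.count(1)
    qtn_idx = itertools.count(1)

    hotspot_members: list[list[GenomicInterval]] = [[] for _ in truth.loci]

    for locus_i, core in enumerate(truth.loci):
        order = rng_qtl.permutation(len(combos))
        chosen = [combos[i] for i in order[: config.clusters_per_locus]]
        for trait, kind in chosen:
            if kind == "QTL":
                member_spans = []
                for _ in range(config.qtls_per_cluster):
                    iv = _qtl_interval_over_core(core, config, rng_qtl)
                    qtl_id = f"sQTL{next(qtl_idx):05d}"
                    left = f"M{next(marker_idx):06d}"
                    right = f"M{next(marker_idx):06d}"
                    markers[left] = (iv.chrom, iv.start)
                    markers[right] = (iv.chrom, iv.end)
                    lm, rm = left, right
                    if rng_qtl.random() < config.missing_marker_rate:
                        lm = None if rng_qtl.random() < 0.5 else lm
                        rm = None if lm is not None else rm
                    else:
                        member_spans.append(iv)
                    qtls.append(QTLRecord(qtl_id, trait, lm, rm, study="sim-planted"))
                if len(member_spans) >= 3:
                    span = GenomicInterval(
                        core.chrom,
                        min(s.start for s in member_spans),
                        max(s.end for s in member_spans),
                    )
                    truth.expected_clusters.setdefault((trait, kind), []).append(span)
                    hotspot_members[locus_i].append(span)
            else:
                half = config.qtn_window // 4
                lo = max(1, core.start - half)
                hi = min(genome.chromosomes[core.chrom], core.end + half)
                positions = sorted(
                    int(rng_qtn.integers(lo, hi + 1)) for _ in range(config.qtns_per_cluster)
                )
                for pos in positions:
                    qtns.append(
                        QTNRecord(f"sQTN{next(qtn_idx):05d}", trait, core.chrom, pos, "sim-planted")
                    )
                if len(positions) >= 5:
                    span = GenomicInterval(core.chrom, positions[0], positions[-1])
                    truth.expected_clusters.setdefault((trait, kind), []).append(span)
                    hotspot_members[locus_i].append(span)

    for members in hotspot_members:
        if len(members) >= 3:
            truth.expected_hotspots.append(
                GenomicInterval(
                    members[0].chrom,
                    min(m.start for m in members),
                    max(m.end for m in members),
                )
            )
    truth.expected_hotspots.sort()

    # background records, rejection-sampled away from the planted loci
    chrom_names = list(genome.chromosomes)
    weights = np.array([genome.chromosomes[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    for _ in range(config.background_qtls):
        for _attempt in range(1000):
            chrom = chrom_names[rng_qtl.choice(len(chrom_names), p=weights)]
            width = int(rng_qtl.lognormal(np.log(config.qtl_width_median), config.qtl_width_sigma))
            width = min(max(width, 2), int(config.qtl_width_max), genome.chromosomes[chrom] - 1)
            start = int(rng_qtl.integers(1, genome.chromosomes[chrom] - width + 1))
            iv = GenomicInterval(chrom, start, start + width - 1)
            if _away_from_loci(iv, truth.loci, config.locus_separation_min):
                break
        else:
            raise ValidationError("could not place background QTL away from loci")
        trait = TRAITS[rng_qtl.integers(len(TRAITS))]
        qtl_id = f"bQTL{next(qtl_idx):05d}"
        left = f"M{next(marker_idx):06d}"
        right = f"M{next(marker_idx):06d}"
        markers[left] = (iv.chrom, iv.start)
        markers[right] = (iv.chrom, iv.end)
        lm, rm = left, right
        if rng_qtl.random() < config.missing_marker_rate:
            lm = None if rng_qtl.random() < 0.5 else lm
            rm = None if lm is not None else rm
        qtls.append(QTLRecord(qtl_id, trait, lm, rm, study="sim-background"))

    for _ in range(config.background_qtns):
        for _attempt in range(1000):
            chrom = chrom_names[rng_qtn.choice(len(chrom_names), p=weights)]
            pos = int(rng_qtn.integers(1, genome.chromosomes[chrom] + 1))
            iv = GenomicInterval(chrom, pos, pos)
            if _away_from_loci(iv, truth.loci, config.locus_separation_min):
                break
        else:
            raise ValidationError("could not place background QTN away from loci")
        trait = TRAITS[rng_qtn.integers(len(TRAITS))]
        qtns.append(QTNRecord(f"bQTN{next(qtn_idx):05d}", trait, iv.chrom, iv.start, "sim-background"))

    # genes: a few planted inside each locus core, the rest uniform
    genes: list[GeneRecord] = []
    gene_idx = itertools.count(1)
    gene_width = 3_000
    for core in truth.loci:
        for _ in range(config.genes_per_locus):
            start = int(rng_gene.integers(core.start, core.end - gene_width + 1))
            gid = f"SynZm{next(gene_idx):05d}"
            genes.append(
                GeneRecord(gid, gid, core.chrom, start, start + gene_width - 1,
                           annotation="synthetic hotspot gene")
            )
            truth.genes_in_hotspots.append(gid)
    while len(genes) < config.n_genes:
        chrom = chrom_names[rng_gene.choice(len(chrom_names), p=weights)]
        start = int(rng_gene.integers(1, genome.chromosomes[chrom] - gene_width + 1))
        gid = f"SynZm{next(gene_idx):05d}"
        annotation = (
            "PPR protein, RNA editing" if rng_gene.random() < 0.15
            else "synthetic background gene"
        )
        genes.append(GeneRecord(gid, gid, chrom, start, start + gene_width - 1, annotation))

    # expression: pass-designated genes peak in kernels at >= 50 FPKM with
    # ratio <= 3; fail-designated genes violate one criterion each
    expression: dict[str, dict[str, float]] = {}
    for g in genes:
        designed_pass = rng_expr.random() < config.kernel_gene_fraction
        profile: dict[str, float] = {}
        if designed_pass:
            kernel_peak = 0.0
            while kernel_peak < 50.0:
                kernel_peak = float(rng_expr.lognormal(np.log(200.0), 0.8))
            for t in KERNEL_TISSUES:
                profile[t] = round(float(rng_expr.uniform(0.3, 1.0)) * kernel_peak, 3)
            peak_tissue = KERNEL_TISSUES[rng_expr.integers(len(KERNEL_TISSUES))]
            profile[peak_tissue] = round(kernel_peak, 3)
            for t in OTHER_TISSUES:
                profile[t] = round(float(rng_expr.uniform(0.0, 3.0)) * kernel_peak, 3)
            truth.expression_pass.add(g.gene_id)
        else:
            if rng_expr.random() < 0.5:  # fail on kernel level
                kernel_peak = float(rng_expr.uniform(0.0, 45.0))
                for t in KERNEL_TISSUES:
                    profile[t] = round(float(rng_expr.uniform(0.0, 1.0)) * kernel_peak, 3)
                for t in OTHER_TISSUES:
                    profile[t] = round(float(rng_expr.uniform(0.0, 400.0)), 3)
            else:  # fail on ratio: strong somewhere else
                kernel_peak = 0.0
                while kernel_peak < 50.0:
                    kernel_peak = float(rng_expr.lognormal(np.log(200.0), 0.8))
                for t in KERNEL_TISSUES:
                    profile[t] = round(float(rng_expr.uniform(0.3, 1.0)) * kernel_peak, 3)
                for t in OTHER_TISSUES:
                    profile[t] = round(float(rng_expr.uniform(0.0, 2.0)) * kernel_peak, 3)
                loud = OTHER_TISSUES[rng_expr.integers(len(OTHER_TISSUES))]
                profile[loud] = round(float(rng_expr.uniform(3.5, 8.0)) * kernel_peak, 3)
            truth.expression_fail.add(g.gene_id)
        expression[g.gene_id] = profile

    # GO annotations over all genes; term 1 planted enriched in locus genes
    go: dict[str, set[str]] = {}
    gene_ids = [g.gene_id for g in genes]
    if config.n_go_terms > 0 and gene_ids:
        enriched = "GO:SYN0001"
        go[enriched] = set(truth.genes_in_hotspots)
        extra = rng_go.choice(len(gene_ids), size=min(3, len(gene_ids)), replace=False)
        go[enriched] |= {gene_ids[i] for i in extra}
        truth.enriched_term = enriched
        for t in range(2, config.n_go_terms + 1):
            size = int(rng_go.integers(5, max(6, min(30, len(gene_ids)))))
            picks = rng_go.choice(len(gene_ids), size=min(size, len(gene_ids)), replace=False)
            go[f"GO:SYN{t:04d}"] = {gene_ids[i] for i in picks}

    return SyntheticDataset(
        config=config,
        qtls=qtls,
        markers=markers,
        qtns=qtns,
        genes=genes,
        expression=expression,
        kernel_tissues=KERNEL_TISSUES,
        go_annotations=go,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, min_frac: float = 0.5) -> bool:
    if not a.overlaps(b):
        return False
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    return ov >= min_frac * a.length() and ov >= min_frac * b.length()


def _match_sets(
    predicted: Sequence[GenomicInterval],
    expected: Sequence[GenomicInterval],
    min_frac: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (matches, n_predicted, n_expected)."""
    unused = list(range(len(predicted)))
    matches = 0
    for exp in expected:
        for idx in unused:
            if _reciprocal_overlap(predicted[idx], exp, min_frac):
                unused.remove(idx)
                matches += 1
                break
    return matches, len(predicted), len(expected)


@dataclass(frozen=True)
class RecoveryReport:
    cluster_matches: int
    cluster_predicted: int
    cluster_expected: int
    hotspot_matches: int
    hotspot_predicted: int
    hotspot_expected: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else 1.0

    @property
    def cluster_precision(self) -> float:
        return self._ratio(self.cluster_matches, self.cluster_predicted)

    @property
    def cluster_recall(self) -> float:
        return self._ratio(self.cluster_matches, self.cluster_expected)

    @property
    def hotspot_precision(self) -> float:
        return self._ratio(self.hotspot_matches, self.hotspot_predicted)

    @property
    def hotspot_recall(self) -> float:
        return self._ratio(self.hotspot_matches, self.hotspot_expected)


def recovery_report(
    clusters: Sequence[Cluster],
    hotspots: Sequence[Hotspot],
    truth: GroundTruth,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryReport:
    """Precision/recall of inferred clusters and hotspots against the planted
    truth; an interval match requires reciprocal overlap >= 0.5 and, for
    clusters, the same (trait, kind)."""
    cm = cp = ce = 0
    keys = set(truth.expected_clusters) | {(c.trait, c.kind) for c in clusters}
    for key in sorted(keys):
        pred = [c.interval for c in clusters if (c.trait, c.kind) == key]
        exp = truth.expected_clusters.get(key, [])
        m, p, e = _match_sets(pred, exp, min_reciprocal_overlap)
        cm, cp, ce = cm + m, cp + p, ce + e
    hm, hp, he = _match_sets(
        [h.interval for h in hotspots], truth.expected_hotspots, min_reciprocal_overlap
    )
    return RecoveryReport(cm, cp, ce, hm, hp, he)
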