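"""Consensus hotspots: regions where >= 3 QTL/QTN clusters co-localize.

Clusters of all four traits and both kinds are pooled, overlap components are
formed (same merge semantics as QTL clustering), and components with at least
``min_clusters`` members become hotspots named ``HS01``, ``HS02``, ... in
genome order (chromosome, then start). The hotspot extent is the union span
of its member clusters. Cloned genes with physical coordinates are co-located
by any-overlap (>= 1 nt).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .core_io import GenomeBuild, GeneRecord, GenomicInterval, logger
from .qtl_clustering import Cluster, merge_overlapping


@dataclass(frozen=True)
class Hotspot:
    """A named consensus region with its member clusters and co-located genes."""

    name: str
    interval: GenomicInterval
    member_clusters: tuple[str, ...]
    genes: tuple[str, ...] = ()

    @property
    def n_clusters(self) -> int:
        return len(self.member_clusters)


def _chrom_key(chrom: str, build: GenomeBuild | None):
    if build is not None:
        return build.chrom_order(chrom)
    label = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(label)) if label.isdigit() else (1, label)


def integrate_hotspots(
    clusters: Sequence[Cluster],
    min_clusters: int = 3,
    build: GenomeBuild | None = None,
) -> list[Hotspot]:
    """Pool clusters across traits and kinds and return named hotspots."""
    intervals = [c.interval for c in clusters]
    components = [
        comp for comp in merge_overlapping(intervals)
        if len(comp.member_indices) >= min_clusters
    ]
    components.sort(key=lambda comp: (_chrom_key(comp.interval.chrom, build), comp.interval.start))
    hotspots = []
    for i, comp in enumerate(components, start=1):
        members = tuple(clusters[j].name for j in comp.member_indices)
        hotspots.append(Hotspot(f"HS{i:02d}", comp.interval, members))
    logger.info("hotspot integration: %d hotspots from %d clusters", len(hotspots), len(clusters))
    return hotspots


def assign_genes(hotspots: Iterable[Hotspot], genes: Sequence[GeneRecord]) -> list[Hotspot]:
    """Attach genes overlapping each hotspot by >= 1 nt.

    Genes without physical coordinates cannot be co-located and are skipped
    with a logged warning.
    """
    located = []
    for g in genes:
        if g.interval is None:
            logger.warning("gene %s (%s) has no coordinates; skipped", g.name, g.gene_id)
        else:
            located.append(g)
    out = []
    for hs in hotspots:
        hits = tuple(
            g.name for g in located if g.interval.overlaps(hs.interval)
        )
        out.append(replace(hs, genes=hits))
    return out


def span_mb(interval: GenomicInterval, ndigits: int = 1) -> float:
    """Interval span in megabases: (end - start) / 1e6, rounded half-up.

    The difference convention (not the inclusive +1 length) matches how
    hotspot spans are conventionally reported for these coordinates.
    """
    mb = Decimal(interval.end - interval.start) / Decimal(10**6)
    q = Decimal(1).scaleb(-ndigits) if ndigits > 0 else Decimal(1)
    return float(mb.quantize(q, rounding=ROUND_HALF_UP))


def summarize_hotspots(
    hotspots: Sequence[Hotspot],
    build: GenomeBuild | None = None,
) -> dict:
    """Deterministic summary statistics over a hotspot collection.

    Returns per-chromosome counts (including zero-count chromosomes when a
    build is given), the distribution of member-cluster counts, counts of
    hotspots with/without co-located cloned genes, and min/max member counts.
    """
    per_chrom: dict[str, int] = (
        {c: 0 for c in build.chromosomes} if build is not None else {}
    )
    member_counts: dict[int, int] = {}
    with_genes = 0
    for hs in hotspots:
        per_chrom[hs.interval.chrom] = per_chrom.get(hs.interval.chrom, 0) + 1
        member_counts[hs.n_clusters] = member_counts.get(hs.n_clusters, 0) + 1
        if hs.genes:
            with_genes += 1
    n = len(hotspots)
    sizes = [hs.n_clusters for hs in hotspots]
    return {
        "n_hotspots": n,
        "per_chromosome": per_chrom,
        "member_count_distribution": dict(sorted(member_counts.items())),
        "with_cloned_genes": with_genes,
        "without_cloned_genes": n - with_genes,
        "min_members": min(sizes) if sizes else 0,
        "max_members": max(sizes) if sizes else 0,
    }


def hotspots_from_table(df: pd.DataFrame) -> list[Hotspot]:
    """Build Hotspot objects from a hotspot table (the bundled published
    survey or a pipeline output re-read from disk)."""
    out = []
    for row in df.itertuples(index=False):
        members = tuple(m for m in str(row.clusters).split(",") if m)
        genes = tuple(g for g in str(getattr(row, "genes", "")).split(",") if g)
        out.append(
            Hotspot(
                name=row.hotspot_id,
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                member_clusters=members,
                genes=genes,
            )
        )
    return out


def hotspots_to_table(hotspots: Iterable[Hotspot]) -> pd.DataFrame:
    rows = [
        {
            "hotspot_id": hs.name,
            "chrom": hs.interval.chrom,
            "start": hs.interval.start,
            "end": hs.interval.end,
            "n_clusters": hs.n_clusters,
            "clusters": ",".join(hs.member_clusters),
            "n_genes": len(hs.genes),
            "genes": ",".join(hs.genes),
        }
        for hs in hotspots
    ]
    return pd.DataFrame(
        rows,
        columns=(
            "hotspot_id", "chrom", "start", "end",
            "n_clusters", "clusters", "n_genes", "genes",
        ),
    )
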