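"""Trait-specific QTL clusters: regions where >= 3 projected QTLs co-localize.

"Co-localized" is read as connected components of the pairwise-overlap graph,
per trait per chromosome — the merge semantics of bedtools with distance 0.
Touching-but-not-overlapping intervals (end + 1 == start in 1-based inclusive
coordinates) are NOT merged. The cluster span is the union extent
[min start, max end] of its members.

Cluster names follow the field convention ``{trait}-qCL{chr}-{i}`` for QTL
clusters and ``{trait}-gCL{chr}-{i}`` for QTN (GWAS) clusters, with the index
restarting at 1 per chromosome per trait in genome order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core_io import GenomeBuild, GenomicInterval, ValidationError
from .projection import ProjectedQTL


@dataclass(frozen=True)
class Cluster:
    """A named, trait- and kind-tagged co-localization region."""

    name: str
    trait: str
    kind: str  # "QTL" or "QTN"
    interval: GenomicInterval
    member_ids: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class MergeComponent:
    """One connected component of interval overlap: merged span + member
    indices into the input collection."""

    interval: GenomicInterval
    member_indices: tuple[int, ...]


def merge_overlapping(intervals: Sequence[GenomicInterval]) -> list[MergeComponent]:
    """Connected components of pairwise overlap, per chromosome (sweep line).

    Components are returned sorted by (chromosome name, start); each span is
    the union extent of its members and components are pairwise disjoint.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append(i)

    components: list[MergeComponent] = []
    for chrom in sorted(by_chrom):
        order = sorted(by_chrom[chrom], key=lambda i: (intervals[i].start, intervals[i].end))
        current: list[int] = []
        span_start = span_end = 0
        for i in order:
            iv = intervals[i]
            if current and iv.start <= span_end:  # closed-interval overlap
                current.append(i)
                span_end = max(span_end, iv.end)
            else:
                if current:
                    components.append(
                        MergeComponent(GenomicInterval(chrom, span_start, span_end), tuple(current))
                    )
                current = [i]
                span_start, span_end = iv.start, iv.end
        if current:
            components.append(
                MergeComponent(GenomicInterval(chrom, span_start, span_end), tuple(current))
            )
    return components


def find_qtl_clusters(
    projected: Sequence[ProjectedQTL],
    trait: str,
    min_members: int = 3,
) -> list[Cluster]:
    """Clusters of >= ``min_members`` co-localized QTLs for one trait.

    Returned unsorted-by-name (names are assigned by :func:`name_clusters`)
    but ordered by (chromosome, start).
    """
    for p in projected:
        if p.record.trait != trait:
            raise ValidationError(
                f"QTL {p.record.qtl_id!r} has trait {p.record.trait!r}, expected {trait!r}"
            )
    intervals = [p.interval for p in projected]
    clusters = []
    for comp in merge_overlapping(intervals):
        if len(comp.member_indices) >= min_members:
            members = tuple(projected[i].record.qtl_id for i in comp.member_indices)
            clusters.append(Cluster("", trait, "QTL", comp.interval, members))
    return clusters


def _chrom_label(chrom: str) -> str:
    """Chromosome label used in cluster names ('chr1' and '1' both -> '1')."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def name_clusters(
    clusters: Iterable[Cluster],
    trait: str,
    kind: str,
    build: GenomeBuild | None = None,
) -> list[Cluster]:
    """Assign ``{trait}-qCL{chr}-{i}`` / ``{trait}-gCL{chr}-{i}`` names.

    The index restarts at 1 per chromosome; ordering is genome order
    (build order when a build is given, else natural chromosome sort).
    """
    tag = {"QTL": "qCL", "QTN": "gCL"}[kind]
    clusters = list(clusters)

    def chrom_key(c: Cluster):
        if build is not None:
            return build.chrom_order(c.interval.chrom)
        label = _chrom_label(c.interval.chrom)
        return (0, int(label)) if label.isdigit() else (1, label)

    ordered = sorted(clusters, key=lambda c: (chrom_key(c), c.interval.start, c.interval.end))
    named = []
    counter: dict[str, int] = {}
    for c in ordered:
        label = _chrom_label(c.interval.chrom)
        counter[label] = counter.get(label, 0) + 1
        named.append(replace(c, name=f"{trait}-{tag}{label}-{counter[label]}", trait=trait, kind=kind))
    return named
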