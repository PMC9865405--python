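"""Projection of literature QTLs onto physical coordinates.

Each QTL is reported with two flanking genetic markers; its physical interval
on the reference assembly is the span between the markers' physical positions.
Records whose markers are missing, unmapped, or on different chromosomes are
partitioned out with an explicit reason, mirroring the curation reality that a
substantial fraction of literature QTLs cannot be placed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .core_io import GenomicInterval, MarkerMap, QTLRecord, logger

#: Rejection reasons, in the order they are checked.
MISSING_MARKER = "missing-marker"
UNMAPPED_MARKER = "unmapped-marker"
CROSS_CHROMOSOME = "cross-chromosome"


@dataclass(frozen=True)
class ProjectedQTL:
    """A QTL with its physical interval (flanking-marker span, endpoints
    ordered by physical position)."""

    record: QTLRecord
    interval: GenomicInterval


@dataclass
class ProjectionReport:
    """Exhaustive partition of the input into projected and rejected QTLs."""

    projected: list[ProjectedQTL] = field(default_factory=list)
    rejected: list[tuple[QTLRecord, str]] = field(default_factory=list)

    def counts_by_trait(self) -> dict[str, dict[str, int]]:
        """Per-trait tallies of projected and rejected records."""
        out: dict[str, dict[str, int]] = {}
        for p in self.projected:
            out.setdefault(p.record.trait, {"projected": 0, "rejected": 0})["projected"] += 1
        for r, _ in self.rejected:
            out.setdefault(r.trait, {"projected": 0, "rejected": 0})["rejected"] += 1
        return out

    def rejection_reasons(self) -> Counter:
        return Counter(reason for _, reason in self.rejected)


def project_qtl(qtl: QTLRecord, markers: MarkerMap) -> ProjectedQTL | str:
    """Project one QTL; returns a ProjectedQTL or a rejection reason.

    Marker orientation on the genetic map often disagrees with physical
    orientation, so endpoints are swapped silently when needed. Two identical
    markers give a degenerate 1-nt interval rather than a rejection.
    """
    if not qtl.left_marker or not qtl.right_marker:
        return MISSING_MARKER
    if qtl.left_marker not in markers or qtl.right_marker not in markers:
        return UNMAPPED_MARKER
    chrom_l, pos_l = markers[qtl.left_marker]
    chrom_r, pos_r = markers[qtl.right_marker]
    if chrom_l != chrom_r:
        return CROSS_CHROMOSOME
    start, end = min(pos_l, pos_r), max(pos_l, pos_r)
    return ProjectedQTL(qtl, GenomicInterval(chrom_l, start, end))


def project_batch(qtls: Iterable[QTLRecord], markers: MarkerMap) -> ProjectionReport:
    """Project a batch; the partition is exhaustive and input-order stable."""
    report = ProjectionReport()
    for qtl in qtls:
        result = project_qtl(qtl, markers)
        if isinstance(result, ProjectedQTL):
            report.projected.append(result)
        else:
            report.rejected.append((qtl, result))
    n_in = len(report.projected) + len(report.rejected)
    logger.info(
        "projection: %d/%d QTLs projected (%s)",
        len(report.projected), n_in, dict(report.rejection_reasons()),
    )
    return report
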