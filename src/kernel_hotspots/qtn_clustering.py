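"""Trait-specific QTN clusters via a 5 Mb sliding window.

A region qualifies when a window of ``window`` nt (default 5 Mb) contains at
least ``min_count`` QTNs (default 5). The slide is effectively continuous:
candidate windows are anchored at QTN positions, since a window boundary only
matters at a data point — equivalent to a 1-nt step without the arbitrary
stride. Overlapping qualifying windows are chained (union), and each chained
region is trimmed to the extremal member QTN positions, so cluster spans are
data-defined and may exceed one window length.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

from .core_io import QTNRecord, ValidationError
from .qtl_clustering import Cluster, GenomicInterval


@dataclass(frozen=True)
class QTNClusterConfig:
    """Sliding-window parameters: window length (nt) and minimum QTN count."""

    window: int = 5_000_000
    min_count: int = 5

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValidationError("window must be > 0")
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")


def chain_windows(windows: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping qualifying windows (closed coordinates).

    ``windows`` must be sorted by start; windows overlapping by >= 1 nt are
    merged into maximal regions.
    """
    regions: list[tuple[int, int]] = []
    for start, end in windows:
        if regions and start <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], end))
        else:
            regions.append((start, end))
    return regions


def find_qtn_clusters(
    qtns: Sequence[QTNRecord],
    config: QTNClusterConfig = QTNClusterConfig(),
) -> list[Cluster]:
    """QTN clusters for a single trait, per chromosome.

    Returns unnamed clusters ordered by (chromosome, start); the span is
    trimmed to member positions and members are all QTNs inside the span.
    """
    traits = {q.trait for q in qtns}
    if len(traits) > 1:
        raise ValidationError(f"find_qtn_clusters expects a single trait, got {sorted(traits)}")

    by_chrom: dict[str, list[QTNRecord]] = {}
    for q in qtns:
        by_chrom.setdefault(q.chrom, []).append(q)

    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda q: (q.position, q.qtn_id))
        positions = [q.position for q in recs]
        # qualifying windows anchored at each QTN position
        qualifying: list[tuple[int, int]] = []
        for i, p in enumerate(positions):
            j = bisect.bisect_right(positions, p + config.window) - 1
            if j - i + 1 >= config.min_count:
                qualifying.append((p, p + config.window))
        for wstart, wend in chain_windows(qualifying):
            lo = bisect.bisect_left(positions, wstart)
            hi = bisect.bisect_right(positions, wend) - 1
            span = GenomicInterval(chrom, positions[lo], positions[hi])
            members = tuple(q.qtn_id for q in recs[lo : hi + 1])
            clusters.append(Cluster("", next(iter(traits)) if traits else "", "QTN", span, members))
    return clusters
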