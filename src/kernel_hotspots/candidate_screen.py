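"""Candidate-gene screening by kernel expression pattern and PPR annotation.

A gene's kernel specificity is summarised by two numbers: MaxExpKernel, its
maximal FPKM over the kernel tissues, and the ratio MaxExp/MaxExpKernel of its
overall maximum to that. A ratio of exactly 1 means the gene peaks in kernels.
The screen keeps genes with MaxExpKernel >= 50 FPKM and ratio <= 3 (both
bounds inclusive); genes with no expression data are excluded and tallied
separately. Pentatricopeptide-repeat (PPR) genes — the dominant family among
cloned kernel-development genes — are found by annotation keyword.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import ExpressionProfile, ValidationError
from .hotspots import Hotspot

#: MaxExpKernel bins in the order reported for the cloned-gene survey.
FPKM_BINS = (">500", "200-500", "100-200", "50-100", "20-50", "10-20", "<10")
#: MaxExp/MaxExpKernel ratio bins.
RATIO_BINS = ("=1", "(1,3]", "(3,5]", ">5")

_PPR_PATTERN = re.compile(r"pentatricopeptide|\bppr\b", re.IGNORECASE)


@dataclass(frozen=True)
class ExpressionSummary:
    """MaxExp / MaxExpKernel summary for one gene. ``ratio`` is None when the
    gene is silent in all kernel tissues (undefined division)."""

    gene_id: str
    max_exp: float
    max_exp_kernel: float

    @property
    def ratio(self) -> float | None:
        if self.max_exp_kernel == 0:
            return None
        return self.max_exp / self.max_exp_kernel


def expression_summary(profile: ExpressionProfile) -> ExpressionSummary:
    """Maxima over all tissues and over the kernel subset."""
    if not profile.kernel_tissues:
        raise ValidationError(f"gene {profile.gene_id!r}: empty kernel tissue set")
    max_exp = max(profile.fpkm.values())
    max_exp_kernel = max(profile.fpkm[t] for t in profile.kernel_tissues)
    return ExpressionSummary(profile.gene_id, max_exp, max_exp_kernel)


@dataclass(frozen=True)
class ScreenResult:
    """Partition of screened genes: passing, failing, and lacking data."""

    passing: tuple[str, ...]
    failing: tuple[str, ...]
    no_data: tuple[str, ...]


def filter_candidates(
    summaries: Mapping[str, ExpressionSummary | None],
    min_kernel_fpkm: float = 50.0,
    max_ratio: float = 3.0,
) -> ScreenResult:
    """Apply the kernel-expression filter (inclusive bounds).

    ``summaries`` maps gene -> summary, with None marking genes that have no
    expression data; those are excluded from the pass/fail partition and
    counted separately.
    """
    passing, failing, no_data = [], [], []
    for gene_id in summaries:
        s = summaries[gene_id]
        if s is None:
            no_data.append(gene_id)
            continue
        r = s.ratio
        if s.max_exp_kernel >= min_kernel_fpkm and r is not None and r <= max_ratio:
            passing.append(gene_id)
        else:
            failing.append(gene_id)
    return ScreenResult(tuple(passing), tuple(failing), tuple(no_data))


def bin_expression(summaries: Iterable[ExpressionSummary]) -> dict[str, dict[str, int]]:
    """Histogram MaxExpKernel and the expression ratio into reporting bins.

    FPKM bins are [lower, upper) descending with ">500" strict, so 500 falls
    in "200-500". Ratio bins: exactly 1, (1,3], (3,5], >5; undefined ratios
    (kernel-silent genes) land in no ratio bin but still count in "<10" FPKM.
    """
    fpkm = {b: 0 for b in FPKM_BINS}
    ratio = {b: 0 for b in RATIO_BINS}
    fpkm_edges = ((500, ">500"), (200, "200-500"), (100, "100-200"),
                  (50, "50-100"), (20, "20-50"), (10, "10-20"))
    for s in summaries:
        for edge, label in fpkm_edges:
            if (s.max_exp_kernel > edge) if edge == 500 else (s.max_exp_kernel >= edge):
                fpkm[label] += 1
                break
        else:
            fpkm["<10"] += 1
        r = s.ratio
        if r is None:
            continue
        if math.isclose(r, 1.0) or r < 1.0:
            ratio["=1"] += 1
        elif r <= 3.0:
            ratio["(1,3]"] += 1
        elif r <= 5.0:
            ratio["(3,5]"] += 1
        else:
            ratio[">5"] += 1
    return {"fpkm": fpkm, "ratio": ratio}


def is_ppr_annotation(text: str) -> bool:
    """True when an annotation names the PPR family: case-insensitive
    'pentatricopeptide', or 'PPR' as a whole token (no substring hits)."""
    return bool(_PPR_PATTERN.search(text))


def find_ppr_genes(
    hotspots: Sequence[Hotspot],
    annotations: Mapping[str, str],
) -> dict[str, tuple[str, ...]]:
    """Per-hotspot PPR genes among each hotspot's assigned gene list."""
    return {
        hs.name: tuple(
            g for g in hs.genes if is_ppr_annotation(annotations.get(g, ""))
        )
        for hs in hotspots
    }
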