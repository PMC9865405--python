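"""End-to-end orchestration: project -> cluster -> integrate -> screen -> enrich.

A run consumes the curated input tables, applies the canonical thresholds
(>= 3 QTLs per QTL cluster, 5 Mb window with >= 5 QTNs per QTN cluster,
>= 3 clusters per hotspot, kernel FPKM >= 50 with expression ratio <= 3,
FDR 0.05), and writes every stage's output plus a plain-text report and a
machine-readable JSON summary into the run directory. All thresholds live in
:class:`RunConfig`; nothing is hard-coded in stage logic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import core_io
from .candidate_screen import (
    bin_expression,
    expression_summary,
    filter_candidates,
    find_ppr_genes,
)
from .core_io import GenomeBuild, TRAITS, logger
from .go_enrichment import enrich, enrichment_table
from .hotspots import (
    Hotspot,
    assign_genes,
    hotspots_from_table,
    hotspots_to_table,
    integrate_hotspots,
    span_mb,
    summarize_hotspots,
)
from .projection import project_batch
from .qtl_clustering import Cluster, find_qtl_clusters, name_clusters
from .qtn_clustering import QTNClusterConfig, find_qtn_clusters


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run. Threshold defaults are the
    canonical values of the meta-analysis protocol."""

    qtl_table: Path | None = None
    marker_table: Path | None = None
    qtn_table: Path | None = None
    gene_table: Path | None = None
    expression_table: Path | None = None
    kernel_tissues: tuple[str, ...] = ()
    go_table: Path | None = None
    out_dir: Path = Path("run")
    min_qtl_members: int = 3
    qtn_window: int = 5_000_000
    min_qtn_count: int = 5
    min_hotspot_clusters: int = 3
    min_kernel_fpkm: float = 50.0
    max_expression_ratio: float = 3.0
    fdr_threshold: float = 0.05
    log_level: str = "INFO"
    build: GenomeBuild = field(default_factory=GenomeBuild)

    def __post_init__(self) -> None:
        for name in ("min_qtl_members", "qtn_window", "min_qtn_count",
                     "min_hotspot_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            if key.endswith("_table"):
                kwargs[key] = Path(value)
            elif key == "out_dir":
                kwargs[key] = Path(value)
            elif key == "kernel_tissues":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def clusters_to_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    rows = [
        {
            "name": c.name,
            "trait": c.trait,
            "kind": c.kind,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "n_members": c.n_members,
            "members": ",".join(c.member_ids),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=("name", "trait", "kind", "chrom", "start", "end", "n_members", "members"),
    )


def clusters_from_table(df: pd.DataFrame) -> list[Cluster]:
    return [
        Cluster(
            name=str(row["name"]),
            trait=str(row["trait"]),
            kind=str(row["kind"]),
            interval=core_io.GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
            member_ids=tuple(str(row["members"]).split(",")) if str(row["members"]) else (),
        )
        for row in df.to_dict("records")
    ]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the run directory.

    Stage outputs are written as TSV (re-loadable as the next stage's input)
    plus BED for genome-browser use, a ``report.txt`` and ``summary.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "thresholds: min_qtl_members=%d qtn_window=%d min_qtn_count=%d "
        "min_hotspot_clusters=%d min_kernel_fpkm=%g max_expression_ratio=%g fdr=%g",
        config.min_qtl_members, config.qtn_window, config.min_qtn_count,
        config.min_hotspot_clusters, config.min_kernel_fpkm,
        config.max_expression_ratio, config.fdr_threshold,
    )
    summary: dict = {"thresholds": {
        "min_qtl_members": config.min_qtl_members,
        "qtn_window": config.qtn_window,
        "min_qtn_count": config.min_qtn_count,
        "min_hotspot_clusters": config.min_hotspot_clusters,
        "min_kernel_fpkm": config.min_kernel_fpkm,
        "max_expression_ratio": config.max_expression_ratio,
        "fdr_threshold": config.fdr_threshold,
    }}

    # --- stage 1: projection ---
    all_clusters: list[Cluster] = []
    if config.qtl_table is not None:
        try:
            qtls = core_io.read_qtl_table(config.qtl_table, config.build)
            markers = core_io.read_marker_map(config.marker_table, config.build)
            report = project_batch(qtls, markers)
        except Exception as exc:
            raise RuntimeError(f"stage 'project' failed: {exc}") from exc
        proj_rows = [
            {
                "qtl_id": p.record.qtl_id,
                "trait": p.record.trait,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
            }
            for p in report.projected
        ]
        pd.DataFrame(
            proj_rows, columns=("qtl_id", "trait", "chrom", "start", "end")
        ).to_csv(out / "projected.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"qtl_id": r.qtl_id, "trait": r.trait, "reason": reason}
             for r, reason in report.rejected],
            columns=("qtl_id", "trait", "reason"),
        ).to_csv(out / "rejects.tsv", sep="\t", index=False)
        summary["projection"] = {
            "collected": len(qtls),
            "projected": len(report.projected),
            "rejected": len(report.rejected),
            "per_trait": report.counts_by_trait(),
        }

        # --- stage 2: QTL clusters per trait ---
        try:
            qtl_clusters: list[Cluster] = []
            for trait in TRAITS:
                per_trait = [p for p in report.projected if p.record.trait == trait]
                found = find_qtl_clusters(per_trait, trait, config.min_qtl_members)
                qtl_clusters.extend(name_clusters(found, trait, "QTL", config.build))
        except Exception as exc:
            raise RuntimeError(f"stage 'cluster-qtl' failed: {exc}") from exc
        clusters_to_table(qtl_clusters).to_csv(out / "clusters_qtl.tsv", sep="\t", index=False)
        core_io.write_bed(
            [(c.name, c.interval) for c in qtl_clusters], out / "clusters_qtl.bed"
        )
        summary["qtl_clusters"] = {
            "total": len(qtl_clusters),
            "per_trait": {t: sum(1 for c in qtl_clusters if c.trait == t) for t in TRAITS},
        }
        all_clusters.extend(qtl_clusters)

    # --- stage 3: QTN clusters per trait ---
    if config.qtn_table is not None:
        try:
            qtns = core_io.read_qtn_table(config.qtn_table, config.build)
            qtn_cfg = QTNClusterConfig(config.qtn_window, config.min_qtn_count)
            qtn_clusters: list[Cluster] = []
            for trait in TRAITS:
                per_trait = [q for q in qtns if q.trait == trait]
                found = find_qtn_clusters(per_trait, qtn_cfg)
                qtn_clusters.extend(name_clusters(found, trait, "QTN", config.build))
        except Exception as exc:
            raise RuntimeError(f"stage 'cluster-qtn' failed: {exc}") from exc
        clusters_to_table(qtn_clusters).to_csv(out / "clusters_qtn.tsv", sep="\t", index=False)
        core_io.write_bed(
            [(c.name, c.interval) for c in qtn_clusters], out / "clusters_qtn.bed"
        )
        summary["qtn_clusters"] = {
            "total": len(qtn_clusters),
            "per_trait": {t: sum(1 for c in qtn_clusters if c.trait == t) for t in TRAITS},
        }
        all_clusters.extend(qtn_clusters)

    # --- stage 4: hotspot integration + gene co-location ---
    try:
        hotspots = integrate_hotspots(all_clusters, config.min_hotspot_clusters, config.build)
        genes = core_io.read_gene_table(config.gene_table) if config.gene_table else []
        located = [g for g in genes if g.interval is not None]
        hotspots = assign_genes(hotspots, genes)
    except Exception as exc:
        raise RuntimeError(f"stage 'hotspots' failed: {exc}") from exc
    hotspots_to_table(hotspots).to_csv(out / "hotspots.tsv", sep="\t", index=False)
    core_io.write_bed([(h.name, h.interval) for h in hotspots], out / "hotspots.bed")
    hs_summary = summarize_hotspots(hotspots, config.build)
    hs_summary["spans_mb"] = {h.name: span_mb(h.interval) for h in hotspots}
    summary["hotspots"] = hs_summary

    # --- stage 5: candidate screen ---
    hotspot_gene_ids: list[str] = []
    if config.expression_table is not None and hotspots:
        try:
            profiles = core_io.read_expression_table(
                config.expression_table, config.kernel_tissues
            )
            name_to_id = {g.name: g.gene_id for g in genes}
            hotspot_gene_names = sorted({g for h in hotspots for g in h.genes})
            hotspot_gene_ids = [name_to_id.get(n, n) for n in hotspot_gene_names]
            summaries = {
                gid: (expression_summary(profiles[gid]) if gid in profiles else None)
                for gid in hotspot_gene_ids
            }
            screen = filter_candidates(
                summaries, config.min_kernel_fpkm, config.max_expression_ratio
            )
            annotations = {g.name: g.annotation for g in genes}
            ppr = find_ppr_genes(hotspots, annotations)
        except Exception as exc:
            raise RuntimeError(f"stage 'screen' failed: {exc}") from exc
        pd.DataFrame(
            [{"gene_id": g, "status": status}
             for status, ids in (("pass", screen.passing), ("fail", screen.failing),
                                 ("no-data", screen.no_data))
             for g in ids],
            columns=("gene_id", "status"),
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
        defined = [s for s in summaries.values() if s is not None]
        summary["screen"] = {
            "hotspot_genes": len(hotspot_gene_ids),
            "passing": len(screen.passing),
            "failing": len(screen.failing),
            "no_data": len(screen.no_data),
            "bins": bin_expression(defined),
            "ppr_per_hotspot": {k: len(v) for k, v in ppr.items()},
        }

    # --- stage 6: GO enrichment of passing candidates ---
    if config.go_table is not None and hotspot_gene_ids:
        try:
            term_to_genes = core_io.read_go_annotations(config.go_table)
            background = sorted({g for gs in term_to_genes.values() for g in gs})
            study = [g for g in screen.passing if g in set(background)]
            rows = enrich(study, background, term_to_genes, config.fdr_threshold)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc
        enrichment_table(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            "tested_terms": len(rows),
            "significant": sum(r.significant for r in rows),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "report.txt").write_text(format_report(summary, hotspots))
    return out


def format_report(summary: dict, hotspots: Sequence[Hotspot]) -> str:
    """Human-readable run report in the style of the published hotspot table."""
    lines = ["QTL/QTN hotspot meta-analysis report", "=" * 40, ""]
    if "projection" in summary:
        p = summary["projection"]
        lines.append(
            f"QTLs: {p['collected']} collected, {p['projected']} projected, "
            f"{p['rejected']} unprojectable"
        )
    if "qtl_clusters" in summary:
        lines.append(f"QTL clusters: {summary['qtl_clusters']['total']} "
                     f"{summary['qtl_clusters']['per_trait']}")
    if "qtn_clusters" in summary:
        lines.append(f"QTN clusters: {summary['qtn_clusters']['total']} "
                     f"{summary['qtn_clusters']['per_trait']}")
    hs = summary.get("hotspots", {})
    lines.append(f"Hotspots: {hs.get('n_hotspots', 0)}")
    lines.append("")
    lines.append("ID\tChr\tSpan (Mb)\tClusters\tGenes")
    for h in hotspots:
        lines.append(
            f"{h.name}\t{h.interval.chrom}\t"
            f"{span_mb(h.interval):.1f}\t{h.n_clusters}\t{','.join(h.genes) or '-'}"
        )
    if "screen" in summary:
        s = summary["screen"]
        lines += ["", f"Candidate screen: {s['passing']} pass / {s['failing']} fail "
                      f"/ {s['no_data']} without expression data"]
    if "enrichment" in summary:
        e = summary["enrichment"]
        lines += [f"GO enrichment: {e['significant']} of {e['tested_terms']} "
                  f"tested terms significant"]
    return "\n".join(lines) + "\n"


def report_fixture(hotspot_table: str | Path | pd.DataFrame, build: GenomeBuild | None = None) -> dict:
    """Summary statistics for a hotspot table, bypassing inference.

    Accepts a path to a hotspot TSV (the bundled published survey or a
    pipeline output) or an already-loaded DataFrame.
    """
    if isinstance(hotspot_table, pd.DataFrame):
        df = hotspot_table
    else:
        df = pd.read_csv(hotspot_table, sep="\t", dtype=str, keep_default_na=False)
        for col in ("start", "end", "n_clusters", "n_genes"):
            df[col] = df[col].astype(int)
    hotspots = hotspots_from_table(df)
    summary = summarize_hotspots(hotspots, build or GenomeBuild())
    summary["spans_mb"] = {h.name: span_mb(h.interval) for h in hotspots}
    return summary
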