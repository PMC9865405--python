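"""Data model and tabular I/O for the kernel-size QTL/QTN meta-analysis.

All genomic coordinates are 1-based and inclusive on both ends, matching the
nucleotide spans printed for maize B73 RefGen_v4. BED export converts to the
0-based half-open convention.

The module also bundles two fixtures transcribed from the literature survey
this package operationalises: ``table1_genes.tsv`` (132 cloned kernel-size
genes with phenotype class and annotation) and ``table2_hotspots.tsv``
(31 consensus QTL/QTN hotspots with member clusters and co-located genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("kernel_hotspots")

#: The four kernel size-related traits: kernel length, kernel width,
#: kernel thickness, hundred-kernel weight.
TRAITS = ("KL", "KW", "KT", "HKW")

#: Phenotype classes of cloned kernel-mutant genes.
PHENOTYPE_CLASSES = (
    "Dek", "Emb", "Emp", "End", "opaque/floury", "shrunken", "Smk",
)

#: Published chromosome lengths (nt) of the maize B73 RefGen_v4 assembly.
B73_V4_LENGTHS = {
    "1": 307_041_717,
    "2": 244_442_276,
    "3": 235_667_834,
    "4": 246_994_605,
    "5": 223_902_240,
    "6": 174_033_170,
    "7": 182_381_542,
    "8": 181_122_637,
    "9": 159_769_782,
    "10": 150_982_314,
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A record violates a domain invariant (with row context where known)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeBuild:
    """A named reference assembly: ordered chromosome-name -> length (nt)."""

    name: str = "B73_V4"
    chromosomes: Mapping[str, int] = field(default_factory=lambda: dict(B73_V4_LENGTHS))

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names")
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length")

    def chrom_order(self, chrom: str) -> int:
        """Genome-wide sort key for a chromosome name."""
        try:
            return list(self.chromosomes).index(chrom)
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r} in build {self.name}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed span on a named chromosome, 1-based inclusive at both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )

    def validate(self, build: GenomeBuild) -> "GenomicInterval":
        if self.chrom not in build:
            raise ValidationError(f"unknown chromosome {self.chrom!r}")
        if self.end > build.chromosomes[self.chrom]:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {build.chromosomes[self.chrom]}"
            )
        return self

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two closed intervals share at least one nucleotide."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def length(self) -> int:
        """Inclusive length in nt."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class QTLRecord:
    """A literature QTL before projection: trait plus flanking-marker names.

    ``r_squared`` (proportion of variance explained) and ``lod`` are carried
    as study metadata only; the clustering rules use positions alone.
    """

    qtl_id: str
    trait: str
    left_marker: str | None = None
    right_marker: str | None = None
    study: str = ""
    r_squared: float | None = None
    lod: float | None = None
    env_count: str | None = None
    population: str | None = None

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValidationError(
                f"QTL {self.qtl_id!r}: trait {self.trait!r} not in {TRAITS}"
            )


@dataclass(frozen=True)
class QTNRecord:
    """A point trait-associated variant (typically a GWAS hit)."""

    qtn_id: str
    trait: str
    chrom: str
    position: int
    study: str = ""

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValidationError(
                f"QTN {self.qtn_id!r}: trait {self.trait!r} not in {TRAITS}"
            )
        if self.position < 1:
            raise ValidationError(f"QTN {self.qtn_id!r}: position must be >= 1")


class MarkerMap(dict):
    """marker-name -> (chrom, position nt). Plain dict plus validation."""

    def validate(self, build: GenomeBuild) -> "MarkerMap":
        for name, (chrom, pos) in self.items():
            if chrom not in build:
                raise ValidationError(f"marker {name!r}: unknown chromosome {chrom!r}")
            if not (1 <= pos <= build.chromosomes[chrom]):
                raise ValidationError(f"marker {name!r}: position {pos} out of bounds")
        return self


@dataclass(frozen=True)
class GeneRecord:
    """A cloned gene. Coordinates are optional: the cloned-gene survey prints
    only the chromosome, so co-location ops skip coordinate-less genes."""

    name: str
    gene_id: str
    chrom: str
    start: int | None = None
    end: int | None = None
    annotation: str = ""
    phenotype_class: str | None = None

    def __post_init__(self) -> None:
        if self.phenotype_class is not None and self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValidationError(
                f"gene {self.gene_id!r}: phenotype class {self.phenotype_class!r} "
                f"not in {PHENOTYPE_CLASSES}"
            )
        if (self.start is None) != (self.end is None):
            raise ValidationError(f"gene {self.gene_id!r}: start/end must come together")

    @property
    def interval(self) -> GenomicInterval | None:
        if self.start is None:
            return None
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene FPKM by tissue, with a designated kernel-tissue subset."""

    gene_id: str
    fpkm: Mapping[str, float]
    kernel_tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = set(self.kernel_tissues) - set(self.fpkm)
        if missing:
            raise ValidationError(
                f"gene {self.gene_id!r}: kernel tissues {sorted(missing)} absent from profile"
            )
        for tissue, value in self.fpkm.items():
            if value < 0:
                raise ValidationError(
                    f"gene {self.gene_id!r}: negative FPKM in tissue {tissue!r}"
                )


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

QTL_COLUMNS = ("qtl_id", "trait", "left_marker", "right_marker", "study")
QTN_COLUMNS = ("qtn_id", "trait", "chrom", "position", "study")
MARKER_COLUMNS = ("marker", "chrom", "position")
GENE_COLUMNS = ("gene_name", "gene_id", "chrom", "annotation", "phenotype_class")


def _read_tsv(source: str | Path | IO, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return df


def _opt_float(value: str) -> float | None:
    return float(value) if value not in ("", "NA") else None


def read_qtl_table(source: str | Path | IO, build: GenomeBuild | None = None) -> list[QTLRecord]:
    """Read a curated QTL table (TSV). Unknown traits are rejected with the
    offending row number; markers may be blank (unprojectable records)."""
    df = _read_tsv(source, ("qtl_id", "trait"))
    records: list[QTLRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        trait = row.trait
        if trait not in TRAITS:
            raise ValidationError(f"row {i}: trait {trait!r} not in {TRAITS}")
        if row.qtl_id in seen:
            raise ValidationError(f"row {i}: duplicate qtl_id {row.qtl_id!r}")
        seen.add(row.qtl_id)
        records.append(
            QTLRecord(
                qtl_id=row.qtl_id,
                trait=trait,
                left_marker=getattr(row, "left_marker", "") or None,
                right_marker=getattr(row, "right_marker", "") or None,
                study=getattr(row, "study", ""),
                r_squared=_opt_float(getattr(row, "r_squared", "")),
                lod=_opt_float(getattr(row, "lod", "")),
            )
        )
    return records


def write_qtl_table(records: Iterable[QTLRecord], dest: str | Path | IO) -> None:
    rows = [
        {
            "qtl_id": r.qtl_id,
            "trait": r.trait,
            "left_marker": r.left_marker or "",
            "right_marker": r.right_marker or "",
            "study": r.study,
            "r_squared": "" if r.r_squared is None else repr(r.r_squared),
            "lod": "" if r.lod is None else repr(r.lod),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=QTL_COLUMNS + ("r_squared", "lod")).to_csv(
        dest, sep="\t", index=False
    )


def read_qtn_table(source: str | Path | IO, build: GenomeBuild | None = None) -> list[QTNRecord]:
    df = _read_tsv(source, QTN_COLUMNS[:4])
    records: list[QTNRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.trait not in TRAITS:
            raise ValidationError(f"row {i}: trait {row.trait!r} not in {TRAITS}")
        if row.qtn_id in seen:
            raise ValidationError(f"row {i}: duplicate qtn_id {row.qtn_id!r}")
        seen.add(row.qtn_id)
        rec = QTNRecord(
            qtn_id=row.qtn_id,
            trait=row.trait,
            chrom=row.chrom,
            position=int(row.position),
            study=getattr(row, "study", ""),
        )
        if build is not None:
            if rec.chrom not in build:
                raise ValidationError(f"row {i}: unknown chromosome {rec.chrom!r}")
            if rec.position > build.chromosomes[rec.chrom]:
                raise ValidationError(f"row {i}: position {rec.position} out of bounds")
        records.append(rec)
    return records


def write_qtn_table(records: Iterable[QTNRecord], dest: str | Path | IO) -> None:
    rows = [
        {
            "qtn_id": r.qtn_id,
            "trait": r.trait,
            "chrom": r.chrom,
            "position": r.position,
            "study": r.study,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=QTN_COLUMNS).to_csv(dest, sep="\t", index=False)


def read_marker_map(source: str | Path | IO, build: GenomeBuild | None = None) -> MarkerMap:
    df = _read_tsv(source, MARKER_COLUMNS)
    markers = MarkerMap()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.marker in markers:
            raise ValidationError(f"row {i}: duplicate marker {row.marker!r}")
        markers[row.marker] = (row.chrom, int(row.position))
    if build is not None:
        markers.validate(build)
    return markers


def write_marker_map(markers: MarkerMap, dest: str | Path | IO) -> None:
    rows = [
        {"marker": name, "chrom": chrom, "position": pos}
        for name, (chrom, pos) in markers.items()
    ]
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(dest, sep="\t", index=False)


def read_gene_table(source: str | Path | IO) -> list[GeneRecord]:
    """Read a gene table; ``start``/``end`` columns are optional (the cloned-
    gene fixture has none)."""
    df = _read_tsv(source, ("gene_name", "gene_id", "chrom"))
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.gene_id in seen:
            raise ValidationError(f"row {i}: duplicate gene_id {row.gene_id!r}")
        seen.add(row.gene_id)
        start = getattr(row, "start", "")
        end = getattr(row, "end", "")
        genes.append(
            GeneRecord(
                name=row.gene_name,
                gene_id=row.gene_id,
                chrom=row.chrom,
                start=int(start) if start else None,
                end=int(end) if end else None,
                annotation=getattr(row, "annotation", ""),
                phenotype_class=getattr(row, "phenotype_class", "") or None,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], dest: str | Path | IO) -> None:
    rows = [
        {
            "gene_name": g.name,
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": "" if g.start is None else g.start,
            "end": "" if g.end is None else g.end,
            "annotation": g.annotation,
            "phenotype_class": g.phenotype_class or "",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS[:3] + ("start", "end") + GENE_COLUMNS[3:]).to_csv(
        dest, sep="\t", index=False
    )


def read_expression_table(
    source: str | Path | IO, kernel_tissues: Sequence[str]
) -> dict[str, ExpressionProfile]:
    """Read a gene x tissue FPKM matrix (first column ``gene_id``)."""
    df = pd.read_csv(source, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise SchemaError("expression table must have a leading 'gene_id' column")
    tissues = list(df.columns)
    missing = set(kernel_tissues) - set(tissues)
    if missing:
        raise SchemaError(f"kernel tissues {sorted(missing)} absent from matrix")
    kt = tuple(kernel_tissues)
    return {
        gene_id: ExpressionProfile(gene_id, dict(zip(tissues, row)), kt)
        for gene_id, row in zip(df.index, df.to_numpy())
    }


def write_expression_table(
    profiles: Mapping[str, Mapping[str, float]], dest: str | Path | IO
) -> None:
    df = pd.DataFrame.from_dict(profiles, orient="index")
    df.index.name = "gene_id"
    df.to_csv(dest, sep="\t")


def read_go_annotations(source: str | Path | IO) -> dict[str, set[str]]:
    """Read gene -> GO term annotations (two-column TSV) as term -> gene set."""
    df = _read_tsv(source, ("gene_id", "term_id"))
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.term_id, set()).add(row.gene_id)
    return mapping


def write_go_annotations(term_to_genes: Mapping[str, Iterable[str]], dest: str | Path | IO) -> None:
    rows = [
        {"gene_id": g, "term_id": t}
        for t in sorted(term_to_genes)
        for g in sorted(term_to_genes[t])
    ]
    pd.DataFrame(rows, columns=("gene_id", "term_id")).to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[str, GenomicInterval]], dest: str | Path | IO) -> None:
    """Write named intervals as BED4: 1-based inclusive -> 0-based half-open."""
    lines = []
    for name, iv in intervals:
        if not isinstance(iv, GenomicInterval):
            raise ValidationError(f"not a GenomicInterval: {iv!r}")
        lines.append(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def read_bed(source: str | Path | IO) -> list[tuple[str, GenomicInterval]]:
    """Read BED4 back into named 1-based inclusive intervals."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        chrom, start, end, name = line.split("\t")[:4]
        out.append((name, GenomicInterval(chrom, int(start) + 1, int(end))))
    return out


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

def _data_path(filename: str) -> Path:
    return Path(resources.files("kernel_hotspots") / "data" / filename)


def load_cloned_genes() -> list[GeneRecord]:
    """The bundled survey of 132 cloned maize kernel-size genes."""
    return read_gene_table(_data_path("table1_genes.tsv"))


def load_published_hotspots() -> pd.DataFrame:
    """The bundled table of 31 published consensus hotspots.

    Columns: hotspot_id, chrom, start, end, n_clusters, clusters (comma-
    separated member names), n_genes, genes (comma-separated cloned genes).
    """
    df = pd.read_csv(_data_path("table2_hotspots.tsv"), sep="\t", dtype=str, keep_default_na=False)
    for col in ("start", "end", "n_clusters", "n_genes"):
        df[col] = df[col].astype(int)
    return df
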