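"""Core genomic coordinate types and readers/writers for pipeline inputs.

All internal coordinates are 0-based half-open (BED convention).
Chromosome names are opaque strings; no ``chr`` normalization is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MARKS = ("PXR", "p300", "H3K4me1", "H3K27ac")
CONDITIONS = ("DMSO", "rifampin")
ASSAY_SCHEMAS = ("promoter_assay", "enhancer_assay", "qpcr")

#: Required value columns per assay schema, besides unit_id/condition/replicate.
_SCHEMA_COLUMNS = {
    "promoter_assay": ("signal",),
    "enhancer_assay": ("firefly", "renilla"),
    "qpcr": ("ct",),
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """1 bp minimum, half-open semantics: adjacency is not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak (TF) or enriched island (histone mark)."""

    interval: GenomicInterval
    mark: str
    condition: str
    score: float | None = None
    source_id: str = ""

    def __post_init__(self):
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("score must be nonnegative")


@dataclass(frozen=True)
class GeneModel:
    """Gene body with strand, exons and a derivable TSS.

    The transcription start site is ``interval.start`` for + strand genes
    and ``interval.end`` for − strand genes.
    """

    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand is mandatory")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.name}: exon on wrong chromosome")
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"gene {self.name}: exon outside gene body")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or are unsorted")
            prev_end = exon.end

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class PhasedPanel:
    """Phased biallelic genotype panel.

    ``haplotypes`` has 2·n_samples rows (two consecutive rows per sample,
    sample order preserved) and one 0/1 column per variant.
    """

    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    haplotypes: np.ndarray  # shape (2*n_samples, n_variants), dtype int8
    samples: list[str]
    sample_population: dict[str, str]

    def __post_init__(self):
        n_hap, n_var = self.haplotypes.shape
        if n_hap != 2 * len(self.samples):
            raise ValueError("haplotype row count must be twice sample count")
        if n_var != len(self.variants):
            raise ValueError("haplotype column count must match variant count")
        vals = np.unique(self.haplotypes)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("haplotype entries must be 0/1")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"variant positions not strictly increasing on {chrom}"
                )
        missing = [s for s in self.samples if s not in self.sample_population]
        if missing:
            raise ValueError(f"samples missing from population table: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def population_rows(self, population: str) -> np.ndarray:
        """Haplotype row indices for all samples of one population."""
        idx = []
        for i, s in enumerate(self.samples):
            if self.sample_population[s] == population:
                idx.extend((2 * i, 2 * i + 1))
        return np.asarray(idx, dtype=int)

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(hits[0])

    def allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        m = self.haplotypes if rows is None else self.haplotypes[rows]
        return m.mean(axis=0)


@dataclass
class AssayTable:
    """Replicate-level reporter or qPCR measurements.

    ``data`` columns: unit_id, condition, replicate, plus the schema's
    signal columns (promoter_assay: signal; enhancer_assay: firefly,
    renilla; qpcr: ct).
    """

    data: pd.DataFrame
    schema: str

    def __post_init__(self):
        if self.schema not in ASSAY_SCHEMAS:
            raise ValueError(f"unknown schema {self.schema!r}")
        required = ("unit_id", "condition", "replicate") + _SCHEMA_COLUMNS[self.schema]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"assay table missing columns: {missing}")
        bad_cond = set(self.data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {sorted(bad_cond)}")
        for col in _SCHEMA_COLUMNS[self.schema]:
            vals = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in column {col}")
            if col != "ct" and np.any(vals < 0):
                raise ValueError(f"negative signal in column {col}")

    def replicate_counts(self) -> pd.Series:
        return self.data.groupby(["unit_id", "condition"]).size()

    def units(self) -> list[str]:
        return list(dict.fromkeys(self.data["unit_id"]))


# ---------------------------------------------------------------------------
# Interval / peak files


def _parse_bed_line(line: str, lineno: int, path: str) -> tuple[str, int, int, list[str]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start >= end or start < 0:
        raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
    return chrom, start, end, fields


def read_intervals(path: str, format: str = "bed", *, mark: str, condition: str) -> list[Peak]:
    """Read a BED3+/narrowPeak file into Peaks, sorted by (chrom, start).

    Coordinates are taken verbatim as 0-based half-open. narrowPeak summit
    fields are parsed but unused.
    """
    if format not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, fields = _parse_bed_line(line, lineno, path)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{os.path.basename(path)}:{lineno}"
            score = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    mark=mark,
                    condition=condition,
                    score=score,
                    source_id=name,
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.mark))
    return peaks


def write_bed(intervals: Iterable[GenomicInterval | Peak], path: str, *, names: Sequence[str] | None = None, scores: Sequence[float] | None = None) -> None:
    """Write intervals (or Peaks) as tab-separated BED, no header."""
    rows = []
    for i, item in enumerate(intervals):
        iv = item.interval if isinstance(item, Peak) else item
        name = names[i] if names is not None else (item.source_id if isinstance(item, Peak) else ".")
        score = scores[i] if scores is not None else (
            item.score if isinstance(item, Peak) and item.score is not None else 0
        )
        rows.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# Gene models


def read_gene_models(path: str, format: str = "refflat_tsv") -> list[GeneModel]:
    """Read gene models from refFlat-like TSV or BED12.

    refFlat-like columns: gene, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma-separated absolute coordinates).
    """
    if format not in ("bed12", "refflat_tsv"):
        raise ValueError(f"unknown format {format!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if format == "refflat_tsv":
                genes.append(_parse_refflat(fields, lineno, path))
            else:
                genes.append(_parse_bed12(fields, lineno, path))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.name))
    return genes


def _parse_refflat(fields: list[str], lineno: int, path: str) -> GeneModel:
    if len(fields) < 7:
        raise FormatError(f"{path}:{lineno}: expected 7 refFlat fields")
    name, chrom, strand = fields[0], fields[1], fields[2]
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
    tx_start, tx_end = int(fields[3]), int(fields[4])
    starts = [int(x) for x in fields[5].rstrip(",").split(",") if x]
    ends = [int(x) for x in fields[6].rstrip(",").split(",") if x]
    if len(starts) != len(ends):
        raise FormatError(f"{path}:{lineno}: exonStarts/exonEnds length mismatch")
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends))
    try:
        return GeneModel(name, GenomicInterval(chrom, tx_start, tx_end, strand), exons)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def _parse_bed12(fields: list[str], lineno: int, path: str) -> GeneModel:
    if len(fields) < 12:
        raise FormatError(f"{path}:{lineno}: expected 12 BED12 fields")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name, strand = fields[3], fields[5]
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
    if len(sizes) != len(offsets):
        raise FormatError(f"{path}:{lineno}: blockSizes/blockStarts length mismatch")
    exons = tuple(
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(offsets, sizes)
    )
    try:
        return GeneModel(name, GenomicInterval(chrom, start, end, strand), exons)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_gene_models(genes: Iterable[GeneModel], path: str) -> None:
    """Write genes as refFlat-like TSV."""
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.name}\t{g.interval.chrom}\t{g.strand}\t"
                f"{g.interval.start}\t{g.interval.end}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# Phased panels (VCF + sample→population table)


def read_phased_panel(path: str, population_table: str) -> PhasedPanel:
    """Read a phased biallelic VCF plus a sample→population TSV.

    Every genotype must be phased (``|`` separator) and every site
    biallelic; violations raise :class:`FormatError` naming the site
    and sample.
    """
    from cyvcf2 import VCF

    pops = pd.read_csv(population_table, sep="\t", dtype=str)
    if not {"sample", "population"} <= set(pops.columns):
        raise FormatError("population table requires columns: sample, population")
    pop_map = dict(zip(pops["sample"], pops["population"]))

    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_map]
    if missing:
        raise FormatError(f"samples missing from population table: {missing}")

    var_rows = []
    hap_cols = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(f"site {v.CHROM}:{v.POS}: multiallelic sites are rejected")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if not phased or a < 0 or b < 0:
                raise FormatError(
                    f"site {v.CHROM}:{v.POS}, sample {samples[i]}: unphased or missing genotype"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        var_rows.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        hap_cols.append(col)

    variants = pd.DataFrame(var_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    haplotypes = (
        np.column_stack(hap_cols) if hap_cols else np.zeros((2 * len(samples), 0), np.int8)
    )
    return PhasedPanel(variants, haplotypes, samples, {s: pop_map[s] for s in samples})


def write_phased_panel(panel: PhasedPanel, vcf_path: str, population_path: str) -> None:
    """Write a panel as minimal VCF 4.2 plus a sample→population TSV."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j, row in panel.variants.iterrows():
            gts = "\t".join(
                f"{panel.haplotypes[2 * i, j]}|{panel.haplotypes[2 * i + 1, j]}"
                for i in range(panel.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos'] + 1}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    pd.DataFrame(
        {"sample": panel.samples, "population": [panel.sample_population[s] for s in panel.samples]}
    ).to_csv(population_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assay tables


def read_assay_table(path: str, schema: str) -> AssayTable:
    """Read a headered assay TSV and validate it against its schema."""
    if schema not in ASSAY_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t")
    required = ("unit_id", "condition", "replicate") + _SCHEMA_COLUMNS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns for schema {schema}: {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return AssayTable(df, schema)


def write_assay_table(table: AssayTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
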