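"""Genomic feature annotation, TSS profiling and binomial term enrichment.

Feature classes follow the priority promoter > exon > intron > intergenic,
with the promoter window defined strand-aware around the TSS (default
−2500/+500 bp). Term enrichment follows the basal-plus-extension regulatory
domain model: each gene owns a basal window around its TSS (default 5 kb
upstream / 1 kb downstream) extended outward to the nearest neighboring
basal window, capped (default 1 Mb); a term's genome fraction p is the
merged length of its genes' domains over the genome length, and regions
hit a term when their midpoint falls in that merged span. Significance is
the upper binomial tail P(X >= k), X ~ Binomial(n, p), with
Benjamini–Hochberg adjustment across terms.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import GeneModel, GenomicInterval, Peak

FEATURES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class FeatureAssignment:
    interval: GenomicInterval
    feature: str
    gene: str | None

    def __post_init__(self):
        if (self.feature == "intergenic") != (self.gene is None):
            raise ValueError("gene must be null iff feature is intergenic")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene: str
    domain: GenomicInterval


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int
    n: int
    p: float
    fold: float
    p_binom: float
    q: float


def promoter_window(gene: GeneModel, upstream: int = 2500, downstream: int = 500) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at 0."""
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.interval.chrom, max(0, start), end)


def assign_genomic_feature(
    interval: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2500,
    promoter_downstream: int = 500,
) -> FeatureAssignment:
    """Classify an interval as promoter, exon, intron or intergenic.

    Assignment is by >=1 bp overlap with the highest-priority feature of
    any gene; ties between genes at equal priority resolve to the first
    gene in (chrom, start, name) order.
    """
    best: tuple[int, str] | None = None  # (priority rank, gene name)
    for gene in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.name)):
        if gene.interval.chrom != interval.chrom:
            continue
        prom = promoter_window(gene, promoter_upstream, promoter_downstream)
        if interval.overlaps(prom):
            rank = 0
        elif any(interval.overlaps(e) for e in gene.exons):
            rank = 1
        elif interval.overlaps(gene.interval):
            rank = 2
        else:
            continue
        if best is None or rank < best[0]:
            best = (rank, gene.name)
        if best[0] == 0:
            break
    if best is None:
        return FeatureAssignment(interval, "intergenic", None)
    return FeatureAssignment(interval, FEATURES[best[0]], best[1])


def feature_distribution(
    intervals: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    **kwargs,
) -> dict[str, int]:
    """Count feature-class assignments over a set of intervals."""
    counts = {f: 0 for f in FEATURES}
    for iv in intervals:
        counts[assign_genomic_feature(iv, genes, **kwargs).feature] += 1
    return counts


def tss_distance_profile(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = 50000,
    bin_width: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed peak-midpoint distances to the nearest TSS.

    Distance is signed in gene orientation (negative = upstream of the
    TSS). Peaks whose nearest TSS lies beyond ``window`` are excluded.
    Returns (counts, bin_edges) with edges spanning [-window, window].
    """
    if not genes:
        raise ValueError("no genes supplied")
    if window <= 0 or (2 * window) % bin_width != 0:
        raise ValueError("window must be positive and bin_width divide 2*window")
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append((g.tss, g.strand, g.name))
    for lst in by_chrom.values():
        lst.sort()

    distances = []
    for p in peaks:
        entries = by_chrom.get(p.interval.chrom)
        if not entries:
            continue
        mid = p.interval.midpoint
        positions = [e[0] for e in entries]
        i = bisect.bisect_left(positions, mid)
        # nearest by absolute distance; ties by TSS position then name
        candidates = entries[max(0, i - 1): i + 1]
        tss, strand, _ = min(candidates, key=lambda e: (abs(mid - e[0]), e[0], e[2]))
        signed = mid - tss if strand == "+" else tss - mid
        if -window <= signed <= window:
            distances.append(signed)
    edges = np.arange(-window, window + bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return counts, edges


def build_regulatory_domains(
    genes: Sequence[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    extension_cap: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains, clipped to chromosomes."""
    chrom_sizes = dict(chrom_sizes or {})

    def basal(g: GeneModel) -> tuple[int, int]:
        if g.strand == "+":
            return g.tss - basal_up, g.tss + basal_down
        return g.tss - basal_down, g.tss + basal_up

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        chrom = g.interval.chrom
        if chrom in chrom_sizes and g.interval.end > chrom_sizes[chrom]:
            raise ValueError(f"gene {g.name} extends beyond chromosome {chrom}")
        by_chrom.setdefault(chrom, []).append(g)

    domains: list[RegulatoryDomain] = []
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.tss, g.name))
        basals = [basal(g) for g in glist]
        size = chrom_sizes.get(chrom)
        for i, g in enumerate(glist):
            b_start, b_end = basals[i]
            left = g.tss - extension_cap
            if i > 0:
                left = max(left, basals[i - 1][1])
            right = g.tss + extension_cap
            if i + 1 < len(glist):
                right = min(right, basals[i + 1][0])
            # extension never shrinks the basal window
            start = max(0, min(left, b_start))
            end = max(right, b_end)
            if size is not None:
                end = min(end, size)
                end = max(end, min(b_end, size))
            domains.append(
                RegulatoryDomain(g.name, GenomicInterval(chrom, start, max(end, start + 1)))
            )
    domains.sort(key=lambda d: (d.domain.chrom, d.domain.start, d.gene))
    return domains


def _merge_spans(spans: list[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    merged: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in spans:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def binomial_term_enrichment(
    regions: Sequence[GenomicInterval],
    domains: Sequence[RegulatoryDomain],
    term_gene_sets: Mapping[str, set[str] | Sequence[str]],
    genome_length: int,
    fold_min: float = 6.0,
    q_max: float = 5e-3,
) -> list[EnrichmentResult]:
    """Binomial term enrichment over regulatory domains, filtered and ranked.

    Returns terms with fold > ``fold_min`` and BH-adjusted q < ``q_max``,
    sorted by raw binomial p ascending. BH adjustment is computed across
    all tested terms before filtering.
    """
    n = len(regions)
    dom_by_gene: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        dom_by_gene.setdefault(d.gene, []).append(d)

    rows = []
    for term, gene_set in term_gene_sets.items():
        spans = [
            (d.domain.chrom, d.domain.start, d.domain.end)
            for g in gene_set
            for d in dom_by_gene.get(g, [])
        ]
        merged = _merge_spans(spans)
        total = sum(e - s for ivs in merged.values() for s, e in ivs)
        if total == 0:
            raise ValueError(f"term {term!r} has zero domain coverage; untestable")
        p = total / genome_length
        k = 0
        for iv in regions:
            mid = iv.midpoint
            for s, e in merged.get(iv.chrom, ()):
                if s <= mid < e:
                    k += 1
                    break
        fold = (k / n) / p if n > 0 else 0.0
        p_binom = float(stats.binom.sf(k - 1, n, p)) if n > 0 else 1.0
        rows.append((term, k, p, fold, p_binom))

    if not rows:
        return []
    pvals = np.array([r[4] for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(term, k, n, p, fold, p_binom, float(q))
        for (term, k, p, fold, p_binom), q in zip(rows, qvals)
    ]
    kept = [r for r in results if r.fold > fold_min and r.q < q_max]
    kept.sort(key=lambda r: (r.p_binom, r.term))
    return kept


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT term file: term, description, then gene symbols, tab-separated."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            terms[fields[0]] = set(fields[2:])
    return terms
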