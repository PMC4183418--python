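"""GWAS lead SNP expansion to LD proxies and GWAS-linked peak (GLP) calling.

Pharmacogenomic GWAS lead SNPs are expanded to linkage-disequilibrium
proxies (r² > 0.8 by default) within the phased panel of the study's
population; drug-induced PXR peaks containing at least one proxy are
called GWAS-linked peaks. Enrichment of pharmacogenomic versus
non-pharmacogenomic leads among peak-overlapping LD blocks is tested with
a two-tailed chi-squared test with Yates' continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genomic_io import Peak, PhasedPanel


@dataclass(frozen=True)
class GwasCatalogEntry:
    lead_snp: str
    chrom: str
    position: int
    trait: str
    pharmacogenomic: bool
    population: str

    def __post_init__(self):
        if self.position < 0:
            raise ValueError("position must be nonnegative")


@dataclass(frozen=True)
class ProxyRecord:
    variant_id: str
    position: int
    lead_snp: str
    trait: str


@dataclass(frozen=True)
class GLP:
    """A drug-induced PXR peak containing >=1 GWAS-LD proxy SNP."""

    peak: Peak
    proxies: tuple[ProxyRecord, ...]
    id: str


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = SNP class (pharmacogenomic / other), columns = overlap yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both row sums must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def pairwise_r2(panel: PhasedPanel, snp_a: str, snp_b: str, population: str) -> float:
    """Haplotype-frequency r² between two variants within a population.

    D = p_AB − p_A·p_B; r² = D² / (p_A(1−p_A)·p_B(1−p_B)), computed from
    the population's phased haplotype rows. Raises for monomorphic sites
    (undefined denominator).
    """
    rows = panel.population_rows(population)
    if rows.size == 0:
        raise ValueError(f"no samples in population {population!r}")
    col_a = panel.haplotypes[rows, panel.variant_index(snp_a)].astype(float)
    col_b = panel.haplotypes[rows, panel.variant_index(snp_b)].astype(float)
    return _r2_from_columns(col_a, col_b, snp_a, snp_b, population)


def _r2_from_columns(col_a: np.ndarray, col_b: np.ndarray, snp_a: str, snp_b: str, population: str) -> float:
    p_a = col_a.mean()
    p_b = col_b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError(
            f"monomorphic variant in population {population!r}: "
            f"{snp_a if p_a in (0.0, 1.0) else snp_b}"
        )
    p_ab = (col_a * col_b).mean()
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(min(1.0, r2))


def expand_ld_proxies(
    panel: PhasedPanel,
    lead: GwasCatalogEntry,
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> list[str]:
    """All panel variants within ±window of the lead with r² > threshold.

    The lead itself is always included. Panel variants monomorphic in the
    lead's population cannot pass the threshold and are skipped. Output is
    ordered by genomic position.
    """
    try:
        lead_idx = panel.variant_index(lead.lead_snp)
    except KeyError as exc:
        raise ValueError(f"lead SNP {lead.lead_snp!r} absent from panel") from exc
    rows = panel.population_rows(lead.population)
    if rows.size == 0:
        raise ValueError(f"no samples in population {lead.population!r}")
    variants = panel.variants
    lead_chrom = variants.at[lead_idx, "chrom"]
    lead_pos = int(variants.at[lead_idx, "pos"])
    in_window = (
        (variants["chrom"] == lead_chrom)
        & (variants["pos"] >= lead_pos - window)
        & (variants["pos"] <= lead_pos + window)
    ).to_numpy()

    hap = panel.haplotypes[rows].astype(float)
    lead_col = hap[:, lead_idx]
    p_lead = lead_col.mean()
    if p_lead in (0.0, 1.0):
        raise ValueError(
            f"lead SNP {lead.lead_snp!r} monomorphic in population {lead.population!r}"
        )

    proxies = []
    for j in np.flatnonzero(in_window):
        if j == lead_idx:
            continue
        col = hap[:, j]
        p = col.mean()
        if p in (0.0, 1.0):
            continue
        r2 = _r2_from_columns(lead_col, col, lead.lead_snp, variants.at[j, "id"], lead.population)
        if r2 > r2_threshold:
            proxies.append((int(variants.at[j, "pos"]), str(variants.at[j, "id"])))
    proxies.append((lead_pos, str(variants.at[lead_idx, "id"])))
    proxies.sort()
    return [vid for _, vid in proxies]


def expand_catalog(
    panel: PhasedPanel,
    catalog: list[GwasCatalogEntry],
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> dict[str, list[tuple[str, str, int, str]]]:
    """Expand every catalog lead to proxy records.

    Returns lead SNP id → [(variant id, chrom, position, trait), ...],
    each lead expanded only within its study's population.
    """
    pos_by_id = dict(
        zip(panel.variants["id"], zip(panel.variants["chrom"], panel.variants["pos"]))
    )
    out: dict[str, list[tuple[str, str, int, str]]] = {}
    for entry in catalog:
        proxies = expand_ld_proxies(panel, entry, r2_threshold, window)
        records = out.setdefault(entry.lead_snp, [])
        seen = {(r[0]) for r in records}
        for vid in proxies:
            if vid in seen:
                continue
            chrom, p = pos_by_id[vid]
            records.append((vid, str(chrom), int(p), entry.trait))
            seen.add(vid)
    return out


def identify_glps(
    pxr_peaks: list[Peak],
    proxies: dict[str, list[tuple[str, str, int, str]]],
) -> list[GLP]:
    """Call GLPs: peaks containing (start <= pos < end) >=1 proxy SNP.

    ``proxies`` maps lead SNP id to records of
    (variant id, chrom, position, trait). IDs are assigned GLP1..GLPm in
    genome order of the peaks.
    """
    tree_by_chrom: dict[str, IntervalTree] = {}
    for i, p in enumerate(pxr_peaks):
        tree_by_chrom.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i
        )
    hits: dict[int, list[ProxyRecord]] = {}
    for lead, records in proxies.items():
        for variant_id, chrom, pos, trait in records:
            tree = tree_by_chrom.get(chrom)
            if tree is None:
                continue
            for iv in tree.at(pos):
                hits.setdefault(iv.data, []).append(
                    ProxyRecord(variant_id, pos, lead, trait)
                )
    ordered = sorted(
        hits, key=lambda i: (pxr_peaks[i].interval.chrom, pxr_peaks[i].interval.start)
    )
    glps = []
    for rank, i in enumerate(ordered, start=1):
        recs = sorted(set(hits[i]), key=lambda r: (r.position, r.variant_id, r.lead_snp))
        glps.append(GLP(peak=pxr_peaks[i], proxies=tuple(recs), id=f"GLP{rank}"))
    return glps


def yates_chi2_enrichment(
    table: ContingencyTable2x2, correction: bool = True
) -> tuple[float, float]:
    """Two-tailed chi-squared test on a 2×2 table, Yates-corrected.

    χ² = Σ (max(|O−E| − 0.5, 0))² / E over the four cells (the correction
    term is clamped at zero so that a table already at expectation yields
    χ² = 0, p = 1); p is the upper tail of χ²(1 df).
    """
    obs = table.as_array()
    if np.any(obs.sum(axis=0) == 0):
        raise ValueError("zero column marginal; test undefined")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff**2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def lead_level_contingency(
    catalog: list[GwasCatalogEntry],
    proxy_positions: dict[str, list[tuple[str, int]]],
    pxr_peaks: list[Peak],
) -> ContingencyTable2x2:
    """Build the pharmacogenomic-vs-other 2×2 table at the LD-block level.

    ``proxy_positions`` maps lead SNP id to (chrom, position) records for
    all its proxies (lead included). A lead overlaps when any proxy falls
    inside any peak.
    """
    tree_by_chrom: dict[str, IntervalTree] = {}
    for p in pxr_peaks:
        tree_by_chrom.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end
        )

    def overlaps(lead_id: str) -> bool:
        for chrom, pos in proxy_positions.get(lead_id, ()):
            tree = tree_by_chrom.get(chrom)
            if tree is not None and tree.at(pos):
                return True
        return False

    a = b = c = d = 0
    for entry in catalog:
        hit = overlaps(entry.lead_snp)
        if entry.pharmacogenomic:
            a += hit
            b += not hit
        else:
            c += hit
            d += not hit
    return ContingencyTable2x2(a, b, c, d)


def read_gwas_catalog(path: str) -> list[GwasCatalogEntry]:
    """Catalog TSV columns: snp, chrom, pos, trait, pharmacogenomic{0,1}, population."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str, "population": str})
    required = {"snp", "chrom", "pos", "trait", "pharmacogenomic", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalog columns {sorted(missing)}")
    return [
        GwasCatalogEntry(
            lead_snp=str(r.snp),
            chrom=str(r.chrom),
            position=int(r.pos),
            trait=str(r.trait),
            pharmacogenomic=bool(int(r.pharmacogenomic)),
            population=str(r.population),
        )
        for r in df.itertuples()
    ]
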