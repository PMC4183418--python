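"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of the study's data at desk scale:
a peak landscape where planted sites carry all four marks (PXR, p300,
H3K4me1, H3K27ac) exclusively in the drug condition over a background of
partial-mark or condition-shared clusters; a phased haplotype panel with
planted LD blocks of controllable r²; a GWAS catalog with controllable
peak-overlap fractions per SNP class; and reporter/qPCR tables with
planted effect sizes under multiplicative log-normal noise (additive
normal noise on the Ct scale for qPCR).

Every generator is deterministic under (seed, parameters). Planted truth
is returned alongside the data and is sufficient to score precision and
recall of each stage without inspecting generator internals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    MARKS,
    AssayTable,
    GeneModel,
    GenomicInterval,
    Peak,
    PhasedPanel,
)

# Geometry mirrors the sequencing design: TF fragments sonicated to
# 300-500 bp, histone islands averaging ~5 kb.
TF_PEAK_LENGTH = (300, 500)
ISLAND_LENGTH = (4000, 5500)


@dataclass
class SimulationTruth:
    """Planted ground truth emitted alongside synthetic data."""

    seed: int
    planted_rirs: list[GenomicInterval] = field(default_factory=list)
    planted_glp_peaks: list[str] = field(default_factory=list)
    planted_ld_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)
    planted_assay_labels: dict[str, str] = field(default_factory=dict)
    planted_qpcr_folds: dict[str, float] = field(default_factory=dict)
    lead_overlap_status: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_rirs"] = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in self.planted_rirs
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Genome annotation


def simulate_genome_annotation(
    n_chroms: int = 2,
    chrom_length: int = 10_000_000,
    n_genes: int = 200,
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene bodies with random strands and 2-10 exons."""
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    gi = 0
    for ci, (chrom, n_c) in enumerate(zip(chrom_sizes, per_chrom)):
        if n_c == 0:
            continue
        slot = chrom_length // n_c
        if slot < 4000:
            raise ValueError("infeasible gene packing: chromosome too short")
        for j in range(n_c):
            length = int(rng.integers(2000, min(50_000, slot - 1000)))
            offset = int(rng.integers(0, slot - length))
            start = j * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 11))
            # 2*n_exons sorted distinct breakpoints inside the body
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons, replace=False))
            exons = tuple(
                GenomicInterval(chrom, start + int(cuts[2 * k]), start + int(cuts[2 * k + 1]), strand)
                for k in range(n_exons)
            )
            gi += 1
            genes.append(
                GeneModel(f"GENE{gi}", GenomicInterval(chrom, start, start + length, strand), exons)
            )
    return genes, chrom_sizes


# ---------------------------------------------------------------------------
# Peak landscape


def _cluster_peaks(
    rng: np.random.Generator,
    chrom: str,
    center: int,
    marks: Sequence[str],
    conditions: Sequence[str],
    tag: str,
) -> list[Peak]:
    """Co-located peaks/islands around a center, all mutually overlapping."""
    peaks = []
    for mark in marks:
        lo, hi = ISLAND_LENGTH if mark in ("H3K4me1", "H3K27ac") else TF_PEAK_LENGTH
        length = int(rng.integers(lo, hi + 1))
        jitter = int(rng.integers(-100, 101))
        start = max(0, center - length // 2 + jitter)
        for condition in conditions:
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + length),
                    mark=mark,
                    condition=condition,
                    score=float(rng.integers(50, 1000)),
                    source_id=f"{tag}_{mark}_{condition}",
                )
            )
    return peaks


def simulate_peak_landscape(
    chrom_sizes: Mapping[str, int],
    n_planted_rirs: int = 20,
    n_background_per_mark: int = 200,
    p_shared_cluster: float = 0.15,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], list[Peak]], SimulationTruth]:
    """Peak landscape with planted four-mark drug-exclusive regions.

    Planted sites receive overlapping PXR + p300 peaks and broader
    H3K4me1/H3K27ac islands in the drug condition only. Background
    clusters carry 1-3 marks (any condition pattern) or all four marks in
    both conditions, so they can never yield a drug-exclusive four-mark
    region. Clusters occupy disjoint slots separated by >=10 kb.

    Returns peaks keyed by (mark, condition), plus the planted truth.
    """
    rng = np.random.default_rng(seed)
    slot_content, slot_gap, margin = 6000, 12_000, 50_000
    pitch = slot_content + slot_gap
    slots = []
    for chrom, size in chrom_sizes.items():
        n_slots = (size - 2 * margin) // pitch
        for i in range(n_slots):
            slots.append((chrom, margin + i * pitch + slot_content // 2))
    rng.shuffle(slots)

    budgets = {m: n_background_per_mark for m in MARKS}
    peaks: dict[tuple[str, str], list[Peak]] = {
        (m, c): [] for m in MARKS for c in ("DMSO", "rifampin")
    }
    truth = SimulationTruth(seed=seed)

    def add(plist: list[Peak]):
        for p in plist:
            peaks[(p.mark, p.condition)].append(p)

    needed = n_planted_rirs
    if len(slots) < needed + 1:
        raise ValueError("not enough genomic slots for requested counts")

    si = 0
    for k in range(n_planted_rirs):
        chrom, center = slots[si]
        si += 1
        plist = _cluster_peaks(rng, chrom, center, MARKS, ["rifampin"], f"plant{k + 1}")
        add(plist)
        span = GenomicInterval(
            chrom, min(p.interval.start for p in plist), max(p.interval.end for p in plist)
        )
        truth.planted_rirs.append(span)

    bg = 0
    while any(b > 0 for b in budgets.values()):
        if si >= len(slots):
            raise ValueError("not enough genomic slots for requested background")
        chrom, center = slots[si]
        si += 1
        bg += 1
        available = [m for m in MARKS if budgets[m] > 0]
        if len(available) == 4 and rng.random() < p_shared_cluster:
            marks = list(MARKS)
            conditions = ["DMSO", "rifampin"]
        else:
            k = int(rng.integers(1, min(3, len(available)) + 1))
            marks = list(rng.choice(available, size=k, replace=False))
            conditions = [["DMSO"], ["rifampin"], ["DMSO", "rifampin"]][int(rng.integers(0, 3))]
        for m in marks:
            budgets[m] -= 1
        add(_cluster_peaks(rng, chrom, center, marks, conditions, f"bg{bg}"))

    for key in peaks:
        peaks[key].sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    truth.planted_rirs.sort(key=lambda iv: (iv.chrom, iv.start))
    return peaks, truth


# ---------------------------------------------------------------------------
# Phased panel with LD blocks

#: Per-column allele flip probability realizing each within-block r² regime.
LD_REGIMES = {"high": 0.02, "low": 0.25}

#: Toy panel population sizes (the study's 379/286/181/246 scaled to 500).
DEFAULT_POPULATIONS = {"EUR": 174, "ASN": 131, "AMR": 83, "AFR": 112}


@dataclass(frozen=True)
class LDBlockSpec:
    """A set of panel sites copied from one founder column.

    ``members`` are (chrom, position) sites; the first member is the
    founder. Each other member's column is a copy of the founder column
    with a per-entry flip probability set by the regime.
    """

    members: tuple[tuple[str, int], ...]
    regime: str  # "high" (r² > 0.8) or "low" (r² < 0.5)


def simulate_phased_panel(
    n_samples_per_pop: Mapping[str, int] | None = None,
    n_random_variants: int = 400,
    ld_blocks: Sequence[LDBlockSpec] = (),
    chrom_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[PhasedPanel, SimulationTruth]:
    """Phased biallelic panel with planted LD blocks.

    Base columns are iid Bernoulli(MAF) with MAF ~ U(0.2, 0.5); random
    variant positions are scattered uniformly across ``chrom_sizes``.
    Realized r² between each block's founder and its members is verified
    at generation time (>0.8 for "high", <0.5 for "low") and recorded in
    the truth; an unattainable regime raises.
    """
    n_samples_per_pop = dict(n_samples_per_pop or DEFAULT_POPULATIONS)
    chrom_sizes = dict(chrom_sizes or {"chr1": 10_000_000})
    rng = np.random.default_rng(seed)

    sites: set[tuple[str, int]] = set()
    for block in ld_blocks:
        if block.regime not in LD_REGIMES:
            raise ValueError(f"unknown LD regime {block.regime!r}")
        if len(set(block.members)) != len(block.members):
            raise ValueError("duplicate sites within an LD block")
        sites.update(block.members)
    chrom_names = sorted(chrom_sizes)
    while len(sites) < len({s for b in ld_blocks for s in b.members}) + n_random_variants:
        c = chrom_names[int(rng.integers(0, len(chrom_names)))]
        sites.add((c, int(rng.integers(10_000, chrom_sizes[c] - 10_000))))

    ordered = sorted(sites)
    index = {site: i for i, site in enumerate(ordered)}
    n_variants = len(ordered)

    samples, pops = [], {}
    for pop, n in n_samples_per_pop.items():
        for i in range(n):
            s = f"{pop}{i + 1:04d}"
            samples.append(s)
            pops[s] = pop
    n_hap = 2 * len(samples)

    mafs = rng.uniform(0.2, 0.5, size=n_variants)
    matrix = (rng.random((n_hap, n_variants)) < mafs).astype(np.int8)

    for block in ld_blocks:
        eps = LD_REGIMES[block.regime]
        founder = matrix[:, index[block.members[0]]].copy()
        for site in block.members[1:]:
            flips = rng.random(n_hap) < eps
            matrix[:, index[site]] = np.where(flips, 1 - founder, founder)

    variants = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(n_variants)],
            "chrom": [c for c, _ in ordered],
            "pos": [p for _, p in ordered],
            "ref": "A",
            "alt": "G",
        }
    )
    panel = PhasedPanel(variants, matrix, samples, pops)

    truth = SimulationTruth(seed=seed)
    for block in ld_blocks:
        fi = index[block.members[0]]
        f = matrix[:, fi].astype(float)
        for site in block.members[1:]:
            j = index[site]
            r = np.corrcoef(f, matrix[:, j].astype(float))[0, 1]
            r2 = float(r * r)
            ok = r2 > 0.8 if block.regime == "high" else r2 < 0.5
            if not ok:
                raise ValueError(
                    f"LD regime {block.regime!r} unattainable at this sample size "
                    f"(realized r²={r2:.3f} at {site})"
                )
            truth.planted_ld_pairs.append((f"rs{fi + 1}", f"rs{j + 1}", block.regime, r2))
    return panel, truth


def simulate_haplotype_panel(
    hap_counts: Mapping[str, Mapping[str, int]],
    positions: Sequence[int],
    chrom: str = "chr6",
    seed: int = 0,
) -> PhasedPanel:
    """Panel realizing exact haplotype counts per population over a locus.

    ``hap_counts`` maps population → {allele string → haplotype count};
    per-population totals must be even (two haplotypes per sample).
    """
    rng = np.random.default_rng(seed)
    rows, samples, pops = [], [], {}
    for pop, counts in hap_counts.items():
        pool = [h for h, c in counts.items() for _ in range(c)]
        if len(pool) % 2:
            raise ValueError(f"population {pop!r}: haplotype count must be even")
        rng.shuffle(pool)
        for i in range(len(pool) // 2):
            s = f"{pop}H{i + 1:04d}"
            samples.append(s)
            pops[s] = pop
            rows.append([int(a) for a in pool[2 * i]])
            rows.append([int(a) for a in pool[2 * i + 1]])
    variants = pd.DataFrame(
        {
            "id": [f"hv{i + 1}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": sorted(int(p) for p in positions),
            "ref": "A",
            "alt": "G",
        }
    )
    return PhasedPanel(variants, np.asarray(rows, dtype=np.int8), samples, pops)


# ---------------------------------------------------------------------------
# GWAS catalog


def simulate_gwas_catalog(
    panel: PhasedPanel,
    pxr_peaks: Sequence[Peak],
    n_pharmaco: int = 40,
    n_other: int = 400,
    fraction_overlapping: tuple[float, float] = (0.25, 0.025),
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """GWAS catalog with planted per-class peak-overlap fractions.

    Each lead's overlap status is a Bernoulli draw at its class's
    fraction, so the expected 2×2 table matches the requested fractions
    while realized tables carry sampling variability. Leads are then drawn
    without replacement from panel variants inside / outside drug-induced
    PXR peaks accordingly; non-overlapping leads are never drawn from
    variants whose position lies inside a peak, keeping the lead-level
    truth exact under LD proxy expansion.
    """
    rng = np.random.default_rng(seed)
    pos = panel.variants["pos"].to_numpy()
    chroms = panel.variants["chrom"].to_numpy()
    inside = np.zeros(len(pos), dtype=bool)
    for p in pxr_peaks:
        inside |= (
            (chroms == p.interval.chrom)
            & (pos >= p.interval.start)
            & (pos < p.interval.end)
        )
    inside_idx = np.flatnonzero(inside)
    outside_idx = np.flatnonzero(~inside)

    populations = sorted(set(panel.sample_population.values()))
    truth = SimulationTruth(seed=seed)
    if n_other == 0 or n_pharmaco == 0:
        raise ValueError("both SNP classes need at least one lead (zero marginal)")

    pools = {"in": inside_idx, "out": outside_idx}
    ids = panel.variants["id"].to_numpy()
    frames = []
    for n, frac, pharm, tag in (
        (n_pharmaco, fraction_overlapping[0], True, "pgx"),
        (n_other, fraction_overlapping[1], False, "gwas"),
    ):
        n_in = int(rng.binomial(n, frac))
        if n_in > pools["in"].size or (n - n_in) > pools["out"].size:
            raise ValueError("infeasible overlap fractions for panel/peak geometry")
        chosen_in = rng.choice(pools["in"], size=n_in, replace=False)
        chosen_out = rng.choice(pools["out"], size=n - n_in, replace=False)
        pools["in"] = np.setdiff1d(pools["in"], chosen_in)
        pools["out"] = np.setdiff1d(pools["out"], chosen_out)
        chosen = np.concatenate([chosen_in, chosen_out]).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "snp": ids[chosen],
                    "chrom": chroms[chosen],
                    "pos": pos[chosen].astype(int),
                    "trait": [f"{tag}_trait{j + 1}" for j in range(n)],
                    "pharmacogenomic": int(pharm),
                    "population": [
                        populations[int(k)]
                        for k in rng.integers(0, len(populations), size=n)
                    ],
                }
            )
        )
        for j, idx in enumerate(chosen):
            truth.lead_overlap_status[str(ids[idx])] = bool(j < n_in)

    catalog = pd.concat(frames, ignore_index=True)
    # planted GLP truth: peaks containing any overlapping lead
    glp_peaks = set()
    hit_mask = np.array([truth.lead_overlap_status[s] for s in catalog["snp"]])
    for row in catalog[hit_mask].itertuples():
        for p in pxr_peaks:
            if p.interval.contains_position(str(row.chrom), int(row.pos)):
                glp_peaks.add(p.source_id)
                break
    truth.planted_glp_peaks = sorted(glp_peaks)
    return catalog, truth


# ---------------------------------------------------------------------------
# Assay tables


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise at coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return np.exp(rng.normal(-sigma**2 / 2, sigma, size))


def default_promoter_screen(seed: int = 0) -> dict[str, tuple[float, float]]:
    """Planted (basal fold over empty, drug/vehicle ratio) for 227 promoters.

    Mirrors the study design: 179 functional (>2-fold basal), 10 of those
    drug-induced (>2-fold gain), 48 nonfunctional. Effect sizes sit well
    clear of the thresholds.
    """
    rng = np.random.default_rng(seed)
    planted = {}
    for i in range(227):
        unit = f"PROM{i + 1:03d}"
        if i < 10:  # functional and induced
            planted[unit] = (float(rng.uniform(4, 30)), float(rng.uniform(3, 8)))
        elif i < 179:  # functional, not induced
            planted[unit] = (float(rng.uniform(4, 30)), float(rng.uniform(0.7, 1.4)))
        else:  # nonfunctional
            planted[unit] = (float(rng.uniform(0.3, 1.3)), float(rng.uniform(0.7, 1.4)))
    return planted


def default_enhancer_screen(seed: int = 0) -> dict[str, tuple[float, float]]:
    """Planted (DMSO fold, rifampin fold) over empty for 49 enhancers.

    19 functional: 7 drug-independent, 5 drug-increased, 7 drug-dependent;
    30 nonfunctional.
    """
    rng = np.random.default_rng(seed)
    planted = {}
    i = 0
    for _ in range(7):  # independent
        basal = float(rng.uniform(4, 10))
        i += 1
        planted[f"ENH{i:02d}"] = (basal, basal * float(rng.uniform(0.85, 1.2)))
    for _ in range(5):  # increased
        basal = float(rng.uniform(4, 10))
        i += 1
        planted[f"ENH{i:02d}"] = (basal, basal * float(rng.uniform(3, 6)))
    for _ in range(7):  # dependent
        i += 1
        planted[f"ENH{i:02d}"] = (float(rng.uniform(0.4, 1.2)), float(rng.uniform(4, 12)))
    for _ in range(30):  # nonfunctional
        i += 1
        planted[f"ENH{i:02d}"] = (float(rng.uniform(0.3, 1.3)), float(rng.uniform(0.3, 1.3)))
    return planted


def expected_promoter_label(basal_fold: float, ratio: float) -> str:
    if basal_fold <= 2:
        return "nonfunctional"
    return "induced" if ratio > 2 else "functional"


def expected_enhancer_label(dmso_fold: float, rif_fold: float) -> str:
    active_d, active_r = dmso_fold >= 2, rif_fold >= 2
    if not active_d and not active_r:
        return "nonfunctional"
    if active_r and not active_d:
        return "dependent"
    if active_d and rif_fold / dmso_fold >= 2:
        return "increased"
    return "independent"


def simulate_promoter_assay(
    planted: Mapping[str, tuple[float, float]],
    n_replicates: int = 3,
    cv: float = 0.1,
    empty_vector_level: float = 1000.0,
    empty_id: str = "EMPTY",
    seed: int = 0,
) -> tuple[AssayTable, SimulationTruth]:
    """Raw-luminescence promoter table with planted basal/induction folds."""
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    rows = []
    units = {empty_id: (1.0, 1.0), **planted}
    for unit, (basal, ratio) in units.items():
        for condition, fold in (("DMSO", basal), ("rifampin", basal * ratio)):
            noise = _lognormal_noise(rng, cv, n_replicates)
            for r in range(n_replicates):
                rows.append(
                    {
                        "unit_id": unit,
                        "condition": condition,
                        "replicate": r + 1,
                        "signal": empty_vector_level * fold * noise[r],
                    }
                )
        if unit != empty_id:
            truth.planted_assay_labels[unit] = expected_promoter_label(basal, ratio)
    return AssayTable(pd.DataFrame(rows), "promoter_assay"), truth


def simulate_enhancer_assay(
    planted: Mapping[str, tuple[float, float]],
    n_replicates: int = 3,
    cv: float = 0.1,
    empty_vector_level: float = 4.0,
    renilla_level: float = 1000.0,
    empty_id: str = "EMPTY",
    seed: int = 0,
) -> tuple[AssayTable, SimulationTruth]:
    """Dual-luciferase enhancer table (firefly + renilla) with planted folds."""
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    rows = []
    units = {empty_id: (1.0, 1.0), **planted}
    for unit, (dmso_fold, rif_fold) in units.items():
        for condition, fold in (("DMSO", dmso_fold), ("rifampin", rif_fold)):
            noise = _lognormal_noise(rng, cv, n_replicates)
            renilla = renilla_level * _lognormal_noise(rng, cv, n_replicates)
            for r in range(n_replicates):
                activity = empty_vector_level * fold * noise[r]
                rows.append(
                    {
                        "unit_id": unit,
                        "condition": condition,
                        "replicate": r + 1,
                        "firefly": activity * renilla[r],
                        "renilla": renilla[r],
                    }
                )
        if unit != empty_id:
            truth.planted_assay_labels[unit] = expected_enhancer_label(dmso_fold, rif_fold)
    return AssayTable(pd.DataFrame(rows), "enhancer_assay"), truth


def default_qpcr_panel() -> dict[str, float]:
    """Planted fold inductions echoing the hepatocyte induction profile:
    a dominant CYP3A4 response (2^10 = 1024-fold) with weaker CYP family
    inductions and one repressed gene."""
    return {
        "CYP3A4": 1024.0,
        "CYP3A7": 16.0,
        "CYP3A43": 8.0,
        "CYP2B6": 4.0,
        "CYP2C8": 2.5,
        "CYP26B1": 0.5,
        "NR1I2": 1.0,
    }


def simulate_qpcr(
    planted_folds: Mapping[str, float] | None = None,
    n_replicates: int = 3,
    sd_ct: float = 0.1,
    housekeeping: Sequence[str] = ("B2M", "HPRT1", "RPL13A", "GAPDH", "ACTB"),
    seed: int = 0,
) -> tuple[AssayTable, SimulationTruth]:
    """Ct table consistent with planted folds under the ΔΔCt model.

    Housekeeping genes keep a constant expected Ct in both conditions;
    each target's treated Ct is its control Ct minus log2(planted fold).
    Noise is additive normal on the Ct scale with standard deviation
    ``sd_ct`` cycles.
    """
    planted_folds = dict(planted_folds if planted_folds is not None else default_qpcr_panel())
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed, planted_qpcr_folds=dict(planted_folds))
    rows = []

    def emit(gene: str, base_ct: float, treated_shift: float):
        for condition, mu in (("DMSO", base_ct), ("rifampin", base_ct + treated_shift)):
            for r in range(n_replicates):
                ct = mu + (rng.normal(0, sd_ct) if sd_ct > 0 else 0.0)
                rows.append(
                    {"unit_id": gene, "condition": condition, "replicate": r + 1, "ct": ct}
                )

    for h in housekeeping:
        emit(h, float(rng.uniform(16, 20)), 0.0)
    for gene, fold in planted_folds.items():
        emit(gene, float(rng.uniform(22, 30)), -float(np.log2(fold)))
    return AssayTable(pd.DataFrame(rows), "qpcr"), truth


def simulate_assay_data(schema: str, **kwargs):
    """Dispatch to the schema-specific assay generator."""
    if schema == "promoter_assay":
        return simulate_promoter_assay(kwargs.pop("planted", default_promoter_screen()), **kwargs)
    if schema == "enhancer_assay":
        return simulate_enhancer_assay(kwargs.pop("planted", default_enhancer_screen()), **kwargs)
    if schema == "qpcr":
        return simulate_qpcr(kwargs.pop("planted", None), **kwargs)
    raise ValueError(f"unknown schema {schema!r}")


def default_rir46_haplotype_activities(
    n_replicates: int = 4, cv: float = 0.25, seed: int = 0
) -> dict[str, list[float]]:
    """Per-haplotype drug-response replicates for the GSTA-locus enhancer.

    Planted mean responses (rifampin/DMSO fold): reference 2.16 and a
    hypersensitive haplotype 3 at 4.01 (a 1.85-fold gain), with two
    near-reference haplotypes. Replicate scatter is wide enough that the
    gain does not reach significance after FDR adjustment, matching the
    borderline character of such single-locus observations.
    """
    rng = np.random.default_rng(seed)
    means = {"hap1": 2.16, "hap2": 2.30, "hap3": 4.01, "hap4": 2.05}
    out = {}
    for hap, mu in means.items():
        noise = _lognormal_noise(rng, cv, n_replicates)
        # residuals are mean-centered so realized group means equal the
        # planted means exactly; scatter stays at the requested cv
        out[hap] = list(mu * noise / noise.mean())
    return out


def default_rir46_haplotype_panel(seed: int = 0) -> PhasedPanel:
    """AFR-weighted panel where the hypersensitive haplotype segregates at
    a planted 6.7% frequency (15 of 224 AFR haplotypes)."""
    afr = {"00000": 150, "10000": 40, "01100": 15, "11111": 19}
    eur = {"00000": 300, "10000": 40, "11111": 8}
    positions = [52_609_950 + 300 * i for i in range(5)]
    return simulate_haplotype_panel({"AFR": afr, "EUR": eur}, positions, chrom="chr6", seed=seed)
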