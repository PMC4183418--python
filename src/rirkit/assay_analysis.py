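"""Reporter and qPCR assay quantification, classification and haplotype tests.

qPCR fold induction uses the ΔΔCt model with ideal amplification
efficiency: the per-condition reference Ct is the mean of the housekeeping
genes' mean Cts, ΔCt = gene Ct − reference Ct, ΔΔCt = ΔCt(treated) −
ΔCt(control), fold = 2^(−ΔΔCt).

Reporter activities are normalized per replicate (firefly/renilla for the
dual-luciferase enhancer schema; raw luminescence for the promoter schema)
and expressed as fold over the empty vector within the same condition.
Promoters are "functional" at >2-fold over empty in the vehicle condition
and "induced" at an additional >2-fold gain under drug. Enhancers fall in
four exclusive classes: nonfunctional, drug-independent, drug-increased
(active in both conditions with a significant >=2-fold gain) and
drug-dependent (active only under drug).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import AssayTable, GenomicInterval, PhasedPanel

HOUSEKEEPING_GENES = ("B2M", "HPRT1", "RPL13A", "GAPDH", "ACTB")
ENHANCER_CLASSES = ("nonfunctional", "independent", "increased", "dependent")


@dataclass(frozen=True)
class QpcrResult:
    gene: str
    delta_ct_control: float
    delta_ct_treated: float
    delta_delta_ct: float

    @property
    def fold(self) -> float:
        return float(2.0 ** (-self.delta_delta_ct))


@dataclass(frozen=True)
class ReporterActivity:
    unit_id: str
    condition: str
    activities: tuple[float, ...]
    fold_vs_empty: float

    @property
    def mean_activity(self) -> float:
        return float(np.mean(self.activities))


@dataclass(frozen=True)
class PromoterCall:
    unit_id: str
    functional: bool
    induced: bool
    dmso_fold_vs_empty: float
    rif_over_dmso: float


@dataclass(frozen=True)
class EnhancerCall:
    unit_id: str
    klass: str
    dmso_fold_vs_empty: float
    rif_fold_vs_empty: float
    induction_ratio: float
    induction_p: float


@dataclass(frozen=True)
class HaplotypeRecord:
    allele_string: str
    count: int
    frequency: float
    population: str
    common: bool


@dataclass(frozen=True)
class HaplotypeComparison:
    anova_f: float
    anova_p: float
    haplotypes: tuple[str, ...]  # non-reference, in input order
    p_values: tuple[float, ...]
    q_values: tuple[float, ...]
    response_ratios: tuple[float, ...]


# ---------------------------------------------------------------------------
# qPCR


def ddct_fold_induction(
    table: AssayTable,
    gene: str,
    housekeeping: tuple[str, ...] = HOUSEKEEPING_GENES,
    control: str = "DMSO",
    treated: str = "rifampin",
) -> QpcrResult:
    """ΔΔCt fold induction of ``gene`` between the two conditions."""
    if table.schema != "qpcr":
        raise ValueError("ddct_fold_induction requires a qpcr-schema table")
    df = table.data

    def mean_ct(g: str, condition: str) -> float:
        sub = df[(df["unit_id"] == g) & (df["condition"] == condition)]
        if sub.empty:
            raise ValueError(f"gene {g!r} has no replicates in condition {condition!r}")
        return float(sub["ct"].mean())

    delta = {}
    for condition in (control, treated):
        reference = float(np.mean([mean_ct(h, condition) for h in housekeeping]))
        delta[condition] = mean_ct(gene, condition) - reference
    ddct = delta[treated] - delta[control]
    return QpcrResult(gene, delta[control], delta[treated], ddct)


# ---------------------------------------------------------------------------
# Reporter normalization and classification


def normalize_reporter_activity(
    table: AssayTable, empty_vector_id: str
) -> dict[tuple[str, str], ReporterActivity]:
    """Per-replicate normalized activities and fold over empty vector.

    Returns a mapping (unit_id, condition) → ReporterActivity. The
    enhancer schema normalizes firefly by renilla per replicate; the
    promoter schema uses raw luminescence.
    """
    if table.schema == "enhancer_assay":
        if np.any(table.data["renilla"].to_numpy(dtype=float) == 0):
            raise ValueError("renilla signal of zero in an enhancer replicate")
        values = table.data["firefly"].to_numpy(dtype=float) / table.data[
            "renilla"
        ].to_numpy(dtype=float)
    elif table.schema == "promoter_assay":
        values = table.data["signal"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unsupported schema {table.schema!r}")

    df = table.data.assign(_activity=values)
    grouped = {
        (str(u), str(c)): tuple(sub["_activity"].astype(float))
        for (u, c), sub in df.groupby(["unit_id", "condition"], sort=False)
    }
    conditions = sorted({c for _, c in grouped})
    empty_means = {}
    for c in conditions:
        key = (empty_vector_id, c)
        if key not in grouped:
            raise ValueError(f"empty vector {empty_vector_id!r} absent in condition {c!r}")
        empty_means[c] = float(np.mean(grouped[key]))

    return {
        (u, c): ReporterActivity(
            unit_id=u,
            condition=c,
            activities=acts,
            fold_vs_empty=float(np.mean(acts)) / empty_means[c],
        )
        for (u, c), acts in grouped.items()
    }


def classify_promoter(
    dmso: ReporterActivity,
    rifampin: ReporterActivity,
    functional_threshold: float = 2.0,
    induction_threshold: float = 2.0,
) -> PromoterCall:
    """Functional at >threshold over empty in DMSO; induced at an
    additional >threshold rifampin/DMSO gain (strict inequalities)."""
    functional = dmso.fold_vs_empty > functional_threshold
    ratio = rifampin.mean_activity / dmso.mean_activity
    induced = bool(functional and ratio > induction_threshold)
    return PromoterCall(dmso.unit_id, bool(functional), induced, dmso.fold_vs_empty, ratio)


def classify_enhancer(
    dmso: ReporterActivity,
    rifampin: ReporterActivity,
    active_threshold: float = 2.0,
    induction_ratio: float = 2.0,
    alpha: float = 0.05,
) -> EnhancerCall:
    """Four-class enhancer call: nonfunctional / independent / increased /
    dependent.

    Activity is >= ``active_threshold`` fold over empty within a
    condition. Among enhancers active under DMSO, "increased" requires a
    rifampin/DMSO ratio >= ``induction_ratio`` together with a two-sided
    unequal-variance replicate test at ``alpha``.
    """
    if len(dmso.activities) < 2 or len(rifampin.activities) < 2:
        raise ValueError(f"unit {dmso.unit_id!r}: need >=2 replicates per condition")
    active_dmso = dmso.fold_vs_empty >= active_threshold
    active_rif = rifampin.fold_vs_empty >= active_threshold
    ratio = rifampin.mean_activity / dmso.mean_activity
    p = float(
        stats.ttest_ind(rifampin.activities, dmso.activities, equal_var=False).pvalue
    )
    if not active_dmso and not active_rif:
        klass = "nonfunctional"
    elif active_rif and not active_dmso:
        klass = "dependent"
    elif active_dmso and ratio >= induction_ratio and p < alpha:
        klass = "increased"
    else:
        klass = "independent"
    return EnhancerCall(dmso.unit_id, klass, dmso.fold_vs_empty, rifampin.fold_vs_empty, ratio, p)


def classify_promoter_table(
    table: AssayTable, empty_vector_id: str, **kwargs
) -> list[PromoterCall]:
    acts = normalize_reporter_activity(table, empty_vector_id)
    calls = []
    for unit in table.units():
        if unit == empty_vector_id:
            continue
        calls.append(classify_promoter(acts[(unit, "DMSO")], acts[(unit, "rifampin")], **kwargs))
    return calls


def classify_enhancer_table(
    table: AssayTable, empty_vector_id: str, **kwargs
) -> list[EnhancerCall]:
    acts = normalize_reporter_activity(table, empty_vector_id)
    calls = []
    for unit in table.units():
        if unit == empty_vector_id:
            continue
        calls.append(classify_enhancer(acts[(unit, "DMSO")], acts[(unit, "rifampin")], **kwargs))
    return calls


# ---------------------------------------------------------------------------
# Haplotypes


def enumerate_haplotypes(
    panel: PhasedPanel,
    region: GenomicInterval,
    population: str,
    min_frequency: float = 0.05,
) -> list[HaplotypeRecord]:
    """Distinct haplotype allele strings over a region in one population.

    Records are sorted by descending frequency (ties by allele string);
    ``common`` flags frequency >= ``min_frequency``. Frequencies over all
    returned records sum to 1.
    """
    mask = (
        (panel.variants["chrom"] == region.chrom)
        & (panel.variants["pos"] >= region.start)
        & (panel.variants["pos"] < region.end)
    ).to_numpy()
    cols = np.flatnonzero(mask)
    if cols.size == 0:
        raise ValueError(f"no panel variants in region {region.chrom}:{region.start}-{region.end}")
    rows = panel.population_rows(population)
    if rows.size == 0:
        raise ValueError(f"no samples in population {population!r}")
    strings = ["".join(map(str, hap)) for hap in panel.haplotypes[np.ix_(rows, cols)]]
    counts = Counter(strings)
    total = len(strings)
    records = [
        HaplotypeRecord(s, c, c / total, population, c / total >= min_frequency)
        for s, c in counts.items()
    ]
    records.sort(key=lambda r: (-r.frequency, r.allele_string))
    return records


def compare_haplotype_activity(
    activities: dict[str, list[float]], reference: str
) -> HaplotypeComparison:
    """One-way ANOVA across haplotypes plus per-haplotype post tests.

    Each non-reference haplotype is compared to the reference with a
    two-sided unequal-variance test; p-values are BH-adjusted across the
    non-reference haplotypes. Response ratio = mean(haplotype) /
    mean(reference).
    """
    if reference not in activities:
        raise ValueError(f"reference haplotype {reference!r} missing")
    if len(activities) < 2:
        raise ValueError("need >=2 haplotypes")
    for hap, vals in activities.items():
        if len(vals) < 2:
            raise ValueError(f"haplotype {hap!r}: need >=2 replicates")
    groups = [np.asarray(v, dtype=float) for v in activities.values()]
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, anova_p = 0.0, 1.0
    else:
        res = stats.f_oneway(*groups)
        f_stat, anova_p = float(res.statistic), float(res.pvalue)

    ref_vals = np.asarray(activities[reference], dtype=float)
    names, pvals, ratios = [], [], []
    for hap, vals in activities.items():
        if hap == reference:
            continue
        arr = np.asarray(vals, dtype=float)
        if np.ptp(arr) == 0 and np.ptp(ref_vals) == 0:
            p = 1.0 if arr.mean() == ref_vals.mean() else 0.0
        else:
            p = float(stats.ttest_ind(arr, ref_vals, equal_var=False).pvalue)
        names.append(hap)
        pvals.append(p)
        ratios.append(float(arr.mean() / ref_vals.mean()))
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else np.array([])
    return HaplotypeComparison(
        anova_f=f_stat,
        anova_p=anova_p,
        haplotypes=tuple(names),
        p_values=tuple(pvals),
        q_values=tuple(float(q) for q in qvals),
        response_ratios=tuple(ratios),
    )
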