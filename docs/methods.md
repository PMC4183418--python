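# Methods

## Coordinates and overlap semantics

All internal coordinates are 0-based half-open (BED convention); printed
1-based inclusive coordinates are converted on ingest. Overlap means ≥1 bp
of shared span: `[a, b)` and `[b, c)` are adjacent, not overlapping.
Chromosome names are opaque strings; mixing `chr1`/`1` conventions across
inputs is the caller's error. Sorting is always by
(chrom lexicographic, start, end, mark), which makes every output
deterministic.

## Region integration

The merger treats the peaks and islands of all four marks (PXR, p300,
H3K4me1, H3K27ac) of one condition as nodes of a graph with an edge for
every pairwise overlap; merged regions are the connected components. Two
transcription-factor peaks that do not touch are still joined when both
overlap the same histone island — bridging requires a shared overlapping
island, never mere proximity, because a distance rule would need an
arbitrary cutoff the data do not motivate. Since overlap of intervals on a
line is an interval graph, components are computed with a per-chromosome
sorted sweep (O(n log n)); the O(n²) transitive-closure oracle lives in the
test suite and the acceptance script.

Four-mark selection keeps regions whose mark inventory contains all four
marks (the PXR peak need only co-reside in the region, not overlap each
mark individually). Drug-exclusive calling removes any treated four-mark
region overlapping a *four-mark* control region — exclusivity is judged
against control regions, not against individual control peaks. IDs are
assigned in genome order. No minimum region length is imposed.

Reporter fragments are anchored on the PXR/p300 members only (histone
islands are ~5 kb, far longer than a clonable fragment), extended by a
configurable flank (default 500 bp) and clipped at chromosome bounds.

## Annotation and enrichment

Feature classes are mutually exclusive with priority
promoter > exon > intron > intergenic. The promoter window is strand-aware:
`[TSS − 2500, TSS + 500)` for + genes, mirrored for − genes. TSS-distance
profiles use the peak midpoint, signed in gene orientation (negative =
upstream), nearest TSS by absolute distance with deterministic
tie-breaking (position, then name).

Regulatory domains follow the basal-plus-extension model: basal window
5 kb upstream / 1 kb downstream of the TSS, extended on each side to the
neighboring gene's basal window or 1 Mb, whichever is nearer, clipped to
chromosome bounds. Neighboring domains deliberately overlap across the
shared intergenic gap — a region midpoint in the gap associates with both
flanking genes. A term's genome fraction `p` is the merged length of its
genes' domains divided by genome length; `k` counts regions whose midpoint
falls in that merged span (midpoint containment avoids double counting and
boundary ambiguity). The binomial upper tail is computed with
`scipy.stats.binom.sf`; FDR is Benjamini–Hochberg across all tested terms
before filtering. Reported terms satisfy fold > 6 and q < 5×10⁻³; both
thresholds are parameters.

Note on the toy study: with 200 genes on 20 Mb, basal-plus-extension
domains tile the genome about twice over, so even a term containing
exactly the planted-region host genes covers ~25% of the genome and its
fold enrichment is capped near 4 — below the publication filter. The
pipeline therefore writes the full ranked table and applies the filter
separately; the planted signal term ranks first with q ≈ 10⁻¹¹. On a
genome-scale input with sparse term membership the filter behaves as
intended.

## GWAS-LD linkage

r² between two biallelic sites is the squared correlation of allelic
state over the population's phased haplotypes,
D²/(p_A(1−p_A)p_B(1−p_B)) with D = p_AB − p_A·p_B; monomorphic sites make
the statistic undefined and raise. Proxy expansion searches ±1 Mb around
the lead (LD at r² > 0.8 beyond 1 Mb is negligible and the bound keeps
the scan local), only within the lead's study population; the lead is
always its own proxy. Multi-population studies would use the union of
per-population proxies.

GLPs are drug-condition PXR peaks containing ≥1 proxy under half-open
position containment. Enrichment counts at the lead/LD-block level (a
lead overlaps if any of its proxies does), forming a 2×2 table of SNP
class × overlap. The test is the two-tailed chi-squared with Yates
correction, with the correction term clamped at zero when |O−E| < 0.5 so
a table already at expectation gives χ² = 0, p = 1; an uncorrected
variant is available by flag. Recomputing this test on the published
lead-level table (27/397 pharmacogenomic vs 162/5,117 other) gives
χ² ≈ 13.63, p ≈ 2.2×10⁻⁴ — significant, though about twice the bound
printed alongside the original table; the acceptance script reports the
recomputed value.

## Assay quantification

ΔΔCt assumes ideal amplification efficiency. The per-condition reference
Ct is the arithmetic mean of the housekeeping genes' mean Cts
(equivalently the geometric mean of their expression); defaults are the
five-gene panel B2M, HPRT1, RPL13A, GAPDH, ACTB. ΔCt = gene Ct − reference
Ct; ΔΔCt = ΔCt(drug) − ΔCt(vehicle); fold = 2^(−ΔΔCt). A −10-cycle
normalized shift is exactly 1024-fold.

Reporter activities: the enhancer (dual-luciferase) schema normalizes
firefly by renilla per replicate; the promoter schema uses raw
luminescence. Fold over empty vector compares arithmetic means of
normalized activities within the same condition (medians available by
flag). Promoters use strict thresholds — functional ⇔ vehicle fold > 2,
induced ⇔ functional and drug/vehicle mean ratio > 2 — judged on mean
folds alone (no replicate test), matching the screen's decision rule.
Enhancers use ≥2-fold activity per condition; classes are exhaustive and
mutually exclusive: nonfunctional (active in neither), dependent (active
under drug only), increased (active under vehicle, ratio ≥ 2 AND
two-sided Welch replicate test p < 0.05), else independent. The
"significantly increased" criterion is not fully specified by the
screen's description; ratio-plus-Welch at α = 0.05 is this package's
choice and both pieces are flags.

Haplotypes over a region are the distinct allele strings of the
population's phased haplotype rows, sorted by descending frequency
(ties by string); `common` flags frequency ≥ 5%. Per-haplotype responses
are compared with one-way ANOVA plus per-haplotype two-sided Welch tests
against a configured reference haplotype, BH-adjusted across the
non-reference haplotypes (Dunnett's test would be the classical
alternative; BH-adjusted Welch tests were chosen for transparency). The
reference haplotype identity comes from input configuration.

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code; their defaults are the study
conditions the pipeline is validated under.

* **Genome**: 2 chromosomes × 10 Mb, 200 non-overlapping genes with
  random strands and 2–10 exons.
* **Peak landscape**: 20 planted sites carry overlapping PXR (300–500 bp,
  the sonication fragment scale) and p300 peaks plus broader
  H3K4me1/H3K27ac islands (~4–5.5 kb, the island length scale) in the
  drug condition only. 200 background clusters per mark carry 1–3 marks
  in either or both conditions, or all four marks in both conditions;
  clusters occupy disjoint slots ≥10 kb apart, so no background
  configuration can produce a drug-exclusive four-mark region and
  planted recovery is exact by construction. This is deliberate: the
  toy study tests the calling logic, not robustness to ambiguous peak
  geometry.
* **Phased panel**: 500 samples in four populations (174/131/83/112 —
  EUR/ASN/AMR/AFR, the study panel's proportions scaled down), variants
  iid Bernoulli with MAF ~ U(0.2, 0.5), LD blocks made by copying a
  founder column with per-entry flip probability 0.02 ("high" regime,
  r² > 0.8) or 0.25 ("low", r² < 0.5). Realized r² is verified at
  generation time and recorded in the truth; founder-copy LD is simpler
  and more controllable than coalescent simulation but has no recombination
  structure or allele-frequency spectrum realism.
* **GWAS catalog**: 40 pharmacogenomic and 400 other leads; each lead's
  peak-overlap status is Bernoulli at its class fraction (defaults 0.25
  vs 0.025), with overlapping leads drawn from inside-peak variants and
  non-overlapping leads never drawn from inside-peak variants, keeping
  lead-level truth exact under proxy expansion.
* **Assays**: multiplicative mean-one log-normal noise at cv = 10% for
  luminescence (signals positive, noise multiplicative), additive normal
  noise (0.1 cycles) on the Ct scale. Planted effect sizes sit ≥5σ clear
  of the decision thresholds at n = 3 replicates, so the screens'
  composition (227 promoters: 179 functional, 10 induced; 49 enhancers:
  7/5/7/30) is recovered exactly — the screens validate the decision
  rules, not borderline discrimination. The haplotype-response generator
  mean-centers each group's residuals so realized group means equal the
  planted means (reference 2.16, hypersensitive haplotype 4.01; ratio
  1.856) while replicate scatter (cv 25%, n = 4) keeps the post-test
  non-significant after FDR, mirroring the borderline character of
  single-locus reporter comparisons. The planted haplotype panel gives
  the hypersensitive haplotype 15 of 224 AFR haplotypes (6.7%).

What passing tests on these data do **not** show: robustness to partial
mark overlap at region boundaries, LD decay with distance, population
stratification, plate/batch effects, or amplification-efficiency
deviations from the ideal ΔΔCt model — none of which the generators
produce.

## Numerical choices

* Binomial tails via `scipy.stats.binom.sf`; verified against exact
  high-precision summation to 1e−9 relative tolerance for n ≤ 1000.
* BH via `statsmodels.stats.multitest.multipletests`; verified against a
  hand-rolled step-up oracle.
* Welch tests / ANOVA via scipy; ANOVA verified against the explicit
  sums-of-squares formula. Constant-input degenerate cases return
  F = 0, p = 1 instead of NaN.
* The Yates statistic is computed directly from the clamped formula; the
  scipy contingency implementation serves as an independent oracle in
  tests, never as the implementation.
* r² is clipped into [0, 1] against floating-point overshoot.
* Null calibration of the enrichment test uses equal overlap fractions
  (0.25) for 1,600 + 1,600 leads per catalog, sizes at which the
  continuity correction's conservatism is mild; the observed type-I
  error at α = 0.05 is ≈0.04 over 1,000 catalogs.

## Problem sizes

The default toy preset (2 × 10 Mb genome, 200 genes, 20 planted regions,
200 background clusters per mark, ~650-variant panel of 500 samples, 227
promoter / 49 enhancer units, 1,000-catalog calibration) was chosen so a
full pipeline run completes in seconds and the entire validation suite in
well under a minute on one CPU, while every stage still has non-trivial
signal and background to operate on.

## Known limitations

* Peak calling, read alignment and differential expression are out of
  scope: the pipeline consumes peak/island interval files as given and
  does not post-filter them (e.g. no blacklist removal).
* Enrichment depends entirely on the supplied term catalog; no ontology
  propagation is performed, and published term-level p-values from
  proprietary 2011-era catalogs cannot be regenerated from stated inputs.
* r² is computed from phased haplotypes only; no EM estimation from
  unphased genotypes, no imputation.
* The ΔΔCt model assumes doubling per cycle; no efficiency correction.
* Genome-scale headline counts from the original sequencing experiment
  require the deposited raw data and are not reproducible at desk scale;
  the validation strategy substitutes planted-truth recovery and oracle
  equivalence, as reported by `scripts/acceptance.py`.
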