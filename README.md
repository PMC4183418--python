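# rirkit

Discovery and functional characterization of **drug-inducible regulatory
elements** from conditional multi-mark ChIP-seq, GWAS linkage
disequilibrium, and reporter-assay data.

Inter-individual variation in drug response is driven in large part by
regulatory elements controlling drug-metabolizing enzymes (the CYP3A4
pathway alone handles more than half of prescribed drugs). When primary
hepatocytes are treated with rifampin, the nuclear receptor PXR is
recruited genome-wide together with enhancer-associated marks (p300,
H3K4me1, H3K27ac). `rirkit` implements the downstream computational
analysis that turns per-mark peak calls from such an experiment into a
catalog of candidate drug-dependent elements, and quantifies their
functional validation:

1. **Region integration** — peaks/islands of all four marks from one
   condition are merged transitively: features belong to the same region
   iff they are connected through a chain of ≥1 bp overlaps (half-open
   semantics; adjacency is not overlap). Regions carrying all four marks
   under drug, and overlapping no four-mark region of the vehicle control,
   are called **Rifampin-Induced Regions (RIRs)**.
2. **Annotation & enrichment** — regions are assigned to feature classes
   (promoter > exon > intron > intergenic, promoter window −2500/+500 bp
   around the TSS), profiled by distance to the nearest TSS, and tested
   for annotation-term enrichment with the binomial regulatory-domain
   model: each gene owns a basal window (5 kb up / 1 kb down) extended to
   its neighbors' basal windows (≤1 Mb); for a term covering genome
   fraction *p*, hit by *k* of *n* region midpoints,
   *P* = P(X ≥ k), X ~ Binomial(n, p), fold = (k/n)/p, with
   Benjamini–Hochberg FDR across terms (reported at fold > 6,
   q < 5×10⁻³).
3. **GWAS-LD linkage** — pharmacogenomic GWAS lead SNPs are expanded to
   proxies with haplotype r² > 0.8 (r² = D²/(p_A(1−p_A)p_B(1−p_B)))
   within the study population of a phased panel; drug-induced PXR peaks
   containing a proxy become **GWAS-linked peaks (GLPs)**, and
   pharmacogenomic-vs-other enrichment is tested with a two-tailed
   chi-squared test with (clamped) Yates continuity correction.
4. **Assay quantification** — qPCR fold induction by the ΔΔCt method
   (fold = 2^(−ΔΔCt), housekeeping-normalized); dual-luciferase
   normalization (firefly/renilla per replicate, fold over empty vector);
   promoter calls (functional >2-fold basal, induced >2-fold drug gain)
   and four-class enhancer calls (nonfunctional / rifampin-independent /
   rifampin-increased / rifampin-dependent); haplotype enumeration from
   phased panels and per-haplotype response comparison (one-way ANOVA
   with BH-adjusted Welch post tests).
5. **Synthetic data** — every input can be generated at desk scale with
   planted ground truth (four-mark drug-exclusive regions, LD blocks of
   controlled r², catalogs with controlled overlap fractions, assay
   tables with planted effect sizes), so each stage is testable without
   any sequencing data.

## Worked example

Simulate the toy study and run the full pipeline:

```bash
rirkit simulate --preset toy --seed 17 --outdir sim/
rirkit run-all --indir sim/ --outdir out/
```

which prints the stage counts

```json
{"common_haplotypes_afr": 4,
 "enhancer_classes": {"dependent": 7, "increased": 5, "independent": 7, "nonfunctional": 30},
 "four_mark_dmso": 60, "four_mark_rifampin": 80,
 "glps": 9, "promoters_functional": 179, "promoters_induced": 10,
 "regions_merged_dmso": 247, "regions_merged_rifampin": 281, "rirs": 20}
```

All 20 planted drug-exclusive regions are recovered as RIRs (80 four-mark
regions under rifampin minus 60 shared with DMSO), all 9 peaks holding a
planted GWAS-LD variant are called GLPs, and the reporter screens
reproduce their planted composition: 179/227 functional promoters of
which 10 (4.4%) are rifampin-induced, and 19/49 functional enhancers
split 7 independent / 5 increased / 7 dependent. Output files
(`rirs.bed`, `glps.tsv`, `enrichment.tsv`, `promoter_calls.tsv`,
`enhancer_calls.tsv`, `qpcr_folds.tsv`, `haplotypes.tsv`,
`report.json`) land in `out/`.

The same machinery is usable as a library, e.g. ΔΔCt quantification:

```python
>>> from rirkit.synthetic_data import simulate_qpcr
>>> from rirkit.assay_analysis import ddct_fold_induction
>>> table, truth = simulate_qpcr(seed=17)   # planted CYP3A4 fold = 1024
>>> res = ddct_fold_induction(table, "CYP3A4")
>>> round(res.delta_delta_ct, 3), round(res.fold, 1)
(-10.058, 1065.8)
```

A normalized shift of ten PCR cycles corresponds to a >1,000-fold
induction (2¹⁰ = 1024); the small deviation reflects the generator's
0.1-cycle replicate noise.

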