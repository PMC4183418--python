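"""Feature assignment, TSS profiling, regulatory domains, binomial enrichment."""

import math

import numpy as np
import pytest

from rirkit.genomic_io import GeneModel, GenomicInterval, Peak
from rirkit.genome_annotation import (
    assign_genomic_feature,
    binomial_term_enrichment,
    build_regulatory_domains,
    promoter_window,
    tss_distance_profile,
)


def gene(name, chrom, start, end, strand, exons=()):
    return GeneModel(
        name,
        GenomicInterval(chrom, start, end, strand),
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


PLUS = gene("P", "chr1", 10_000, 30_000, "+", [(10_000, 11_000), (20_000, 21_000)])
MINUS = gene("M", "chr1", 50_000, 70_000, "-", [(50_000, 51_000), (69_000, 70_000)])


class TestFeatureAssignment:
    def test_upstream_window_is_promoter(self):
        iv = GenomicInterval("chr1", 9_000, 9_100)  # TSS-1000..-900
        fa = assign_genomic_feature(iv, [PLUS])
        assert (fa.feature, fa.gene) == ("promoter", "P")

    def test_no_genes_on_chromosome_is_intergenic(self):
        fa = assign_genomic_feature(GenomicInterval("chr9", 0, 100), [PLUS, MINUS])
        assert (fa.feature, fa.gene) == ("intergenic", None)

    def test_gene_body_outside_exons_is_intron(self):
        iv = GenomicInterval("chr1", 15_000, 15_100)
        assert assign_genomic_feature(iv, [PLUS]).feature == "intron"

    def test_priority_promoter_over_exon(self):
        # first exon starts at the TSS: overlap with both promoter window and exon
        iv = GenomicInterval("chr1", 10_000, 10_100)
        assert assign_genomic_feature(iv, [PLUS]).feature == "promoter"

    def test_exhaustive_against_gene_structure_oracle(self):
        genes = [PLUS, MINUS]
        rng = np.random.default_rng(3)
        for _ in range(300):
            start = int(rng.integers(0, 80_000))
            iv = GenomicInterval("chr1", start, start + int(rng.integers(1, 300)))
            fa = assign_genomic_feature(iv, genes)
            # oracle: recompute by explicit class membership
            classes = set()
            for g in genes:
                if iv.overlaps(promoter_window(g)):
                    classes.add("promoter")
                if any(iv.overlaps(e) for e in g.exons):
                    classes.add("exon")
                if iv.overlaps(g.interval):
                    classes.add("intron")
            for expected in ("promoter", "exon", "intron", "intergenic"):
                if expected in classes or expected == "intergenic":
                    break
            assert fa.feature == expected

    def test_minus_strand_window_mirrors_plus(self):
        # reflect the + gene around x=40000: TSS 10000 -> 70000 on '-'
        up, down = 2500, 500
        w_plus = promoter_window(gene("A", "chr1", 10_000, 30_000, "+"), up, down)
        w_minus = promoter_window(gene("B", "chr1", 10_000, 70_000, "-"), up, down)
        # + window: [7500, 10500); - window: [69500, 72500) = reflection of + around TSS
        assert (w_plus.start, w_plus.end) == (7_500, 10_500)
        assert (w_minus.start, w_minus.end) == (69_500, 72_500)
        assert w_plus.end - w_plus.start == w_minus.end - w_minus.start


class TestTssDistanceProfile:
    def peak(self, chrom, mid):
        return Peak(GenomicInterval(chrom, mid - 50, mid + 50), "PXR", "rifampin")

    def test_midpoint_at_tss_is_zero(self):
        counts, edges = tss_distance_profile([self.peak("chr1", 10_000)], [PLUS], 5000, 1000)
        center_bin = np.flatnonzero(edges == 0)[0]
        assert counts[center_bin] == 1

    def test_orientation_convention(self):
        # + strand TSS at 10000; midpoint 9000 -> signed distance -1000
        counts, edges = tss_distance_profile([self.peak("chr1", 9_000)], [PLUS], 5000, 1000)
        bin_idx = np.flatnonzero(counts)[0]
        assert edges[bin_idx] == -1000
        # - strand TSS at 70000; midpoint 69000 is downstream -> +1000
        counts, edges = tss_distance_profile([self.peak("chr1", 69_000)], [MINUS], 5000, 1000)
        assert edges[np.flatnonzero(counts)[0]] == 1000

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        genes = [
            gene(f"G{i}", "chr1", s, s + 5000, "+" if i % 2 else "-")
            for i, s in enumerate(sorted(rng.choice(10**6, 30, replace=False)))
        ]
        peaks = [self.peak("chr1", int(m)) for m in rng.integers(100, 10**6, 200)]
        window, bw = 20_000, 500
        counts, edges = tss_distance_profile(peaks, genes, window, bw)
        oracle = []
        for p in peaks:
            mid = p.interval.midpoint
            tss, strand = min(
                ((g.tss, g.strand) for g in genes), key=lambda t: (abs(mid - t[0]), t[0])
            )
            d = mid - tss if strand == "+" else tss - mid
            if -window <= d <= window:
                oracle.append(d)
        expected, _ = np.histogram(oracle, bins=edges)
        assert np.array_equal(counts, expected)
        assert counts.sum() == len(oracle)

    def test_no_genes_is_error(self):
        with pytest.raises(ValueError):
            tss_distance_profile([self.peak("chr1", 100)], [], 5000, 1000)


class TestRegulatoryDomains:
    def test_single_gene_extends_by_cap(self):
        g = gene("A", "chr1", 2_000_000, 2_010_000, "+")
        (d,) = build_regulatory_domains([g], chrom_sizes={"chr1": 10_000_000})
        assert (d.domain.start, d.domain.end) == (1_000_000, 3_000_000)

    def test_two_gene_layout_meets_between_basal_windows(self):
        g1 = gene("A", "chr1", 2_000_000, 2_005_000, "+")
        g2 = gene("B", "chr1", 2_010_000, 2_015_000, "+")
        d1, d2 = build_regulatory_domains([g1, g2], chrom_sizes={"chr1": 10_000_000})
        # g1 basal ends at TSS+1000, g2 basal starts at TSS2-5000 = 2_005_000
        assert d1.domain.end == 2_005_000
        assert d2.domain.start == 2_001_000
        # neither crosses the other's basal window
        assert d1.domain.end <= 2_010_000 - 5_000
        assert d2.domain.start >= 2_000_000 + 1_000

    def test_clipped_at_chromosome_start(self):
        g = gene("A", "chr1", 1_000, 6_000, "+")
        (d,) = build_regulatory_domains([g], chrom_sizes={"chr1": 10_000_000})
        assert d.domain.start == 0

    def test_domain_contains_basal_window(self):
        rng = np.random.default_rng(4)
        starts = np.sort(rng.choice(np.arange(10_000, 9_000_000), 40, replace=False))
        genes = [
            gene(f"G{i}", "chr1", int(s), int(s) + 5_000, "+" if i % 2 else "-")
            for i, s in enumerate(starts)
        ]
        domains = {d.gene: d for d in build_regulatory_domains(genes, chrom_sizes={"chr1": 10_000_000})}
        for g in genes:
            b_lo = g.tss - (5000 if g.strand == "+" else 1000)
            b_hi = g.tss + (1000 if g.strand == "+" else 5000)
            d = domains[g.name].domain
            assert d.start <= max(0, b_lo) and d.end >= min(b_hi, 10_000_000)

    def test_gene_beyond_chromosome_is_error(self):
        g = gene("A", "chr1", 1_000, 6_000, "+")
        with pytest.raises(ValueError):
            build_regulatory_domains([g], chrom_sizes={"chr1": 5_000})


def exact_binomial_upper_tail(k, n, p):
    """Independent oracle: direct tail summation with exact binomial
    coefficients in 60-digit decimal arithmetic (no underflow)."""
    from decimal import Decimal, getcontext

    ctx = getcontext()
    ctx.prec = 60
    ctx.Emin = -999_999
    dp, dq = Decimal(p), 1 - Decimal(p)
    total = Decimal(0)
    for j in range(k, n + 1):
        total += math.comb(n, j) * dp**j * dq ** (n - j)
    return float(min(total, Decimal(1)))


class TestBinomialEnrichment:
    def setup_method(self):
        self.genes = [gene(f"G{i}", "chr1", 100_000 * (i + 1), 100_000 * (i + 1) + 10_000, "+") for i in range(20)]
        self.domains = build_regulatory_domains(self.genes, chrom_sizes={"chr1": 10_000_000})

    def regions_at(self, midpoints):
        return [GenomicInterval("chr1", m - 50, m + 50) for m in midpoints]

    def test_saturated_term_filtered_out(self):
        g = gene("A", "chr1", 5_000_000, 5_010_000, "+")
        domain_all = build_regulatory_domains([g], extension_cap=10_000_000, chrom_sizes={"chr1": 10_000_000})
        regions = self.regions_at([1_000, 9_000_000])
        out = binomial_term_enrichment(regions, domain_all, {"T": {"A"}}, 10_000_000)
        assert out == []  # p = 1, fold = 1, p_binom = 1

    def test_binomial_tail_matches_exact_sum(self):
        rng = np.random.default_rng(12)
        from scipy import stats

        for _ in range(50):
            n = int(rng.integers(1, 1001))
            p = float(rng.uniform(0.001, 0.999))
            k = int(rng.integers(0, n + 1))
            ours = float(stats.binom.sf(k - 1, n, p))
            oracle = exact_binomial_upper_tail(k, n, p)
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-300)

    def test_fold_and_threshold_filters(self):
        # one tight term hosting all regions (high fold), one broad term
        tight = gene("T", "chr1", 5_000_000, 5_001_000, "+")
        broad = gene("B", "chr1", 8_000_000, 8_001_000, "+")
        domains = build_regulatory_domains(
            [tight, broad], extension_cap=50_000, chrom_sizes={"chr1": 10_000_000}
        )
        regions = self.regions_at([5_000_000 + 200 * i for i in range(10)])
        out = binomial_term_enrichment(
            regions, domains, {"hit": {"T"}, "miss": {"B"}}, 10_000_000
        )
        assert [r.term for r in out] == ["hit"]
        assert out[0].fold > 6 and out[0].q < 5e-3
        assert out[0].k == 10 and out[0].n == 10

    def test_worked_fold_example_dropped_by_fold_filter(self):
        # n = 10 regions, p = 0.1 term coverage, k = 5 hits -> fold 5 <= 6
        g = gene("A", "chr1", 5_500_000, 5_501_000, "+")
        domains = build_regulatory_domains(
            [g], extension_cap=500_000, chrom_sizes={"chr1": 10_000_000}
        )  # domain = 1 Mb = 10% of genome
        inside = [5_100_000 + i * 100_000 for i in range(5)]
        outside = [100_000 + i * 100_000 for i in range(5)]
        out_all = binomial_term_enrichment(
            self.regions_at(inside + outside), domains, {"T": {"A"}}, 10_000_000,
            fold_min=0.0, q_max=1.01,
        )
        (res,) = out_all
        assert res.k == 5 and res.p == pytest.approx(0.1)
        assert res.fold == pytest.approx(5.0)
        assert res.p_binom == pytest.approx(exact_binomial_upper_tail(5, 10, 0.1), rel=1e-12)
        filtered = binomial_term_enrichment(
            self.regions_at(inside + outside), domains, {"T": {"A"}}, 10_000_000
        )
        assert filtered == []

    def test_bh_monotone_and_order_invariant(self):
        rng = np.random.default_rng(6)
        mids = [100_000 * (i + 1) + 1000 for i in range(20)]
        regions = self.regions_at(rng.choice(mids, 12, replace=False))
        terms = {f"T{i}": {f"G{j}" for j in rng.choice(20, 4, replace=False)} for i in range(15)}
        out = binomial_term_enrichment(
            regions, self.domains, terms, 10_000_000, fold_min=0.0, q_max=1.01
        )
        ps = [r.p_binom for r in out]
        qs = [r.q for r in out]
        assert all(q >= p for p, q in zip(ps, qs))
        assert qs == sorted(qs)  # monotone in ranked p
        shuffled = dict(reversed(list(terms.items())))
        out2 = binomial_term_enrichment(
            regions, self.domains, shuffled, 10_000_000, fold_min=0.0, q_max=1.01
        )
        assert {r.term: r.q for r in out2} == {r.term: r.q for r in out}

    def test_zero_coverage_term_is_error(self):
        with pytest.raises(ValueError, match="untestable"):
            binomial_term_enrichment(
                self.regions_at([500_000]), self.domains, {"T": {"NOPE"}}, 10_000_000
            )
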