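"""Multi-mark peak integration and treatment-exclusive region calling.

The central procedure: peaks/islands from all four marks (PXR, p300,
H3K4me1, H3K27ac) of one treatment condition are merged transitively —
two features belong to the same region iff they are connected through a
chain of pairwise genomic overlaps (>=1 bp, half-open semantics). Regions
carrying all four marks in the drug condition but overlapping no four-mark
region of the vehicle condition are called Rifampin-Induced Regions (RIRs).
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .genomic_io import MARKS, GenomicInterval, Peak

ALL_MARKS = frozenset(MARKS)


@dataclass(frozen=True)
class MergedRegion:
    """Connected component of overlapping peaks/islands across marks."""

    span: GenomicInterval
    members: tuple[Peak, ...]
    condition: str

    @property
    def marks_present(self) -> frozenset[str]:
        return frozenset(p.mark for p in self.members)


@dataclass(frozen=True)
class RIR:
    """A four-mark merged region exclusive to the treated condition."""

    region: MergedRegion
    id: str


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    a_overlapping_b: int
    b_overlapping_a: int


def _sort_key(p: Peak):
    return (p.interval.chrom, p.interval.start, p.interval.end, p.mark)


def merge_marks(peak_sets: list[list[Peak]]) -> list[MergedRegion]:
    """Merge peaks of all marks (one condition) into transitive regions.

    Regions are the connected components of the overlap graph over all
    input peaks. Because overlap on a line is an interval relation, the
    components are found by a per-chromosome sorted sweep: a new component
    starts whenever the next peak begins at or beyond the running maximum
    end. Output spans are pairwise non-overlapping and the union of
    members equals the input.
    """
    peaks = [p for ps in peak_sets for p in ps]
    conditions = {p.condition for p in peaks}
    if len(conditions) > 1:
        raise ValueError(f"mixed conditions in merge input: {sorted(conditions)}")
    if not peaks:
        return []
    condition = peaks[0].condition
    peaks.sort(key=_sort_key)

    regions: list[MergedRegion] = []
    members: list[Peak] = []
    cur_chrom = None
    cur_end = -1

    def flush():
        if members:
            span = GenomicInterval(
                members[0].interval.chrom,
                min(m.interval.start for m in members),
                max(m.interval.end for m in members),
            )
            regions.append(MergedRegion(span, tuple(members), condition))

    for p in peaks:
        iv = p.interval
        if iv.chrom != cur_chrom or iv.start >= cur_end:
            flush()
            members = [p]
            cur_chrom, cur_end = iv.chrom, iv.end
        else:
            members.append(p)
            cur_end = max(cur_end, iv.end)
    flush()
    return regions


def select_full_mark_regions(
    regions: list[MergedRegion], required_marks: frozenset[str] | set[str] = ALL_MARKS
) -> list[MergedRegion]:
    """Keep regions whose mark inventory covers ``required_marks``."""
    required = frozenset(required_marks)
    if not required:
        raise ValueError("required_marks must be non-empty")
    return [r for r in regions if r.marks_present >= required]


def call_condition_exclusive_regions(
    treated_regions: list[MergedRegion], control_regions: list[MergedRegion]
) -> list[RIR]:
    """Treated four-mark regions overlapping no control four-mark region.

    IDs are assigned RIR1..RIRk in genome order (chrom lexicographic,
    then start).
    """
    control_trees: dict[str, IntervalTree] = {}
    for r in control_regions:
        control_trees.setdefault(r.span.chrom, IntervalTree()).addi(
            r.span.start, r.span.end
        )
    exclusive = [
        r
        for r in treated_regions
        if not (
            r.span.chrom in control_trees
            and control_trees[r.span.chrom].overlap(r.span.start, r.span.end)
        )
    ]
    exclusive.sort(key=lambda r: (r.span.chrom, r.span.start, r.span.end))
    return [RIR(region=r, id=f"RIR{i}") for i, r in enumerate(exclusive, start=1)]


def pairwise_overlap_summary(set_a: list[Peak], set_b: list[Peak]) -> OverlapSummary:
    """Count peaks of each set overlapping >=1 peak of the other set."""

    def build(peaks: list[Peak]) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for p in peaks:
            trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end
            )
        return trees

    def count(peaks: list[Peak], trees: dict[str, IntervalTree]) -> int:
        return sum(
            1
            for p in peaks
            if p.interval.chrom in trees
            and trees[p.interval.chrom].overlap(p.interval.start, p.interval.end)
        )

    trees_b = build(set_b)
    trees_a = build(set_a)
    return OverlapSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        a_overlapping_b=count(set_a, trees_b),
        b_overlapping_a=count(set_b, trees_a),
    )


def select_candidate_fragment(
    rir: RIR, flank: int = 500, chrom_size: int | None = None
) -> GenomicInterval:
    """Reporter fragment spanning the RIR's PXR/p300 peaks plus flanks.

    Histone islands are long (~5 kb), so cloned fragments cover only the
    focal TF peaks with up to ``flank`` bp of extra sequence on each side,
    clipped to [0, chrom_size).
    """
    anchors = [m.interval for m in rir.region.members if m.mark in ("PXR", "p300")]
    if not anchors:
        raise ValueError(f"{rir.id}: no PXR/p300 members to anchor a fragment")
    start = max(0, min(a.start for a in anchors) - flank)
    end = max(a.end for a in anchors) + flank
    if chrom_size is not None:
        end = min(end, chrom_size)
    return GenomicInterval(rir.region.span.chrom, start, end)
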