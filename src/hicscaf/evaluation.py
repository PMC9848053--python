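"""Contiguity statistics and truth-based misassembly classification.

Scaffold adjacencies are classified against simulator provenance into
translocations (neighbours from different chromosomes), inversions
(inconsistent relative orientation) and relocations (right chromosome and
orientation but wrong distance or order). Correction quality is scored by
matching reported breaks to injected junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .error_correction import BreakPoint
from .formats_io import ScaffoldPath
from .synthetic_data import Segment, TruthMap

__all__ = [
    "AdjacencyCounts",
    "EvalReport",
    "nx_stats",
    "classify_adjacencies",
    "score_correction",
    "evaluate_scaffolds",
]


def nx_stats(lengths: list[int], x: float) -> tuple[int, int]:
    """(Nx, Lx): the length at which the descending cumulative sum first
    reaches x% of the total, and its 1-based rank."""
    if not lengths:
        raise ValueError("empty length list")
    if any(ln <= 0 for ln in lengths):
        raise ValueError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    threshold = x / 100.0 * sum(srt)
    cum = 0
    for rank, ln in enumerate(srt, 1):
        cum += ln
        if cum >= threshold:
            return ln, rank
    return srt[-1], len(srt)  # unreachable for x <= 100


@dataclass
class AdjacencyCounts:
    correct: int = 0
    relocations: int = 0
    inversions: int = 0
    translocations: int = 0

    @property
    def total(self) -> int:
        return self.correct + self.relocations + self.inversions + self.translocations


def _facing_segment(truth: TruthMap, cid: str, orient: str, side: str) -> tuple[Segment, str]:
    """Outermost truth segment of a placed contig on one side ('left' or
    'right' in scaffold order), with its effective strand."""
    segs = truth.segments[cid]
    if not segs:
        raise ValueError(f"contig {cid!r} has no truth provenance")
    take_last = (side == "right") == (orient == "+")
    seg = segs[-1] if take_last else segs[0]
    strand = seg.strand if orient == "+" else ("-" if seg.strand == "+" else "+")
    return seg, strand


def classify_adjacencies(paths: list[ScaffoldPath], truth: TruthMap,
                         reloc_tol: int) -> AdjacencyCounts:
    """Classify every adjacent contig pair in every path against truth.

    Composite (misjoined) contigs are judged by the truth segment facing
    each junction. Counts are invariant under whole-path reversal.
    """
    counts = AdjacencyCounts()
    for path in paths:
        for (c1, o1), (c2, o2) in zip(path.items, path.items[1:]):
            seg1, s1 = _facing_segment(truth, c1, o1, "right")
            seg2, s2 = _facing_segment(truth, c2, o2, "left")
            if seg1.chrom != seg2.chrom:
                counts.translocations += 1
            elif s1 != s2:
                counts.inversions += 1
            else:
                gap = seg2.start - seg1.end if s1 == "+" else seg1.start - seg2.end
                if abs(gap) <= reloc_tol:
                    counts.correct += 1
                else:
                    counts.relocations += 1
    return counts


def score_correction(breaks: list[BreakPoint], truth: TruthMap,
                     tol: int) -> tuple[int, int]:
    """(detected junctions, false-positive breaks).

    A junction is detected when a break on its contig lies within tol bp;
    each break matches at most one junction, nearest pairs first. Breaks
    matching no junction are false positives.
    """
    junctions = [(err.contig, pos) for err in truth.errors for pos in err.positions]
    candidates = []
    for bi, bp in enumerate(breaks):
        for ji, (cid, jpos) in enumerate(junctions):
            if bp.contig == cid and abs(bp.position - jpos) <= tol:
                candidates.append((abs(bp.position - jpos), bi, ji))
    candidates.sort()
    used_breaks: set[int] = set()
    used_junctions: set[int] = set()
    for _, bi, ji in candidates:
        if bi in used_breaks or ji in used_junctions:
            continue
        used_breaks.add(bi)
        used_junctions.add(ji)
    return len(used_junctions), len(breaks) - len(used_breaks)


@dataclass
class EvalReport:
    n50: int
    l50: int
    n90: int
    l90: int
    adjacencies: AdjacencyCounts
    detected_junctions: int = 0
    false_positive_breaks: int = 0
    scaffold_lengths: list[int] = field(default_factory=list)

    def to_tsv(self) -> str:
        rows = [
            ("N50", self.n50), ("L50", self.l50),
            ("N90", self.n90), ("L90", self.l90),
            ("correct_adjacencies", self.adjacencies.correct),
            ("relocations", self.adjacencies.relocations),
            ("inversions", self.adjacencies.inversions),
            ("translocations", self.adjacencies.translocations),
            ("detected_junctions", self.detected_junctions),
            ("false_positive_breaks", self.false_positive_breaks),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"

    def summary(self) -> str:
        a = self.adjacencies
        return (f"N50 {self.n50} (L50 {self.l50}), N90 {self.n90} (L90 {self.l90}); "
                f"adjacencies: {a.correct} correct, {a.relocations} relocations, "
                f"{a.inversions} inversions, {a.translocations} translocations; "
                f"breaks: {self.detected_junctions} true junctions detected, "
                f"{self.false_positive_breaks} false positives")


def evaluate_scaffolds(paths: list[ScaffoldPath], truth: TruthMap,
                       lengths: dict[str, int], gap_len: int, reloc_tol: int,
                       breaks: list[BreakPoint] | None = None,
                       break_tol: int = 5_000) -> EvalReport:
    """One-stop report: Nx/Lx over scaffold lengths (gaps included) plus
    adjacency classification and, if breaks are given, correction scores."""
    scaffold_lengths = [p.length(lengths, gap_len) for p in paths]
    n50, l50 = nx_stats(scaffold_lengths, 50)
    n90, l90 = nx_stats(scaffold_lengths, 90)
    adjacencies = classify_adjacencies(paths, truth, reloc_tol)
    detected, fps = (0, 0)
    if breaks is not None:
        detected, fps = score_correction(
            [b for b in breaks if b.kind == "pre_scaffold"], truth, break_tol)
    return EvalReport(n50, l50, n90, l90, adjacencies, detected, fps,
                      sorted(scaffold_lengths, reverse=True))
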