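"""Synthetic genomes, fragmented assemblies, injected misjoins and Hi-C
pairs with full truth provenance.

The benchmark protocol: draw a multi-chromosome random genome, cut it into
contigs of a configurable length range, optionally concatenate randomly
chosen contigs into misjoined ones (single intra-chromosomal, single
inter-chromosomal, or double misjoins), and sample Hi-C pairs whose cis
separation follows a truncated power law plus a uniform trans-noise
fraction. Pairs are emitted in contig coordinates via the truth map, so a
misjoined contig receives the union of its parts' signal and its junction
shows a natural spanning-coverage valley.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats_io import Assembly, Contig, PairTable, revcomp

__all__ = [
    "SimParams",
    "Segment",
    "ErrorRecord",
    "TruthMap",
    "simulate_genome",
    "fragment_genome",
    "introduce_misjoins",
    "simulate_hic",
    "simulate_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Desk-scale defaults: 20 x 1 Mb chromosomes, 20-100 kb contigs,
    2e6 pairs with s^-1 decay and 5% trans background."""

    n_chromosomes: int = 20
    chrom_length: int = 1_000_000
    contig_min: int = 20_000
    contig_max: int = 100_000
    n_pairs: int = 2_000_000
    alpha: float = 1.0
    trans_fraction: float = 0.05
    s_min: int = 1_000
    mapq: int = 60
    seed: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.contig_min <= self.contig_max <= self.chrom_length:
            raise ValueError("need 1 <= contig_min <= contig_max <= chrom_length")
        if self.alpha <= 0:
            raise ValueError("decay exponent must be positive")
        if not 0 <= self.trans_fraction < 1:
            raise ValueError("trans fraction must be in [0, 1)")


@dataclass(frozen=True)
class Segment:
    """A contig piece's true placement: genome interval + strand."""

    chrom: str
    start: int
    end: int  # half-open
    strand: str  # '+' | '-'

    @property
    def length(self) -> int:
        return self.end - self.start

    def flipped(self) -> "Segment":
        return replace(self, strand="-" if self.strand == "+" else "+")


@dataclass(frozen=True)
class ErrorRecord:
    contig: str
    positions: tuple[int, ...]  # junction positions, contig coordinates
    cls: str  # 'intra' | 'inter' | 'double'


@dataclass
class TruthMap:
    """Provenance of every contig: ordered genome segments per contig,
    injected error junctions, and chromosome lengths."""

    segments: dict[str, list[Segment]]
    chrom_lengths: dict[str, int]
    errors: list[ErrorRecord] = field(default_factory=list)

    def contig_length(self, cid: str) -> int:
        return sum(s.length for s in self.segments[cid])

    def n_junctions(self) -> int:
        return sum(len(e.positions) for e in self.errors)

    def lifted(self, liftmap) -> "TruthMap":
        """Truth for the post-break assembly: segment lists are sliced at
        fragment boundaries; junction records move to the fragment that
        contains them (junctions exactly at a cut are resolved)."""
        new_segments: dict[str, list[Segment]] = {}
        frag_spans: dict[str, list[tuple[int, int, str]]] = {}
        for cid, segs in self.segments.items():
            frags = liftmap.fragments(cid)
            frag_spans[cid] = frags
            for fstart, fend, fname in frags:
                out = []
                pos = 0
                for seg in segs:
                    s0, s1 = pos, pos + seg.length
                    lo, hi = max(s0, fstart), min(s1, fend)
                    if lo < hi:
                        if seg.strand == "+":
                            out.append(replace(seg, start=seg.start + (lo - s0),
                                               end=seg.start + (hi - s0)))
                        else:
                            out.append(replace(seg, start=seg.start + (s1 - hi),
                                               end=seg.start + (s1 - lo)))
                    pos = s1
                new_segments[fname] = out
        new_errors = []
        for err in self.errors:
            for jpos in err.positions:
                for fstart, fend, fname in frag_spans.get(err.contig, ()):
                    if fstart < jpos < fend:
                        new_errors.append(ErrorRecord(fname, (jpos - fstart,), err.cls))
        return TruthMap(new_segments, dict(self.chrom_lengths), new_errors)

    def errors_tsv(self) -> str:
        lines = [f"{e.contig}\t{','.join(map(str, e.positions))}\t{e.cls}"
                 for e in self.errors]
        return "\n".join(lines) + ("\n" if lines else "")


def simulate_genome(params: SimParams) -> dict[str, str]:
    """I.i.d. uniform ACGT chromosomes named chr1..chrN; reproducible."""
    rng = np.random.default_rng(params.seed)
    genome = {}
    for i in range(1, params.n_chromosomes + 1):
        arr = rng.integers(0, 4, size=params.chrom_length, dtype=np.uint8)
        genome[f"chr{i}"] = _BASES[arr].tobytes().decode("ascii")
    return genome


def fragment_genome(genome: dict[str, str], min_len: int, max_len: int,
                    seed: int) -> tuple[Assembly, TruthMap]:
    """Cut each chromosome into fragments of uniform length in
    [min_len, max_len] (the final fragment takes the remainder and may be
    shorter); fragments are shuffled and renamed."""
    if min_len < 1 or min_len > max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    rng = np.random.default_rng(seed)
    pieces: list[tuple[str, int, int]] = []
    for chrom, seq in genome.items():
        L = len(seq)
        pos = 0
        while pos < L:
            ln = int(rng.integers(min_len, max_len + 1))
            end = min(pos + ln, L)
            pieces.append((chrom, pos, end))
            pos = end
    order = rng.permutation(len(pieces))
    width = len(str(len(pieces)))
    contigs = []
    segments = {}
    for k, idx in enumerate(order, 1):
        chrom, start, end = pieces[idx]
        name = f"ctg{k:0{width}d}"
        contigs.append(Contig(name, end - start, genome[chrom][start:end]))
        segments[name] = [Segment(chrom, start, end, "+")]
    truth = TruthMap(segments, {c: len(s) for c, s in genome.items()})
    return Assembly(contigs), truth


def _oriented_segments(segs: list[Segment], orient: str) -> list[Segment]:
    if orient == "+":
        return list(segs)
    return [s.flipped() for s in reversed(segs)]


def introduce_misjoins(assembly: Assembly, truth: TruthMap,
                       n_intra: int, n_inter: int, n_double: int,
                       seed: int) -> tuple[Assembly, TruthMap]:
    """Concatenate randomly chosen contigs (no gap, random orientations)
    into erroneous ones: n_intra single same-chromosome misjoins, n_inter
    single cross-chromosome misjoins, n_double with two junctions across
    any three contigs. Contig count drops by n_intra + n_inter + 2*n_double.
    """
    rng = np.random.default_rng(seed)
    pool = [c.id for c in assembly if len(truth.segments[c.id]) == 1]
    chrom_of = {cid: truth.segments[cid][0].chrom for cid in pool}

    def draw(cids: list[str]) -> None:
        for cid in cids:
            pool.remove(cid)

    plans: list[tuple[str, list[str]]] = []
    for _ in range(n_intra):
        by_chrom: dict[str, list[str]] = {}
        for cid in pool:
            by_chrom.setdefault(chrom_of[cid], []).append(cid)
        eligible = sorted(c for c, lst in by_chrom.items() if len(lst) >= 2)
        if not eligible:
            raise ValueError("not enough same-chromosome contigs for an intra misjoin")
        chrom = eligible[int(rng.integers(len(eligible)))]
        picks = [by_chrom[chrom][i] for i in
                 rng.choice(len(by_chrom[chrom]), size=2, replace=False)]
        draw(picks)
        plans.append(("intra", picks))
    for _ in range(n_inter):
        by_chrom = {}
        for cid in pool:
            by_chrom.setdefault(chrom_of[cid], []).append(cid)
        if len(by_chrom) < 2:
            raise ValueError("not enough cross-chromosome contigs for an inter misjoin")
        chroms = sorted(by_chrom)
        c1, c2 = [chroms[i] for i in rng.choice(len(chroms), size=2, replace=False)]
        picks = [by_chrom[c1][int(rng.integers(len(by_chrom[c1])))],
                 by_chrom[c2][int(rng.integers(len(by_chrom[c2])))]]
        draw(picks)
        plans.append(("inter", picks))
    for _ in range(n_double):
        if len(pool) < 3:
            raise ValueError("not enough contigs for a double misjoin")
        picks = [pool[i] for i in rng.choice(len(pool), size=3, replace=False)]
        draw(picks)
        plans.append(("double", picks))

    used = {cid for _, parts in plans for cid in parts}
    contigs = [c for c in assembly if c.id not in used]
    segments = {c.id: list(truth.segments[c.id]) for c in contigs}
    errors = list(truth.errors)
    counters = {"intra": 0, "inter": 0, "double": 0}
    for cls, parts in plans:
        counters[cls] += 1
        name = f"mis_{cls}_{counters[cls]}"
        orients = ["+" if rng.random() < 0.5 else "-" for _ in parts]
        seq_parts = []
        seg_list: list[Segment] = []
        junctions = []
        pos = 0
        for k, (cid, orient) in enumerate(zip(parts, orients)):
            if k > 0:
                junctions.append(pos)
            seq = assembly[cid].sequence
            if seq is not None:
                seq_parts.append(seq if orient == "+" else revcomp(seq))
            seg_list.extend(_oriented_segments(truth.segments[cid], orient))
            pos += assembly[cid].length
        seq = "".join(seq_parts) if seq_parts else None
        contigs.append(Contig(name, pos, seq))
        segments[name] = seg_list
        errors.append(ErrorRecord(name, tuple(junctions), cls))
    return Assembly(contigs), TruthMap(segments, dict(truth.chrom_lengths), errors)


# ---------------------------------------------------------------------------
# Hi-C pair simulation
# ---------------------------------------------------------------------------

def _sample_separations(rng, L: np.ndarray, s_min: int, alpha: float) -> np.ndarray:
    """Inverse-CDF samples from p(s) ~ s^-alpha on [s_min, L] (per-element L)."""
    u = rng.random(len(L))
    if abs(alpha - 1.0) < 1e-12:
        s = s_min * (L / s_min) ** u
    else:
        a = 1.0 - alpha
        s = (s_min ** a + u * (L ** a - s_min ** a)) ** (1.0 / a)
    return np.minimum(s.astype(np.int64), L)


def simulate_hic(assembly: Assembly, truth: TruthMap, params: SimParams,
                 return_genome_coords: bool = False):
    """Sample Hi-C pairs on the true genome and express them in contig
    coordinates through the truth map.

    Cis pairs (fraction 1 - trans_fraction): chromosome chosen by length,
    separation from the truncated power law on [s_min, L], leftmost end
    uniform over positions keeping the pair on-chromosome. Trans pairs:
    both ends uniform on length-weighted random chromosomes. A constant
    mapq is implied; the returned PairTable is canonical and seeded.
    """
    rng = np.random.default_rng(params.seed)
    chroms = list(truth.chrom_lengths)
    lens = np.array([truth.chrom_lengths[c] for c in chroms], dtype=np.int64)
    weights = lens / lens.sum()
    n = params.n_pairs
    n_trans = int(round(n * params.trans_fraction))
    n_cis = n - n_trans

    # cis: separation drawn first, then the leftmost end placed uniformly
    # over valid positions — this keeps the separation marginal exactly
    # the truncated power law (naive draw-and-reject would skew it)
    chrom_i = rng.choice(len(chroms), size=n_cis, p=weights)
    L = lens[chrom_i]
    s = _sample_separations(rng, L, params.s_min, params.alpha)
    g1 = (rng.random(n_cis) * (L - s)).astype(np.int64)
    g2 = g1 + s

    # trans
    t1 = rng.choice(len(chroms), size=n_trans, p=weights)
    t2 = rng.choice(len(chroms), size=n_trans, p=weights)
    tp1 = (rng.random(n_trans) * lens[t1]).astype(np.int64)
    tp2 = (rng.random(n_trans) * lens[t2]).astype(np.int64)

    chrom_a = np.concatenate([chrom_i, t1])
    chrom_b = np.concatenate([chrom_i, t2])
    gpos_a = np.concatenate([g1, tp1])
    gpos_b = np.concatenate([g2, tp2])

    # genome -> contig coordinates via the segment table
    names = assembly.names
    name_idx = {nm: i for i, nm in enumerate(names)}
    chrom_off = np.concatenate([[0], np.cumsum(lens)])
    rows = []  # (global gstart, glen, contig idx, contig offset, strand-)
    for cid, segs in truth.segments.items():
        coff = 0
        for seg in segs:
            ci = chroms.index(seg.chrom)
            rows.append((chrom_off[ci] + seg.start, seg.length,
                         name_idx[cid], coff, seg.strand == "-"))
            coff += seg.length
    rows.sort()
    seg_start = np.array([r[0] for r in rows], dtype=np.int64)
    seg_len = np.array([r[1] for r in rows], dtype=np.int64)
    seg_contig = np.array([r[2] for r in rows], dtype=np.int64)
    seg_off = np.array([r[3] for r in rows], dtype=np.int64)
    seg_rev = np.array([r[4] for r in rows], dtype=bool)

    def to_contig(chrom_idx, gpos):
        glo = chrom_off[chrom_idx] + gpos
        k = np.searchsorted(seg_start, glo, side="right") - 1
        delta = glo - seg_start[k]
        fwd = seg_off[k] + delta
        rev = seg_off[k] + seg_len[k] - 1 - delta
        return seg_contig[k], np.where(seg_rev[k], rev, fwd)

    ca, pa = to_contig(chrom_a, gpos_a)
    cb, pb = to_contig(chrom_b, gpos_b)
    table = PairTable(names, ca, pa, cb, pb)
    if return_genome_coords:
        genome_coords = (np.array(chroms)[chrom_a], gpos_a,
                         np.array(chroms)[chrom_b], gpos_b)
        return table, genome_coords
    return table


def simulate_benchmark(params: SimParams, misjoins: tuple[int, int, int] | None = None):
    """Full benchmark bundle: genome, fragmented assembly, optional
    misjoins, and Hi-C pairs over the (possibly errored) assembly.

    Returns (assembly, truth, pairs). Sub-steps derive their seeds from
    params.seed so error-free and errored siblings share a genome.
    """
    genome = simulate_genome(params)
    assembly, truth = fragment_genome(genome, params.contig_min, params.contig_max,
                                      seed=params.seed + 1)
    if misjoins is not None:
        n_intra, n_inter, n_double = misjoins
        assembly, truth = introduce_misjoins(assembly, truth, n_intra, n_inter,
                                             n_double, seed=params.seed + 2)
    pairs = simulate_hic(assembly, truth, params)
    return assembly, truth, pairs
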