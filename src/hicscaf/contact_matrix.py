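"""Resolution-chunked Hi-C contact matrix and the expected-contact profile.

Each contig is split into fixed-size chunks; pair hits accumulate in cells
keyed by (chunk, chunk). Cells within one contig are *intra* cells, cells
between contigs are *inter* cells. The expected profile E(d) is the median
intra-cell count at chunk separation d, including empty cells, restricted
to full-length chunks, and forced non-increasing — it is the normalization
baseline for join scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .formats_io import Assembly, PairTable

__all__ = [
    "ChunkIndex",
    "ContactMatrix",
    "ExpectedProfile",
    "ProfileError",
    "assign_chunk",
    "build_matrix",
    "expected_profile",
    "site_normalize",
    "count_motif_sites",
    "DEFAULT_MIN_SUPPORT",
    "DEFAULT_D_CAP",
]

DEFAULT_MIN_SUPPORT = 8
DEFAULT_D_CAP = 32


class ProfileError(RuntimeError):
    """No usable intra cells at this resolution."""


class ChunkIndex:
    """Maps (contig, position) to global chunk ids at one resolution.

    A contig of length L has ceil(L / resolution) chunks; the trailing
    chunk has length L - (n-1)*resolution, in (0, resolution]. Chunks that
    overlap a recorded gap interval (scaffold N-filler) are flagged so the
    expected profile can skip them.
    """

    def __init__(self, assembly: Assembly, resolution: int) -> None:
        if resolution < 1:
            raise ValueError("resolution must be >= 1")
        self.resolution = int(resolution)
        self.names = assembly.names
        self.name_to_idx = {n: i for i, n in enumerate(self.names)}
        self.lengths = np.array([assembly[n].length for n in self.names], dtype=np.int64)
        self.n_chunks = -(-self.lengths // self.resolution)  # ceil div
        self.offsets = np.concatenate([[0], np.cumsum(self.n_chunks)])
        self.total_chunks = int(self.offsets[-1])
        # per-gid lookups
        self.gid_contig = np.repeat(np.arange(len(self.names)), self.n_chunks)
        self.gid_ordinal = np.arange(self.total_chunks) - self.offsets[self.gid_contig]
        self.chunk_len = np.full(self.total_chunks, self.resolution, dtype=np.int64)
        last = self.offsets[1:] - 1
        self.chunk_len[last] = self.lengths - (self.n_chunks - 1) * self.resolution
        self.full_mask = self.chunk_len == self.resolution
        # chunks dominated by scaffold-gap filler (> 10% N) are excluded
        # from profile estimation; a 200 bp gap in a 10 kb chunk is noise
        gap_bp = np.zeros(self.total_chunks, dtype=np.int64)
        for name, ivals in assembly.gaps.items():
            i = self.name_to_idx.get(name)
            if i is None:
                continue
            off = self.offsets[i]
            for start, end in ivals:
                w0 = start // self.resolution
                w1 = (end - 1) // self.resolution
                for w in range(w0, w1 + 1):
                    lo = max(start, w * self.resolution)
                    hi = min(end, (w + 1) * self.resolution)
                    gap_bp[off + w] += hi - lo
        self.clean_mask = self.full_mask & (gap_bp <= self.resolution // 10)

    def trailing_length(self, name: str) -> int:
        i = self.name_to_idx[name]
        return int(self.lengths[i] - (self.n_chunks[i] - 1) * self.resolution)

    def chunks_of(self, name: str) -> int:
        return int(self.n_chunks[self.name_to_idx[name]])

    def gid(self, name: str, ordinal: int) -> int:
        i = self.name_to_idx[name]
        if not 0 <= ordinal < self.n_chunks[i]:
            raise ValueError(f"chunk ordinal {ordinal} out of range for {name!r}")
        return int(self.offsets[i] + ordinal)


def assign_chunk(contig: str, pos: int, index: ChunkIndex) -> int:
    """0-based chunk ordinal of a position within its contig."""
    i = index.name_to_idx[contig]
    if not 0 <= pos < index.lengths[i]:
        raise ValueError(f"position {pos} out of range for contig {contig!r} "
                         f"(length {index.lengths[i]})")
    return int(pos // index.resolution)


class ContactMatrix:
    """Sparse symmetric chunk-pair counts, stored upper-triangular (a <= b)."""

    def __init__(self, index: ChunkIndex, gid_a: np.ndarray, gid_b: np.ndarray,
                 values: np.ndarray) -> None:
        self.index = index
        self.gid_a = np.asarray(gid_a, dtype=np.int64)
        self.gid_b = np.asarray(gid_b, dtype=np.int64)
        self.values = np.asarray(values, dtype=np.float64)
        if np.any(self.gid_a > self.gid_b):
            raise ValueError("cells must be canonical (gid_a <= gid_b)")
        self._inter_cache: dict | None = None
        self._intra_cache: dict | None = None

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def is_intra(self) -> np.ndarray:
        return self.index.gid_contig[self.gid_a] == self.index.gid_contig[self.gid_b]

    def get(self, gid_a: int, gid_b: int) -> float:
        a, b = min(gid_a, gid_b), max(gid_a, gid_b)
        hit = (self.gid_a == a) & (self.gid_b == b)
        return float(self.values[hit].sum())

    def contig_mass(self) -> np.ndarray:
        """Total cell mass touching each contig (a cell is counted once)."""
        n = len(self.index.names)
        ca = self.index.gid_contig[self.gid_a]
        cb = self.index.gid_contig[self.gid_b]
        mass = np.bincount(ca, weights=self.values, minlength=n)
        other = ca != cb
        mass += np.bincount(cb[other], weights=self.values[other], minlength=n)
        return mass

    def _build_caches(self) -> None:
        idx = self.index
        ca = idx.gid_contig[self.gid_a]
        cb = idx.gid_contig[self.gid_b]
        oa = self.gid_a - idx.offsets[ca]
        ob = self.gid_b - idx.offsets[cb]
        intra = ca == cb
        self._intra_cache = {}
        if intra.any():
            order = np.lexsort((oa[intra], ob[intra], ca[intra]))
            c, i, j, v = ca[intra][order], oa[intra][order], ob[intra][order], self.values[intra][order]
            bounds = np.flatnonzero(np.diff(c)) + 1
            for seg_c, seg_i, seg_j, seg_v in zip(
                    np.split(c, bounds), np.split(i, bounds),
                    np.split(j, bounds), np.split(v, bounds)):
                self._intra_cache[int(seg_c[0])] = (seg_i, seg_j, seg_v)
        self._inter_cache = {}
        inter = ~intra
        if inter.any():
            key = ca[inter].astype(np.int64) * len(idx.names) + cb[inter]
            order = np.argsort(key, kind="stable")
            k, i, j, v = key[order], oa[inter][order], ob[inter][order], self.values[inter][order]
            bounds = np.flatnonzero(np.diff(k)) + 1
            for seg_k, seg_i, seg_j, seg_v in zip(
                    np.split(k, bounds), np.split(i, bounds),
                    np.split(j, bounds), np.split(v, bounds)):
                pair = (int(seg_k[0]) // len(idx.names), int(seg_k[0]) % len(idx.names))
                self._inter_cache[pair] = (seg_i, seg_j, seg_v)

    def inter_cells(self, contig_i: int, contig_j: int):
        """(ordinals_i, ordinals_j, values) for inter cells of a contig pair.

        Arguments are contig indices with contig_i < contig_j.
        """
        if self._inter_cache is None:
            self._build_caches()
        empty = (np.array([], dtype=np.int64),) * 2 + (np.array([], dtype=np.float64),)
        return self._inter_cache.get((contig_i, contig_j), empty)

    def intra_cells(self, contig_i: int):
        if self._intra_cache is None:
            self._build_caches()
        empty = (np.array([], dtype=np.int64),) * 2 + (np.array([], dtype=np.float64),)
        return self._intra_cache.get(contig_i, empty)

    def inter_pair_keys(self) -> list[tuple[int, int]]:
        if self._inter_cache is None:
            self._build_caches()
        return sorted(self._inter_cache)

    def inter_pair_mass(self) -> dict[tuple[int, int], float]:
        if self._inter_cache is None:
            self._build_caches()
        return {k: float(v[2].sum()) for k, v in self._inter_cache.items()}

    def dump_tsv(self) -> str:
        idx = self.index
        lines = []
        for a, b, v in zip(self.gid_a, self.gid_b, self.values):
            ca, cb = idx.gid_contig[a], idx.gid_contig[b]
            lines.append(f"{idx.names[ca]}\t{a - idx.offsets[ca]}\t"
                         f"{idx.names[cb]}\t{b - idx.offsets[cb]}\t{v:g}")
        return "\n".join(lines) + ("\n" if lines else "")


def build_matrix(pairs: PairTable, index: ChunkIndex) -> ContactMatrix:
    """Bin pairs into chunk-pair cells; total cell mass equals pair count."""
    if pairs.names != index.names:
        raise ValueError("pair table and chunk index reference different assemblies")
    g1 = index.offsets[pairs.cid1] + pairs.pos1 // index.resolution
    g2 = index.offsets[pairs.cid2] + pairs.pos2 // index.resolution
    a = np.minimum(g1, g2)
    b = np.maximum(g1, g2)
    key = a * index.total_chunks + b
    uniq, counts = np.unique(key, return_counts=True)
    return ContactMatrix(index, uniq // index.total_chunks, uniq % index.total_chunks,
                         counts.astype(np.float64))


@dataclass
class ExpectedProfile:
    """Median intra-cell count per chunk separation, non-increasing in d."""

    resolution: int
    values: np.ndarray   # values[d-1] = E(d) for d = 1..D_max
    support: np.ndarray  # number of intra cells used at each d

    @property
    def D_max(self) -> int:
        return len(self.values)

    def expected(self, d: int) -> float:
        if not 1 <= d <= self.D_max:
            raise ValueError(f"separation {d} outside supported range 1..{self.D_max}")
        return float(self.values[d - 1])


def _median_with_zeros(nonzero_sorted: np.ndarray, n_total: int) -> float:
    """Median of a multiset of n_total values of which the smallest
    n_total - len(nonzero_sorted) are zeros."""
    n_zero = n_total - len(nonzero_sorted)
    if n_zero < 0:
        raise ValueError("more nonzero values than total cells")

    def at(k: int) -> float:  # k-th order statistic, 0-based
        return 0.0 if k < n_zero else float(nonzero_sorted[k - n_zero])

    if n_total % 2:
        return at(n_total // 2)
    return 0.5 * (at(n_total // 2 - 1) + at(n_total // 2))


def expected_profile(matrix: ContactMatrix, min_support: int = DEFAULT_MIN_SUPPORT,
                     D_cap: int = DEFAULT_D_CAP) -> ExpectedProfile:
    """Estimate E(d) from intra cells between full (non-gap) chunks.

    Empty cells count as zeros in the median. E is made non-increasing by
    a cumulative minimum; the profile is truncated at the last separation
    with both adequate support and a positive median.
    """
    idx = matrix.index
    clean = idx.clean_mask
    # support per separation: pairs (i, i+d) of clean chunks within a contig
    support = np.zeros(D_cap + 1, dtype=np.int64)
    for ci in range(len(idx.names)):
        ok = clean[idx.offsets[ci]: idx.offsets[ci + 1]]
        n = len(ok)
        for d in range(1, min(D_cap, n - 1) + 1):
            support[d] += int(np.count_nonzero(ok[:-d] & ok[d:]))
    # nonzero observed counts per separation
    vals: dict[int, list[float]] = {d: [] for d in range(1, D_cap + 1)}
    for ci in range(len(idx.names)):
        oi, oj, v = matrix.intra_cells(ci)
        if len(oi) == 0:
            continue
        off = idx.offsets[ci]
        keep = clean[off + oi] & clean[off + oj]
        d_arr = (oj - oi)[keep]
        for d, val in zip(d_arr, v[keep]):
            if 1 <= d <= D_cap:
                vals[int(d)].append(float(val))

    E = []
    sup = []
    for d in range(1, D_cap + 1):
        if support[d] < min_support:
            break
        E.append(_median_with_zeros(np.sort(vals[d]), int(support[d])))
        sup.append(int(support[d]))
    if not E:
        raise ProfileError(
            "no intra-cell separations with sufficient support; "
            "use a coarser resolution (larger chunk size)")
    E = np.minimum.accumulate(np.array(E, dtype=np.float64))
    positive = np.flatnonzero(E > 0)
    if len(positive) == 0:
        raise ProfileError(
            "expected profile is zero at all separations; "
            "use a coarser resolution (larger chunk size)")
    d_max = int(positive[-1]) + 1
    return ExpectedProfile(idx.resolution, E[:d_max], np.array(sup[:d_max]))


# ---------------------------------------------------------------------------
# restriction-site normalization
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _motif_regex(motif: str) -> re.Pattern:
    try:
        body = "".join(_IUPAC[ch] for ch in motif.upper())
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in motif {motif!r}") from None
    return re.compile(f"(?=({body}))")  # lookahead => overlapping matches


def count_motif_sites(sequence: str, motifs: list[str]) -> np.ndarray:
    """Per-position motif start indicator summed over motifs.

    For each motif, matches of the motif and of its reverse complement are
    located on the forward strand; a position matching both (palindrome)
    counts once per motif.
    """
    starts = np.zeros(len(sequence), dtype=np.int64)
    seq = sequence.upper()
    for motif in motifs:
        pos = {m.start() for m in _motif_regex(motif).finditer(seq)}
        rc = motif.upper().translate(str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))[::-1]
        pos |= {m.start() for m in _motif_regex(rc).finditer(seq)}
        for p in pos:
            starts[p] += 1
    return starts


def site_normalize(matrix: ContactMatrix, assembly: Assembly,
                   motifs: list[str]) -> ContactMatrix:
    """Rescale cells by restriction-site density.

    With s_a, s_b the motif-site counts of the two chunks and m the mean
    of (sites + 1) over all chunks, a cell becomes raw * m^2 /
    ((s_a + 1) * (s_b + 1)). Total mass is not conserved.
    """
    if not motifs:
        raise ValueError("motif list is empty")
    idx = matrix.index
    sites = np.zeros(idx.total_chunks, dtype=np.float64)
    for ci, name in enumerate(idx.names):
        seq = assembly[name].sequence
        if seq is None:
            raise ValueError(f"contig {name!r} has no sequence; cannot count cut sites")
        starts = count_motif_sites(seq, motifs)
        per_chunk = np.bincount(np.arange(len(seq)) // idx.resolution, weights=starts,
                                minlength=int(idx.n_chunks[ci]))
        sites[idx.offsets[ci]: idx.offsets[ci + 1]] = per_chunk
    w = sites + 1.0
    m_bar = float(w.mean())
    new_values = matrix.values * (m_bar ** 2) / (w[matrix.gid_a] * w[matrix.gid_b])
    return ContactMatrix(idx, matrix.gid_a.copy(), matrix.gid_b.copy(), new_values)
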