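"""Readers and writers for the on-disk formats the scaffolder touches.

Supported formats: FASTA contigs, Hi-C read-pair alignments (canonical
6-column TSV, BED-style interval pairs, and name-grouped SAM/BAM), AGP
v2.1 and scaffold FASTA output.

All internal coordinates are 0-based half-open; AGP is written 1-based
inclusive as the v2.1 standard requires.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Contig",
    "Assembly",
    "AlignedPair",
    "PairTable",
    "ScaffoldPath",
    "revcomp",
    "read_pairs",
    "load_pair_table",
    "write_pairs",
    "write_agp",
    "read_agp",
    "emit_scaffold_fasta",
    "DEFAULT_GAP_LEN",
    "DEFAULT_MAPQ_MIN",
]

DEFAULT_GAP_LEN = 200
DEFAULT_MAPQ_MIN = 10

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed record in an input file."""


@dataclass(frozen=True)
class Contig:
    """A named sequence unit of scaffolding."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id!r}: sequence length {len(self.sequence)} != declared {self.length}"
            )


class Assembly:
    """An ordered collection of uniquely named contigs.

    ``gaps`` optionally records, per contig, 0-based half-open intervals of
    gap filler (runs of N inserted when flattening scaffolds); downstream
    code uses it to mask gap-containing chunks out of profile estimation.
    """

    def __init__(self, contigs: Iterable[Contig],
                 gaps: dict[str, list[tuple[int, int]]] | None = None) -> None:
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            if c.id in self._contigs:
                raise ValueError(f"duplicate contig id {c.id!r}")
            self._contigs[c.id] = c
        self.gaps: dict[str, list[tuple[int, int]]] = dict(gaps or {})

    # -- construction -------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Assembly":
        from Bio import SeqIO

        contigs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
            contigs.append(Contig(rec.id, len(seq), seq))
        return cls(contigs)

    @classmethod
    def from_lengths(cls, lengths: dict[str, int]) -> "Assembly":
        return cls(Contig(n, ln) for n, ln in lengths.items())

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "Assembly":
        return cls(Contig(n, len(s), s.upper()) for n, s in seqs.items())

    # -- mapping protocol ---------------------------------------------
    def __getitem__(self, name: str) -> Contig:
        return self._contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: c.length for n, c in self._contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self._contigs.values())

    def has_sequences(self) -> bool:
        return all(c.sequence is not None for c in self._contigs.values())

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for c in self:
                if c.sequence is None:
                    raise ValueError(f"contig {c.id!r} has no sequence")
                fh.write(f">{c.id}\n")
                for i in range(0, c.length, width):
                    fh.write(c.sequence[i:i + width] + "\n")


@dataclass(frozen=True)
class AlignedPair:
    """One Hi-C read pair, canonicalized so (contig1, pos1) <= (contig2, pos2)."""

    contig1: str
    pos1: int
    mapq1: int
    contig2: str
    pos2: int
    mapq2: int

    @classmethod
    def make(cls, contig1: str, pos1: int, mapq1: int,
             contig2: str, pos2: int, mapq2: int) -> "AlignedPair":
        if (contig1, pos1) > (contig2, pos2):
            contig1, pos1, mapq1, contig2, pos2, mapq2 = contig2, pos2, mapq2, contig1, pos1, mapq1
        return cls(contig1, pos1, mapq1, contig2, pos2, mapq2)


@dataclass
class ScaffoldPath:
    """An ordered, oriented list of contigs making up one scaffold."""

    name: str
    items: list[tuple[str, str]]  # (contig id, '+' or '-')

    def __post_init__(self) -> None:
        for cid, orient in self.items:
            if orient not in ("+", "-"):
                raise ValueError(f"bad orientation {orient!r} for {cid!r}")

    def reversed(self) -> "ScaffoldPath":
        flip = {"+": "-", "-": "+"}
        return ScaffoldPath(self.name, [(c, flip[o]) for c, o in reversed(self.items)])

    def length(self, lengths: dict[str, int], gap_len: int = DEFAULT_GAP_LEN) -> int:
        return sum(lengths[c] for c, _ in self.items) + gap_len * (len(self.items) - 1)


# ---------------------------------------------------------------------------
# pair reading
# ---------------------------------------------------------------------------

def _check_pair(pair: AlignedPair, assembly: Assembly | None, where: str) -> None:
    for cid, pos in ((pair.contig1, pair.pos1), (pair.contig2, pair.pos2)):
        if assembly is not None:
            if cid not in assembly:
                raise FormatError(f"{where}: unknown contig {cid!r}")
            if not 0 <= pos < assembly[cid].length:
                raise FormatError(f"{where}: position {pos} out of range for contig {cid!r}")
        elif pos < 0:
            raise FormatError(f"{where}: negative position {pos}")


def _read_pairs_tsv(path, mapq_min, assembly):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                c1, p1, c2, p2, q1, q2 = (fields[0], int(fields[1]), fields[2],
                                          int(fields[3]), int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if q1 < mapq_min or q2 < mapq_min:
                continue
            pair = AlignedPair.make(c1, p1, q1, c2, p2, q2)
            _check_pair(pair, assembly, f"{path}:{lineno}")
            yield pair


def _read_pairs_bed(path, mapq_min, assembly):
    """BED dialect: consecutive lines sharing a read name form one pair.

    Columns: chrom start end name score strand; score is taken as mapq.
    """
    pending = None  # (name, chrom, start, mapq)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 BED columns")
            try:
                chrom, start, score = fields[0], int(fields[1]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            name = fields[3]
            if pending is None:
                pending = (name, chrom, start, score, lineno)
                continue
            pname, pchrom, pstart, pscore, plineno = pending
            if pname != name:
                raise FormatError(
                    f"{path}:{plineno}: unpaired BED record {pname!r} "
                    f"(next record is {name!r})")
            pending = None
            if pscore < mapq_min or score < mapq_min:
                continue
            pair = AlignedPair.make(pchrom, pstart, pscore, chrom, start, score)
            _check_pair(pair, assembly, f"{path}:{lineno}")
            yield pair
    if pending is not None:
        raise FormatError(f"{path}:{pending[4]}: unpaired trailing BED record {pending[0]!r}")


def _read_pairs_bam(path, mapq_min, assembly):
    """Name-grouped SAM/BAM: primary alignments of the two mates form a pair."""
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    pending: dict[str, object] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            if mate.mapping_quality < mapq_min or rec.mapping_quality < mapq_min:
                continue
            pair = AlignedPair.make(
                mate.reference_name, mate.reference_start, mate.mapping_quality,
                rec.reference_name, rec.reference_start, rec.mapping_quality)
            _check_pair(pair, assembly, f"{path}: read {rec.query_name!r}")
            yield pair


def read_pairs(path: str | os.PathLike, format: str = "tsv",
               mapq_min: int = DEFAULT_MAPQ_MIN,
               assembly: Assembly | None = None) -> Iterator[AlignedPair]:
    """Stream aligned Hi-C pairs, keeping those with both mapq >= mapq_min.

    ``format`` is one of ``tsv`` (canonical 6-column dialect:
    contig1 pos1 contig2 pos2 mapq1 mapq2, positions 0-based), ``bed``
    (interval pairs on consecutive lines) or ``bam`` (also accepts SAM).
    When ``assembly`` is given, contig names and positions are validated.
    """
    readers = {"tsv": _read_pairs_tsv, "bed": _read_pairs_bed, "bam": _read_pairs_bam}
    if format not in readers:
        raise ValueError(f"unknown pairs format {format!r}")
    return readers[format](path, mapq_min, assembly)


def sniff_pairs_format(path: str | os.PathLike) -> str:
    p = str(path)
    if p.endswith((".bam", ".sam")):
        return "bam"
    if p.endswith(".bed"):
        return "bed"
    return "tsv"


class PairTable:
    """Column-oriented store of Hi-C pairs for vectorized processing.

    Contigs are referenced by index into ``names``; pairs are canonical,
    i.e. (cid1, pos1) <= (cid2, pos2) in (index, position) order.
    """

    def __init__(self, names: Sequence[str], cid1, pos1, cid2, pos2) -> None:
        self.names = list(names)
        cid1 = np.asarray(cid1, dtype=np.int64)
        pos1 = np.asarray(pos1, dtype=np.int64)
        cid2 = np.asarray(cid2, dtype=np.int64)
        pos2 = np.asarray(pos2, dtype=np.int64)
        swap = (cid1 > cid2) | ((cid1 == cid2) & (pos1 > pos2))
        self.cid1 = np.where(swap, cid2, cid1)
        self.pos1 = np.where(swap, pos2, pos1)
        self.cid2 = np.where(swap, cid1, cid2)
        self.pos2 = np.where(swap, pos1, pos2)

    def __len__(self) -> int:
        return len(self.cid1)

    @property
    def n(self) -> int:
        return len(self.cid1)

    @classmethod
    def from_aligned_pairs(cls, pairs: Iterable[AlignedPair],
                           names: Sequence[str]) -> "PairTable":
        idx = {n: i for i, n in enumerate(names)}
        c1, p1, c2, p2 = [], [], [], []
        for pr in pairs:
            c1.append(idx[pr.contig1])
            p1.append(pr.pos1)
            c2.append(idx[pr.contig2])
            p2.append(pr.pos2)
        return cls(names, c1, p1, c2, p2)

    def subset(self, mask) -> "PairTable":
        return PairTable(self.names, self.cid1[mask], self.pos1[mask],
                         self.cid2[mask], self.pos2[mask])

    def iter_pairs(self, mapq: int = 60) -> Iterator[AlignedPair]:
        for i in range(self.n):
            yield AlignedPair.make(
                self.names[self.cid1[i]], int(self.pos1[i]), mapq,
                self.names[self.cid2[i]], int(self.pos2[i]), mapq)


def load_pair_table(path: str | os.PathLike, assembly: Assembly,
                    format: str | None = None,
                    mapq_min: int = DEFAULT_MAPQ_MIN) -> PairTable:
    """Load a pairs file into a :class:`PairTable` indexed on ``assembly``.

    The TSV fast path uses pandas; BED/BAM go through :func:`read_pairs`.
    """
    fmt = format or sniff_pairs_format(path)
    names = assembly.names
    if fmt == "tsv":
        import pandas as pd

        try:
            df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                             names=["c1", "p1", "c2", "p2", "q1", "q2"],
                             dtype={"c1": str, "c2": str})
        except pd.errors.EmptyDataError:
            return PairTable(names, [], [], [], [])
        idx = {n: i for i, n in enumerate(names)}
        for col in ("c1", "c2"):
            unknown = ~df[col].isin(idx)
            if unknown.any():
                bad = df[col][unknown].iloc[0]
                raise FormatError(f"{path}: unknown contig {bad!r}")
        keep = (df["q1"] >= mapq_min) & (df["q2"] >= mapq_min)
        df = df[keep]
        cid1 = df["c1"].map(idx).to_numpy(dtype=np.int64)
        cid2 = df["c2"].map(idx).to_numpy(dtype=np.int64)
        pos1 = df["p1"].to_numpy(dtype=np.int64)
        pos2 = df["p2"].to_numpy(dtype=np.int64)
        lens = np.array([assembly[n].length for n in names])
        if len(df) and (
            (pos1 < 0).any() or (pos1 >= lens[cid1]).any()
            or (pos2 < 0).any() or (pos2 >= lens[cid2]).any()
        ):
            raise FormatError(f"{path}: position out of contig range")
        return PairTable(names, cid1, pos1, cid2, pos2)
    return PairTable.from_aligned_pairs(
        read_pairs(path, fmt, mapq_min=mapq_min, assembly=assembly), names)


def write_pairs(path: str | os.PathLike, table: PairTable, mapq: int = 60) -> None:
    """Write a PairTable in the canonical 6-column TSV dialect."""
    with open(path, "w") as fh:
        for i in range(table.n):
            fh.write(f"{table.names[table.cid1[i]]}\t{table.pos1[i]}\t"
                     f"{table.names[table.cid2[i]]}\t{table.pos2[i]}\t{mapq}\t{mapq}\n")


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------

def write_agp(paths: Sequence[ScaffoldPath], assembly: Assembly,
              gap_len: int = DEFAULT_GAP_LEN) -> str:
    """Serialize scaffold paths as AGP v2.1 text.

    W and U lines alternate within each object; gaps are written as
    ``scaffold`` gaps with ``proximity_ligation`` evidence.
    """
    lines = []
    for path in paths:
        pos = 0  # 0-based running offset within the object
        part = 0
        for k, (cid, orient) in enumerate(path.items):
            if cid not in assembly:
                raise ValueError(f"path {path.name!r}: unknown contig {cid!r}")
            if k > 0:
                part += 1
                lines.append("\t".join([
                    path.name, str(pos + 1), str(pos + gap_len), str(part),
                    "U", str(gap_len), "scaffold", "yes", "proximity_ligation"]))
                pos += gap_len
            ln = assembly[cid].length
            part += 1
            lines.append("\t".join([
                path.name, str(pos + 1), str(pos + ln), str(part),
                "W", cid, "1", str(ln), orient]))
            pos += ln
    return "\n".join(lines) + ("\n" if lines else "")


def read_agp(text: str) -> list[ScaffoldPath]:
    """Parse AGP text back into scaffold paths, validating the tiling."""
    paths: dict[str, ScaffoldPath] = {}
    expected_beg: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise FormatError(f"AGP line {lineno}: expected 9 columns, got {len(f)}")
        obj, obeg, oend, _part, ctype = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
        if obj not in paths:
            paths[obj] = ScaffoldPath(obj, [])
            expected_beg[obj] = 1
        if obeg != expected_beg[obj]:
            raise FormatError(f"AGP line {lineno}: object {obj!r} does not tile "
                              f"(expected begin {expected_beg[obj]}, got {obeg})")
        if oend < obeg:
            raise FormatError(f"AGP line {lineno}: end < begin")
        expected_beg[obj] = oend + 1
        if ctype == "W":
            cid, cbeg, cend, orient = f[5], int(f[6]), int(f[7]), f[8]
            if cend - cbeg != oend - obeg:
                raise FormatError(f"AGP line {lineno}: component span mismatch")
            if orient not in ("+", "-"):
                raise FormatError(f"AGP line {lineno}: bad orientation {orient!r}")
            paths[obj].items.append((cid, orient))
        elif ctype in ("U", "N"):
            if int(f[5]) != oend - obeg + 1:
                raise FormatError(f"AGP line {lineno}: gap length != declared span")
        else:
            raise FormatError(f"AGP line {lineno}: unsupported component type {ctype!r}")
    return list(paths.values())


def emit_scaffold_fasta(paths: Sequence[ScaffoldPath], assembly: Assembly,
                        gap_len: int = DEFAULT_GAP_LEN, width: int = 60) -> str:
    """Render scaffold sequences: oriented contigs joined by runs of N."""
    out = []
    gap = "N" * gap_len
    for path in paths:
        parts = []
        for cid, orient in path.items:
            contig = assembly[cid]
            if contig.sequence is None:
                raise ValueError(f"contig {cid!r} has no sequence")
            parts.append(contig.sequence if orient == "+" else revcomp(contig.sequence))
        seq = gap.join(parts)
        out.append(f">{path.name}")
        out.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + ("\n" if out else "")


def flatten_paths(paths: Sequence[ScaffoldPath], assembly: Assembly,
                  gap_len: int = DEFAULT_GAP_LEN) -> Assembly:
    """Turn scaffold paths into a new assembly of flattened sequence units.

    Gap intervals are recorded in ``Assembly.gaps`` so later rounds can
    exclude gap-containing chunks from profile estimation. Sequences are
    carried over only if every member contig has one.
    """
    with_seq = assembly.has_sequences()
    contigs = []
    gaps: dict[str, list[tuple[int, int]]] = {}
    for path in paths:
        pos = 0
        ivals: list[tuple[int, int]] = []
        parts: list[str] = []
        for k, (cid, orient) in enumerate(path.items):
            if k > 0:
                ivals.append((pos, pos + gap_len))
                pos += gap_len
                if with_seq:
                    parts.append("N" * gap_len)
            c = assembly[cid]
            if with_seq:
                parts.append(c.sequence if orient == "+" else revcomp(c.sequence))
            pos += c.length
        contigs.append(Contig(path.name, pos, "".join(parts) if with_seq else None))
        if ivals:
            gaps[path.name] = ivals
    return Assembly(contigs, gaps=gaps)
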