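"""Scoring of candidate contig joins from expectation-normalized contacts.

A join of contigs A and B in a given orientation implies, for every inter
cell between them, a chunk separation d = a + b + 1 where a and b are the
chunk distances from the joining ends. Over the band d <= D_max the score
is sum(obs) / sum(E(d)) — the E(d)-weighted mean of obs/E ratios — so a
truly adjacent pair scores near 1 and an unrelated pair near 0. Partial
trailing chunks have their observed counts rescaled to full-chunk scale.

Orientation codes name the joining ends: H is the coordinate-0 end of a
contig, T the high-coordinate end; "TH" joins A's tail to B's head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_matrix import ContactMatrix, ExpectedProfile

__all__ = [
    "ORIENTATIONS",
    "JoinScore",
    "reverse_orientation",
    "orientation_score",
    "best_join",
    "score_all",
    "DEFAULT_MIN_PAIRS",
]

# tie-break order for best_join
ORIENTATIONS = ("TH", "HT", "TT", "HH")

DEFAULT_MIN_PAIRS = 5


def reverse_orientation(code: str) -> str:
    """Orientation of the same join read from the other contig's side."""
    return code[1] + code[0]


@dataclass(frozen=True)
class JoinScore:
    contig_a: str
    contig_b: str
    orientation: str  # end of contig_a paired with end of contig_b
    score: float
    n_cells: int

    def ends(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.contig_a, self.orientation[0]), (self.contig_b, self.orientation[1])


def _band_expectation(n_a: int, n_b: int, profile: ExpectedProfile) -> tuple[float, int]:
    """Sum of E(d) and cell count over the band {(a,b): a+b+1 <= D_max}."""
    e_sum = 0.0
    n_cells = 0
    top = min(profile.D_max, n_a + n_b - 1)
    for d in range(1, top + 1):
        lo = max(0, d - n_b)
        hi = min(n_a - 1, d - 1)
        cnt = hi - lo + 1
        if cnt > 0:
            e_sum += profile.expected(d) * cnt
            n_cells += cnt
    return e_sum, n_cells


def orientation_score(matrix: ContactMatrix, profile: ExpectedProfile,
                      contig_a: str, contig_b: str, orientation: str) -> JoinScore:
    """Score one oriented join of two distinct contigs."""
    if contig_a == contig_b:
        raise ValueError(f"self-join of contig {contig_a!r} is not allowed")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    idx = matrix.index
    ia = idx.name_to_idx[contig_a]
    ib = idx.name_to_idx[contig_b]
    n_a = int(idx.n_chunks[ia])
    n_b = int(idx.n_chunks[ib])

    lo, hi = (ia, ib) if ia < ib else (ib, ia)
    oi, oj, vals = matrix.inter_cells(lo, hi)
    # ordinals for contig_a / contig_b respectively
    if ia < ib:
        ord_a, ord_b = oi, oj
    else:
        ord_a, ord_b = oj, oi

    end_a, end_b = orientation
    a = (n_a - 1 - ord_a) if end_a == "T" else ord_a
    b = (n_b - 1 - ord_b) if end_b == "T" else ord_b
    d = a + b + 1
    in_band = d <= profile.D_max
    obs = 0.0
    if np.any(in_band):
        res = float(idx.resolution)
        scale = (res / idx.chunk_len[idx.offsets[ia] + ord_a[in_band]]) * \
                (res / idx.chunk_len[idx.offsets[ib] + ord_b[in_band]])
        obs = float(np.sum(vals[in_band] * scale))

    e_sum, n_cells = _band_expectation(n_a, n_b, profile)
    score = obs / e_sum if e_sum > 0 else 0.0
    return JoinScore(contig_a, contig_b, orientation, score, n_cells)


def best_join(matrix: ContactMatrix, profile: ExpectedProfile,
              contig_a: str, contig_b: str) -> JoinScore:
    """Highest-scoring of the four orientations; ties broken by the fixed
    orientation order TH, HT, TT, HH, with contigs in lexicographic order."""
    if contig_b < contig_a:
        contig_a, contig_b = contig_b, contig_a
    best = None
    for code in ORIENTATIONS:
        js = orientation_score(matrix, profile, contig_a, contig_b, code)
        if best is None or js.score > best.score:
            best = js
    return best


def score_all(matrix: ContactMatrix, profile: ExpectedProfile,
              min_pairs: int = DEFAULT_MIN_PAIRS,
              raw_matrix: ContactMatrix | None = None) -> list[JoinScore]:
    """Best join for every contig pair sharing >= min_pairs raw contacts.

    ``raw_matrix`` supplies the gating counts when ``matrix`` has been
    site-normalized; by default the scoring matrix itself is used. Output
    is sorted by descending score, then lexicographic contig pair.
    """
    gate = (raw_matrix if raw_matrix is not None else matrix).inter_pair_mass()
    names = matrix.index.names
    out = []
    for (ci, cj), mass in sorted(gate.items()):
        if mass < min_pairs:
            continue
        a, b = names[ci], names[cj]
        if b < a:
            a, b = b, a
        out.append(best_join(matrix, profile, a, b))
    out.sort(key=lambda js: (-js.score, js.contig_a, js.contig_b))
    return out


def scores_tsv(scores: list[JoinScore]) -> str:
    lines = [f"{js.contig_a}\t{js.contig_b}\t{js.orientation}\t"
             f"{js.score:.6g}\t{js.n_cells}" for js in scores]
    return "\n".join(lines) + ("\n" if lines else "")
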