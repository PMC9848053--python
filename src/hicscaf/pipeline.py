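"""Hierarchical multi-round scaffolding orchestration.

Optional pre-scaffolding contig correction, then one scaffolding round per
resolution-ladder entry (ascending chunk size). Each round bins the pairs
over the current sequence units, estimates the expected profile, scores
joins, builds and simplifies the graph and traverses paths; the paths are
flattened into the next round's units and the pairs are lifted into their
coordinates. An optional post-scaffolding check dissolves joins with
insufficient bridging coverage. Everything is deterministic for a fixed
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import error_correction as ec
from .contact_matrix import (ChunkIndex, ProfileError, build_matrix,
                             expected_profile, site_normalize)
from .formats_io import (Assembly, PairTable, ScaffoldPath, emit_scaffold_fasta,
                         flatten_paths, write_agp)
from .join_scoring import score_all
from .scaffold_graph import build_graph, run_cascade, traverse

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run", "run_round", "lift_pairs", "DEFAULT_LADDER"]

DEFAULT_LADDER = [10_000, 20_000, 50_000, 100_000, 200_000, 500_000,
                  1_000_000, 2_000_000, 5_000_000]


@dataclass(frozen=True)
class RunConfig:
    resolutions: tuple[int, ...] = tuple(DEFAULT_LADDER)
    scale: float = 1.0  # multiplies every ladder entry (desk-scale runs)
    mapq_min: int = 10
    motifs: tuple[str, ...] | None = None
    # contact matrix / profile
    min_support: int = 8
    d_cap: int = 32
    # scoring / graph
    min_pairs: int = 5
    min_score: float = 0.1
    max_tip_contigs: int = 1
    repeat_factor: float = 2.0
    max_bubble_edges: int = 3
    orientation_ratio: float = 1.5
    weak_theta: float = 0.75
    # error correction
    pre_correct: bool = True
    post_check: bool = True
    window: int = 1_000
    max_span: int = 1_000_000
    # breakpoint detection uses a short span so that pairs whose true loci
    # are far apart cannot mask a misjoin valley; in units of `window`
    break_span_windows: int = 10
    # bridging span for the post-scaffolding join check (windows)
    join_span_windows: int = 100
    flank_windows: int = 10
    min_cov_ratio: float = 0.1
    end_guard_windows: int = 5
    min_join_ratio: float = 0.1
    # output
    gap_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = self.ladder()
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("resolution ladder must be strictly increasing")

    def ladder(self) -> list[int]:
        return [max(1, int(round(r * self.scale))) for r in self.resolutions]

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """key=value config file; lists are comma-separated."""
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key in ("resolutions", "motifs"):
                    items = [v.strip() for v in value.split(",") if v.strip()]
                    kwargs[key] = tuple(int(v) for v in items) if key == "resolutions" \
                        else tuple(items)
                elif key in ("pre_correct", "post_check"):
                    kwargs[key] = value.lower() in ("1", "true", "yes", "on")
                elif key in ("scale", "min_score", "repeat_factor", "orientation_ratio",
                             "weak_theta", "min_cov_ratio", "min_join_ratio"):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class RunResult:
    paths: list[ScaffoldPath]          # final scaffolds over corrected contigs
    assembly: Assembly                 # corrected contig assembly
    breaks: list[ec.BreakPoint]        # pre- and post-scaffolding breaks
    round_stats: list[dict] = field(default_factory=list)

    def agp(self, gap_len: int = 200) -> str:
        return write_agp(self.paths, self.assembly, gap_len)

    def fasta(self, gap_len: int = 200) -> str:
        return emit_scaffold_fasta(self.paths, self.assembly, gap_len)

    def breaks_tsv(self) -> str:
        lines = [f"{b.contig}\t{b.position}\t{b.kind}\t{b.evidence:.6g}"
                 for b in self.breaks]
        return "\n".join(lines) + ("\n" if lines else "")


def lift_pairs(pairs: PairTable, paths: Sequence[ScaffoldPath], assembly: Assembly,
               gap_len: int) -> PairTable:
    """Re-address pairs from contig coordinates to scaffold coordinates.

    Every contig must be placed by exactly one path; '-' placements flip
    positions; pair count is conserved and gap positions are unreachable.
    """
    placement: dict[str, tuple[int, int, str]] = {}  # cid -> (path idx, offset, orient)
    names = [p.name for p in paths]
    for pi, path in enumerate(paths):
        off = 0
        for k, (cid, orient) in enumerate(path.items):
            if k > 0:
                off += gap_len
            if cid in placement:
                raise ValueError(f"contig {cid!r} placed twice")
            placement[cid] = (pi, off, orient)
            off += assembly[cid].length

    n_old = len(pairs.names)
    new_cid_of = np.empty(n_old, dtype=np.int64)
    offset_of = np.empty(n_old, dtype=np.int64)
    flip_of = np.empty(n_old, dtype=bool)
    len_of = np.empty(n_old, dtype=np.int64)
    for i, cid in enumerate(pairs.names):
        if cid not in placement:
            raise ValueError(f"contig {cid!r} not placed by any path")
        pi, off, orient = placement[cid]
        new_cid_of[i] = pi
        offset_of[i] = off
        flip_of[i] = orient == "-"
        len_of[i] = assembly[cid].length

    def lift_side(cid_arr, pos_arr):
        fwd = offset_of[cid_arr] + pos_arr
        rev = offset_of[cid_arr] + len_of[cid_arr] - 1 - pos_arr
        return new_cid_of[cid_arr], np.where(flip_of[cid_arr], rev, fwd)

    c1, p1 = lift_side(pairs.cid1, pairs.pos1)
    c2, p2 = lift_side(pairs.cid2, pairs.pos2)
    return PairTable(names, c1, p1, c2, p2)


def run_round(assembly: Assembly, pairs: PairTable, resolution: int,
              config: RunConfig) -> tuple[list[ScaffoldPath], dict]:
    """One scaffolding round at a single resolution.

    On profile failure the round is skipped: every unit passes through as
    a singleton path.
    """
    index = ChunkIndex(assembly, resolution)
    matrix = build_matrix(pairs, index)
    stats: dict = {"resolution": resolution, "units_in": len(assembly)}
    try:
        if config.motifs:
            scoring_matrix = site_normalize(matrix, assembly, list(config.motifs))
        else:
            scoring_matrix = matrix
        profile = expected_profile(scoring_matrix, config.min_support, config.d_cap)
    except ProfileError as exc:
        logger.warning("round at resolution %d skipped: %s", resolution, exc)
        stats["skipped"] = str(exc)
        paths = [ScaffoldPath(f"round_passthrough_{i}", [(c.id, "+")])
                 for i, c in enumerate(assembly, 1)]
        return paths, stats

    scores = score_all(scoring_matrix, profile, config.min_pairs, raw_matrix=matrix)
    graph = build_graph(scores, config.min_score, contigs=assembly.names)
    cascade = run_cascade(
        graph, matrix,
        max_tip_contigs=config.max_tip_contigs,
        repeat_factor=config.repeat_factor,
        max_bubble_edges=config.max_bubble_edges,
        orientation_ratio=config.orientation_ratio,
        weak_theta=config.weak_theta,
    )
    paths = traverse(graph, assembly)
    stats.update({"d_max": profile.D_max, "candidates": len(scores),
                  "cascade": cascade, "units_out": len(paths)})
    return paths, stats


def _compose(path: ScaffoldPath, members: dict[str, list[tuple[str, str]]]) -> list[tuple[str, str]]:
    flip = {"+": "-", "-": "+"}
    items: list[tuple[str, str]] = []
    for unit, orient in path.items:
        part = members[unit]
        if orient == "+":
            items.extend(part)
        else:
            items.extend((cid, flip[o]) for cid, o in reversed(part))
    return items


def run(assembly: Assembly, pairs: PairTable, config: RunConfig) -> RunResult:
    """Full pipeline: optional correction, the resolution ladder, optional
    post-scaffold join check; scaffolds named by descending length."""
    breaks: list[ec.BreakPoint] = []
    if config.pre_correct:
        profiles = ec.spanning_coverage_all(
            pairs, assembly, config.window,
            max_span=config.break_span_windows * config.window)
        for name in assembly.names:
            breaks.extend(ec.find_breakpoints(
                profiles[name],
                flank=config.flank_windows * config.window,
                min_ratio=config.min_cov_ratio,
                end_guard=config.end_guard_windows * config.window))
        if breaks:
            assembly, lift = ec.apply_breaks(assembly, breaks)
            pairs = lift.lift_table(pairs)
        logger.info("pre-scaffolding correction: %d breaks", len(breaks))

    base_assembly = assembly
    base_pairs = pairs
    # members: current unit -> ordered oriented list of base contigs
    members = {c.id: [(c.id, "+")] for c in base_assembly}
    round_stats = []
    cur_assembly = base_assembly
    cur_pairs = base_pairs
    for resolution in config.ladder():
        if len(cur_assembly) <= 1:
            break
        paths, stats = run_round(cur_assembly, cur_pairs, resolution, config)
        round_stats.append(stats)
        if "skipped" in stats:
            continue
        members = {p.name: _compose(p, members) for p in paths}
        cur_pairs = lift_pairs(cur_pairs, paths, cur_assembly, config.gap_len)
        cur_assembly = flatten_paths(paths, cur_assembly, config.gap_len)
        logger.info("round r=%d: %d -> %d units", resolution,
                    stats["units_in"], stats["units_out"])

    final_paths = [ScaffoldPath(name, items) for name, items in members.items()]

    if config.post_check and final_paths:
        post = ec.post_scaffold_check(final_paths, base_pairs, base_assembly,
                                      gap_len=config.gap_len,
                                      max_span=config.join_span_windows * config.window,
                                      min_join_ratio=config.min_join_ratio)
        if post:
            final_paths = ec.dissolve_joins(final_paths, post)
            breaks.extend(post)
        logger.info("post-scaffolding check: %d joins dissolved", len(post))

    lengths = base_assembly.lengths
    final_paths.sort(key=lambda p: (-p.length(lengths, config.gap_len), p.items))
    final_paths = [ScaffoldPath(f"scaffold_{i}", p.items)
                   for i, p in enumerate(final_paths, 1)]
    return RunResult(final_paths, base_assembly, breaks, round_stats)
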