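"""Scaffolding graph construction, simplification cascade and traversal.

Nodes are contig ends — (contig id, 'H') for the coordinate-0 end and
(contig id, 'T') for the high-coordinate end — with an implicit internal
H–T link through each contig. Join edges connect ends of different
contigs and carry the join score. The simplification cascade runs, in
order: low-score filtering (at build time), tip trimming, blunt-end
trimming, repeat solving, transitive-edge removal, bubble popping,
orientation resolution, weak-edge trimming and ambiguous-edge removal;
afterwards every end has degree <= 1 and the graph decomposes into simple
paths that are traversed into scaffolds.

Every operation only deletes edges, never adds them.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .contact_matrix import ContactMatrix
from .formats_io import Assembly, ScaffoldPath
from .join_scoring import JoinScore

__all__ = [
    "End",
    "ScaffoldGraph",
    "build_graph",
    "trim_tips",
    "trim_blunt_ends",
    "solve_repeats",
    "remove_transitive",
    "pop_bubbles",
    "resolve_orientations",
    "trim_weak_edges",
    "drop_ambiguous",
    "traverse",
    "run_cascade",
    "DEFAULTS",
]

End = tuple[str, str]  # (contig id, 'H' | 'T')

DEFAULTS = {
    "min_score": 0.1,
    "max_tip_contigs": 1,
    "repeat_factor": 2.0,
    "max_bubble_edges": 3,
    "orientation_ratio": 1.5,
    "weak_theta": 0.75,
}


def other_end(end: End) -> End:
    return (end[0], "T" if end[1] == "H" else "H")


def _canon(u: End, v: End) -> tuple[End, End]:
    return (u, v) if u <= v else (v, u)


class ScaffoldGraph:
    """Undirected edge-weighted graph over contig ends."""

    def __init__(self, contigs: Iterable[str] = ()) -> None:
        self.contigs: set[str] = set(contigs)
        self._adj: dict[End, dict[End, float]] = {}

    def copy(self) -> "ScaffoldGraph":
        g = ScaffoldGraph(self.contigs)
        g._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        return g

    def add_edge(self, u: End, v: End, score: float) -> None:
        if u[0] == v[0]:
            raise ValueError(f"self-edge on contig {u[0]!r}")
        if v in self._adj.get(u, ()):
            raise ValueError(f"duplicate edge {u}—{v}")
        self._adj.setdefault(u, {})[v] = score
        self._adj.setdefault(v, {})[u] = score
        self.contigs.add(u[0])
        self.contigs.add(v[0])

    def remove_edge(self, u: End, v: End) -> None:
        del self._adj[u][v]
        del self._adj[v][u]
        if not self._adj[u]:
            del self._adj[u]
        if not self._adj[v]:
            del self._adj[v]

    def has_edge(self, u: End, v: End) -> bool:
        return v in self._adj.get(u, ())

    def score(self, u: End, v: End) -> float:
        return self._adj[u][v]

    def degree(self, end: End) -> int:
        return len(self._adj.get(end, ()))

    def neighbors(self, end: End) -> list[End]:
        return sorted(self._adj.get(end, ()))

    def ends(self) -> list[End]:
        return sorted(self._adj)

    def edges(self) -> list[tuple[End, End, float]]:
        out = []
        for u, nbrs in self._adj.items():
            for v, s in nbrs.items():
                if u <= v:
                    out.append((u, v, s))
        out.sort()
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(n) for n in self._adj.values()) // 2

    def max_score_at(self, end: End) -> float:
        nbrs = self._adj.get(end)
        return max(nbrs.values()) if nbrs else 0.0

    def to_dot(self) -> str:
        """GraphViz text dump for stage-by-stage debugging."""
        lines = ["graph scaffolding {"]
        for u, v, s in self.edges():
            lines.append(f'  "{u[0]}.{u[1]}" -- "{v[0]}.{v[1]}" [label="{s:.3g}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_graph(scores: Sequence[JoinScore], min_score: float = DEFAULTS["min_score"],
                contigs: Iterable[str] = ()) -> ScaffoldGraph:
    """One edge per JoinScore with score >= min_score, connecting the
    oriented ends. Duplicate (end, end) edges indicate an upstream bug."""
    g = ScaffoldGraph(contigs)
    for js in scores:
        if js.score >= min_score:
            ea, eb = js.ends()
            g.add_edge(ea, eb, js.score)
    return g


# ---------------------------------------------------------------------------
# simplification cascade
# ---------------------------------------------------------------------------

def _branch_is_tip(g: ScaffoldGraph, junction: End, first: End, max_tip: int) -> bool:
    """Does the branch entered through edge junction—first dead-end within
    max_tip contigs without meeting another junction or a cycle?"""
    if g.degree(first) >= 2:
        return False
    seen = {first[0]}
    count = 1
    far = other_end(first)
    while True:
        if count > max_tip:
            return False
        nbrs = g.neighbors(far)
        if not nbrs:
            return True
        if len(nbrs) >= 2:
            return False
        nxt = nbrs[0]
        if nxt == junction or nxt[0] == junction[0] or nxt[0] in seen:
            return False  # loops back
        if g.degree(nxt) >= 2:
            return False  # merges into a junction
        seen.add(nxt[0])
        count += 1
        far = other_end(nxt)


def trim_tips(g: ScaffoldGraph, max_tip_contigs: int = DEFAULTS["max_tip_contigs"]) -> ScaffoldGraph:
    """At each junction end, delete edges into short dead-end branches.

    Tip edges are removed one at a time in ascending (score, end) order
    while the junction still has degree >= 2, so at least one branch —
    the strongest, when all of them are tips — always survives. Iterates
    to a fixpoint over the whole graph.
    """
    changed = True
    while changed:
        changed = False
        for u in g.ends():
            while g.degree(u) >= 2:
                tips = [v for v in g.neighbors(u)
                        if _branch_is_tip(g, u, v, max_tip_contigs)]
                if not tips:
                    break
                v = min(tips, key=lambda v: (g.score(u, v), v))
                g.remove_edge(u, v)
                changed = True
    return g


def trim_blunt_ends(g: ScaffoldGraph) -> ScaffoldGraph:
    """Single pass: delete every edge that is the best at neither endpoint."""
    best = {end: g.max_score_at(end) for end in g.ends()}
    doomed = [(u, v) for u, v, s in g.edges() if s < best[u] and s < best[v]]
    for u, v in doomed:
        g.remove_edge(u, v)
    return g


def solve_repeats(g: ScaffoldGraph, matrix: ContactMatrix,
                  repeat_factor: float = DEFAULTS["repeat_factor"]) -> ScaffoldGraph:
    """Isolate contigs whose contact density (matrix mass touching the
    contig per bp) exceeds repeat_factor times the median density."""
    import numpy as np

    idx = matrix.index
    density = matrix.contig_mass() / idx.lengths
    med = float(np.median(density))
    flagged = [idx.names[i] for i in range(len(idx.names))
               if density[i] > repeat_factor * med]
    for cid in sorted(flagged):
        for side in ("H", "T"):
            end = (cid, side)
            for v in g.neighbors(end):
                g.remove_edge(end, v)
    return g


def remove_transitive(g: ScaffoldGraph) -> ScaffoldGraph:
    """Delete direct edges u—w shortcutting a consistent two-step chain
    u—v' .. v''—w through some contig v (v', v'' its opposite ends)."""
    doomed: set[tuple[End, End]] = set()
    for cid in sorted(g.contigs):
        near, far = (cid, "H"), (cid, "T")
        for u in g.neighbors(near):
            for w in g.neighbors(far):
                if u[0] == w[0]:
                    continue
                if g.has_edge(u, w):
                    doomed.add(_canon(u, w))
    for u, v in sorted(doomed):
        if g.has_edge(u, v):
            g.remove_edge(u, v)
    return g


def _scaffold_paths_between(g: ScaffoldGraph, u: End, w: End,
                            max_edges: int) -> list[list[tuple[End, End]]]:
    """All simple scaffold paths (alternating join edges and contig
    traversals) from end u to end w using <= max_edges join edges."""
    results: list[list[tuple[End, End]]] = []

    def dfs(cur: End, edges: list[tuple[End, End]], seen: frozenset[str]) -> None:
        if len(edges) >= max_edges:
            return
        for nxt in g.neighbors(cur):
            edge = _canon(cur, nxt)
            if edge in edges:
                continue
            if nxt == w:
                results.append(edges + [edge])
                continue
            if nxt[0] in seen or nxt[0] == w[0]:
                continue
            dfs(other_end(nxt), edges + [edge], seen | {nxt[0]})

    dfs(u, [], frozenset({u[0]}))
    return results


def pop_bubbles(g: ScaffoldGraph, max_bubble_edges: int = DEFAULTS["max_bubble_edges"]) -> ScaffoldGraph:
    """Where edge-disjoint alternative paths connect the same pair of ends,
    keep the path with the highest minimum edge score (ties: keep the
    lexicographically earlier path) and delete the edges of the others."""
    ends = g.ends()
    for i, u in enumerate(ends):
        for w in ends[i + 1:]:
            if w[0] == u[0]:
                continue
            if g.degree(u) == 0 or g.degree(w) == 0:
                continue
            paths = _scaffold_paths_between(g, u, w, max_bubble_edges)
            if len(paths) < 2:
                continue

            def rank(path):
                return (-min(g.score(a, b) for a, b in path), path)

            paths.sort(key=rank)
            kept = set(paths[0])
            for path in paths[1:]:
                if kept.isdisjoint(path):
                    for a, b in path:
                        if g.has_edge(a, b):
                            g.remove_edge(a, b)
    return g


def resolve_orientations(g: ScaffoldGraph, ratio: float = DEFAULTS["orientation_ratio"]) -> ScaffoldGraph:
    """When a contig pair is connected through several end combinations,
    keep the best only if it dominates by >= ratio, else drop them all."""
    by_pair: dict[tuple[str, str], list[tuple[float, End, End]]] = {}
    for u, v, s in g.edges():
        key = tuple(sorted((u[0], v[0])))
        by_pair.setdefault(key, []).append((s, u, v))
    for key in sorted(by_pair):
        group = by_pair[key]
        if len(group) < 2:
            continue
        group.sort(key=lambda t: (-t[0], t[1], t[2]))
        best, second = group[0][0], group[1][0]
        if best >= ratio * second:
            doomed = group[1:]
        else:
            doomed = group
        for _, u, v in doomed:
            if g.has_edge(u, v):
                g.remove_edge(u, v)
    return g


def trim_weak_edges(g: ScaffoldGraph, theta: float = DEFAULTS["weak_theta"]) -> ScaffoldGraph:
    """Single pass against endpoint maxima computed up front: drop edge e
    when score(e) < theta * max score among edges at either endpoint."""
    best = {end: g.max_score_at(end) for end in g.ends()}
    doomed = [(u, v) for u, v, s in g.edges() if s < theta * max(best[u], best[v])]
    for u, v in doomed:
        g.remove_edge(u, v)
    return g


def drop_ambiguous(g: ScaffoldGraph) -> ScaffoldGraph:
    """Final pass: every end still holding >= 2 edges loses all of them."""
    ambiguous = [end for end in g.ends() if g.degree(end) >= 2]
    for end in ambiguous:
        for v in g.neighbors(end):
            g.remove_edge(end, v)
    return g


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------

def _walk(g: ScaffoldGraph, start: End, visited: set[str]) -> list[tuple[str, str]]:
    items = []
    cur = start  # the end through which we enter the current contig
    while True:
        cid, side = cur
        visited.add(cid)
        items.append((cid, "+" if side == "H" else "-"))
        nbrs = g.neighbors(other_end(cur))
        if not nbrs or nbrs[0][0] in visited:
            return items
        cur = nbrs[0]


def traverse(g: ScaffoldGraph, contigs: Assembly | dict[str, int]) -> list[ScaffoldPath]:
    """Walk the fully simplified graph into scaffold paths.

    Requires max end-degree 1. Isolated contigs become singleton paths;
    cycles are broken at their minimum-score edge. Scaffolds are named
    scaffold_1.. by descending length (gaps excluded), deterministically.
    """
    for end in g.ends():
        if g.degree(end) > 1:
            raise ValueError(f"end {end} has degree {g.degree(end)}; "
                             "run the simplification cascade first")
    lengths = contigs.lengths if isinstance(contigs, Assembly) else dict(contigs)
    for cid in g.contigs:
        if cid not in lengths:
            raise ValueError(f"graph references unknown contig {cid!r}")

    visited: set[str] = set()
    raw: list[list[tuple[str, str]]] = []

    # termini: free ends of contigs whose other end is linked
    starts = sorted(end for cid in lengths
                    for end in ((cid, "H"), (cid, "T"))
                    if g.degree(end) == 0 and g.degree(other_end(end)) == 1)
    for start in starts:
        if start[0] not in visited:
            raw.append(_walk(g, start, visited))

    # cycles: remaining contigs with both ends linked
    remaining = sorted(cid for cid in lengths
                       if cid not in visited and g.degree((cid, "H")) == 1)
    for cid in remaining:
        if cid in visited:
            continue
        # collect the cycle's edges starting from this contig
        cycle_edges = []
        cur = (cid, "H")
        while True:
            nxt = g.neighbors(other_end(cur))[0]
            cycle_edges.append(_canon(other_end(cur), nxt))
            cur = nxt
            if cur[0] == cid:
                break
        u, v = min(cycle_edges, key=lambda e: (g.score(*e), e))
        g.remove_edge(u, v)
        raw.append(_walk(g, min(u, v), visited))

    # isolated contigs
    for cid in sorted(lengths):
        if cid not in visited:
            visited.add(cid)
            raw.append([(cid, "+")])

    raw.sort(key=lambda items: (-sum(lengths[c] for c, _ in items), items))
    return [ScaffoldPath(f"scaffold_{i}", items) for i, items in enumerate(raw, 1)]


def run_cascade(g: ScaffoldGraph, matrix: ContactMatrix, *,
                max_tip_contigs: int = DEFAULTS["max_tip_contigs"],
                repeat_factor: float = DEFAULTS["repeat_factor"],
                max_bubble_edges: int = DEFAULTS["max_bubble_edges"],
                orientation_ratio: float = DEFAULTS["orientation_ratio"],
                weak_theta: float = DEFAULTS["weak_theta"]) -> dict[str, int]:
    """Apply the full simplification cascade in its fixed order, mutating
    ``g``; returns edge counts after each stage for logging."""
    stats = {"built": g.n_edges}
    trim_tips(g, max_tip_contigs)
    stats["tips"] = g.n_edges
    trim_blunt_ends(g)
    stats["blunt"] = g.n_edges
    solve_repeats(g, matrix, repeat_factor)
    stats["repeats"] = g.n_edges
    remove_transitive(g)
    stats["transitive"] = g.n_edges
    pop_bubbles(g, max_bubble_edges)
    stats["bubbles"] = g.n_edges
    resolve_orientations(g, orientation_ratio)
    stats["orientations"] = g.n_edges
    trim_weak_edges(g, weak_theta)
    stats["weak"] = g.n_edges
    drop_ambiguous(g)
    stats["ambiguous"] = g.n_edges
    return stats
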