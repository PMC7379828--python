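"""Isoform reconstruction by iterative path extension.

Paths in the assembly graph are grown edge by edge.  At each step the
paired-end selector is tried first: it returns a single extension edge only
when one candidate's junction-link support both clears ``min_support`` and
dominates the runner-up.  Only when paired-end evidence does not help does
the long-read selector run: among all candidate edges it keeps every edge
e for which some long-read path in the filtered matching set R_P also
matches the prolonged path P+e.  Selecting several edges forks the path —
one copy per edge — which is precisely how alternatively spliced isoforms
sharing long common stretches are phased apart.

A long-read path R matches the path P being extended when a suffix of P is
a prefix of R, or P occurs inside R preceded by at least one edge.  R_P
additionally requires the longest common contiguous subpath of P and R to
span >= l_min nucleotides and >= n_min edges (both capped at P's own size,
so that single-edge seeds can begin extending at all).

Seeds are unused edges in descending sequence-length order; each branch
grows rightward and then, via its reverse-complement twin, leftward, until
every edge of the graph is contained in at least one path.  Full-length
(FL) read paths bypass extension and are added verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .align import LongReadPath, PairedLink
from .graph import AssemblyGraph

logger = logging.getLogger(__name__)

DEFAULT_L_MIN = 200
DEFAULT_N_MIN = 2
DEFAULT_MIN_SUPPORT = 5
DEFAULT_DOMINANCE = 2.0
DEFAULT_PE_WINDOW = 3
DEFAULT_MAX_FORKS = 16
DEFAULT_MAX_EDGE_MULTIPLICITY = 4


@dataclass(frozen=True)
class EdgePath:
    """An ordered, adjacency-consistent run of edge ids; the unit of
    isoform representation."""

    edges: Tuple[int, ...]
    origin: str = "seeded"  # "seeded" | "fl"

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class MatchingPathSet:
    """The filtered set R_P of long-read paths matching a path ``base``."""

    base: Tuple[int, ...]
    members: Tuple[LongReadPath, ...]
    l_min: int
    n_min: int


@dataclass
class PathSet:
    """The growing collection of reconstructed paths."""

    paths: List[EdgePath] = field(default_factory=list)

    @property
    def covered_edges(self) -> Set[int]:
        out: Set[int] = set()
        for p in self.paths:
            out.update(p.edges)
        return out

    def __len__(self) -> int:
        return len(self.paths)


def is_matching(P: Sequence[int], R: Sequence[int]) -> bool:
    """True iff a suffix of P is a prefix of R, or P occurs inside R
    preceded by >= 1 edge.  Orientation-sensitive; pure function."""
    if not P or not R:
        raise ValueError("is_matching requires nonempty paths")
    P = tuple(P)
    R = tuple(R)
    n = len(P)
    for i in range(n):  # case (i): suffix (p_i..p_n) is a prefix of R
        L = n - i
        if L <= len(R) and P[i:] == R[:L]:
            return True
    for s in range(1, len(R) - n + 1):  # case (ii): containment, l >= 1
        if R[s : s + n] == P:
            return True
    return False


def longest_common_subpath(P: Sequence[int], R: Sequence[int]) -> Tuple[int, ...]:
    """Longest contiguous run of edges shared by P and R (classic
    longest-common-substring DP over edge ids)."""
    n, m = len(P), len(R)
    best_len = 0
    best_end = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        pi = P[i - 1]
        for j in range(1, m + 1):
            if pi == R[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len = cur[j]
                    best_end = i
        prev = cur
    return tuple(P[best_end - best_len : best_end])


def find_matching_paths(
    graph: AssemblyGraph,
    P: Sequence[int],
    lr_paths: Iterable[LongReadPath],
    l_min: int = DEFAULT_L_MIN,
    n_min: int = DEFAULT_N_MIN,
) -> MatchingPathSet:
    """Build R_P: long-read paths matching P whose longest common subpath
    with P spans >= l_min nt and >= n_min edges.

    Subpath nt length follows the graph convention: edge lengths minus a
    (k-1)-nt overlap per junction.  Both thresholds are capped at P's own
    size so short seed paths are extendable.
    """
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if l_min < 0:
        raise ValueError("l_min must be >= 0")
    P = tuple(P)
    n_eff = min(n_min, len(P))
    l_eff = min(l_min, graph.path_nt_length(P))
    pset = set(P)
    last = P[-1]
    members = []
    for R in lr_paths:
        rp = R.path
        if rp[0] not in pset and last not in rp:
            continue  # cannot satisfy either matching case
        if not is_matching(P, rp):
            continue
        sub = longest_common_subpath(P, rp)
        if len(sub) >= n_eff and graph.path_nt_length(sub) >= l_eff:
            members.append(R)
    return MatchingPathSet(P, tuple(members), l_min, n_min)


def select_extension_edges_lr(
    P: Sequence[int], R_P: MatchingPathSet, candidates: Sequence[int]
) -> List[int]:
    """All candidate edges e such that at least one path in R_P matches
    P+e; using only R_P (not all matching paths) keeps spurious extensions
    out.  Deterministic ascending-edge-id order; may be empty or plural."""
    P = tuple(P)
    chosen = []
    for e in sorted(candidates):
        ext = P + (e,)
        if any(is_matching(ext, R.path) for R in R_P.members):
            chosen.append(e)
    return chosen


def select_extension_edge_pe(
    P: Sequence[int],
    link_support: Dict[Tuple[int, int], int],
    candidates: Sequence[int],
    min_support: int = DEFAULT_MIN_SUPPORT,
    dominance: float = DEFAULT_DOMINANCE,
    window: int = DEFAULT_PE_WINDOW,
) -> Optional[int]:
    """Paired-end extension: score each candidate by total link support
    from the last ``window`` edges of P; return the top candidate only if
    it clears ``min_support`` and dominates the runner-up by ``dominance``,
    else None ("paired-end reads do not help")."""
    tail = tuple(P)[-window:]
    scores = []
    for e in sorted(candidates):
        s = sum(link_support.get((u, e), 0) for u in tail)
        scores.append((s, e))
    if not scores:
        return None
    scores.sort(key=lambda t: (-t[0], t[1]))
    top_score, top_edge = scores[0]
    runner = scores[1][0] if len(scores) > 1 else 0
    if top_score >= min_support and top_score >= dominance * runner:
        return top_edge
    return None


@dataclass
class ExtensionConfig:
    l_min: int = DEFAULT_L_MIN
    n_min: int = DEFAULT_N_MIN
    min_support: int = DEFAULT_MIN_SUPPORT
    dominance: float = DEFAULT_DOMINANCE
    pe_window: int = DEFAULT_PE_WINDOW
    max_forks: int = DEFAULT_MAX_FORKS
    max_edge_multiplicity: int = DEFAULT_MAX_EDGE_MULTIPLICITY
    # PE abstains when a candidate edge is too short to have accrued mate
    # placements at all: link scores at such junctions are structurally
    # biased toward the long alternative, exactly where isoform phasing
    # must come from long reads.
    min_pe_edge_len: int = 100


def _grow_right(
    graph: AssemblyGraph,
    start: Tuple[int, ...],
    link_support: Dict[Tuple[int, int], int],
    pool: List[LongReadPath],
    cfg: ExtensionConfig,
    budget: List[int],
    truncated: List[int],
) -> List[Tuple[int, ...]]:
    """Grow a path rightward; fork on plural long-read selections within
    the shared per-seed budget."""
    done: List[Tuple[int, ...]] = []
    stack: List[Tuple[int, ...]] = [start]
    while stack:
        p = stack.pop()
        while True:
            cands = [
                e for e in graph.successors(p[-1])
                if p.count(e) < cfg.max_edge_multiplicity
            ]
            if not cands:
                done.append(p)
                break
            pe_applicable = all(
                len(graph.edges[e].seq) >= cfg.min_pe_edge_len for e in cands
            )
            e_pe = None
            if pe_applicable:
                e_pe = select_extension_edge_pe(
                    p, link_support, cands, cfg.min_support, cfg.dominance, cfg.pe_window
                )
            if e_pe is not None:
                chosen = [e_pe]
            else:
                R_P = find_matching_paths(graph, p, pool, cfg.l_min, cfg.n_min)
                chosen = select_extension_edges_lr(p, R_P, cands)
            if not chosen:
                done.append(p)
                break
            for e in chosen[1:]:
                if budget[0] > 0:
                    budget[0] -= 1
                    stack.append(p + (e,))
                else:
                    truncated[0] += 1
            p = p + (chosen[0],)
    return done


def extend_all_paths(
    graph: AssemblyGraph,
    links: Iterable[PairedLink],
    lr_paths: Iterable[LongReadPath],
    config: Optional[ExtensionConfig] = None,
) -> PathSet:
    """Iteratively extend seed paths with paired-end and long-read evidence
    until every graph edge is included in at least one path.

    Each finished branch is recorded together with its twin path, so edge
    coverage holds literally on both strands; strand-collapsed
    deduplication later keeps one representative per twin pair.
    """
    cfg = config or ExtensionConfig()
    link_support: Dict[Tuple[int, int], int] = {}
    for l in links:
        link_support[(l.edge_a, l.edge_b)] = link_support.get((l.edge_a, l.edge_b), 0) + l.support
    lr_paths = list(lr_paths)
    pool = lr_paths + [
        LongReadPath(r.read_id + "|rc", graph.twin_path(r.path), r.span, r.is_fl)
        for r in lr_paths
    ]
    covered: Set[int] = set()
    result = PathSet()
    truncated = [0]
    seeds = sorted(graph.edge_ids(), key=lambda e: (-len(graph.edges[e].seq), e))
    for seed in seeds:
        if seed in covered:
            continue
        budget = [cfg.max_forks]
        finals: List[Tuple[int, ...]] = []
        for p in _grow_right(graph, (seed,), link_support, pool, cfg, budget, truncated):
            for q in _grow_right(
                graph, graph.twin_path(p), link_support, pool, cfg, budget, truncated
            ):
                finals.append(graph.twin_path(q))
        for p in finals:
            result.paths.append(EdgePath(p, "seeded"))
            result.paths.append(EdgePath(graph.twin_path(p), "seeded"))
            covered.update(p)
            covered.update(graph.twin_path(p))
    if truncated[0]:
        logger.warning("fork budget exhausted %d time(s); branches truncated", truncated[0])
    missing = set(graph.edge_ids()) - result.covered_edges
    if missing:  # cannot happen: every edge is its own seed of last resort
        raise AssertionError(f"edges left uncovered by path extension: {sorted(missing)}")
    return result


def add_fl_paths(result: PathSet, fl_paths: Iterable[LongReadPath], graph: AssemblyGraph) -> PathSet:
    """Append full-length read paths verbatim (origin 'fl'), bypassing
    extension; twins added for strand symmetry."""
    for r in fl_paths:
        result.paths.append(EdgePath(tuple(r.path), "fl"))
        result.paths.append(EdgePath(graph.twin_path(r.path), "fl"))
    return result
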