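"""Read-to-graph alignment.

Short read pairs are placed on edges by shared-anchor counting and turned
into direction-aware paired-edge links; long error-prone reads are aligned
by anchor-and-chain: exact ``anchor_k``-mers shared with edge sequences are
chained colinearly per edge, and chained edges are stitched into a
graph-adjacency-consistent edge path in read order.  Because every edge has
an explicit reverse-complement twin, a single forward scan of the read
covers both strands: a read from the opposite strand chains onto twin
edges, and aligning the reverse complement of a read yields exactly the
reversed twin path.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .graph import AssemblyGraph, revcomp

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR_K = 15
DEFAULT_MIN_ANCHORS = 3
DEFAULT_MAX_SKIP = 2


@dataclass
class PairedLink:
    """A direction-aware junction link: ``support`` read pairs had one mate
    on ``edge_a`` and the other on ``edge_b``, oriented a->b."""

    edge_a: int
    edge_b: int
    support: int
    gap_estimate: float = 0.0


@dataclass
class LongReadPath:
    """The edge path of one long read: consecutive edges are graph-adjacent;
    ``span`` is the anchored read interval (0-based half-open)."""

    read_id: str
    path: Tuple[int, ...]
    span: Tuple[int, int]
    is_fl: bool = False


class AnchorIndex:
    """Exact ``anchor_k``-mer index over all edge sequences (twins included).

    Anchors occurring on more than ``max_occ`` edge positions are dropped as
    repeats; they would contribute ambiguous placements anyway.
    """

    def __init__(self, graph: AssemblyGraph, anchor_k: int = DEFAULT_ANCHOR_K, max_occ: int = 64):
        if anchor_k > graph.k:
            raise ValueError(f"anchor_k={anchor_k} must not exceed graph k={graph.k}")
        self.graph = graph
        self.anchor_k = anchor_k
        index: Dict[str, List[Tuple[int, int]]] = {}
        for eid in graph.edge_ids():
            seq = graph.edges[eid].seq
            for pos in range(len(seq) - anchor_k + 1):
                index.setdefault(seq[pos : pos + anchor_k], []).append((eid, pos))
        self._index = {km: hits for km, hits in index.items() if len(hits) <= max_occ}

    def hits(self, seq: str) -> Dict[int, List[Tuple[int, int]]]:
        """Per-edge (read_pos, edge_pos) anchor pairs for a forward scan."""
        ak = self.anchor_k
        out: Dict[int, List[Tuple[int, int]]] = {}
        get = self._index.get
        for i in range(len(seq) - ak + 1):
            for eid, pos in get(seq[i : i + ak], ()):
                out.setdefault(eid, []).append((i, pos))
        return out


def _best_diagonal_cluster(
    pairs: List[Tuple[int, int]], gap: int = 20
) -> List[Tuple[int, int]]:
    """Largest cluster of anchors on a consistent alignment diagonal.

    Anchors are grouped by read_pos - edge_pos; a true alignment drifts
    gradually (one indel at a time) while anchors inherited from shared
    junction context on a different part of the read jump by the length of
    the intervening sequence, so splitting at diagonal gaps > ``gap``
    separates them."""
    pairs = sorted(pairs, key=lambda p: (p[0] - p[1], p[0]))
    clusters: List[List[Tuple[int, int]]] = [[pairs[0]]]
    for prev, cur in zip(pairs, pairs[1:]):
        if (cur[0] - cur[1]) - (prev[0] - prev[1]) > gap:
            clusters.append([])
        clusters[-1].append(cur)
    return max(clusters, key=lambda c: (len(c), -(c[0][0] - c[0][1])))


def _longest_colinear_chain(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Longest chain with strictly increasing read and edge coordinates,
    restricted to the best diagonal cluster."""
    pairs = sorted(_best_diagonal_cluster(pairs), key=lambda p: (p[0], -p[1]))
    eps = [p[1] for p in pairs]
    tails: List[int] = []
    tails_idx: List[int] = []
    parent = [-1] * len(pairs)
    for i, e in enumerate(eps):
        j = bisect_left(tails, e)
        if j == len(tails):
            tails.append(e)
            tails_idx.append(i)
        else:
            tails[j] = e
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    if not tails_idx:
        return []
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(pairs[i])
        i = parent[i]
    chain.reverse()
    return chain


def _bridge(
    graph: AssemblyGraph,
    a: int,
    b: int,
    max_skip: int,
    max_skip_len: int,
    gap_nt: int,
) -> Optional[List[int]]:
    """Run of <= max_skip short intervening edges connecting a to b whose
    inserted nucleotide length agrees with the read-coordinate gap.

    Among all connections (including direct adjacency, which inserts 0 nt)
    the one closest to ``gap_nt`` wins; if even the best disagrees by more
    than 100 + 0.3*|gap| nt the junction is not bridged (None), so an
    unanchored stretch is never papered over with the wrong branch of a
    bubble."""
    k1 = graph.k - 1
    options: List[Tuple[int, int, List[int]]] = []  # (|gap error|, n_edges, path)
    if graph.adjacent(a, b):
        options.append((abs(gap_nt), 0, []))
    frontier: List[List[int]] = [[a]]
    for _ in range(max_skip):
        nxt: List[List[int]] = []
        for path in frontier:
            for mid in graph.successors(path[-1]):
                if len(graph.edges[mid].seq) > max_skip_len:
                    continue
                cand = path + [mid]
                if graph.adjacent(mid, b):
                    inserted = sum(len(graph.edges[m].seq) - k1 for m in cand[1:])
                    options.append((abs(inserted - gap_nt), len(cand) - 1, cand[1:]))
                nxt.append(cand)
        frontier = nxt
    if not options:
        return None
    options.sort(key=lambda o: (o[0], o[1], o[2]))
    err, _, best = options[0]
    if err > 100 + 0.3 * abs(gap_nt):
        return None
    return best


def align_long_read(
    graph: AssemblyGraph,
    read: str,
    anchor_k: int = DEFAULT_ANCHOR_K,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_skip: int = DEFAULT_MAX_SKIP,
    max_skip_len: Optional[int] = None,
    index: Optional[AnchorIndex] = None,
    read_id: str = "read",
    is_fl: bool = False,
) -> Optional[LongReadPath]:
    """Align one long read to the graph; return its edge path or None.

    Edges with >= ``min_anchors`` colinearly chained anchors become path
    candidates ordered by read coordinate; consecutive candidates must be
    graph-adjacent, directly or through <= ``max_skip`` short (<=
    ``max_skip_len``, default 3k nt) intervening edges, which are inserted
    into the path.  The single best contiguous run (most chained anchors)
    is kept.
    """
    if len(read) < anchor_k:
        return None
    read = read.upper()
    if index is None:
        index = AnchorIndex(graph, anchor_k)
    if max_skip_len is None:
        max_skip_len = 3 * graph.k
    hits = index.hits(read)
    k1 = graph.k - 1
    # candidate: (r_start, r_end, eid, n_anchors, e_start, e_end)
    cands: List[Tuple[int, int, int, int, int, int]] = []
    for eid in sorted(hits):
        chain = _longest_colinear_chain(hits[eid])
        if len(chain) < min_anchors:
            continue
        # at least one anchor must overlap the edge's internal region:
        # anchors lying entirely within the terminal (k-1)-nt vertex
        # context are shared with sibling edges and prove nothing about
        # traversal of this edge
        L = len(graph.edges[eid].seq)
        if not any(p + anchor_k > k1 and p < L - k1 for _, p in chain):
            continue
        cands.append(
            (chain[0][0], chain[-1][0] + anchor_k, eid, len(chain),
             chain[0][1], chain[-1][1] + anchor_k)
        )
    if not cands:
        return None
    # Drop candidates whose anchored read interval lies inside a stronger
    # candidate's interval: anchors inherited from shared junction context
    # produce exactly such contained phantom candidates, whereas a
    # genuinely traversed edge straddles its neighbours' anchor spans.
    cands.sort(key=lambda c: (-c[3], c[0], c[2]))
    filtered: List[Tuple[int, int, int, int, int, int]] = []
    for c in cands:
        if any(kc[0] <= c[0] and c[1] <= kc[1] for kc in filtered):
            continue
        filtered.append(c)
    cands = sorted(filtered)
    runs: List[Tuple[int, List[int], Tuple[int, int]]] = []  # (anchors, path, span)
    cur_path = [cands[0][2]]
    cur_anchors = cands[0][3]
    cur_span = (cands[0][0], cands[0][1])
    prev = cands[0]
    for c in cands[1:]:
        r_start, r_end, eid, n_anc, e_start, e_end = c
        bridge = None
        if eid != cur_path[-1]:
            # nt the graph walk must insert between the two anchored spans
            prev_len = len(graph.edges[cur_path[-1]].seq)
            gap_nt = (r_start - prev[1]) - (prev_len - k1) + prev[5] - e_start
            bridge = _bridge(graph, cur_path[-1], eid, max_skip, max_skip_len, gap_nt)
        if bridge is None:
            runs.append((cur_anchors, cur_path, cur_span))
            cur_path = [eid]
            cur_anchors = n_anc
            cur_span = (r_start, r_end)
        else:
            cur_path.extend(bridge)
            cur_path.append(eid)
            cur_anchors += n_anc
            cur_span = (cur_span[0], max(cur_span[1], r_end))
        prev = c
    runs.append((cur_anchors, cur_path, cur_span))
    best = max(runs, key=lambda r: (r[0], -r[2][0]))
    return LongReadPath(read_id, tuple(best[1]), best[2], is_fl)


def align_long_reads(
    graph: AssemblyGraph,
    reads: Iterable[Tuple[str, str]],
    anchor_k: int = DEFAULT_ANCHOR_K,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_skip: int = DEFAULT_MAX_SKIP,
    is_fl: bool = False,
    index: Optional[AnchorIndex] = None,
) -> List[LongReadPath]:
    """Align a batch of (read_id, sequence) long reads; unalignable reads
    are dropped (tally logged).  Input order is preserved."""
    if index is None:
        index = AnchorIndex(graph, anchor_k)
    paths: List[LongReadPath] = []
    n_total = 0
    for read_id, seq in reads:
        n_total += 1
        p = align_long_read(
            graph, seq, anchor_k, min_anchors, max_skip,
            index=index, read_id=read_id, is_fl=is_fl,
        )
        if p is not None:
            paths.append(p)
    logger.info("aligned %d/%d long reads (is_fl=%s)", len(paths), n_total, is_fl)
    return paths


def _place_mate(index: AnchorIndex, seq: str) -> Optional[Tuple[int, float]]:
    """Place one mate on the unique edge sharing the most anchors with it.

    Returns (edge_id, mean edge offset) or None on ties / no anchors.
    """
    hits = index.hits(seq)
    if not hits:
        return None
    scored = sorted(((len(v), -eid) for eid, v in hits.items()), reverse=True)
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return None
    eid = -scored[0][1]
    pairs = hits[eid]
    mean_off = sum(p - r for r, p in pairs) / len(pairs)
    return eid, mean_off


def map_paired_reads(
    graph: AssemblyGraph,
    pairs: Iterable[Tuple[str, str]],
    anchor_k: int = DEFAULT_ANCHOR_K,
    index: Optional[AnchorIndex] = None,
) -> List[PairedLink]:
    """Map (mate1, mate2) read pairs onto the graph and produce PairedLinks.

    Mate 2 is reverse-complemented before placement so both mates are in
    transcript orientation.  Pairs with both mates on the same edge carry
    no junction information and are dropped; each informative pair
    increments its link and, for strand symmetry, the twin link.
    """
    if index is None:
        index = AnchorIndex(graph, anchor_k)
    support: Dict[Tuple[int, int], int] = {}
    gaps: Dict[Tuple[int, int], float] = {}
    n_short = 0
    for r1, r2 in pairs:
        if len(r1) < anchor_k or len(r2) < anchor_k:
            n_short += 1
            continue
        p1 = _place_mate(index, r1.upper())
        p2 = _place_mate(index, revcomp(r2.upper()))
        if p1 is None or p2 is None or p1[0] == p2[0]:
            continue
        e1, off1 = p1
        e2, off2 = p2
        gap = off2 + (len(graph.edges[e1].seq) - off1 - len(r1))
        for key, g in (((e1, e2), gap), ((graph.twin_of(e2), graph.twin_of(e1)), gap)):
            support[key] = support.get(key, 0) + 1
            gaps[key] = gaps.get(key, 0.0) + g
    if n_short:
        logger.info("skipped %d read pairs shorter than anchor_k", n_short)
    return [
        PairedLink(a, b, n, gaps[(a, b)] / n)
        for (a, b), n in sorted(support.items())
    ]
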