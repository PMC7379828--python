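"""Condensed de Bruijn assembly graph built from accurate short reads.

The graph is double-stranded: k-mers are counted canonically (lexicographic
minimum of a k-mer and its reverse complement) and every condensed edge
carries an explicit reverse-complement twin edge, so that mixed-strand
RNA-Seq libraries need no strand assignment.  Vertices are (k-1)-mers;
edges carry nucleotide sequence and mean k-mer coverage.  Simplification
follows the RNA-aware philosophy of transcriptome assemblers: relative
(not global) coverage criteria, so that genuine low-expressed isoform
branches survive while point-error tips and bubbles are clipped.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from statistics import fmean
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT_RUN = re.compile(r"[ACGT]+")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form: lexicographic minimum of a k-mer and its rc."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerTable:
    """Canonical k-mer occurrence counts.

    Keys are canonical k-mers over {A,C,G,T}; values are counts >= 1.
    """

    k: int
    counts: Dict[str, int]

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_kmers(reads: Iterable[str], k: int) -> KmerTable:
    """Count canonical k-mers over all ACGT windows of ``reads``.

    Windows containing non-ACGT symbols are skipped.  Counting is
    order-independent.  ``k`` must be odd (an even k admits palindromic
    k-mers whose canonical form is ambiguous between strands) and within
    [11, 127].
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k} (palindromic k-mer hazard)")
    if not 11 <= k <= 127:
        raise ValueError(f"k must be in [11, 127], got {k}")
    counts: Dict[str, int] = {}
    longest = 0
    for read in reads:
        read = read.upper()
        if len(read) > longest:
            longest = len(read)
        for m in _ACGT_RUN.finditer(read):
            seg = m.group()
            n = len(seg)
            if n < k:
                continue
            rcseg = seg.translate(_COMPLEMENT)[::-1]
            for i in range(n - k + 1):
                fwd = seg[i : i + k]
                rev = rcseg[n - k - i : n - i]
                km = fwd if fwd <= rev else rev
                counts[km] = counts.get(km, 0) + 1
    if longest and longest < k:
        warnings.warn(
            f"k={k} exceeds the longest read ({longest} nt); no k-mers counted",
            stacklevel=2,
        )
    return KmerTable(k=k, counts=counts)


@dataclass
class Edge:
    """A condensed edge (unitig) of the assembly graph.

    ``seq`` starts with the source (k-1)-mer and ends with the target
    (k-1)-mer; ``cov`` is the arithmetic mean count of the constituent
    k-mers; ``twin`` is the edge id of the reverse-complement edge
    (possibly ``eid`` itself for rc-palindromic edges).
    """

    eid: int
    source: str
    target: str
    seq: str
    cov: float
    twin: int
    kmers: Tuple[str, ...] = field(default=(), repr=False)

    def __len__(self) -> int:
        return len(self.seq)


class AssemblyGraph:
    """Condensed de Bruijn graph with explicit reverse-complement twins."""

    def __init__(self, k: int, edges: Sequence[Edge], kmer_counts: Optional[Dict[str, int]] = None):
        self.k = k
        self.edges: Dict[int, Edge] = {e.eid: e for e in edges}
        self.kmer_counts: Dict[str, int] = kmer_counts or {}
        self._out: Dict[str, List[int]] = {}
        self._in: Dict[str, List[int]] = {}
        for e in edges:
            self._out.setdefault(e.source, []).append(e.eid)
            self._in.setdefault(e.target, []).append(e.eid)
        for ids in self._out.values():
            ids.sort()
        for ids in self._in.values():
            ids.sort()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, eid: int) -> bool:
        return eid in self.edges

    def edge_ids(self) -> List[int]:
        return sorted(self.edges)

    def out_edges(self, vertex: str) -> List[int]:
        return self._out.get(vertex, [])

    def in_edges(self, vertex: str) -> List[int]:
        return self._in.get(vertex, [])

    def successors(self, eid: int) -> List[int]:
        """Edge ids leaving the target vertex of ``eid``."""
        return self._out.get(self.edges[eid].target, [])

    def predecessors(self, eid: int) -> List[int]:
        return self._in.get(self.edges[eid].source, [])

    def adjacent(self, a: int, b: int) -> bool:
        return self.edges[a].target == self.edges[b].source

    def is_valid_path(self, path: Sequence[int]) -> bool:
        if not path:
            return False
        return all(self.adjacent(a, b) for a, b in zip(path, path[1:]))

    def twin_of(self, eid: int) -> int:
        return self.edges[eid].twin

    def twin_path(self, path: Sequence[int]) -> Tuple[int, ...]:
        """The reverse-complement path: twins of the edges, reversed."""
        return tuple(self.edges[e].twin for e in reversed(path))

    def path_nt_length(self, path: Sequence[int]) -> int:
        """Nucleotide length of a path: edge lengths minus (k-1)-nt overlaps."""
        if not path:
            return 0
        return sum(len(self.edges[e].seq) for e in path) - (self.k - 1) * (len(path) - 1)


def build_condensed_graph(table: KmerTable, min_count: int = 2) -> AssemblyGraph:
    """Build a condensed de Bruijn graph from a k-mer table.

    K-mers with count below ``min_count`` are discarded; the survivors (in
    both orientations) form a directed graph on (k-1)-mer vertices whose
    maximal non-branching runs are merged into condensed edges.  Twin links
    are established by reverse-complement sequence identity (with a
    constituent-k-mer-set fallback for circular components, whose break
    points need not coincide between strands).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    k = table.k
    kept = {km: c for km, c in table.counts.items() if c >= min_count}
    if not kept:
        logger.info("k-mer table empty after min_count=%d filter; empty graph", min_count)
        return AssemblyGraph(k, [], {})

    oriented = set()
    for km in kept:
        oriented.add(km)
        oriented.add(revcomp(km))

    out_map: Dict[str, List[str]] = {}
    in_map: Dict[str, List[str]] = {}
    for x in oriented:
        out_map.setdefault(x[:-1], []).append(x)
        in_map.setdefault(x[1:], []).append(x)
    for v in out_map:
        out_map[v].sort()
    for v in in_map:
        in_map[v].sort()

    def _internal(v: str) -> bool:
        return len(out_map.get(v, ())) == 1 and len(in_map.get(v, ())) == 1

    visited: set = set()
    chains: List[List[str]] = []

    def _walk(x0: str) -> List[str]:
        chain = [x0]
        visited.add(x0)
        v = x0[1:]
        while _internal(v):
            y = out_map[v][0]
            if y in visited:  # closed a cycle
                break
            chain.append(y)
            visited.add(y)
            v = y[1:]
        return chain

    for x in sorted(oriented):
        if x not in visited and not _internal(x[:-1]):
            chains.append(_walk(x))
    for x in sorted(oriented):  # leftover pure cycles
        if x not in visited:
            chains.append(_walk(x))

    seqs: List[str] = []
    covs: List[float] = []
    kmsets: List[Tuple[str, ...]] = []
    for chain in chains:
        seqs.append(chain[0] + "".join(x[-1] for x in chain[1:]))
        kms = tuple(canonical(x) for x in chain)
        kmsets.append(kms)
        covs.append(fmean(kept[km] for km in kms))

    by_seq = {s: i for i, s in enumerate(seqs)}
    by_kset: Dict[frozenset, List[int]] = {}
    for i, kms in enumerate(kmsets):
        by_kset.setdefault(frozenset(kms), []).append(i)

    partner: List[int] = []
    for i, s in enumerate(seqs):
        j = by_seq.get(revcomp(s))
        if j is None:
            # circular unitig whose twin was broken at a different rotation
            others = [o for o in by_kset[frozenset(kmsets[i])] if o != i]
            j = others[0] if others else i
        partner.append(j)

    # canonical edge id order: twin pairs sorted by the lexicographically
    # smaller member sequence; the smaller member is the forward edge.
    pairs = []
    seen = set()
    for i in range(len(seqs)):
        j = partner[i]
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        fwd = i if seqs[i] <= seqs[j] else j
        pairs.append((min(seqs[i], seqs[j]), fwd, partner[fwd]))
    pairs.sort()

    edges: List[Edge] = []
    next_id = 0
    for _, fwd, bwd in pairs:
        fid = next_id
        next_id += 1
        if bwd == fwd:
            tid = fid
        else:
            tid = next_id
            next_id += 1
        edges.append(
            Edge(fid, seqs[fwd][: k - 1], seqs[fwd][-(k - 1):], seqs[fwd], covs[fwd], tid, kmsets[fwd])
        )
        if bwd != fwd:
            edges.append(
                Edge(tid, seqs[bwd][: k - 1], seqs[bwd][-(k - 1):], seqs[bwd], covs[bwd], fid, kmsets[bwd])
            )
    return AssemblyGraph(k, edges, kept)


@dataclass
class SimplifyParams:
    """Settings for RNA-aware graph simplification.

    ``tip_len_max`` defaults to 2k at call time.  Tip and bubble removal use
    coverage relative to the local alternative (RNA-Seq coverage is too
    non-uniform for global thresholds); ``cov_abs_min`` is the only absolute
    cut, aimed at residual error edges.
    """

    tip_len_max: Optional[int] = None
    tip_cov_frac: float = 0.1
    cov_abs_min: float = 2.0
    bubble_cov_frac: float = 0.05
    max_rounds: int = 8


def simplify(graph: AssemblyGraph, params: Optional[SimplifyParams] = None) -> AssemblyGraph:
    """Remove tips, low-coverage edges and error bubbles; re-condense.

    Removals operate on the underlying canonical k-mer set and the graph is
    rebuilt after every round, so twin symmetry and the condensed invariant
    hold by construction.  A bubble branch is removed only when its coverage
    is below ``bubble_cov_frac`` times the best parallel branch — comparable
    branches are retained as putative isoform variation.
    """
    params = params or SimplifyParams()
    tip_len_max = params.tip_len_max if params.tip_len_max is not None else 2 * graph.k
    counts = dict(graph.kmer_counts)
    g = graph
    for _ in range(params.max_rounds):
        removed: set = set()
        for e in g.edges.values():
            if e.eid in removed:
                continue
            head_dead = not g.in_edges(e.source)
            tail_dead = not g.out_edges(e.target)
            if head_dead == tail_dead:
                continue  # internal edge, or isolated edge (a whole transcript)
            if len(e.seq) >= tip_len_max:
                continue
            if head_dead:
                alts = [g.edges[o] for o in g.in_edges(e.target) if o != e.eid]
            else:
                alts = [g.edges[o] for o in g.out_edges(e.source) if o != e.eid]
            if alts and e.cov < params.tip_cov_frac * max(a.cov for a in alts):
                removed.add(e.eid)
                removed.add(e.twin)
        for e in g.edges.values():
            if e.cov < params.cov_abs_min:
                removed.add(e.eid)
                removed.add(e.twin)
        groups: Dict[Tuple[str, str], List[Edge]] = {}
        for e in g.edges.values():
            groups.setdefault((e.source, e.target), []).append(e)
        for grp in groups.values():
            if len(grp) < 2:
                continue
            best = max(a.cov for a in grp)
            for e in grp:
                if e.cov < params.bubble_cov_frac * best:
                    removed.add(e.eid)
                    removed.add(e.twin)
        if not removed:
            break
        for eid in removed:
            if eid in g.edges:
                for km in g.edges[eid].kmers:
                    counts.pop(km, None)
        g = build_condensed_graph(KmerTable(graph.k, counts), min_count=1)
    return g


def write_gfa(graph: AssemblyGraph, handle) -> None:
    """Export the graph as GFA1: one S line per twin pair, L lines with
    (k-1)M overlaps."""
    k = graph.k
    handle.write("H\tVN:Z:1.0\n")

    def _oriented(eid: int) -> Tuple[str, str]:
        e = graph.edges[eid]
        if eid <= e.twin:
            return f"E{eid}", "+"
        return f"E{e.twin}", "-"

    for eid in graph.edge_ids():
        e = graph.edges[eid]
        if eid <= e.twin:
            handle.write(f"S\tE{eid}\t{e.seq}\tdc:f:{e.cov:.4f}\n")
    emitted = set()
    for eid in graph.edge_ids():
        for nxt in graph.successors(eid):
            na, oa = _oriented(eid)
            nb, ob = _oriented(nxt)
            flip = {"+": "-", "-": "+"}
            link = (na, oa, nb, ob)
            rc_link = (nb, flip[ob], na, flip[oa])
            key = min(link, rc_link)
            if key in emitted:
                continue
            emitted.add(key)
            handle.write(f"L\t{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t{k - 1}M\n")
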