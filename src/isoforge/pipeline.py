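"""End-to-end assembly pipeline over in-memory reads.

The stages mirror the classical short-read assembler layout — k-mer
counting, condensed de Bruijn graph construction, RNA-aware
simplification, paired-read and long-read alignment to the graph — and
then reconstruct isoforms by paired-end-first / long-read-fallback path
extension with multi-edge forking, add full-length read paths verbatim,
deduplicate and render transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

from . import align as _align
from . import extend as _extend
from . import graph as _graph
from . import output as _output

logger = logging.getLogger(__name__)


@dataclass
class AssemblyConfig:
    """All tunable parameters of the assembler, with shipped defaults."""

    k: int = 25
    min_count: int = 2
    tip_len_max: Optional[int] = None  # defaults to 2k
    tip_cov_frac: float = 0.1
    cov_abs_min: float = 2.0
    bubble_cov_frac: float = 0.05
    anchor_k: int = 15
    min_anchors: int = 3
    max_skip: int = 2
    l_min: int = 200
    n_min: int = 2
    min_support: int = 5
    dominance: float = 2.0
    pe_window: int = 3
    max_forks: int = 16
    max_edge_multiplicity: int = 4
    min_pe_edge_len: int = 100
    min_contig_len: int = 200

    def as_dict(self) -> Dict[str, object]:
        return asdict(self)


def default_config() -> AssemblyConfig:
    return AssemblyConfig()


@dataclass
class AssemblyResult:
    graph: _graph.AssemblyGraph
    raw_paths: _extend.PathSet
    paths: _extend.PathSet  # deduplicated
    contigs: List[_output.TranscriptContig]
    stats: Dict[str, object] = field(default_factory=dict)

    def contig_records(self) -> List[Tuple[str, str]]:
        return [(c.contig_id, c.sequence) for c in self.contigs]


def assemble(
    short_pairs: Sequence[Tuple[str, str]] = (),
    singles: Sequence[str] = (),
    long_reads: Sequence[Tuple[str, str]] = (),
    fl_reads: Sequence[Tuple[str, str]] = (),
    config: Optional[AssemblyConfig] = None,
) -> AssemblyResult:
    """Run the full hybrid assembly over in-memory reads.

    ``short_pairs`` are (mate1, mate2) sequences; ``long_reads`` and
    ``fl_reads`` are (read_id, sequence).  Long and FL channels are
    optional; with neither this is a short-read-only assembly.
    """
    cfg = config or AssemblyConfig()
    kmer_reads: List[str] = []
    for m1, m2 in short_pairs:
        kmer_reads.append(m1)
        kmer_reads.append(m2)
    kmer_reads.extend(singles)
    table = _graph.count_kmers(kmer_reads, cfg.k)
    g = _graph.build_condensed_graph(table, cfg.min_count)
    g = _graph.simplify(
        g,
        _graph.SimplifyParams(
            tip_len_max=cfg.tip_len_max,
            tip_cov_frac=cfg.tip_cov_frac,
            cov_abs_min=cfg.cov_abs_min,
            bubble_cov_frac=cfg.bubble_cov_frac,
        ),
    )
    stats: Dict[str, object] = {
        "n_kmers": len(table),
        "n_edges": g.n_edges,
        "config": cfg.as_dict(),
    }
    if g.n_edges == 0:
        logger.warning("assembly graph is empty")
        empty = _extend.PathSet()
        return AssemblyResult(g, empty, empty, [], stats)

    index = _align.AnchorIndex(g, cfg.anchor_k)
    links = _align.map_paired_reads(g, short_pairs, cfg.anchor_k, index=index)
    lr = _align.align_long_reads(
        g, long_reads, cfg.anchor_k, cfg.min_anchors, cfg.max_skip, is_fl=False, index=index
    )
    fl = _align.align_long_reads(
        g, fl_reads, cfg.anchor_k, cfg.min_anchors, cfg.max_skip, is_fl=True, index=index
    )
    stats.update(
        n_links=len(links),
        n_long_paths=len(lr),
        n_long_reads=len(long_reads),
        n_fl_paths=len(fl),
        n_fl_reads=len(fl_reads),
    )
    ext_cfg = _extend.ExtensionConfig(
        l_min=cfg.l_min,
        n_min=cfg.n_min,
        min_support=cfg.min_support,
        dominance=cfg.dominance,
        pe_window=cfg.pe_window,
        max_forks=cfg.max_forks,
        max_edge_multiplicity=cfg.max_edge_multiplicity,
        min_pe_edge_len=cfg.min_pe_edge_len,
    )
    raw = _extend.extend_all_paths(g, links, lr + fl, ext_cfg)
    raw = _extend.add_fl_paths(raw, fl, g)
    deduped = _output.dedup_paths(raw, g)
    contigs = _output.render_transcripts(g, deduped, cfg.min_contig_len)
    stats.update(n_raw_paths=len(raw), n_paths=len(deduped), n_contigs=len(contigs))
    return AssemblyResult(g, raw, deduped, contigs, stats)
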