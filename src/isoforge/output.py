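"""Path deduplication, sequence rendering and transcript FASTA output."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .extend import EdgePath, PathSet
from .graph import AssemblyGraph

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG_LEN = 200


@dataclass
class TranscriptContig:
    """One output transcript: rendered sequence plus its originating path."""

    contig_id: str
    sequence: str
    path: EdgePath


def path_sequence(graph: AssemblyGraph, path: Sequence[int]) -> str:
    """Overlap-merged concatenation of a path's edge sequences.

    Length is sum(len(e_i)) - (k-1)(n-1).  An adjacency violation is an
    upstream invariant breach and raises.
    """
    edges = tuple(path.edges) if isinstance(path, EdgePath) else tuple(path)
    if not graph.is_valid_path(edges):
        raise ValueError(f"path is not adjacency-consistent: {edges}")
    k = graph.k
    parts = [graph.edges[edges[0]].seq]
    for e in edges[1:]:
        parts.append(graph.edges[e].seq[k - 1 :])
    return "".join(parts)


def path_mean_coverage(graph: AssemblyGraph, path: Sequence[int]) -> float:
    """Length-weighted mean edge coverage along a path."""
    edges = tuple(path.edges) if isinstance(path, EdgePath) else tuple(path)
    k = graph.k
    num = 0.0
    den = 0
    for e in edges:
        w = len(graph.edges[e].seq) - k + 1  # constituent k-mer count
        num += graph.edges[e].cov * w
        den += w
    return num / den if den else 0.0


def _contains(big: Tuple[int, ...], small: Tuple[int, ...]) -> bool:
    n = len(small)
    if n > len(big):
        return False
    return any(big[i : i + n] == small for i in range(len(big) - n + 1))


def dedup_paths(paths: PathSet, graph: AssemblyGraph) -> PathSet:
    """Remove identical paths and exact subpaths, strand-collapsed.

    A path is dropped when its edge list — or its twin's — occurs as a
    contiguous sub-run of a kept path, so a transcript and its reverse
    complement are never both emitted.  Survivors are chosen longest-first
    (nt length), ties by lowest path index; the result is subpath-free and
    the operation is idempotent.
    """
    order = sorted(
        range(len(paths.paths)),
        key=lambda i: (-graph.path_nt_length(paths.paths[i].edges), i),
    )
    kept: List[EdgePath] = []
    kept_tuples: List[Tuple[int, ...]] = []
    for i in order:
        p = paths.paths[i]
        t = tuple(p.edges)
        tw = graph.twin_path(t)
        if any(_contains(q, t) or _contains(q, tw) for q in kept_tuples):
            continue
        kept.append(p)
        kept_tuples.append(t)
    return PathSet(kept)


def render_transcripts(
    graph: AssemblyGraph,
    paths: PathSet,
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
) -> List[TranscriptContig]:
    """Render deduplicated paths to contigs, keeping those >= min_contig_len
    nt, in descending length (ties: path order).  Headers follow the
    NODE_<serial>_length_<L>_cov_<mean coverage> convention."""
    rendered = []
    for idx, p in enumerate(paths.paths):
        seq = path_sequence(graph, p)
        if len(seq) >= min_contig_len:
            rendered.append((len(seq), idx, seq, p))
    rendered.sort(key=lambda t: (-t[0], t[1]))
    contigs = []
    for serial, (length, _idx, seq, p) in enumerate(rendered, start=1):
        cov = path_mean_coverage(graph, p)
        contigs.append(
            TranscriptContig(f"NODE_{serial}_length_{length}_cov_{cov:.6g}", seq, p)
        )
    if not contigs and paths.paths:
        logger.warning("all %d paths fall below min_contig_len=%d", len(paths.paths), min_contig_len)
    return contigs


def write_transcripts(
    graph: AssemblyGraph,
    paths: PathSet,
    handle,
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
) -> List[TranscriptContig]:
    """Write the rendered transcripts as FASTA (60-column wrap)."""
    contigs = render_transcripts(graph, paths, min_contig_len)
    for c in contigs:
        handle.write(f">{c.contig_id}\n")
        for i in range(0, len(c.sequence), 60):
            handle.write(c.sequence[i : i + 60] + "\n")
    return contigs


def write_paths_tsv(paths: PathSet, handle) -> None:
    """Dump paths as TSV: path_id, origin, comma-separated edge ids."""
    handle.write("path_id\torigin\tedges\n")
    for i, p in enumerate(paths.paths):
        handle.write(f"{i}\t{p.origin}\t{','.join(map(str, p.edges))}\n")
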