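"""Shared fixtures and graph builders for the test suite."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from isoforge.graph import AssemblyGraph, Edge, build_condensed_graph, count_kmers


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tile_reads(seq: str, read_len: int = 100, step: int = 3) -> List[str]:
    """Error-free reads tiling a sequence, covering every k-mer."""
    if len(seq) <= read_len:
        return [seq]
    reads = [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    reads.append(seq[-read_len:])
    return reads


def graph_from_seqs(seqs: Sequence[str], k: int = 25, min_count: int = 1) -> AssemblyGraph:
    """Condensed graph from error-free reads tiling the given sequences."""
    reads: List[str] = []
    for s in seqs:
        reads.extend(tile_reads(s))
    return build_condensed_graph(count_kmers(reads, k), min_count)


def toy_graph(
    edge_defs: Sequence[Tuple[str, str, str, int]], k: int = 25
) -> Tuple[AssemblyGraph, Dict[str, int]]:
    """Abstract graph for path-logic tests: (name, source, target, length).

    Twin edges are materialised with mirrored vertices so twin-path
    traversal works; sequences are synthetic placeholders (poly-A of the
    requested length), adequate for every operation that only needs
    adjacency, twins and nt lengths.
    """
    edges: List[Edge] = []
    ids: Dict[str, int] = {}
    for i, (name, u, v, length) in enumerate(edge_defs):
        fid, tid = 2 * i, 2 * i + 1
        ids[name] = fid
        ids[name + "*"] = tid
        edges.append(Edge(fid, u, v, "A" * length, 10.0, tid))
        edges.append(Edge(tid, v + "~", u + "~", "A" * length, 10.0, fid))
    return AssemblyGraph(k, edges), ids


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bubble_setup():
    """Two isoforms differing by a 150 nt cassette exon: the canonical
    error-free bubble graph plus its generating sequences."""
    r = np.random.default_rng(42)
    pre, cas, suf = random_seq(r, 300), random_seq(r, 150), random_seq(r, 300)
    iso_incl, iso_skip = pre + cas + suf, pre + suf
    g = graph_from_seqs([iso_incl, iso_skip], k=25)
    return {"pre": pre, "cas": cas, "suf": suf, "incl": iso_incl, "skip": iso_skip, "graph": g}
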