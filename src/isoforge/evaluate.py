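"""Transcript-space assembly evaluation.

Scores an assembly FASTA against a reference transcript set: contigs are
seeded onto references by shared 21-mers, chained colinearly, and the
chained span is aligned base-level with edlib.  From the surviving
alignments the report derives the X%-assembled gene/isoform counts (a
reference entity counts when a single contig covers >= X% of its bases),
database coverage, duplication ratio (total aligned contig bases over
distinct covered reference bases, 1.0 ideal), chimeric-contig
misassemblies and mean mismatches per contig.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import edlib

from .graph import revcomp

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_BLOCK = 50
DEFAULT_SEED_K = 21
DEFAULT_CHIMERA_FRAC = 0.3

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ContigAlignment:
    """Best alignment chain of one contig onto one reference isoform.

    The chain may consist of several blocks (0-based half-open reference
    intervals): a contig that skips or gains an exon relative to the
    reference aligns block-wise, and the structural difference is not
    miscounted as mismatches.  ``mismatches`` are substitution columns
    within blocks; ``ref_covered`` is the union length of the blocks.
    """

    contig_id: str
    isoform_id: str
    ref_covered: int
    identity: float
    mismatches: int
    blocks: List[Tuple[int, int]]
    q_blocks: List[Tuple[int, int]] = field(default_factory=list)  # contig coords, original orientation


@dataclass
class EvalReport:
    n_transcripts: int
    x_assembled_genes: Dict[int, int]
    x_assembled_isoforms: Dict[int, int]
    database_coverage: float
    duplication_ratio: Optional[float]
    misassemblies: int
    mismatches_per_contig: float

    def to_dict(self) -> Dict[str, object]:
        d: Dict[str, object] = {"n_transcripts": self.n_transcripts}
        for x, c in sorted(self.x_assembled_genes.items()):
            d[f"{x}%-assembled genes"] = c
        for x, c in sorted(self.x_assembled_isoforms.items()):
            d[f"{x}%-assembled isoforms"] = c
        d["database coverage"] = self.database_coverage
        d["duplication ratio"] = self.duplication_ratio
        d["misassemblies"] = self.misassemblies
        d["mismatches per contig"] = self.mismatches_per_contig
        return d


def _chain(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    from bisect import bisect_left

    pairs = sorted(pairs, key=lambda p: (p[0], -p[1]))
    tails: List[int] = []
    tails_idx: List[int] = []
    parent = [-1] * len(pairs)
    for i, (_, e) in enumerate(pairs):
        j = bisect_left(tails, e)
        if j == len(tails):
            tails.append(e)
            tails_idx.append(i)
        else:
            tails[j] = e
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(pairs[i])
        i = parent[i]
    chain.reverse()
    return chain


def _cigar_stats(cigar: str) -> Tuple[int, int, int, int]:
    """(aligned_cols, mismatches, insertions, deletions) from an edlib
    extended CIGAR; 'M' columns (if ever present) count as matches."""
    cols = x = ins = dele = 0
    for num, op in _CIGAR_OP.findall(cigar):
        n = int(num)
        cols += n
        if op == "X":
            x += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
    return cols, x, ins, dele


def align_contigs(
    contigs: Sequence[Tuple[str, str]],
    references: Sequence[Tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_block: int = DEFAULT_MIN_BLOCK,
    seed_k: int = DEFAULT_SEED_K,
) -> List[ContigAlignment]:
    """Align each contig (both orientations) to every reference sharing a
    seed; keep the best chain per (contig, isoform) passing the identity
    and block-length filters."""
    ref_index: Dict[str, List[Tuple[int, int]]] = {}
    ref_seqs = [seq for _, seq in references]
    for ri, seq in enumerate(ref_seqs):
        for pos in range(len(seq) - seed_k + 1):
            ref_index.setdefault(seq[pos : pos + seed_k], []).append((ri, pos))

    best: Dict[Tuple[str, str], ContigAlignment] = {}
    for cid, cseq in contigs:
        for orient, oriented in (("+", cseq), ("-", revcomp(cseq))):
            hits: Dict[int, List[Tuple[int, int]]] = {}
            for i in range(len(oriented) - seed_k + 1):
                for ri, pos in ref_index.get(oriented[i : i + seed_k], ()):
                    hits.setdefault(ri, []).append((i, pos))
            for ri, pairs in hits.items():
                chain = _chain(pairs)
                if not chain:
                    continue
                # split the chain at diagonal jumps: a skipped or gained
                # exon shifts read-vs-reference offset by its length
                segments: List[List[Tuple[int, int]]] = [[chain[0]]]
                for prev_a, cur_a in zip(chain, chain[1:]):
                    if abs((cur_a[0] - cur_a[1]) - (prev_a[0] - prev_a[1])) > 30:
                        segments.append([])
                    segments[-1].append(cur_a)
                blocks: List[Tuple[int, int]] = []
                q_blocks: List[Tuple[int, int]] = []
                total_cols = total_ed = total_x = 0
                pad = 50
                for seg in segments:
                    qs, rs = seg[0]
                    qe, re_ = seg[-1][0] + seed_k, seg[-1][1] + seed_k
                    if qe - qs < min_block:
                        continue
                    t0 = max(0, rs - pad)
                    target = ref_seqs[ri][t0 : re_ + pad]
                    res = edlib.align(oriented[qs:qe], target, mode="HW", task="path")
                    loc = res["locations"][0]
                    cols, x, ins, dele = _cigar_stats(res["cigar"])
                    ref_lo, ref_hi = t0 + loc[0], t0 + loc[1] + 1
                    if ref_hi - ref_lo < min_block:
                        continue
                    blocks.append((ref_lo, ref_hi))
                    if orient == "+":
                        q_blocks.append((qs, qe))
                    else:
                        q_blocks.append((len(cseq) - qe, len(cseq) - qs))
                    total_cols += cols
                    total_ed += res["editDistance"]
                    total_x += x
                if not blocks:
                    continue
                identity = 1.0 - total_ed / total_cols if total_cols else 0.0
                covered = _union_len(blocks)
                if identity < min_identity or covered < min_block:
                    continue
                key = (cid, references[ri][0])
                aln = ContigAlignment(
                    cid, references[ri][0], covered, identity, total_x, blocks, q_blocks
                )
                prev = best.get(key)
                if prev is None or (covered, identity) > (prev.ref_covered, prev.identity):
                    best[key] = aln
    return sorted(best.values(), key=lambda a: (a.contig_id, a.isoform_id))


def chimeric_contigs(
    alignments: Iterable[ContigAlignment],
    contig_lengths: Dict[str, int],
    gene_map: Dict[str, str],
    min_frac: float = DEFAULT_CHIMERA_FRAC,
) -> Set[str]:
    """Contigs whose two best per-gene chains each cover >= min_frac of the
    contig length while hitting different genes."""
    per_contig: Dict[str, Dict[str, float]] = {}
    for a in alignments:
        gene = gene_map.get(a.isoform_id, a.isoform_id)
        frac = _union_len(a.q_blocks) / contig_lengths[a.contig_id]
        d = per_contig.setdefault(a.contig_id, {})
        d[gene] = max(d.get(gene, 0.0), frac)
    flagged = set()
    for cid, per_gene in per_contig.items():
        big = [g for g, f in per_gene.items() if f >= min_frac]
        if len(big) >= 2:
            flagged.add(cid)
    return flagged


def x_assembled(
    alignments: Iterable[ContigAlignment],
    references: Sequence[Tuple[str, str]],
    gene_map: Dict[str, str],
    X: float,
) -> Tuple[int, int]:
    """(gene count, isoform count) with >= X% of bases captured by a single
    contig."""
    if not 0 < X <= 100:
        raise ValueError("X must be in (0, 100]")
    ref_len = {rid: len(seq) for rid, seq in references}
    iso_ok: Set[str] = set()
    for a in alignments:
        if 100.0 * a.ref_covered / ref_len[a.isoform_id] >= X:
            iso_ok.add(a.isoform_id)
    genes_ok = {gene_map.get(i, i) for i in iso_ok}
    return len(genes_ok), len(iso_ok)


def _union_len(intervals: List[Tuple[int, int]]) -> int:
    total = 0
    last = -1
    for lo, hi in sorted(intervals):
        if lo > last:
            total += hi - lo
            last = hi
        elif hi > last:
            total += hi - last
            last = hi
    return total


def duplication_ratio(
    alignments: Iterable[ContigAlignment],
    references: Sequence[Tuple[str, str]],
) -> Optional[float]:
    """Total aligned contig bases / distinct covered reference bases; None
    when nothing aligns."""
    per_contig: Dict[str, List[Tuple[int, int]]] = {}
    per_ref: Dict[str, List[Tuple[int, int]]] = {}
    for a in alignments:
        per_contig.setdefault(a.contig_id, []).extend(a.q_blocks)
        per_ref.setdefault(a.isoform_id, []).extend(a.blocks)
    covered = sum(_union_len(iv) for iv in per_ref.values())
    if covered == 0:
        return None
    aligned = sum(_union_len(iv) for iv in per_contig.values())
    return aligned / covered


def evaluate(
    contigs: Sequence[Tuple[str, str]],
    references: Sequence[Tuple[str, str]],
    gene_map: Dict[str, str],
    xs: Sequence[int] = (50, 95),
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_block: int = DEFAULT_MIN_BLOCK,
) -> EvalReport:
    """Full evaluation report against the reference transcript set."""
    alignments = align_contigs(contigs, references, min_identity, min_block)
    contig_lengths = {cid: len(seq) for cid, seq in contigs}
    chimeric = chimeric_contigs(alignments, contig_lengths, gene_map)
    per_ref: Dict[str, List[Tuple[int, int]]] = {}
    for a in alignments:
        per_ref.setdefault(a.isoform_id, []).extend(a.blocks)
    total_ref = sum(len(seq) for _, seq in references)
    covered = sum(_union_len(iv) for iv in per_ref.values())
    primary: Dict[str, ContigAlignment] = {}
    for a in alignments:
        prev = primary.get(a.contig_id)
        if prev is None or (a.ref_covered, a.identity) > (prev.ref_covered, prev.identity):
            primary[a.contig_id] = a
    mm = (
        sum(a.mismatches for a in primary.values()) / len(primary) if primary else 0.0
    )
    return EvalReport(
        n_transcripts=len(contigs),
        x_assembled_genes={x: x_assembled(alignments, references, gene_map, x)[0] for x in xs},
        x_assembled_isoforms={x: x_assembled(alignments, references, gene_map, x)[1] for x in xs},
        database_coverage=covered / total_ref if total_ref else 0.0,
        duplication_ratio=duplication_ratio(alignments, references),
        misassemblies=len(chimeric),
        mismatches_per_contig=mm,
    )


def write_report(report: EvalReport, handle) -> None:
    """Flat key<TAB>value table of the report."""
    import pandas as pd

    d = report.to_dict()
    pd.Series(
        {k: ("NA" if v is None else v) for k, v in d.items()}, dtype=object
    ).to_csv(handle, sep="\t", header=False)
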