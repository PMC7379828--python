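"""Self-contained benchmark scenarios for the hybrid-vs-short comparison.

Each scenario simulates ground-truthed reads, runs the assembler (hybrid
and, where relevant, short-read-only on identical short reads) and scores
the result against the simulated truth.  These are the canonical
demonstrations of what long RNA reads add to a short-read transcriptome
assembly: exact recovery stays exact, and distant alternative exons that
paired-end inserts cannot phase are recovered one isoform per spanning
long read path.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .evaluate import EvalReport, evaluate
from .graph import revcomp
from .pipeline import AssemblyConfig, AssemblyResult, assemble
from .simulate import (
    GeneModel,
    Isoform,
    TranscriptRecord,
    gene_map_of,
    generate_gene_models,
    simulate_long_reads,
    simulate_short_pairs,
    transcripts_of,
)


def _random_exon(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _refs_and_map(txs: List[TranscriptRecord]):
    refs = [(t.isoform_id, t.sequence) for t in txs]
    gmap = {t.isoform_id: t.gene_id for t in txs}
    return refs, gmap


def single_isoform_benchmark(seed: int) -> Dict[str, object]:
    """One gene, one isoform (5 exons x 300 nt), 30x error-free short
    pairs, no long reads: the assembly should be the transcript itself."""
    rng = np.random.default_rng(seed)
    gm = GeneModel("G0", [_random_exon(rng, 300) for _ in range(5)],
                   [Isoform("G0_I0", tuple(range(5)))])
    txs = transcripts_of([gm])
    truth = txs[0].sequence
    pairs, _ = simulate_short_pairs(txs, coverage=30, error_rate=0.0, seed=seed + 1)
    res = assemble([(m1, m2) for _, m1, m2 in pairs])
    refs, gmap = _refs_and_map(txs)
    rep = evaluate(res.contig_records(), refs, gmap)
    contigs = [c.sequence for c in res.contigs]
    exact = len(contigs) == 1 and contigs[0] in (truth, revcomp(truth))
    return {
        "n_contigs": len(contigs),
        "exact_recovery": exact,
        "duplication_ratio": rep.duplication_ratio,
        "misassemblies": rep.misassemblies,
    }


def double_skip_gene(seed: int) -> GeneModel:
    """The distant double-skip gene: two alternative 200 nt exons flanking
    a shared 2000 nt exon (far beyond the 300 nt short-read insert);
    isoform I1 includes both alternatives, I2 skips both."""
    rng = np.random.default_rng(seed)
    return GeneModel(
        "G0",
        [_random_exon(rng, 300), _random_exon(rng, 200), _random_exon(rng, 2000),
         _random_exon(rng, 200), _random_exon(rng, 300)],
        [Isoform("G0_I1", (0, 1, 2, 3, 4)), Isoform("G0_I2", (0, 2, 4))],
    )


def double_skip_benchmark(seed: int) -> Dict[str, object]:
    """Hybrid vs short-read-only assembly of the double-skip gene: 30x
    short pairs (insert 300), 15x long reads at ~10% error spanning whole
    transcripts."""
    txs = transcripts_of([double_skip_gene(seed)])
    pairs, _ = simulate_short_pairs(txs, coverage=30, seed=seed + 1)
    long_reads, _ = simulate_long_reads(
        txs, coverage=15, fl_fraction=0.0, truncation_max_frac=0.0, seed=seed + 2
    )
    sp = [(m1, m2) for _, m1, m2 in pairs]
    refs, gmap = _refs_and_map(txs)
    rep_h = evaluate(assemble(sp, long_reads=long_reads).contig_records(), refs, gmap)
    rep_s = evaluate(assemble(sp).contig_records(), refs, gmap)
    return {
        "n_isoforms": len(txs),
        "hybrid_iso95": rep_h.x_assembled_isoforms[95],
        "short_iso95": rep_s.x_assembled_isoforms[95],
        "hybrid_duplication_ratio": rep_h.duplication_ratio,
        "hybrid_misassemblies": rep_h.misassemblies,
    }


def fl_benchmark(seed: int) -> Dict[str, object]:
    """A third exon combination (include first alternative, skip second)
    exists only as full-length reads; short and regular long reads come
    from I1/I2 only.  The FL-only isoform's exact sequence must appear in
    the assembly precisely when the FL channel is supplied."""
    gm = double_skip_gene(seed)
    txs = transcripts_of([gm])
    i3_seq = gm.exons[0] + gm.exons[1] + gm.exons[2] + gm.exons[4]
    i3 = TranscriptRecord("G0_I3", "G0", i3_seq, (0, 1, 2, 4))
    pairs, _ = simulate_short_pairs(txs, coverage=30, seed=seed + 1)
    long_reads, _ = simulate_long_reads(
        txs, coverage=15, fl_fraction=0.0, truncation_max_frac=0.0, seed=seed + 2
    )
    _, fl = simulate_long_reads([i3], coverage=5, fl_fraction=1.0, seed=seed + 3)
    sp = [(m1, m2) for _, m1, m2 in pairs]
    with_fl = assemble(sp, long_reads=long_reads, fl_reads=fl)
    without = assemble(sp, long_reads=long_reads)

    def has_i3(res: AssemblyResult) -> bool:
        return any(c.sequence in (i3_seq, revcomp(i3_seq)) for c in res.contigs)

    return {"i3_with_fl": has_i3(with_fl), "i3_without_fl": has_i3(without)}


def scale_benchmark(seed: int, n_genes: int = 20) -> Dict[str, object]:
    """The desk-scale analogue of the paper-style comparison: ``n_genes``
    genes with 2-3 isoforms each, 30x short pairs, 10x long reads at ~10%
    error with an FL fraction of 0.2; hybrid vs short-read-only."""
    models = generate_gene_models(
        n_genes, isoforms_per_gene_range=(2, 3), seed=seed
    )
    txs = transcripts_of(models)
    pairs, _ = simulate_short_pairs(txs, coverage=30, seed=seed + 1)
    long_reads, fl = simulate_long_reads(txs, coverage=10, fl_fraction=0.2, seed=seed + 2)
    sp = [(m1, m2) for _, m1, m2 in pairs]
    refs = [(t.isoform_id, t.sequence) for t in txs]
    gmap = gene_map_of(models)
    rep_h = evaluate(assemble(sp, long_reads=long_reads, fl_reads=fl).contig_records(), refs, gmap)
    rep_s = evaluate(assemble(sp).contig_records(), refs, gmap)
    n = len(txs)
    return {
        "n_isoforms": n,
        "n_genes": n_genes,
        "hybrid_iso95": rep_h.x_assembled_isoforms[95],
        "short_iso95": rep_s.x_assembled_isoforms[95],
        "hybrid_pct_iso95": 100.0 * rep_h.x_assembled_isoforms[95] / n,
        "short_pct_iso95": 100.0 * rep_s.x_assembled_isoforms[95] / n,
        "hybrid_gene95": rep_h.x_assembled_genes[95],
        "short_gene95": rep_s.x_assembled_genes[95],
        "hybrid_duplication_ratio": rep_h.duplication_ratio,
        "hybrid_mismatches_per_contig": rep_h.mismatches_per_contig,
        "hybrid_database_coverage": rep_h.database_coverage,
        "short_database_coverage": rep_s.database_coverage,
        "hybrid_misassemblies": rep_h.misassemblies,
    }
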