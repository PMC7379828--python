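"""Ground-truthed synthetic RNA-Seq data.

Generates multi-exon gene models with alternatively spliced isoforms, then
three read channels over the spliced transcripts: low-error short paired
reads with a truncated-normal insert distribution, high-error long reads
with i.i.d. per-base substitutions/insertions/deletions and 5'-biased
truncation (mimicking incomplete cDNA synthesis), and a full-length (FL)
subset spanning whole transcripts.  Libraries are non-strand-specific:
every fragment is emitted from a uniformly random strand.

Half of the genes with >= 5 exons receive a "distant double-skip"
structure: two alternative exons separated by a shared exon much longer
than the short-read insert, the canonical case where paired-end reads
cannot phase the two alternative exons but a spanning long read can.

Every generator is fully deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import revcomp

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Isoform:
    isoform_id: str
    exon_indices: Tuple[int, ...]
    weight: float = 1.0


@dataclass
class GeneModel:
    """A gene as an ordered exon list plus spliced isoform definitions.

    Isoform exon-index lists are strictly increasing and always include the
    first and last exon; exons are >= 50 nt."""

    gene_id: str
    exons: List[str]
    isoforms: List[Isoform]


@dataclass
class TranscriptRecord:
    isoform_id: str
    gene_id: str
    sequence: str
    exon_indices: Tuple[int, ...]
    weight: float = 1.0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def generate_gene_models(
    n_genes: int,
    exons_per_gene_range: Tuple[int, int] = (4, 7),
    exon_len_range: Tuple[int, int] = (150, 400),
    isoforms_per_gene_range: Tuple[int, int] = (2, 3),
    seed: int = 0,
    double_skip_prob: float = 0.5,
    double_skip_shared_len: int = 2000,
    double_skip_alt_len: int = 200,
) -> List[GeneModel]:
    """Random gene models with alternative splicing.

    Exon sequences are uniform ACGT; every isoform keeps the first and last
    exon and a strictly increasing interior subset.  With probability
    ``double_skip_prob``, a gene with >= 5 exons gets the distant
    double-skip structure: alternative exons of ``double_skip_alt_len`` nt
    flanking a shared exon of ``double_skip_shared_len`` nt, with one
    isoform including both alternatives and one skipping both.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi, name in (
        (*exons_per_gene_range, "exons_per_gene_range"),
        (*exon_len_range, "exon_len_range"),
        (*isoforms_per_gene_range, "isoforms_per_gene_range"),
    ):
        if lo > hi or lo < 1:
            raise ValueError(f"infeasible {name}: ({lo}, {hi})")
    if exon_len_range[0] < 50:
        raise ValueError("exons must be >= 50 nt")
    rng = np.random.default_rng(seed)
    models: List[GeneModel] = []
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        lens = [int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)) for _ in range(n_ex)]
        double_skip = n_ex >= 5 and rng.random() < double_skip_prob
        iso_sets: List[Tuple[int, ...]] = []
        if double_skip:
            m = n_ex // 2  # shared middle exon; alternatives flank it
            lens[m] = max(lens[m], double_skip_shared_len)
            lens[m - 1] = double_skip_alt_len
            lens[m + 1] = double_skip_alt_len
            iso_sets.append(tuple(range(n_ex)))  # includes both alternatives
            iso_sets.append(tuple(i for i in range(n_ex) if i not in (m - 1, m + 1)))
        else:
            iso_sets.append(tuple(range(n_ex)))
        exons = [_random_seq(rng, L) for L in lens]
        n_iso = int(rng.integers(isoforms_per_gene_range[0], isoforms_per_gene_range[1] + 1))
        n_iso = max(n_iso, len(iso_sets))
        attempts = 0
        while len(iso_sets) < n_iso and attempts < 50:
            attempts += 1
            interior = [i for i in range(1, n_ex - 1)]
            keep = tuple(
                [0] + [i for i in interior if rng.random() < 0.6] + [n_ex - 1]
            )
            if keep not in iso_sets and len(keep) >= 2:
                iso_sets.append(keep)
        isoforms = [
            Isoform(f"G{g}_I{i}", idxs, 1.0) for i, idxs in enumerate(iso_sets)
        ]
        models.append(GeneModel(f"G{g}", exons, isoforms))
    return models


def transcripts_of(models: Sequence[GeneModel]) -> List[TranscriptRecord]:
    """Spliced transcript sequences for every isoform of every gene."""
    out = []
    for gm in models:
        for iso in gm.isoforms:
            seq = "".join(gm.exons[i] for i in iso.exon_indices)
            out.append(TranscriptRecord(iso.isoform_id, gm.gene_id, seq, iso.exon_indices, iso.weight))
    return out


def _apply_subs(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_short_pairs(
    transcripts: Sequence[TranscriptRecord],
    coverage: float = 30.0,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> Tuple[List[Tuple[str, str, str]], List[str]]:
    """Paired short reads per transcript.

    Pair count = round(coverage * len / (2 * read_len)) scaled by isoform
    abundance weight.  Fragments come from random-phase tiling of transcript
    copies (each simulated cDNA copy is cut into consecutive fragments with
    insert ~ Normal(mean, sd) truncated below at 2*read_len and clipped to
    the transcript), so transcript termini are sequenced the way terminal
    fragments of a real library are; i.i.d. substitution errors; mate 2 is
    the reverse complement of the fragment end.  Returns
    ([(pair_id, mate1, mate2)], skipped_transcript_ids).
    """
    rng = np.random.default_rng(seed)
    pairs: List[Tuple[str, str, str]] = []
    skipped: List[str] = []
    min_insert = 2 * read_len
    for t in transcripts:
        L = len(t.sequence)
        if L < min_insert:
            skipped.append(t.isoform_id)
            logger.warning("transcript %s (%d nt) shorter than minimum insert %d; skipped",
                           t.isoform_id, L, min_insert)
            continue
        n_pairs = int(round(coverage * L / (2 * read_len) * t.weight))
        j = 0
        while j < n_pairs:
            pos = -int(rng.integers(0, int(insert_mean)))  # copy phase
            while pos < L and j < n_pairs:
                insert = int(round(rng.normal(insert_mean, insert_sd)))
                insert = max(insert, min_insert)
                lo, hi = max(0, pos), min(L, pos + insert)
                pos += insert
                if hi - lo < min_insert:
                    continue
                frag = t.sequence[lo:hi]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                m1 = _apply_subs(frag[:read_len], error_rate, rng)
                m2 = _apply_subs(revcomp(frag[-read_len:]), error_rate, rng)
                pairs.append((f"{t.isoform_id}_p{j}", m1, m2))
                j += 1
    return pairs, skipped


def _mutate(seq: str, sub: float, ins: float, dele: float, rng: np.random.Generator) -> str:
    if sub + ins + dele <= 0:
        return seq
    n = len(seq)
    draws = rng.random(n)
    extra = _BASES[rng.integers(0, 4, n)]
    out = bytearray()
    arr = seq.encode()
    for i in range(n):
        r = draws[i]
        if r < dele:
            continue
        if r < dele + ins:
            out.append(extra[i])
            out.append(arr[i])
        elif r < dele + ins + sub:
            choices = _BASES[_BASES != arr[i]]
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(arr[i])
    return out.decode()


def simulate_long_reads(
    transcripts: Sequence[TranscriptRecord],
    coverage: float = 10.0,
    sub_rate: float = 0.034,
    ins_rate: float = 0.033,
    del_rate: float = 0.033,
    fl_fraction: float = 0.2,
    truncation_max_frac: float = 0.3,
    seed: int = 0,
) -> Tuple[List[Tuple[str, str]], List[Tuple[str, str]]]:
    """Long error-prone reads plus a full-length (FL) channel.

    Per transcript, round(coverage * weight) reads are drawn; each read
    spans the whole transcript with probability ``fl_fraction`` (emitted to
    the FL channel), otherwise it loses up to ``truncation_max_frac`` of
    its length from the 5' end.  Errors are i.i.d. per base at the given
    substitution/insertion/deletion rates.  Returns (long, fl) as lists of
    (read_id, sequence).
    """
    if sub_rate + ins_rate + del_rate > 0.5:
        raise ValueError("combined error rate above 0.5 is unrealistic; refusing")
    rng = np.random.default_rng(seed)
    long_reads: List[Tuple[str, str]] = []
    fl_reads: List[Tuple[str, str]] = []
    for t in transcripts:
        L = len(t.sequence)
        n_reads = int(round(coverage * t.weight))
        for j in range(n_reads):
            full = rng.random() < fl_fraction
            if full:
                frag = t.sequence
            else:
                cut = int(round(rng.random() * truncation_max_frac * L))
                frag = t.sequence[cut:]
            read = _mutate(frag, sub_rate, ins_rate, del_rate, rng)
            if rng.random() < 0.5:
                read = revcomp(read)
            rid = f"{t.isoform_id}_{'fl' if full else 'lr'}{j}"
            (fl_reads if full else long_reads).append((rid, read))
    return long_reads, fl_reads


def gene_map_of(models: Sequence[GeneModel]) -> Dict[str, str]:
    """isoform_id -> gene_id mapping for the evaluator."""
    return {iso.isoform_id: gm.gene_id for gm in models for iso in gm.isoforms}


def write_truth(models: Sequence[GeneModel], outdir) -> None:
    """Ground-truth sidecars: transcript FASTA and gene<->isoform TSV."""
    from pathlib import Path

    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    txs = transcripts_of(models)
    write_fasta([(t.isoform_id, t.sequence) for t in txs], outdir / "transcripts.fasta")
    with open(outdir / "gene_map.tsv", "w") as fh:
        fh.write("gene_id\tisoform_id\n")
        for t in txs:
            fh.write(f"{t.gene_id}\t{t.isoform_id}\n")
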