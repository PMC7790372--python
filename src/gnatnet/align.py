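"""Pairwise local alignment and Karlin-Altschul E-value statistics.

This module provides the all-vs-all comparison behind SSN edges: optimal
Smith-Waterman local alignment with affine gap costs (default BLOSUM62,
gap open 11, gap extend 1 in the BLAST convention where a gap of length g
costs ``open + g * extend``), with E-values from the Karlin-Altschul formula

    E = K * m * n * exp(-lambda * S)

using the published gapped BLOSUM62/11/1 constants lambda = 0.267,
K = 0.041.  No search heuristics (seeding, two-hit) are applied: every
alignment is the exact optimum, which is affordable at desk scale.

``X`` scores 0 against every residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import AMINO_ACIDS, SequenceRecord, VALID_RESIDUES

#: E-value floor used when converting to edge scores (-log10 E).
EVALUE_FLOOR = 1e-180


@dataclass(frozen=True)
class ScoringParams:
    """Scoring configuration for local alignment and its statistics.

    ``gap_open``/``gap_extend`` follow the BLAST convention (gap of length
    g costs ``gap_open + g * gap_extend``).  ``lam``/``K`` are the gapped
    Karlin-Altschul constants matching the matrix and gap costs.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041


DEFAULT_SCORING = ScoringParams()


@dataclass(frozen=True)
class PairwiseHit:
    """One alignment-derived edge candidate between two sequences."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    pct_identity: float
    aln_length: int


@lru_cache(maxsize=8)
def _load_matrix(name: str) -> substitution_matrices.Array:
    """Load a substitution matrix restricted to the 20 residues + X.

    X is forced to score 0 against everything (including itself).
    """
    source = substitution_matrices.load(name)
    alphabet = AMINO_ACIDS + "X"
    matrix = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "X" or b == "X":
                matrix[a, b] = 0.0
            else:
                matrix[a, b] = source[a, b]
    return matrix


@lru_cache(maxsize=8)
def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(params.matrix)
    # biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; BLAST's 11/1 is therefore
    # open=-(11+1), extend=-1.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _validate(rec: SequenceRecord) -> None:
    bad = set(rec.residues) - VALID_RESIDUES
    if bad:
        raise ValueError(f"{rec.id}: invalid residues {sorted(bad)!r}")
    if not rec.residues:
        raise ValueError(f"{rec.id}: empty sequence")


def evalue_from_score(score: float, m: int, n: int, params: ScoringParams = DEFAULT_SCORING) -> float:
    """Karlin-Altschul expectation value for a raw local alignment score."""
    return params.K * m * n * math.exp(-params.lam * score)


def bit_score(raw_score: float, params: ScoringParams = DEFAULT_SCORING) -> float:
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)


def local_score(a: SequenceRecord, b: SequenceRecord, params: ScoringParams = DEFAULT_SCORING) -> float:
    """Optimal Smith-Waterman score only (no traceback)."""
    _validate(a)
    _validate(b)
    return _make_aligner(params).score(a.residues, b.residues)


def _alignment_stats(alignment) -> tuple[int, int]:
    """(identities, alignment columns incl. gaps) from a biopython alignment."""
    blocks_a, blocks_b = alignment.aligned
    seq_a = alignment.sequences[0]
    seq_b = alignment.sequences[1]
    identities = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a_start, a_end), (b_start, b_end) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a_start - prev_a_end) + (b_start - prev_b_end)
        columns += a_end - a_start
        for x, y in zip(seq_a[a_start:a_end], seq_b[b_start:b_end]):
            if x == y and x != "X":
                identities += 1
        prev_a_end, prev_b_end = a_end, b_end
    return identities, columns


def align_pair(a: SequenceRecord, b: SequenceRecord, params: ScoringParams = DEFAULT_SCORING) -> PairwiseHit:
    """Optimal local alignment of two records with E-value statistics."""
    _validate(a)
    _validate(b)
    aligner = _make_aligner(params)
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    identities, columns = _alignment_stats(best)
    raw = float(best.score)
    ev = evalue_from_score(raw, len(a), len(b), params)
    pct = 100.0 * identities / columns if columns else 0.0
    return PairwiseHit(
        query_id=a.id,
        subject_id=b.id,
        raw_score=raw,
        bit_score=bit_score(raw, params),
        evalue=ev,
        pct_identity=pct,
        aln_length=columns,
    )


def pairwise_identity(a: SequenceRecord, b: SequenceRecord, params: ScoringParams = DEFAULT_SCORING) -> float:
    """Fraction of identical residues, cd-hit style.

    Identities from the optimal local alignment divided by the length of
    the shorter sequence, giving a global-ish identity measure that is
    robust to short spurious local alignments between unrelated pairs.
    """
    aligner = _make_aligner(params)
    best = aligner.align(a.residues, b.residues)[0]
    identities, _ = _alignment_stats(best)
    return identities / min(len(a), len(b))


def all_vs_all(
    sequences: Sequence[SequenceRecord],
    params: ScoringParams = DEFAULT_SCORING,
    evalue_cutoff: float = 1e-5,
) -> list[PairwiseHit]:
    """One hit per unordered pair with E <= cutoff, sorted by id pair.

    The optimal score is computed first (cheap, no traceback); the full
    traceback for identity/length runs only for pairs passing the cutoff.
    """
    if len(sequences) < 2:
        raise ValueError("all_vs_all needs at least 2 sequences")
    ordered = sorted(sequences, key=lambda r: r.id)
    hits: list[PairwiseHit] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            score = local_score(a, b, params)
            if evalue_from_score(score, len(a), len(b), params) <= evalue_cutoff:
                hits.append(align_pair(a, b, params))
    return hits


def edge_score(evalue: float) -> float:
    """SSN edge score: -log10(E) with the E-value floored at 1e-180."""
    return -math.log10(max(evalue, EVALUE_FLOOR))


def write_hits_tsv(hits: Iterable[PairwiseHit], path) -> None:
    """Write hits as 12-column BLAST outfmt-6-compatible rows.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Coordinate and mismatch columns that a
    traceback-free pipeline does not track are written as 0.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{h.aln_length}\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.3e}\t{h.bit_score:.1f}\n"
            )


def read_hits_tsv(path) -> list[PairwiseHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            ev = float(f[10])
            bits = float(f[11])
            lam, K = DEFAULT_SCORING.lam, DEFAULT_SCORING.K
            raw = (bits * math.log(2.0) + math.log(K)) / lam
            hits.append(
                PairwiseHit(
                    query_id=f[0],
                    subject_id=f[1],
                    raw_score=raw,
                    bit_score=bits,
                    evalue=ev,
                    pct_identity=float(f[2]),
                    aln_length=int(f[3]),
                )
            )
    return hits
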