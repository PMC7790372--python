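"""Hierarchical greedy redundancy filtering of sequence datasets.

Mirrors the incremental-clustering convention of cd-hit run hierarchically:
a descending ladder of identity thresholds (e.g. 0.9, then 0.8, then 0.7),
where each step greedily clusters the previous step's representatives.
Within a step, sequences are visited longest-first; a sequence joins the
first existing representative it matches at or above the step's identity
(identical residues from the optimal local alignment divided by the length
of the shorter sequence), otherwise it becomes a representative itself.

Curated and explicitly protected records are never removed: they are
always representatives and are visited first, so redundant unreviewed
sequences collapse onto them rather than the other way around.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .align import DEFAULT_SCORING, ScoringParams, pairwise_identity
from .records import SequenceRecord

logger = logging.getLogger(__name__)

#: Sequences shorter than this are dropped before network construction;
#: shorter fragments are unlikely to span a functional part of the fold.
MIN_SEQUENCE_LENGTH = 34


def filter_short(
    sequences: Sequence[SequenceRecord], min_length: int = MIN_SEQUENCE_LENGTH
) -> list[SequenceRecord]:
    kept = []
    for rec in sequences:
        if len(rec) < min_length:
            logger.warning(
                "dropping %s: length %d < minimum %d", rec.id, len(rec), min_length
            )
        else:
            kept.append(rec)
    return kept


def _never_removed(rec: SequenceRecord) -> bool:
    return rec.is_curated or rec.protected


def _one_step(
    sequences: list[SequenceRecord],
    threshold: float,
    params: ScoringParams,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    order = sorted(
        sequences, key=lambda r: (not _never_removed(r), -len(r), r.id)
    )
    representatives: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for rec in order:
        if _never_removed(rec):
            representatives.append(rec)
            assignment[rec.id] = rec.id
            continue
        for rep in representatives:
            if pairwise_identity(rec, rep, params) >= threshold:
                assignment[rec.id] = rep.id
                break
        else:
            representatives.append(rec)
            assignment[rec.id] = rec.id
    return representatives, assignment


def redundancy_filter(
    sequences: Sequence[SequenceRecord],
    identity_steps: Sequence[float] = (0.9, 0.8, 0.7),
    params: ScoringParams = DEFAULT_SCORING,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Hierarchical greedy redundancy filtering.

    Returns the representatives surviving all steps and a map from every
    input id to its final representative id.
    """
    steps = list(identity_steps)
    if any(not 0.0 < s <= 1.0 for s in steps):
        raise ValueError("identity steps must be in (0, 1]")
    if any(b >= a for a, b in zip(steps, steps[1:])):
        raise ValueError("identity steps must be strictly descending")
    current = list(sequences)
    final_assignment = {rec.id: rec.id for rec in current}
    for threshold in steps:
        current, step_assignment = _one_step(current, threshold, params)
        for seq_id, rep_id in final_assignment.items():
            final_assignment[seq_id] = step_assignment.get(rep_id, rep_id)
        logger.info(
            "redundancy step %.2f: %d representatives", threshold, len(current)
        )
    # preserve original input order among survivors
    surviving = {rec.id for rec in current}
    representatives = [rec for rec in sequences if rec.id in surviving]
    return representatives, final_assignment
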