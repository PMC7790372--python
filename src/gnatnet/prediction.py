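"""Annotation transfer within isofunctional clusters and NAT candidate calls.

Two prediction steps operate on a clustered SSN:

* **Annotation transfer** — a cluster whose labelled curated members agree
  on one functional label donates that label to its unlabelled members
  (provenance "transferred"); conflicting labels flag the cluster "mixed"
  and block transfer; clusters with no labelled member are
  "uncharacterized".  Curated labels are never overwritten.

* **Candidate nomination** — uncharacterized clusters adjacent, in the
  pivot network, to a cluster of known function (plus any isolated
  clusters explicitly requested) are scanned against every group
  fingerprint.  A candidate is called *consistent* with its best-matching
  group when at least half its members match the fingerprint at the
  chosen significance and no key conserved position differs, *divergent*
  when some members match or a key-position substitution is found, and
  *no-match* otherwise.  Key positions are columns whose modal residue
  frequency in the known group's motif is at least 0.7 — the strongly
  conserved, typically mutation-sensitive positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .clustering import Cluster, Clustering
from .motifs import (
    GroupFingerprint,
    Motif,
    MotifDifference,
    assign_elements,
    diff_fingerprints,
    discover_motifs,
    fingerprint_score,
)
from .records import SequenceRecord, UNKNOWN

logger = logging.getLogger(__name__)

MIXED = "mixed"
UNCHARACTERIZED = "uncharacterized"

#: Modal-frequency floor defining a "key" (mutation-sensitive) position.
KEY_POSITION_FREQUENCY = 0.7


@dataclass
class TransferResult:
    clustering: Clustering
    annotations: dict[str, tuple[str, str]]  # seq id -> (label, provenance)


@dataclass
class CandidateReport:
    cluster_id: int
    neighbour_of: list[int]
    best_group: str
    combined_p: float
    member_fraction: float
    differences: list[MotifDifference] = field(default_factory=list)
    verdict: str = "no-match"

    def __post_init__(self) -> None:
        if not 0.0 <= self.member_fraction <= 1.0:
            raise ValueError("member_fraction must be in [0, 1]")


def transfer_annotations(
    clustering: Clustering, records: Sequence[SequenceRecord]
) -> TransferResult:
    """Label clusters from their curated members and transfer to unknowns."""
    by_id = {rec.id: rec for rec in records}
    annotations: dict[str, tuple[str, str]] = {
        rec.id: (rec.label, "curated" if rec.is_curated else "input")
        for rec in records
        if rec.label != UNKNOWN
    }
    for cluster in clustering.clusters:
        labels = {
            by_id[m].label
            for m in cluster.members
            if m in by_id and by_id[m].is_curated and by_id[m].label != UNKNOWN
        }
        if not labels:
            cluster.label = UNCHARACTERIZED
        elif len(labels) > 1:
            cluster.label = MIXED
            logger.warning(
                "cluster %d has conflicting labels %s; no transfer",
                cluster.cluster_id,
                sorted(labels),
            )
        else:
            label = labels.pop()
            cluster.label = label
            for member in cluster.members:
                rec = by_id.get(member)
                if rec is None or rec.is_curated:
                    continue
                if rec.label == UNKNOWN and member not in annotations:
                    annotations[member] = (label, "transferred")
    return TransferResult(clustering=clustering, annotations=annotations)


def _key_differences(
    differences: Sequence[MotifDifference],
) -> list[MotifDifference]:
    return [d for d in differences if d.frequency_1 >= KEY_POSITION_FREQUENCY]


def predict_nat_candidates(
    pivot: nx.Graph,
    clustering: Clustering,
    fingerprints: Sequence[GroupFingerprint],
    records: Sequence[SequenceRecord],
    alpha: float = 0.01,
    include_isolated: Sequence[int] = (),
    background: np.ndarray | None = None,
    discovery_seed: int = 0,
    discovery_kwargs: Mapping | None = None,
) -> list[CandidateReport]:
    """Nominate and score candidate NAT clusters.

    Candidates are uncharacterized clusters adjacent in the pivot network
    to a known-labelled cluster, plus the explicitly requested isolated
    clusters.  Each candidate is scored with :func:`fingerprint_score`
    against every group fingerprint; its own motifs are discovered and
    diffed against the best group for the per-element difference report.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    known = {
        c.cluster_id
        for c in clustering.clusters
        if c.label not in (UNCHARACTERIZED, MIXED)
    }
    if not known:
        raise ValueError("no known-NAT cluster: nothing to predict from")
    by_id = {rec.id: rec for rec in records}

    candidate_ids: dict[int, list[int]] = {}
    for cluster in clustering.clusters:
        if cluster.label != UNCHARACTERIZED:
            continue
        neighbours = sorted(
            n for n in pivot.neighbors(cluster.cluster_id) if n in known
        ) if cluster.cluster_id in pivot else []
        if neighbours:
            candidate_ids[cluster.cluster_id] = neighbours
        elif cluster.cluster_id in include_isolated:
            candidate_ids[cluster.cluster_id] = []

    reports: list[CandidateReport] = []
    for cluster_id in sorted(candidate_ids):
        cluster = clustering.by_id(cluster_id)
        members = [by_id[m] for m in sorted(cluster.members) if m in by_id]
        best_group, best_p, best_combined = None, np.inf, {}
        for fp in fingerprints:
            combined, _, cluster_p = fingerprint_score(
                fp, members, background=background
            )
            if cluster_p < best_p:
                best_group, best_p, best_combined = fp.name, cluster_p, combined
        assert best_group is not None
        fraction = (
            sum(1 for p in best_combined.values() if p <= alpha) / len(members)
            if members
            else 0.0
        )
        best_fp = next(fp for fp in fingerprints if fp.name == best_group)
        differences = _candidate_differences(
            members, best_fp, background, discovery_seed, discovery_kwargs or {}
        )
        key_diffs = _key_differences(differences)
        if fraction >= 0.5 and not key_diffs:
            verdict = "consistent"
        elif fraction > 0.0 or key_diffs:
            verdict = "divergent"
        else:
            verdict = "no-match"
        reports.append(
            CandidateReport(
                cluster_id=cluster_id,
                neighbour_of=candidate_ids[cluster_id],
                best_group=best_group,
                combined_p=best_p,
                member_fraction=fraction,
                differences=differences,
                verdict=verdict,
            )
        )
    return reports


def _candidate_differences(
    members: Sequence[SequenceRecord],
    reference: GroupFingerprint,
    background: np.ndarray | None,
    seed: int,
    discovery_kwargs: Mapping,
) -> list[MotifDifference]:
    """Discover the candidate's motifs and diff them against the reference."""
    if len(members) < 5:
        return []
    kwargs = dict(discovery_kwargs)
    kwargs.setdefault("max_motifs", len(reference.motifs))
    try:
        candidate_motifs = discover_motifs(members, seed=seed, **kwargs)
    except ValueError:
        return []
    if not candidate_motifs:
        return []
    labelled = assign_elements(candidate_motifs, reference)
    if not labelled:
        return []
    candidate_fp = GroupFingerprint(name="candidate", motifs=labelled)
    return diff_fingerprints(reference, candidate_fp)


def write_candidate_tsv(reports: Sequence[CandidateReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tneighbour_of\tbest_group\tcombined_p\t"
            "member_fraction\tn_key_differences\tverdict\n"
        )
        for r in reports:
            neigh = ",".join(str(n) for n in r.neighbour_of) or "-"
            fh.write(
                f"{r.cluster_id}\t{neigh}\t{r.best_group}\t{r.combined_p:.3e}\t"
                f"{r.member_fraction:.2f}\t{len(_key_differences(r.differences))}\t"
                f"{r.verdict}\n"
            )


def write_candidate_report(
    reports: Sequence[CandidateReport], path: str | Path
) -> None:
    """Human-readable report listing per-element motif differences."""
    with open(path, "w") as fh:
        for r in reports:
            fh.write(
                f"Cluster {r.cluster_id} (neighbour of "
                f"{', '.join(map(str, r.neighbour_of)) or 'none; isolated'}): "
                f"best match {r.best_group}, combined p = {r.combined_p:.2e}, "
                f"{r.member_fraction:.0%} of members significant -> {r.verdict}\n"
            )
            for d in r.differences:
                key = " [key position]" if d.frequency_1 >= KEY_POSITION_FREQUENCY else ""
                fh.write(
                    f"  {d.element} position {d.position}: conserved "
                    f"{d.residue_1} ({d.frequency_1:.0%}) is replaced by "
                    f"{d.residue_2} ({d.frequency_2:.0%}){key}\n"
                )
            fh.write("\n")
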