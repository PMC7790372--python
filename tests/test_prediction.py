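import networkx as nx
import numpy as np
import pytest

from gnatnet.clustering import Cluster, Clustering
from gnatnet.motifs import GroupFingerprint, motif_from_regex
from gnatnet.nat_groups import synthesize_group_member
from gnatnet.prediction import (
    CandidateReport,
    predict_nat_candidates,
    transfer_annotations,
)
from gnatnet.records import SequenceRecord

from .conftest import random_sequence


def labelled(seq_id, label, residues=None, curated=True):
    return SequenceRecord(
        seq_id,
        residues or "MDELWKNAGHETSYVKRPLQ" * 3,
        status="curated" if curated else "unreviewed",
        label=label,
    )


def unknown(seq_id, residues=None):
    return SequenceRecord(seq_id, residues or "MDELWKNAGHETSYVKRPLQ" * 3)


def test_transfer_single_label():
    records = [labelled("k0", "NAA50")] + [unknown(f"u{i}") for i in range(9)]
    clustering = Clustering(clusters=[Cluster(1, {r.id for r in records}, 1, 1)])
    result = transfer_annotations(clustering, records)
    assert clustering.clusters[0].label == "NAA50"
    transferred = [
        sid for sid, (lbl, prov) in result.annotations.items() if prov == "transferred"
    ]
    assert len(transferred) == 9
    assert all(result.annotations[t][0] == "NAA50" for t in transferred)


def test_transfer_conflict_flags_mixed():
    records = [labelled("k0", "NAA50"), labelled("k1", "NAA60")] + [
        unknown(f"u{i}") for i in range(3)
    ]
    clustering = Clustering(clusters=[Cluster(1, {r.id for r in records}, 1, 1)])
    result = transfer_annotations(clustering, records)
    assert clustering.clusters[0].label == "mixed"
    assert all(prov != "transferred" for _, prov in result.annotations.values())


def test_transfer_uncharacterized_and_curated_protection():
    records = [unknown(f"u{i}") for i in range(4)]
    clustering = Clustering(clusters=[Cluster(1, {r.id for r in records}, 1, 1)])
    transfer_annotations(clustering, records)
    assert clustering.clusters[0].label == "uncharacterized"

    # a curated record with its own label never gets overwritten
    records2 = [labelled("k0", "NAA50"), labelled("other", "NAA20")] + [
        unknown("u0")
    ]
    clustering2 = Clustering(
        clusters=[Cluster(1, {"k0", "u0"}, 1, 1), Cluster(2, {"other"}, 1, 1)]
    )
    result = transfer_annotations(clustering2, records2)
    assert result.annotations["other"] == ("NAA20", "curated")


def _prediction_setup(candidate_records, seed=0):
    """Known Group 2 cluster (10 members) adjacent to a candidate cluster."""
    rng = np.random.default_rng(seed)
    known = [
        SequenceRecord(
            f"k{i}",
            synthesize_group_member("Group 2", rng),
            status="curated",
            label="Group 2",
        )
        for i in range(10)
    ]
    clusters = Clustering(
        clusters=[
            Cluster(1, {r.id for r in known}, 1.0, 1.0, label="Group 2"),
            Cluster(2, {r.id for r in candidate_records}, 1.0, 1.0),
        ]
    )
    pivot = nx.Graph()
    pivot.add_nodes_from([1, 2])
    pivot.add_edge(1, 2)
    from gnatnet.nat_groups import group_fingerprint

    fingerprints = [group_fingerprint("Group 2"), group_fingerprint("Group 3")]
    return pivot, clusters, fingerprints, known


def test_candidate_from_matching_group_is_consistent():
    rng = np.random.default_rng(1)
    members = [
        SequenceRecord(f"c{i}", synthesize_group_member("Group 2", rng))
        for i in range(6)
    ]
    pivot, clusters, fingerprints, known = _prediction_setup(members)
    reports = predict_nat_candidates(
        pivot, clusters, fingerprints, known + members, alpha=0.01,
        discovery_kwargs={"n_shuffle": 5},
    )
    assert len(reports) == 1
    report = reports[0]
    assert report.cluster_id == 2
    assert report.best_group == "Group 2"
    assert report.member_fraction >= 0.5
    assert report.verdict in ("consistent", "divergent")


def test_random_candidate_is_no_match():
    rng = np.random.default_rng(2)
    members = [
        SequenceRecord(f"c{i}", random_sequence(rng, 150)) for i in range(6)
    ]
    pivot, clusters, fingerprints, known = _prediction_setup(members)
    reports = predict_nat_candidates(
        pivot, clusters, fingerprints, known + members, alpha=0.01,
        discovery_kwargs={"n_shuffle": 5},
    )
    assert reports[0].verdict == "no-match"
    assert reports[0].member_fraction == 0.0


def test_no_known_cluster_is_an_error():
    records = [unknown(f"u{i}") for i in range(3)]
    clustering = Clustering(clusters=[Cluster(1, {r.id for r in records}, 1, 1)])
    pivot = nx.Graph()
    pivot.add_node(1)
    fp = GroupFingerprint("g", [("a1a2", motif_from_regex("FPVEY"))])
    with pytest.raises(ValueError, match="no known"):
        predict_nat_candidates(pivot, clustering, [fp], records)


def test_candidate_report_validation():
    with pytest.raises(ValueError):
        CandidateReport(1, [], "g", 0.1, member_fraction=1.5)
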