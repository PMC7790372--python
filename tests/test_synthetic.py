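import numpy as np
import pytest

from gnatnet.align import pairwise_identity
from gnatnet.records import AMINO_ACIDS
from gnatnet.synthetic import (
    FamilySpec,
    SuperfamilyTruth,
    blosum62_background,
    generate_superfamily,
    generate_zscore_matrix,
    mutate_sequence,
    read_truth_tsv,
    write_truth_tsv,
)
from gnatnet.records import write_fasta


def test_generation_counts_and_truth(small_superfamily):
    records, truth = small_superfamily
    assert len(records) == 30
    assert truth.families == ["famA", "famB", "famC"]
    assert sorted(truth.membership) == sorted(r.id for r in records)


def test_generation_is_deterministic(tmp_path, small_superfamily):
    records, _ = small_superfamily
    specs = [
        FamilySpec(
            "famA", 10,
            motifs=[("a1a2", "YYAEKKWPG", 20), ("b4", "LHVQTSN", 60)],
            target_within_identity=0.75,
        ),
        FamilySpec("famB", 10, target_within_identity=0.75),
        FamilySpec("famC", 10, target_within_identity=0.75),
    ]
    again, _ = generate_superfamily(specs, seed=7)
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    write_fasta(records, p1)
    write_fasta(again, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_identity_calibration():
    """Realized within-family identity tracks the target; between is background."""
    specs = [
        FamilySpec("fA", 15, target_within_identity=0.75),
        FamilySpec("fB", 15, target_within_identity=0.75),
    ]
    records, truth = generate_superfamily(specs, seed=11)
    fam_a = [r for r in records if truth.membership[r.id] == "fA"]
    fam_b = [r for r in records if truth.membership[r.id] == "fB"]
    within = [
        pairwise_identity(a, b)
        for i, a in enumerate(fam_a)
        for b in fam_a[i + 1 :]
    ]
    between = [pairwise_identity(a, b) for a in fam_a[:8] for b in fam_b[:8]]
    assert 0.70 <= np.mean(within) <= 0.85
    assert np.mean(between) < 0.15


def test_planted_motifs_remain_modal(small_superfamily):
    records, truth = small_superfamily
    fam_a = [r for r in records if truth.membership[r.id] == "famA"]
    start, end = truth.motif_positions[(fam_a[0].id, "a1a2")]
    consensus = "YYAEKKWPG"
    for k in range(end - start):
        column = [r.residues[start + k] for r in fam_a]
        modal = max(set(column), key=column.count)
        assert modal == consensus[k]


def test_mutate_sequence_exact_substitution_count():
    rng = np.random.default_rng(0)
    parent = "".join(rng.choice(list(AMINO_ACIDS), size=100))
    child = mutate_sequence(parent, 0.8, seed=1)
    assert len(child) == 100
    assert sum(a != b for a, b in zip(parent, child)) == 20


def test_mutate_sequence_identity_and_determinism():
    parent = "MDELWKNAGHETSYV" * 4
    assert mutate_sequence(parent, 1.0, seed=3) == parent
    assert mutate_sequence(parent, 0.7, seed=3) == mutate_sequence(parent, 0.7, seed=3)
    with pytest.raises(ValueError):
        mutate_sequence(parent, 0.0, seed=3)


def test_protected_intervals_mutate_rarely():
    rng = np.random.default_rng(5)
    parent = "".join(rng.choice(list(AMINO_ACIDS), size=200))
    n_changed = 0
    for seed in range(20):
        child = mutate_sequence(parent, 0.5, protected=[(50, 60)], seed=seed)
        n_changed += sum(
            parent[i] != child[i] for i in range(50, 60)
        )
    # protected per-site rate is (1 - 0.5)/10 = 5%: expect ~10 of 200
    assert n_changed < 40


def test_overlapping_motifs_rejected():
    with pytest.raises(ValueError, match="overlap"):
        FamilySpec("f", 5, motifs=[("a1a2", "AAAAA", 10), ("b4", "CCCCC", 12)])
    with pytest.raises(ValueError, match="fit"):
        FamilySpec("f", 5, scaffold_length=20, motifs=[("a1a2", "AAAAAAA", 15)])


def test_zscore_matrix_blocks_and_symmetry():
    truth = SuperfamilyTruth(
        membership={f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)},
        motif_positions={},
        seed=0,
    )
    zm = generate_zscore_matrix(truth, 20.0, 5.0, sd=0.0, seed=0)
    assert np.allclose(zm.Z, zm.Z.T)
    within = zm.Z[:5, :5][~np.eye(5, dtype=bool)]
    between = zm.Z[:5, 5:]
    assert np.allclose(within, 20.0)
    assert np.allclose(between, 5.0)

    noisy = generate_zscore_matrix(truth, 20.0, 5.0, sd=1.0, seed=1)
    within_noisy = noisy.Z[:5, :5][~np.eye(5, dtype=bool)]
    # mean within 3 standard errors of mu_within
    se = 1.0 / np.sqrt(within_noisy.size)
    assert abs(within_noisy.mean() - 20.0) < 3 * se

    with pytest.raises(ValueError):
        generate_zscore_matrix(truth, 5.0, 20.0, sd=1.0)


def test_truth_tsv_roundtrip(tmp_path, small_superfamily):
    _, truth = small_superfamily
    path = tmp_path / "truth.tsv"
    write_truth_tsv(truth, path)
    back = read_truth_tsv(path)
    assert back.membership == truth.membership
    assert back.motif_positions == truth.motif_positions


def test_background_sums_to_one():
    bg = blosum62_background()
    assert bg.shape == (20,)
    assert np.isclose(bg.sum(), 1.0)
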