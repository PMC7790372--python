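import itertools

import numpy as np
import pytest

from gnatnet.motifs import (
    GroupFingerprint,
    Motif,
    _int_log_odds,
    _score_distribution,
    _zoops_em,
    _WindowSet,
    _ppm_from_window,
    assign_elements,
    diff_fingerprints,
    discover_motifs,
    encode,
    fingerprint_score,
    letter_background,
    motif_from_regex,
    parse_regex,
    qfast_combine,
    regex_from_motif,
    sample_from_regex,
    scan_with_motif,
    write_meme_minimal,
)
from gnatnet.nat_groups import KNOWN_GROUP_REGEXES
from gnatnet.records import AMINO_ACIDS, SequenceRecord
from gnatnet.synthetic import blosum62_background

from .conftest import random_records, random_sequence


def planted_records(word, n=12, length=120, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        s = random_sequence(rng, length)
        off = int(rng.integers(0, length - len(word) + 1))
        records.append(SequenceRecord(f"p{i}", s[:off] + word + s[off + len(word):]))
    return records


def test_em_recovers_planted_word():
    word = "WKHDYAEMG"
    records = planted_records(word, n=12, seed=3)
    motifs = discover_motifs(records, max_motifs=3, seed=1)
    assert motifs, "planted motif not reported"
    consensus = motifs[0].consensus
    best = max(
        sum(a == b for a, b in zip(consensus[o:], word))
        for o in range(len(consensus))
    )
    best = max(
        best,
        max(sum(a == b for a, b in zip(consensus, word[o:])) for o in range(len(word))),
    )
    assert best >= 8
    assert motifs[0].evalue < 1.0
    assert motifs[0].n_sites >= 10


def test_duplicated_input_recovers_same_consensus():
    word = "YYAEKKWPG"
    records = planted_records(word, n=8, seed=5)
    doubled = records + [
        SequenceRecord(r.id + "_dup", r.residues) for r in records
    ]
    m1 = discover_motifs(records, max_motifs=1, seed=2)
    m2 = discover_motifs(doubled, max_motifs=1, seed=2)
    assert m1 and m2
    assert m1[0].consensus == m2[0].consensus
    assert m2[0].n_sites >= 1.8 * m1[0].n_sites


def test_em_loglikelihood_monotone():
    records = planted_records("YYAEKKWPG", n=8, seed=7)
    encoded = [encode(r.residues) for r in records]
    bg = letter_background(records)
    ws = _WindowSet(encoded, 9)
    ppm0 = _ppm_from_window(ws.W[0], bg)
    lls = []
    ppm = ppm0
    gamma = 0.8
    for _ in range(15):
        ppm, gamma, _, ll = _zoops_em(ws, bg, ppm, gamma, max_iter=1, tol=-1.0)
        lls.append(ll)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_discovery_input_validation():
    records = planted_records("YYAEKKWPG", n=4)
    with pytest.raises(ValueError, match="at least 5"):
        discover_motifs(records)
    with pytest.raises(ValueError, match="width_range"):
        discover_motifs(planted_records("YYAEKKWPG", n=6), width_range=[3, 4])


def test_regex_from_motif_columns():
    bg = blosum62_background()
    ppm = np.tile(bg, (3, 1))
    # column 0: V/I split; column 1: pure Y; column 2: uniform-ish background
    ppm[0] = 0.0
    ppm[0, AMINO_ACIDS.index("V")] = 0.5
    ppm[0, AMINO_ACIDS.index("I")] = 0.4
    ppm[0, AMINO_ACIDS.index("L")] = 0.1
    ppm[1] = 0.0
    ppm[1, AMINO_ACIDS.index("Y")] = 1.0
    motif = Motif(ppm=ppm / ppm.sum(axis=1, keepdims=True))
    assert regex_from_motif(motif) == "[VI]YX"


def test_regex_parse_and_sample():
    columns = parse_regex("[VI]X[ED]Y")
    assert columns == [["V", "I"], [], ["E", "D"], ["Y"]]
    rng = np.random.default_rng(0)
    for _ in range(20):
        word = sample_from_regex("[VI]X[ED]Y", rng)
        assert len(word) == 4
        assert word[0] in "VI" and word[2] in "ED" and word[3] == "Y"


@pytest.mark.parametrize(
    "regex",
    [KNOWN_GROUP_REGEXES["Group 1a"]["b6b7"], KNOWN_GROUP_REGEXES["Group 2"]["b6b7"]],
)
def test_regex_roundtrip_through_sampled_ppm(regex):
    """Sampling matches of a fingerprint regex and re-deriving the regex
    from their observed PPM reproduces at least 90% of the columns."""
    rng = np.random.default_rng(11)
    words = [sample_from_regex(regex, rng) for _ in range(150)]
    counts = np.zeros((len(words[0]), 20))
    for word in words:
        for k, c in enumerate(word):
            counts[k, AMINO_ACIDS.index(c)] += 1
    motif = Motif(ppm=counts / counts.sum(axis=1, keepdims=True))
    derived = parse_regex(regex_from_motif(motif))
    original = parse_regex(regex)
    agree = sum(
        1 for d, o in zip(derived, original) if set(d) == set(o)
    )
    assert agree >= 0.9 * len(original)


def test_scan_pointmass_pvalue_is_background_product():
    bg = blosum62_background()
    word = "HSYLPYYYSI"
    motif = motif_from_regex(word, consensus_mass=1.0 - 1e-12)
    rng = np.random.default_rng(2)
    seq = random_sequence(rng, 80) + word + random_sequence(rng, 30)
    hit = scan_with_motif(motif, SequenceRecord("s", seq), bg)
    assert hit.position == 80
    expected = np.prod([bg[AMINO_ACIDS.index(c)] for c in word])
    assert hit.p_position == pytest.approx(expected, rel=1e-6)


def test_convolution_matches_enumeration_toy_alphabet():
    letters = [AMINO_ACIDS.index(c) for c in "LVEK"]
    bg = np.zeros(20)
    bg[letters] = 0.25
    rng = np.random.default_rng(6)
    for _ in range(5):
        ppm = np.full((3, 20), 1e-12)
        for k in range(3):
            probs = rng.dirichlet(np.ones(4))
            for l, p in zip(letters, probs):
                ppm[k, l] = p
        motif = Motif(ppm=ppm / ppm.sum(axis=1, keepdims=True))
        lo = _int_log_odds(motif, bg)
        dist, offset = _score_distribution(lo, bg)
        for word in itertools.product(letters, repeat=3):
            s = sum(int(lo[k, word[k]]) for k in range(3))
            brute = sum(
                0.25**3
                for other in itertools.product(letters, repeat=3)
                if sum(int(lo[k, other[k]]) for k in range(3)) >= s
            )
            idx = s - offset
            conv = float(dist[idx:].sum()) if 0 < idx < len(dist) else (
                1.0 if idx <= 0 else 0.0
            )
            assert conv == pytest.approx(brute, abs=1e-12)


def test_hopeless_sequence_has_pvalue_one():
    bg = blosum62_background()
    motif = motif_from_regex("YYYYY", consensus_mass=0.99)
    hit = scan_with_motif(motif, SequenceRecord("s", "A" * 50), bg)
    assert hit.p_sequence == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError, match="shorter"):
        scan_with_motif(motif, SequenceRecord("s", "AAA"), bg)


def test_qfast_identities():
    assert qfast_combine([0.37]) == 0.37
    assert qfast_combine([1.0, 1.0, 1.0]) == 1.0
    # combining adds multiplicity correction: combined >= raw product
    p = [0.01, 0.02]
    assert qfast_combine(p) >= p[0] * p[1]


def test_diff_fingerprints_f_to_l():
    base = motif_from_regex("FPVEYSDKWY")
    changed = motif_from_regex("LPVEYSDKWY")
    f1 = GroupFingerprint("one", [("a1a2", base)])
    f2 = GroupFingerprint("two", [("a1a2", changed)])
    assert diff_fingerprints(f1, f1.__class__("copy", f1.motifs)) == []
    diffs = diff_fingerprints(f1, f2)
    assert len(diffs) == 1
    assert (diffs[0].residue_1, diffs[0].residue_2) == ("F", "L")
    assert diffs[0].position == 0


def test_diff_alignment_recovers_shift():
    bg = blosum62_background()
    inner = motif_from_regex("FPVEYSDKW")  # width 9
    shifted_ppm = np.vstack([bg[None, :], inner.ppm])  # width 10, shift +1
    shifted = Motif(ppm=shifted_ppm / shifted_ppm.sum(axis=1, keepdims=True))
    f1 = GroupFingerprint("a", [("b4", inner)])
    f2 = GroupFingerprint("b", [("b4", shifted)])
    assert diff_fingerprints(f1, f2) == []


def test_diff_no_shared_elements_warns():
    m = motif_from_regex("FPVEY")
    f1 = GroupFingerprint("a", [("a1a2", m)])
    f2 = GroupFingerprint("b", [("b4", m)])
    assert diff_fingerprints(f1, f2) == []


def test_assign_elements_matches_true_element():
    rng = np.random.default_rng(4)
    ref = GroupFingerprint(
        "ref",
        [("a1a2", motif_from_regex("FPVEYSDKWY")), ("b4", motif_from_regex("LYIMTLGVL"))],
    )
    candidate = motif_from_regex("LPVEYSDKWY")
    assigned = assign_elements([candidate], ref)
    assert assigned and assigned[0][0] == "a1a2"
    unrelated = motif_from_regex("QQQQQWWWWW")
    assert assign_elements([unrelated], ref) == []


def test_meme_minimal_output(tmp_path):
    bg = blosum62_background()
    motif = motif_from_regex("FPVEY", name="m1")
    path = tmp_path / "m.meme.txt"
    write_meme_minimal([motif], bg, path)
    text = path.read_text()
    assert "MEME version" in text
    assert "letter-probability matrix" in text
    assert f"w= {motif.width}" in text
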