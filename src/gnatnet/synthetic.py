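"""Synthetic protein superfamilies with planted ground truth.

The generator emulates the structure of a curated superfamily retrieval:
many families of internally similar, mutually dissimilar sequences, each
family carrying short conserved motifs at fixed scaffold positions (the
stand-ins for fold elements such as the α1-α2 loop or the β4 strand), with
a minority of records bearing curated functional labels.

Every family descends from an independently drawn random ancestor
scaffold, so expected between-family identity is random background
(~5-10%), while within-family identity is calibrated to a target: each
member is mutated away from the ancestor at half the target divergence, so
that two members, whose mutations are independent, differ at about the
target rate from one another.  Motif positions are protected (10x-reduced
per-site mutation rate), leaving the planted consensus detectable as the
modal residue per column.

No indels, no tree-structured evolution: the point is controllable
identity structure with exact ground truth, not realism of the
evolutionary process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import AMINO_ACIDS, CURATED, SequenceRecord, UNKNOWN, UNREVIEWED
from .structure import ZScoreMatrix

#: Fold-element labels the motif machinery recognises.
ELEMENT_LABELS = ("a1a2", "b4", "b5", "b6b7")

# Background amino-acid frequencies underlying BLOSUM62 (Robinson-Robinson
# style marginals as published with the matrix), normalised to sum to 1.
_BLOSUM62_FREQ = {
    "A": 0.0742, "R": 0.0520, "N": 0.0449, "D": 0.0536, "C": 0.0247,
    "Q": 0.0341, "E": 0.0543, "G": 0.0741, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0241, "F": 0.0474, "P": 0.0387,
    "S": 0.0573, "T": 0.0508, "W": 0.0132, "Y": 0.0324, "V": 0.0729,
}


def blosum62_background() -> np.ndarray:
    """BLOSUM62 marginal frequencies ordered like :data:`AMINO_ACIDS`."""
    freqs = np.array([_BLOSUM62_FREQ[a] for a in AMINO_ACIDS], dtype=float)
    return freqs / freqs.sum()


_TAXA = ("fungi", "metazoa", "viridiplantae", "protista")
_TAXON_WEIGHTS = (0.6, 0.2, 0.15, 0.05)  # fungi-heavy mixture


@dataclass
class FamilySpec:
    """Specification of one planted family.

    ``motifs`` is a list of ``(element_label, consensus, offset)`` triples:
    the consensus string is written into the ancestor scaffold at the given
    offset and protected from mutation thereafter.  ``scaffold`` may pin the
    ancestor explicitly (e.g. to derive one family from another); when None
    the ancestor is drawn from the background distribution.
    """

    family_id: str
    n_sequences: int
    scaffold_length: int = 150
    motifs: list[tuple[str, str, int]] = field(default_factory=list)
    target_within_identity: float = 0.75
    labelled_fraction: float = 0.2
    scaffold: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError(f"{self.family_id}: n_sequences must be positive")
        if not 0.0 < self.target_within_identity <= 1.0:
            raise ValueError(
                f"{self.family_id}: target_within_identity must be in (0, 1]"
            )
        if self.scaffold is not None and len(self.scaffold) != self.scaffold_length:
            self.scaffold_length = len(self.scaffold)
        intervals = sorted(self.motif_intervals())
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(f"{self.family_id}: overlapping motif intervals")
        for label, consensus, offset in self.motifs:
            if offset < 0 or offset + len(consensus) > self.scaffold_length:
                raise ValueError(
                    f"{self.family_id}: motif {label!r} does not fit the scaffold"
                )

    def motif_intervals(self) -> list[tuple[int, int]]:
        """0-based half-open protected intervals."""
        return [(off, off + len(cons)) for _, cons, off in self.motifs]

    @property
    def annotation_label(self) -> str:
        return self.label if self.label is not None else self.family_id


@dataclass
class SuperfamilyTruth:
    """Planted ground truth: family membership and motif coordinates."""

    membership: dict[str, str]
    motif_positions: dict[tuple[str, str], tuple[int, int]]
    seed: int

    def family_members(self, family_id: str) -> list[str]:
        return [sid for sid, fam in self.membership.items() if fam == family_id]

    @property
    def families(self) -> list[str]:
        seen: list[str] = []
        for fam in self.membership.values():
            if fam not in seen:
                seen.append(fam)
        return seen


def random_scaffold(length: int, background: np.ndarray, rng: np.random.Generator) -> str:
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=background)
    return "".join(letters)


def mutate_sequence(
    parent: str,
    target_identity: float,
    protected: Sequence[tuple[int, int]] = (),
    background: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> str:
    """Substitute residues of ``parent`` down to a target identity.

    Exactly ``round((1 - target_identity) * L_unprotected)`` positions
    outside the protected intervals are substituted by a different residue
    drawn from the background distribution.  Protected positions mutate
    independently with a 10x lower per-site probability, emulating
    conserved motifs with residual variation.  Length is preserved.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if background is None:
        background = blosum62_background()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    is_protected = np.zeros(len(parent), dtype=bool)
    for start, end in protected:
        is_protected[start:end] = True
    unprotected_idx = np.flatnonzero(~is_protected)

    out = list(parent)
    rate = 1.0 - target_identity
    n_sub = int(round(rate * len(unprotected_idx)))
    if n_sub > 0:
        chosen = rng.choice(unprotected_idx, size=n_sub, replace=False)
        for pos in chosen:
            out[pos] = _substitute(parent[pos], background, rng)
    protected_idx = np.flatnonzero(is_protected)
    if len(protected_idx):
        mutate_mask = rng.random(len(protected_idx)) < rate / 10.0
        for pos in protected_idx[mutate_mask]:
            out[pos] = _substitute(parent[pos], background, rng)
    return "".join(out)


def _substitute(current: str, background: np.ndarray, rng: np.random.Generator) -> str:
    """Draw a residue != current from the background (renormalised)."""
    probs = background.copy()
    idx = AMINO_ACIDS.find(current)
    if idx >= 0:
        probs[idx] = 0.0
    probs /= probs.sum()
    return AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=probs)]


def generate_superfamily(
    specs: Sequence[FamilySpec],
    background: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SuperfamilyTruth]:
    """Generate sequences and ground truth for a planted superfamily.

    Per family: one ancestor scaffold is drawn (or taken from the spec),
    motifs are overwritten at their offsets, and each member is produced by
    :func:`mutate_sequence` at half the target divergence so that pairwise
    within-family identity lands near the target.  ``labelled_fraction`` of
    members (rounded down, at least 1 if the fraction is positive) carry
    the family label with curated status.  Deterministic given ``seed``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if background is None:
        background = blosum62_background()
    if not np.isclose(background.sum(), 1.0, atol=1e-6):
        raise ValueError("background frequencies must sum to 1")

    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    motif_positions: dict[tuple[str, str], tuple[int, int]] = {}

    for spec in specs:
        if spec.scaffold is not None:
            ancestor = list(spec.scaffold.upper())
        else:
            ancestor = list(random_scaffold(spec.scaffold_length, background, rng))
        for element, consensus, offset in spec.motifs:
            ancestor[offset : offset + len(consensus)] = consensus.upper()
        ancestor_str = "".join(ancestor)
        protected = spec.motif_intervals()

        # Half the target divergence per member: member mutations are
        # independent, so two members differ at ~2x the per-member rate.
        member_identity = 1.0 - (1.0 - spec.target_within_identity) / 2.0

        n_labelled = int(spec.labelled_fraction * spec.n_sequences)
        if spec.labelled_fraction > 0:
            n_labelled = max(1, n_labelled)
        labelled_idx = set(range(n_labelled))

        for i in range(spec.n_sequences):
            seq_id = f"{spec.family_id}_{i:03d}"
            residues = mutate_sequence(
                ancestor_str, member_identity, protected, background, rng
            )
            taxon = _TAXA[rng.choice(len(_TAXA), p=_TAXON_WEIGHTS)]
            if i in labelled_idx:
                rec = SequenceRecord(
                    seq_id, residues, status=CURATED,
                    taxon=taxon, label=spec.annotation_label,
                )
            else:
                rec = SequenceRecord(
                    seq_id, residues, status=UNREVIEWED, taxon=taxon, label=UNKNOWN
                )
            records.append(rec)
            membership[seq_id] = spec.family_id
            for element, consensus, offset in spec.motifs:
                motif_positions[(seq_id, element)] = (offset, offset + len(consensus))

    return records, SuperfamilyTruth(membership, motif_positions, seed)


def generate_zscore_matrix(
    truth: SuperfamilyTruth,
    mu_within: float = 20.0,
    mu_between: float = 5.0,
    sd: float = 1.0,
    seed: int = 0,
) -> ZScoreMatrix:
    """Structural Z-score fixture matching the planted family structure.

    Within-family entries are Normal(mu_within, sd) truncated at 0,
    between-family entries Normal(mu_between, sd); the matrix is symmetric
    and the diagonal is set to the maximum entry.
    """
    if not mu_within > mu_between >= 0:
        raise ValueError("need mu_within > mu_between >= 0")
    rng = np.random.default_rng(seed)
    ids = list(truth.membership)
    fams = np.array([truth.membership[i] for i in ids])
    n = len(ids)
    z = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mu = mu_within if fams[i] == fams[j] else mu_between
            value = max(0.0, rng.normal(mu, sd)) if sd > 0 else mu
            z[i, j] = z[j, i] = value
    np.fill_diagonal(z, z.max() if n > 1 else mu_within)
    return ZScoreMatrix(ids=ids, Z=z)


def write_truth_tsv(truth: SuperfamilyTruth, path: str | Path) -> None:
    """Truth table: seq_id, family_id, element_label, start, end (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tfamily_id\telement_label\tstart\tend\n")
        for seq_id, fam in truth.membership.items():
            elements = [
                (el, pos)
                for (sid, el), pos in truth.motif_positions.items()
                if sid == seq_id
            ]
            if not elements:
                fh.write(f"{seq_id}\t{fam}\t.\t-1\t-1\n")
            for el, (start, end) in elements:
                fh.write(f"{seq_id}\t{fam}\t{el}\t{start}\t{end}\n")


def read_truth_tsv(path: str | Path) -> SuperfamilyTruth:
    membership: dict[str, str] = {}
    motif_positions: dict[tuple[str, str], tuple[int, int]] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("seq_id")
        for line in fh:
            seq_id, fam, el, start, end = line.rstrip("\n").split("\t")
            membership[seq_id] = fam
            if el != ".":
                motif_positions[(seq_id, el)] = (int(start), int(end))
    return SuperfamilyTruth(membership, motif_positions, seed=-1)
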