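"""Protein sequence records and their FASTA/TSV serialisation.

A record carries the metadata the downstream network stages rely on: the
UniProt-style curation status (``curated`` for manually reviewed entries,
``unreviewed`` otherwise), a free-form taxon tag, and a functional label
(``"unknown"`` for uncharacterized sequences).  Metadata travels in the FASTA
description line as ``key=value`` pairs::

    >famA_001 status=curated label=famA taxon=fungi

so that a dataset round-trips through plain FASTA without side tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue characters tolerated on input; X is scored 0 against everything.
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

CURATED = "curated"
UNREVIEWED = "unreviewed"
UNKNOWN = "unknown"


@dataclass
class SequenceRecord:
    """One protein sequence with annotation metadata.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    residues : str
        Amino-acid string over the 20 standard residues (``X`` tolerated).
    status : str
        ``"curated"`` (manually reviewed) or ``"unreviewed"``.
    taxon : str
        Free-form taxon tag; carries no simulation semantics.
    label : str
        Functional label, or ``"unknown"`` for uncharacterized sequences.
    protected : bool
        Protected records are never removed by redundancy filtering.
    """

    id: str
    residues: str
    status: str = UNREVIEWED
    taxon: str = ""
    label: str = UNKNOWN
    protected: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: non-amino-acid characters {sorted(bad)!r} "
                "(only the 20 standard residues plus X are accepted)"
            )
        if self.status not in (CURATED, UNREVIEWED):
            raise ValueError(f"{self.id}: status must be curated|unreviewed")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_curated(self) -> bool:
        return self.status == CURATED

    def with_label(self, label: str) -> "SequenceRecord":
        return replace(self, label=label)


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id}")
        seen.add(rec.id)


def _parse_metadata(description: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in description.split()[1:]:  # token 0 is the id itself
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read records from FASTA, parsing ``key=value`` metadata in headers."""
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        meta = _parse_metadata(bio.description)
        records.append(
            SequenceRecord(
                id=bio.id,
                residues=str(bio.seq),
                status=meta.get("status", UNREVIEWED),
                taxon=meta.get("taxon", ""),
                label=meta.get("label", UNKNOWN),
                protected=meta.get("protected", "false").lower() == "true",
            )
        )
    check_unique_ids(records)
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with metadata in the description line."""
    bio_records = []
    for rec in records:
        desc = f"status={rec.status} label={rec.label} taxon={rec.taxon}"
        if rec.protected:
            desc += " protected=true"
        bio_records.append(
            _BioSeqRecord(Seq(rec.residues), id=rec.id, description=desc)
        )
    with open(path, "w") as handle:
        SeqIO.write(bio_records, handle, "fasta")
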