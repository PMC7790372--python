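"""Published regex fingerprints of the known eukaryotic NAT groups.

The five NAT groups of the GNAT acetyltransferase superfamily (Group 1a
around NAA10/NAA20, Group 1b around NAA30, Group 2 around NAA50/NAA60,
Group 3 around NAA40 and Group 4 around NAA80) are characterised by short
sequence motifs at four key positions of the GNAT fold: the α1-α2 loop,
the β4 and β5 strands, and the β6-β7 loop.  The regular expressions below
encode those fingerprints in the field's table convention: bare letters
for near-invariant residues, bracketed alternatives ordered by frequency,
and ``X`` wildcards.  Groups 3 and 4 have no conserved β6-β7 motif (that
loop plays no substrate-binding role around NAA40/NAA80).
"""

from __future__ import annotations

import numpy as np

from .motifs import GroupFingerprint, motif_from_regex, sample_from_regex

#: element label order mirrors the fold: α1-α2 loop, β4, β5, β6-β7 loop
ELEMENT_ORDER = ("a1a2", "b4", "b5", "b6b7")

KNOWN_GROUP_REGEXES: dict[str, dict[str, str]] = {
    "Group 1a": {
        "a1a2": "[CV]NLD[CN]L[PT]E[NT]Y",
        "b4": "[WP]HGH[IV]T[SA][LV][STA]V",
        "b5": "[FY]V[DS]L[FH]VR[VK]SN",
        "b6b7": "[VI]X[ED][VI]E[KP]KYYA",
    },
    "Group 1b": {
        "a1a2": "L[IV][DQ]K[DE]LSEPY",
        "b4": "RGYIAMLAVD",
        "b5": "E[VI]VLETE[VI][TD]N",
        "b6b7": "R[DE]KRL[FH]RYYL",
    },
    "Group 2": {
        "a1a2": "FP[VI]XY[PNS][DE][KS][FW]Y",
        "b4": "LYI[ML][TS]LGVLAPYR",
        "b5": "A[IV][YF]LHV[QL][TV][ST]N",
        "b6b7": "HS[FY]LPYYYSI",
    },
    "Group 3": {
        "a1a2": "YEQSSWGW[DN][DE]",
        "b4": "VLYCYE[IL]Q[LV]E",
        "b5": "KV[MV]LTV[FL]KHN",
    },
    "Group 4": {
        "a1a2": "CA[DE]L[LI]N[ES][EQ]W[PK]",
        "b4": "[SA][LC][FL]VE[ST]VVV[AS]",
        "b5": "L[TS]THDKQHFY",
    },
}


def group_fingerprint(
    group: str, background: np.ndarray | None = None
) -> GroupFingerprint:
    """The :class:`GroupFingerprint` of one known NAT group."""
    regexes = KNOWN_GROUP_REGEXES[group]
    motifs = [
        (
            element,
            motif_from_regex(
                regexes[element],
                background=background,
                element_label=element,
                name=f"{group}:{element}",
            ),
        )
        for element in ELEMENT_ORDER
        if element in regexes
    ]
    return GroupFingerprint(name=group, motifs=motifs)


def all_group_fingerprints(
    background: np.ndarray | None = None,
) -> list[GroupFingerprint]:
    return [group_fingerprint(g, background) for g in KNOWN_GROUP_REGEXES]


def synthesize_group_member(
    group: str,
    rng: np.random.Generator,
    length: int = 150,
    background: np.ndarray | None = None,
) -> str:
    """A random background sequence carrying one match of each group motif.

    Motif instances are embedded left to right in fold-element order with
    random spacing, emulating an idealised member of the group.
    """
    if background is None:
        from .synthetic import blosum62_background

        background = blosum62_background()
    from .records import AMINO_ACIDS

    regexes = KNOWN_GROUP_REGEXES[group]
    words = [
        sample_from_regex(regexes[e], rng, background)
        for e in ELEMENT_ORDER
        if e in regexes
    ]
    total_motif = sum(len(wd) for wd in words)
    if total_motif > length:
        raise ValueError("length too short for the group fingerprint")
    residues = [
        AMINO_ACIDS[i]
        for i in rng.choice(len(AMINO_ACIDS), size=length, p=background)
    ]
    n_gaps = len(words) + 1
    slack = length - total_motif
    cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
    gaps = np.diff(np.concatenate(([0], cuts, [slack])))
    pos = 0
    for gap, word in zip(gaps, words):
        pos += int(gap)
        residues[pos : pos + len(word)] = word
        pos += len(word)
    return "".join(residues)
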