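"""Motif discovery (ZOOPS EM), regex fingerprints, and PWM scanning.

Discovery fits, per candidate width, a "zero or one occurrence per
sequence" (ZOOPS) mixture model by expectation-maximisation: each sequence
either contains one motif site (probability gamma) at a uniformly chosen
position, or is pure background.  The best motif per round is reported and
its sites masked before the next round.  Significance is assessed against
an empirical shuffle null: the discovery objective (total information
content times expected site count) is recomputed on residue-shuffled
copies of the dataset, a Gumbel tail is fitted to the null maxima, and the
E-value is the tail probability times the size of the search space
(candidate starting points across all widths) — the expected number of
motifs this good arising from background alone.  Only motifs with
E-value < 1 survive.

Scanning mirrors MAST: integer log-odds scores (log2(ppm/background),
x100, rounded), an exact position p-value from convolving the per-column
score distributions under the background, a sequence p-value
``1 - (1 - p)^(L - w + 1)``, and QFAST combination of several motifs'
sequence p-values into one per-sequence significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import AMINO_ACIDS, SequenceRecord

_N_AA = 20
_X_INDEX = 20  # X scores 0 / ratio 1 everywhere
_AA_TO_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_TO_INDEX["X"] = _X_INDEX

#: Pseudocount per residue when estimating position probability matrices.
PSEUDOCOUNT = 0.01

#: Initial ZOOPS site prior.
GAMMA_INIT = 0.8

#: EM convergence: stop when the log-likelihood improves by less than this.
EM_TOL = 1e-4
EM_MAX_ITER = 200


# ---------------------------------------------------------------------------
# Core types


@dataclass
class Motif:
    """A position probability matrix with discovery statistics.

    ``ppm`` has shape (width, 20) with columns summing to 1; ``evalue`` is
    the expected number of equally good motifs under the background null
    (0.0 for motifs constructed rather than discovered).
    """

    ppm: np.ndarray
    n_sites: float = 0.0
    evalue: float = 0.0
    element_label: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != _N_AA:
            raise ValueError("ppm must have shape (width, 20)")
        sums = self.ppm.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every ppm column must sum to 1 (within 1e-9)")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def width(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.ppm.argmax(axis=1))

    @property
    def consensus_regex(self) -> str:
        return regex_from_motif(self)


@dataclass
class GroupFingerprint:
    """Ordered, labelled motif set characterising one functional group."""

    name: str
    motifs: list[tuple[str, Motif]]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.motifs]
        if len(labels) != len(set(labels)):
            raise ValueError(f"{self.name}: element labels must be unique")

    @property
    def elements(self) -> list[str]:
        return [label for label, _ in self.motifs]

    def motif_for(self, element: str) -> Motif:
        for label, motif in self.motifs:
            if label == element:
                return motif
        raise KeyError(element)


@dataclass
class MotifHit:
    """Best occurrence of one motif in one sequence."""

    sequence_id: str
    motif: Motif
    position: int
    score: int
    p_position: float
    p_sequence: float


# ---------------------------------------------------------------------------
# Encoding and background


def encode(residues: str) -> np.ndarray:
    return np.fromiter(
        (_AA_TO_INDEX[c] for c in residues), dtype=np.int64, count=len(residues)
    )


def letter_background(sequences: Sequence[SequenceRecord]) -> np.ndarray:
    """Background frequencies from the letters of the supplied set."""
    counts = np.zeros(_N_AA, dtype=float)
    for rec in sequences:
        enc = encode(rec.residues)
        counts += np.bincount(enc[enc < _N_AA], minlength=_N_AA)
    counts += 1.0  # one pseudo-observation per residue
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# ZOOPS EM machinery


class _WindowSet:
    """All valid windows of one width across a dataset, flattened."""

    def __init__(self, encoded: Sequence[np.ndarray], width: int, masks: Sequence[np.ndarray] | None = None):
        rows = []
        seq_of_window = []
        positions = []
        for i, seq in enumerate(encoded):
            n_win = len(seq) - width + 1
            if n_win <= 0:
                continue
            valid = np.ones(n_win, dtype=bool)
            if masks is not None and masks[i] is not None:
                masked = masks[i]
                # window invalid when any position inside it is masked
                bad = np.flatnonzero(masked)
                for pos in bad:
                    lo = max(0, pos - width + 1)
                    valid[lo : pos + 1] = False
            idx = np.flatnonzero(valid)
            if len(idx) == 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(seq, width)[idx]
            rows.append(windows)
            seq_of_window.append(np.full(len(idx), i))
            positions.append(idx)
        if rows:
            self.W = np.concatenate(rows, axis=0)
            self.seq_of_window = np.concatenate(seq_of_window)
            self.positions = np.concatenate(positions)
        else:
            self.W = np.empty((0, width), dtype=np.int64)
            self.seq_of_window = np.empty(0, dtype=np.int64)
            self.positions = np.empty(0, dtype=np.int64)
        self.width = width
        self.n_seqs = len(encoded)
        # boundaries for per-sequence segment reductions
        self.seq_ids_present, self.seq_starts = np.unique(
            self.seq_of_window, return_index=True
        )

    @property
    def n_windows(self) -> int:
        return self.W.shape[0]


def _log_ratio_matrix(ppm: np.ndarray, background: np.ndarray) -> np.ndarray:
    """(w, 21) log(ppm/bg) with the X column fixed at 0."""
    w = ppm.shape[0]
    out = np.zeros((w, _N_AA + 1))
    out[:, :_N_AA] = np.log(ppm) - np.log(background)[None, :]
    return out


def _window_log_ratios(ws: _WindowSet, ppm: np.ndarray, background: np.ndarray) -> np.ndarray:
    M = _log_ratio_matrix(ppm, background)
    lr = np.zeros(ws.n_windows)
    for k in range(ws.width):
        lr += M[k, ws.W[:, k]]
    return lr


def _zoops_em(
    ws: _WindowSet,
    background: np.ndarray,
    ppm0: np.ndarray,
    gamma0: float = GAMMA_INIT,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Run ZOOPS EM from a starting PPM.

    Returns (ppm, gamma, window posteriors z, log-likelihood).  The
    log-likelihood is relative to the all-background model (constant
    terms dropped) and is non-decreasing across iterations.
    """
    ppm = ppm0.copy()
    gamma = gamma0
    n_present = len(ws.seq_ids_present)
    m_i = np.diff(np.append(ws.seq_starts, ws.n_windows))  # windows per sequence
    seg = np.repeat(np.arange(n_present), m_i)  # present-sequence index per window
    ll_old = -np.inf
    z = np.zeros(ws.n_windows)
    for _ in range(max_iter):
        lr = _window_log_ratios(ws, ppm, background)
        r = np.exp(lr)
        S_i = np.add.reduceat(r, ws.seq_starts)
        denom_i = (1.0 - gamma) + (gamma / m_i) * S_i
        ll = float(np.sum(np.log(denom_i)))
        z = (gamma / m_i)[seg] * r / denom_i[seg]
        # M-step
        counts = np.zeros((ws.width, _N_AA))
        for k in range(ws.width):
            binned = np.bincount(ws.W[:, k], weights=z, minlength=_N_AA + 1)
            counts[k] = binned[:_N_AA]
        counts += PSEUDOCOUNT
        ppm = counts / counts.sum(axis=1, keepdims=True)
        q_i = (gamma / m_i) * S_i / denom_i
        gamma = float(np.clip(q_i.sum() / max(n_present, 1), 1e-3, 1 - 1e-3))
        if ll - ll_old < tol:
            ll_old = ll
            break
        ll_old = ll
    return ppm, gamma, z, ll_old


def _information_content(ppm: np.ndarray, background: np.ndarray) -> float:
    return float(np.sum(ppm * (np.log2(ppm) - np.log2(background)[None, :])))


def _objective(ppm: np.ndarray, z: np.ndarray, background: np.ndarray) -> float:
    return _information_content(ppm, background) * float(z.sum())


def _seed_windows(ws: _WindowSet, rng: np.random.Generator, n_dup: int = 3, n_rand: int = 2) -> list[np.ndarray]:
    """Starting-point windows: most-repeated w-mers plus random draws.

    A w-mer occurring in many distinct sequences is a strong ZOOPS start;
    repeated exact words dominate conserved-motif datasets.  Random
    windows keep the search honest on diffuse data.
    """
    if ws.n_windows == 0:
        return []
    seen: dict[bytes, set[int]] = {}
    for row, seq_idx in zip(ws.W, ws.seq_of_window):
        key = row.tobytes()
        seen.setdefault(key, set()).add(int(seq_idx))
    ranked = sorted(
        seen.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )
    seeds = [
        np.frombuffer(key, dtype=ws.W.dtype) for key, _ in ranked[:n_dup]
    ]
    taken = {s.tobytes() for s in seeds}
    order = rng.permutation(ws.n_windows)
    for idx in order:
        if len(seeds) >= n_dup + n_rand:
            break
        row = ws.W[idx]
        if row.tobytes() not in taken:
            seeds.append(row.copy())
            taken.add(row.tobytes())
    return seeds


def _ppm_from_window(window: np.ndarray, background: np.ndarray, weight: float = 0.6) -> np.ndarray:
    w = len(window)
    ppm = np.tile(background * (1.0 - weight), (w, 1))
    for k, res in enumerate(window):
        if res < _N_AA:
            ppm[k, res] += weight
        else:  # X seed position: plain background
            ppm[k] = background
    return ppm / ppm.sum(axis=1, keepdims=True)


def _best_motif_for_width(
    ws: _WindowSet, background: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Best EM fit over the starting points; (ppm, z, objective)."""
    seeds = _seed_windows(ws, rng)
    if not seeds:
        return None
    best = None
    for seed in seeds:
        ppm0 = _ppm_from_window(seed, background)
        ppm, gamma, z, ll = _zoops_em(ws, background, ppm0)
        obj = _objective(ppm, z, background)
        if best is None or obj > best[2]:
            best = (ppm, z, obj)
    return best


def _gumbel_tail(null_values: np.ndarray, observed: float) -> float:
    """P(Null >= observed) under a moment-fitted Gumbel.

    Null values are best-over-restarts maxima, for which the Gumbel family
    is the natural fit; its tail is heavier than a normal's, keeping the
    estimate conservative for large exceedances.
    """
    mu_hat = float(np.mean(null_values))
    sd_hat = float(np.std(null_values, ddof=1))
    if sd_hat <= 0:
        return 1.0 if observed <= mu_hat else 0.0
    beta = sd_hat * math.sqrt(6.0) / math.pi
    mu = mu_hat - 0.5772156649 * beta
    t = (observed - mu) / beta
    # 1 - exp(-exp(-t)), stable for large t
    if t > 30:
        return math.exp(-t)
    return -math.expm1(-math.exp(-t))


def discover_motifs(
    sequences: Sequence[SequenceRecord],
    max_motifs: int = 25,
    width_range: Sequence[int] = tuple(range(5, 11)),
    seed: int = 0,
    n_shuffle: int = 20,
    background: np.ndarray | None = None,
) -> list[Motif]:
    """Discover up to ``max_motifs`` ZOOPS motifs with E-value < 1.

    Per round, every width in ``width_range`` (a subset of 5..10) is fitted
    by EM from the best substring-derived starting points; the most
    significant motif is reported and its sites masked before the next
    round.  Motifs are returned sorted ascending by E-value.
    """
    if len(sequences) < 5:
        raise ValueError("motif discovery needs at least 5 sequences")
    widths = sorted(set(int(w) for w in width_range))
    if not widths or widths[0] < 5 or widths[-1] > 10:
        raise ValueError("width_range must be within [5, 10]")
    rng = np.random.default_rng(seed)
    if background is None:
        background = letter_background(sequences)

    encoded = [encode(rec.residues) for rec in sequences]
    n_candidates = sum(
        max(0, len(s) - w + 1) for s in encoded for w in widths
    )

    # Null distribution of the per-width best objective on shuffled data.
    null_best: dict[int, list[float]] = {w: [] for w in widths}
    for _ in range(n_shuffle):
        shuffled = [rng.permutation(seq) for seq in encoded]
        for w in widths:
            ws = _WindowSet(shuffled, w)
            fit = _best_motif_for_width(ws, background, rng)
            null_best[w].append(fit[2] if fit else 0.0)

    masks = [np.zeros(len(s), dtype=bool) for s in encoded]
    motifs: list[Motif] = []
    for round_idx in range(max_motifs):
        # Per round, keep the highest-objective motif among the widths
        # passing the E < 1 filter (the E-values of hugely significant
        # motifs are not finely comparable across widths; the objective,
        # total information x sites, is).
        best_candidate = None
        for w in widths:
            ws = _WindowSet(encoded, w, masks)
            fit = _best_motif_for_width(ws, background, rng)
            if fit is None:
                continue
            ppm, z, obj = fit
            p_tail = _gumbel_tail(np.asarray(null_best[w]), obj)
            evalue = p_tail * n_candidates
            if evalue >= 1.0:
                continue
            if best_candidate is None or obj > best_candidate[1]:
                best_candidate = (evalue, obj, ppm, z, ws)
        if best_candidate is None:
            break
        evalue, obj, ppm, z, ws = best_candidate
        # confident sites: best window per sequence with posterior >= 0.5
        n_sites = 0
        ends = np.append(ws.seq_starts[1:], ws.n_windows)
        for start, end, seq_idx in zip(ws.seq_starts, ends, ws.seq_ids_present):
            j = int(np.argmax(z[start:end])) + int(start)
            if z[j] >= 0.5:
                n_sites += 1
                pos = int(ws.positions[j])
                masks[int(seq_idx)][pos : pos + ws.width] = True
        motifs.append(
            Motif(
                ppm=ppm,
                n_sites=n_sites if n_sites else float(z.sum()),
                evalue=float(evalue),
                name=f"motif_{round_idx + 1}",
            )
        )
    motifs.sort(key=lambda m: m.evalue)
    return [m for m in motifs if m.evalue < 1.0]


# ---------------------------------------------------------------------------
# Regex fingerprints


def regex_from_motif(motif: Motif, include_threshold: float = 0.2) -> str:
    """Table-style regex: per column, residues with probability >= threshold.

    One qualifying residue gives a bare letter, two or three a bracketed
    set ordered by descending probability, anything else the wildcard X.
    """
    if not 0.0 < include_threshold <= 0.5:
        raise ValueError("include_threshold must be in (0, 0.5]")
    parts = []
    for col in motif.ppm:
        qualifying = [
            (float(col[i]), AMINO_ACIDS[i])
            for i in range(_N_AA)
            if col[i] >= include_threshold
        ]
        qualifying.sort(key=lambda pa: (-pa[0], pa[1]))
        if len(qualifying) == 1:
            parts.append(qualifying[0][1])
        elif 2 <= len(qualifying) <= 3:
            parts.append("[" + "".join(a for _, a in qualifying) + "]")
        else:
            parts.append("X")
    return "".join(parts)


def parse_regex(regex: str) -> list[list[str]]:
    """Split a fingerprint regex into per-column residue alternatives.

    ``X`` denotes any residue (empty alternative list).  Whitespace is
    ignored.
    """
    columns: list[list[str]] = []
    i = 0
    regex = "".join(regex.split())
    while i < len(regex):
        c = regex[i]
        if c == "[":
            j = regex.index("]", i)
            columns.append(list(regex[i + 1 : j]))
            i = j + 1
        elif c == "X":
            columns.append([])
            i += 1
        else:
            columns.append([c])
            i += 1
    return columns


def motif_from_regex(
    regex: str,
    background: np.ndarray | None = None,
    consensus_mass: float = 0.95,
    element_label: str | None = None,
    name: str = "",
) -> Motif:
    """Build a PPM from a fingerprint regex.

    Listed residues share ``consensus_mass`` of each column's probability
    (slightly favouring earlier entries, which Table-style regexes order
    by frequency); the remainder follows the background.  ``X`` columns
    are pure background.
    """
    if background is None:
        from .synthetic import blosum62_background

        background = blosum62_background()
    columns = parse_regex(regex)
    ppm = np.zeros((len(columns), _N_AA))
    for k, alts in enumerate(columns):
        if not alts:
            ppm[k] = background
            continue
        ppm[k] = background * (1.0 - consensus_mass)
        # descending weights 1.0, 0.9, 0.8... preserve the regex ordering
        weights = np.array([1.0 - 0.1 * j for j in range(len(alts))])
        weights /= weights.sum()
        for a, wgt in zip(alts, weights):
            ppm[k, _AA_TO_INDEX[a]] += consensus_mass * wgt
    ppm /= ppm.sum(axis=1, keepdims=True)
    return Motif(ppm=ppm, element_label=element_label, name=name or regex)


def sample_from_regex(regex: str, rng: np.random.Generator, background: np.ndarray | None = None) -> str:
    """Draw one string matching a fingerprint regex."""
    if background is None:
        from .synthetic import blosum62_background

        background = blosum62_background()
    out = []
    for alts in parse_regex(regex):
        if not alts:
            out.append(AMINO_ACIDS[rng.choice(_N_AA, p=background)])
        else:
            out.append(alts[rng.integers(len(alts))])
    return "".join(out)


# ---------------------------------------------------------------------------
# Scanning


def _int_log_odds(motif: Motif, background: np.ndarray) -> np.ndarray:
    """(w, 21) integer log-odds, log2(ppm/bg) x 100 rounded; X scores 0."""
    lo = np.zeros((motif.width, _N_AA + 1), dtype=np.int64)
    ratios = (
        np.log2(np.maximum(motif.ppm, 1e-300))
        - np.log2(np.maximum(background, 1e-300))[None, :]
    )
    # residues absent from the background can never be emitted by the
    # null; give them a hard penalty rather than an overflowing ratio
    ratios = np.clip(ratios, -1e4, 1e4)
    lo[:, :_N_AA] = np.rint(100.0 * ratios).astype(np.int64)
    return lo


def _score_distribution(log_odds: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact distribution of the window score under the background.

    Returns (probabilities, offset) with probabilities[s - offset] =
    P(score = s), from convolving the per-column score distributions.
    """
    emitted = np.flatnonzero(background > 0)
    dist = np.array([1.0])
    offset = 0
    for k in range(log_odds.shape[0]):
        scores = log_odds[k, emitted]
        lo, hi = int(scores.min()), int(scores.max())
        col = np.zeros(hi - lo + 1)
        for a, s in zip(emitted, scores):
            col[int(s) - lo] += background[a]
        dist = np.convolve(dist, col)
        offset += lo
    return dist, offset


def scan_with_motif(
    motif: Motif,
    sequence: SequenceRecord | str,
    background: np.ndarray | None = None,
) -> MotifHit:
    """Best motif occurrence in a sequence with exact p-values.

    The position p-value is P(score >= observed) for a single window under
    the background; the sequence p-value corrects for the L - w + 1
    scanned windows.
    """
    if background is None:
        from .synthetic import blosum62_background

        background = blosum62_background()
    if isinstance(sequence, SequenceRecord):
        seq_id, residues = sequence.id, sequence.residues
    else:
        seq_id, residues = "", sequence
    w = motif.width
    if len(residues) < w:
        raise ValueError(f"sequence shorter than motif width {w}")
    log_odds = _int_log_odds(motif, background)
    enc = encode(residues)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    scores = np.zeros(len(windows), dtype=np.int64)
    for k in range(w):
        scores += log_odds[k, windows[:, k]]
    best_pos = int(np.argmax(scores))
    best = int(scores[best_pos])
    dist, offset = _score_distribution(log_odds, background)
    tail_index = best - offset
    if tail_index <= 0:
        p_pos = 1.0
    elif tail_index >= len(dist):
        p_pos = 0.0
    else:
        p_pos = float(dist[tail_index:].sum())
    p_pos = min(max(p_pos, 5e-324), 1.0)
    n_windows = len(residues) - w + 1
    p_seq = -math.expm1(n_windows * math.log1p(-min(p_pos, 1.0 - 1e-16)))
    p_seq = min(max(p_seq, 5e-324), 1.0)
    return MotifHit(
        sequence_id=seq_id,
        motif=motif,
        position=best_pos,
        score=best,
        p_position=p_pos,
        p_sequence=p_seq,
    )


def qfast_combine(p_values: Sequence[float]) -> float:
    """QFAST product-of-p-values correction.

    For k p-values with product p, the combined significance is
    ``p * sum_{i=0}^{k-1} (-ln p)^i / i!`` — the tail of the product of k
    independent uniforms.
    """
    k = len(p_values)
    if k == 0:
        raise ValueError("no p-values to combine")
    log_p = sum(math.log(max(p, 5e-324)) for p in p_values)
    if log_p == 0.0:
        return 1.0
    # sum in log space is unnecessary: k is small (<= a handful of motifs)
    p = math.exp(log_p)
    total = 0.0
    term = 1.0
    for i in range(k):
        total += term
        term *= -log_p / (i + 1)
    return min(p * total, 1.0)


def fingerprint_score(
    fingerprint: GroupFingerprint,
    sequences: Sequence[SequenceRecord],
    background: np.ndarray | None = None,
    presence_alpha: float = 0.05,
) -> tuple[dict[str, float], dict[str, dict[str, bool]], float]:
    """Score sequences against a fingerprint.

    Returns (per-sequence combined p-value, per-sequence per-element
    presence table, cluster-level score = median combined p-value).
    """
    if not fingerprint.motifs:
        raise ValueError("fingerprint is empty")
    combined: dict[str, float] = {}
    presence: dict[str, dict[str, bool]] = {}
    for rec in sequences:
        p_values = []
        presence[rec.id] = {}
        for element, motif in fingerprint.motifs:
            if len(rec) < motif.width:
                p_values.append(1.0)
                presence[rec.id][element] = False
                continue
            hit = scan_with_motif(motif, rec, background)
            p_values.append(hit.p_sequence)
            presence[rec.id][element] = hit.p_sequence <= presence_alpha
        combined[rec.id] = qfast_combine(p_values)
    cluster_score = float(np.median(list(combined.values()))) if combined else 1.0
    return combined, presence, cluster_score


# ---------------------------------------------------------------------------
# Fingerprint comparison


@dataclass
class MotifDifference:
    element: str
    position: int  # column index in the first motif's coordinates
    residue_1: str
    frequency_1: float
    residue_2: str
    frequency_2: float

    def __str__(self) -> str:
        return (
            f"{self.element}[{self.position}]: {self.residue_1}"
            f"({self.frequency_1:.2f}) -> {self.residue_2}({self.frequency_2:.2f})"
        )


def _best_offset(ppm1: np.ndarray, ppm2: np.ndarray, min_overlap: int = 5) -> tuple[int, float]:
    """Ungapped offset of ppm2 relative to ppm1 maximising column correlation."""
    w1, w2 = ppm1.shape[0], ppm2.shape[0]
    min_overlap = min(min_overlap, w1, w2)
    best = (0, -np.inf)
    for offset in range(-(w2 - min_overlap), w1 - min_overlap + 1):
        cols1 = range(max(0, offset), min(w1, offset + w2))
        corrs = []
        for c1 in cols1:
            c2 = c1 - offset
            a, b = ppm1[c1], ppm2[c2]
            sa, sb = a.std(), b.std()
            if sa > 0 and sb > 0:
                corrs.append(float(np.corrcoef(a, b)[0, 1]))
        if corrs and np.mean(corrs) > best[1]:
            best = (offset, float(np.mean(corrs)))
    return best


def diff_fingerprints(
    f1: GroupFingerprint, f2: GroupFingerprint
) -> list[MotifDifference]:
    """Per-element, per-position modal-residue differences.

    For each element label shared by both fingerprints, the two motifs are
    aligned at the ungapped offset maximising mean column-wise Pearson
    correlation of their PPMs; positions whose modal residues differ are
    reported with both residues and their frequencies.  No shared element
    yields an empty report.
    """
    shared = [e for e in f1.elements if e in f2.elements]
    if not shared:
        import logging

        logging.getLogger(__name__).warning(
            "fingerprints %s and %s share no element labels", f1.name, f2.name
        )
        return []
    differences: list[MotifDifference] = []
    for element in shared:
        m1, m2 = f1.motif_for(element), f2.motif_for(element)
        offset, _ = _best_offset(m1.ppm, m2.ppm)
        for c1 in range(max(0, offset), min(m1.width, offset + m2.width)):
            c2 = c1 - offset
            i1 = int(m1.ppm[c1].argmax())
            i2 = int(m2.ppm[c2].argmax())
            if i1 != i2:
                differences.append(
                    MotifDifference(
                        element=element,
                        position=c1,
                        residue_1=AMINO_ACIDS[i1],
                        frequency_1=float(m1.ppm[c1, i1]),
                        residue_2=AMINO_ACIDS[i2],
                        frequency_2=float(m2.ppm[c2, i2]),
                    )
                )
    return differences


def assign_elements(
    candidate_motifs: Sequence[Motif],
    reference: GroupFingerprint,
    min_correlation: float = 0.5,
) -> list[tuple[str, Motif]]:
    """Label candidate motifs by their best-matching reference element.

    Greedy unique assignment by descending alignment correlation;
    candidates correlating below ``min_correlation`` with every reference
    element (unrelated motifs) are dropped rather than force-matched.
    """
    scored = []
    for motif in candidate_motifs:
        for element, ref in reference.motifs:
            _, corr = _best_offset(ref.ppm, motif.ppm)
            scored.append((corr, element, motif))
    scored.sort(key=lambda t: -t[0])
    assigned: list[tuple[str, Motif]] = []
    used_elements: set[str] = set()
    used_motifs: set[int] = set()
    for corr, element, motif in scored:
        if element in used_elements or id(motif) in used_motifs:
            continue
        if corr < min_correlation:
            break
        assigned.append((element, motif))
        used_elements.add(element)
        used_motifs.add(id(motif))
    return assigned


# ---------------------------------------------------------------------------
# Serialisation


def write_meme_minimal(
    motifs: Sequence[Motif], background: np.ndarray, path: str | Path
) -> None:
    """Write motifs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AMINO_ACIDS + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{a} {background[i]:.5f}" for i, a in enumerate(AMINO_ACIDS))
            + "\n\n"
        )
        for motif in motifs:
            name = motif.name or motif.consensus
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= {_N_AA} w= {motif.width} "
                f"nsites= {motif.n_sites:.0f} E= {motif.evalue:.3g}\n"
            )
            for col in motif.ppm:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def write_regex_table(
    fingerprints: Sequence[GroupFingerprint], path: str | Path
) -> None:
    """Regex table TSV: group, element, regex."""
    with open(path, "w") as fh:
        fh.write("group\telement\tregex\n")
        for fp in fingerprints:
            for element, motif in fp.motifs:
                fh.write(f"{fp.name}\t{element}\t{regex_from_motif(motif)}\n")


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmotif_id\tposition\tscore\tp_pos\tp_seq\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.motif.name}\t{h.position}\t{h.score}\t"
                f"{h.p_position:.3e}\t{h.p_sequence:.3e}\n"
            )
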