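"""Position-specific scoring matrices (PSSMs) and best-window promoter scanning.

A PSSM stores per-position log-odds (base 2, so scores read in bits) of each
DNA base against a background distribution.  The motif score of a promoter is
the maximum over all equal-length windows of the summed log-odds — the
highest-scoring window is the matched motif box.  Direct-repeat (DR) motifs,
used for regulators such as ArcA whose sites are tandem copies of a short
unit, are built by concatenating the unit's letter-probability matrix ``k``
times with uniform (zero log-odds) gap columns between copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_io import Promoter, reverse_complement

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

__all__ = [
    "PSSM",
    "MotifHit",
    "build_pssm",
    "build_dr_pssm",
    "dr_cutoff",
    "scan",
    "scan_sequence",
    "hamming",
]


@dataclass(frozen=True)
class PSSM:
    """Log-odds scoring matrix for one binding motif.

    ``matrix`` has shape (length, 4) in A,C,G,T order; entry (i, b) is
    log2 of the smoothed probability of base b at position i over the
    background probability of b.  ``source`` tags provenance: "ChIP", "ICA",
    "DR-k" for a k-fold direct repeat, or "sigma".
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float
    source: str = "ChIP"
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PSSM {self.name}: matrix must be (length, 4)")
        b = np.asarray(self.background, dtype=float)
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValueError(f"PSSM {self.name}: background must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", b)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        """Highest log-odds base at each position."""
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def consensus_score(self) -> float:
        """Sum of per-position column maxima; no window can score above it."""
        return float(self.matrix.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring window of one PSSM on one sequence.

    ``offset`` is the window start relative to the TSS (signed bp); for plain
    sequences without a TSS it is the window start index.  ``start`` is the
    window start index within the scanned sequence.  For reverse-strand hits
    ``site_sequence`` is the reverse complement of the genomic window, so it
    always aligns with the motif reading direction.
    """

    pssm_name: str
    score: float
    offset: int
    start: int
    strand_of_hit: str  # "forward" or "reverse"
    site_sequence: str

    @property
    def distance_to_tss(self) -> int:
        return self.offset


def _smooth_probabilities(
    probs: np.ndarray, background: np.ndarray, pseudocount: float
) -> np.ndarray:
    # p' = (p + c*b) / (1 + c): mass c split by background.
    return (probs + pseudocount * background) / (1.0 + pseudocount)


def build_pssm(
    sites: Sequence[str] | None = None,
    probabilities: np.ndarray | None = None,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.5,
    name: str = "motif",
    source: str = "ChIP",
) -> PSSM:
    """Build a PSSM from aligned binding-site sequences or a letter-probability matrix.

    From sites, per-position probabilities are
    ``(count + pseudocount * background) / (n + pseudocount)``; from a
    probability matrix, rows are smoothed as
    ``(p + pseudocount * background) / (1 + pseudocount)``.  Log-odds are
    taken base 2 against the background.

    Parameters
    ----------
    sites:
        Equal-length aligned binding-site sequences (exclusive with
        ``probabilities``).
    probabilities:
        (length, 4) letter-probability matrix with rows summing to 1.
    pseudocount:
        Total pseudo-observation mass per position, split by background.
        Must be positive whenever any count/probability is zero.
    """
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if (sites is None) == (probabilities is None):
        raise ValueError("provide exactly one of sites or probabilities")

    if sites is not None:
        sites = [s.upper() for s in sites]
        lengths = {len(s) for s in sites}
        if len(lengths) != 1:
            offender = next(s for s in sites if len(s) != len(sites[0]))
            raise ValueError(
                f"ragged alignment: {offender!r} (length {len(offender)}) differs "
                f"from {sites[0]!r} (length {len(sites[0])})"
            )
        length = lengths.pop()
        counts = np.zeros((length, 4))
        for s in sites:
            for i, c in enumerate(s):
                if c not in BASE_INDEX:
                    raise ValueError(f"illegal base {c!r} in site {s!r}")
                counts[i, BASE_INDEX[c]] += 1
        n = len(sites)
        probs = (counts + pseudocount * background) / (n + pseudocount)
    else:
        probs = np.asarray(probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probabilities must be (length, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("probability rows must sum to 1")
        probs = _smooth_probabilities(probs, background, pseudocount)

    if (probs <= 0).any():
        raise ValueError("zero probability with zero pseudocount; use pseudocount > 0")
    matrix = np.log2(probs / background)
    return PSSM(
        name=name,
        matrix=matrix,
        background=background,
        pseudocount=pseudocount,
        source=source,
        probabilities=probs,
    )


def build_dr_pssm(
    unit_probabilities: np.ndarray,
    k: int,
    gap: int = 0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.5,
    name: str | None = None,
) -> PSSM:
    """Build a direct-repeat PSSM: ``k`` copies of a unit motif with uniform gaps.

    The result has length ``k * unit_length + (k - 1) * gap``; gap columns are
    uniform, hence contribute log-odds 0 to every window score.  Tagged with
    source ``"DR-k"``.
    """
    if k < 2:
        raise ValueError(f"direct repeat needs k >= 2 copies, got k={k}")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    unit = np.asarray(unit_probabilities, dtype=float)
    uniform = np.full((gap, 4), 0.25)
    blocks: list[np.ndarray] = []
    for i in range(k):
        if i:
            blocks.append(uniform)
        blocks.append(unit)
    probs = np.vstack(blocks) if blocks else unit
    return build_pssm(
        probabilities=probs,
        background=background,
        pseudocount=pseudocount,
        name=name or f"DR{k}",
        source=f"DR-{k}",
    )


def dr_cutoff(pssm: PSSM, confirmed_site_sequences: Sequence[str]) -> float:
    """Score threshold for calling DR sites: mean scan score of confirmed sites."""
    if not confirmed_site_sequences:
        raise ValueError("need at least one confirmed site sequence")
    return float(
        np.mean([scan_sequence(pssm, s).score for s in confirmed_site_sequences])
    )


def _encode(sequence: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and N -> 4 (scored as background, log-odds 0)."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
    table[ord("N")] = 4
    idx = table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        pos = int(np.argmax(idx < 0))
        raise ValueError(f"illegal character {sequence[pos]!r} at position {pos + 1}")
    return idx.astype(np.intp)


def _window_scores(pssm: PSSM, sequence: str) -> np.ndarray:
    """Score of every window start; N positions contribute 0."""
    idx = _encode(sequence)
    L = pssm.length
    n = len(sequence) - L + 1
    if n <= 0:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif length {L}"
        )
    padded = np.hstack([pssm.matrix, np.zeros((L, 1))])  # column 4 for N
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return padded[np.arange(L), windows].sum(axis=1)


def scan_sequence(
    pssm: PSSM,
    sequence: str,
    strands: str = "both",
    tss_index: int = 0,
) -> MotifHit:
    """Best-window scan of a raw sequence.

    Ties are broken by leftmost window start, with the forward strand
    preferred over reverse at equal offset and score.  ``tss_index`` shifts
    reported offsets so they read relative to a TSS.
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    sequence = sequence.upper()
    fwd = _window_scores(pssm, sequence)
    candidates: list[tuple[float, int, int]] = []  # (score, start, strand_rank)
    best_fwd = int(np.argmax(fwd))
    candidates.append((fwd[best_fwd], best_fwd, 0))
    if strands == "both":
        rc = reverse_complement(sequence)
        rev = _window_scores(pssm, rc)
        # window starting at j on the reverse complement covers forward
        # positions [len - L - j, len - j)
        L = pssm.length
        starts = len(sequence) - L - np.arange(len(rev))
        # pick, among reverse windows, max score then leftmost forward start
        order = np.lexsort((starts, -rev))
        j = int(order[0])
        candidates.append((rev[j], int(starts[j]), 1))
    score, start, strand_rank = max(
        candidates, key=lambda c: (c[0], -c[1], -c[2])
    )
    strand_of_hit = "forward" if strand_rank == 0 else "reverse"
    window_seq = sequence[start : start + pssm.length]
    if strand_of_hit == "reverse":
        window_seq = reverse_complement(window_seq)
    return MotifHit(
        pssm_name=pssm.name,
        score=float(score),
        offset=start - tss_index,
        start=start,
        strand_of_hit=strand_of_hit,
        site_sequence=window_seq,
    )


def scan(
    pssm: PSSM,
    promoter: Promoter,
    search_window: tuple[int, int] = (-150, 50),
    strands: str = "both",
) -> MotifHit:
    """Best-window scan of a promoter within a TSS-relative search window.

    ``search_window = (a, b)`` admits windows fully inside ``[a, b)`` relative
    to the TSS.  The hit's ``offset`` is the window start relative to the TSS.
    """
    a, b = search_window
    lo = max(0, promoter.tss_index + a)
    hi = min(len(promoter.sequence), promoter.tss_index + b)
    if hi - lo < pssm.length:
        raise ValueError(
            f"search window [{a}, {b}) leaves {hi - lo} bp, "
            f"shorter than motif length {pssm.length}"
        )
    sub = promoter.sequence[lo:hi]
    hit = scan_sequence(pssm, sub, strands=strands, tss_index=promoter.tss_index - lo)
    return MotifHit(
        pssm_name=hit.pssm_name,
        score=hit.score,
        offset=hit.offset,
        start=hit.start + lo,
        strand_of_hit=hit.strand_of_hit,
        site_sequence=hit.site_sequence,
    )


def hamming(sequence: str, consensus: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(sequence) != len(consensus):
        raise ValueError(
            f"unequal lengths: {len(sequence)} vs {len(consensus)}"
        )
    return sum(a != b for a, b in zip(sequence.upper(), consensus.upper()))
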