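"""Sigma-factor promoter architecture: -10/-35 boxes, spacer, AT ratios.

Bacterial RNA polymerase holoenzyme recognizes two conserved elements
upstream of the TSS: the -10 (Pribnow) box and the -35 box, separated by a
spacer of variable length.  For each sigma factor this module places both
boxes by best-window PSSM search and derives the feature block used for
classification: box motif scores, Hamming distances to the consensus, box
distances to the TSS, spacer length, the highest AT ratio of any 7 bp
segment within the spacer, and the AT ratio of the extended -10 element
(the bases immediately upstream of the -10 box).

Placement is greedy and two-stage: the -10 box is the best forward-strand
window within 20 bp upstream of the TSS, then the -35 box is the best window
within the 40 bp upstream of the placed -10 box.  Anchoring the -35 search to
the -10 box guarantees a non-negative spacer.  Promoters are already oriented
with transcription, so only the forward strand is searched.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Promoter
from .motifs import PSSM, MotifHit, build_pssm, hamming, scan_sequence

__all__ = [
    "BoxPlacement",
    "SigmaFeatureBlock",
    "locate_boxes",
    "spacer_at_ratio",
    "extended_minus10_at_ratio",
    "sigma_feature_block",
    "default_sigma_pssms",
    "SIGMA_CONSENSUS",
]

# Canonical -35 / -10 consensus hexamers for the six major E. coli sigma
# factors (sigma54 uses -24/-12 elements; they fill the same two slots).
SIGMA_CONSENSUS: dict[str, tuple[str, str]] = {
    "sigma70": ("TTGACA", "TATAAT"),
    "sigma38": ("TTGACA", "TATACT"),
    "sigma32": ("TTGAAA", "CCCCAT"),
    "sigma24": ("GAACTT", "TCTGAT"),
    "sigma54": ("TGGCAC", "TTGCAT"),
    "sigma28": ("TAAAGT", "GCCGAT"),
}

MINUS10_SEARCH_BP = 20  # search range upstream of the TSS for the -10 box
MINUS35_SEARCH_BP = 40  # search range upstream of the -10 box for the -35 box


@dataclass(frozen=True)
class BoxPlacement:
    """Placed -10/-35 boxes of one sigma factor on one promoter."""

    sigma_name: str
    minus10: MotifHit
    minus35: MotifHit
    spacer_sequence: str

    @property
    def spacer_length(self) -> int:
        """Gap in bp between the -35 box end and the -10 box start."""
        return self.minus10.start - (self.minus35.start + len(self.minus35.site_sequence))

    @property
    def minus10_distance(self) -> int:
        """bp from the -10 box start to the TSS (positive upstream)."""
        return -self.minus10.offset

    @property
    def minus35_distance(self) -> int:
        return -self.minus35.offset


@dataclass(frozen=True)
class SigmaFeatureBlock:
    """Per-sigma-factor promoter features (9 values)."""

    sigma_name: str
    minus10_score: float
    minus35_score: float
    minus10_hamming: int
    minus35_hamming: int
    spacer_length: int
    spacer_at_ratio: float
    extended_minus10_at_ratio: float | None
    minus10_distance: int
    minus35_distance: int

    def to_dict(self) -> dict[str, float | None]:
        p = self.sigma_name
        return {
            f"{p}_m10_score": self.minus10_score,
            f"{p}_m35_score": self.minus35_score,
            f"{p}_m10_hamming": float(self.minus10_hamming),
            f"{p}_m35_hamming": float(self.minus35_hamming),
            f"{p}_spacer_len": float(self.spacer_length),
            f"{p}_spacer_at": self.spacer_at_ratio,
            f"{p}_ext_m10_at": self.extended_minus10_at_ratio,
            f"{p}_m10_dist": float(self.minus10_distance),
            f"{p}_m35_dist": float(self.minus35_distance),
        }


def default_sigma_pssms(
    consensus_weight: float = 0.85, pseudocount: float = 0.5
) -> dict[str, tuple[PSSM, PSSM]]:
    """(minus10, minus35) PSSM pairs built from canonical consensus hexamers.

    Columns put ``consensus_weight`` probability on the consensus base and
    split the rest evenly — a soft consensus standing in for alignment-derived
    matrices when none are supplied.
    """
    import numpy as np

    from .motifs import BASE_INDEX

    def soft(seq: str) -> np.ndarray:
        m = np.full((len(seq), 4), (1 - consensus_weight) / 3)
        for i, c in enumerate(seq):
            m[i, BASE_INDEX[c]] = consensus_weight
        return m

    out = {}
    for name, (m35, m10) in SIGMA_CONSENSUS.items():
        p10 = build_pssm(
            probabilities=soft(m10), pseudocount=pseudocount,
            name=f"{name}_m10", source="sigma",
        )
        p35 = build_pssm(
            probabilities=soft(m35), pseudocount=pseudocount,
            name=f"{name}_m35", source="sigma",
        )
        out[name] = (p10, p35)
    return out


def locate_boxes(
    promoter: Promoter, minus10_pssm: PSSM, minus35_pssm: PSSM
) -> BoxPlacement:
    """Place the -10 then the -35 box by greedy best-window search.

    The -10 box is searched on the forward strand among windows lying fully
    within the ``MINUS10_SEARCH_BP`` bases upstream of the TSS; the -35 box
    among windows within the ``MINUS35_SEARCH_BP`` bases upstream of the
    placed -10 box start.
    """
    tss = promoter.tss_index
    L10 = minus10_pssm.length

    lo = tss - MINUS10_SEARCH_BP
    if lo < 0:
        raise ValueError(
            f"promoter {promoter.tu_id}: needs >= {MINUS10_SEARCH_BP} bp upstream "
            f"of the TSS for the -10 search, has {tss}"
        )
    hit10 = scan_sequence(
        minus10_pssm, promoter.sequence[lo:tss], strands="forward", tss_index=tss - lo
    )
    m10_start = hit10.start + lo
    hit10 = MotifHit(
        pssm_name=hit10.pssm_name,
        score=hit10.score,
        offset=m10_start - tss,
        start=m10_start,
        strand_of_hit="forward",
        site_sequence=hit10.site_sequence,
    )

    lo35 = max(0, m10_start - MINUS35_SEARCH_BP)
    if m10_start - lo35 < minus35_pssm.length:
        raise ValueError(
            f"promoter {promoter.tu_id}: insufficient upstream sequence for -35 search"
        )
    hit35 = scan_sequence(
        minus35_pssm,
        promoter.sequence[lo35:m10_start],
        strands="forward",
        tss_index=tss - lo35,
    )
    m35_start = hit35.start + lo35
    hit35 = MotifHit(
        pssm_name=hit35.pssm_name,
        score=hit35.score,
        offset=m35_start - tss,
        start=m35_start,
        strand_of_hit="forward",
        site_sequence=hit35.site_sequence,
    )

    spacer = promoter.sequence[m35_start + minus35_pssm.length : m10_start]
    return BoxPlacement(
        sigma_name=minus10_pssm.name.rsplit("_", 1)[0],
        minus10=hit10,
        minus35=hit35,
        spacer_sequence=spacer,
    )


def _at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(c in "AT" for c in seq) / len(seq)


def spacer_at_ratio(placement: BoxPlacement, segment: int = 7) -> float:
    """Highest AT ratio of any ``segment``-bp window within the spacer.

    Spacers shorter than the segment use the whole-spacer AT ratio; an empty
    spacer scores 0.
    """
    s = placement.spacer_sequence
    if len(s) < segment:
        return _at_fraction(s)
    return max(
        _at_fraction(s[i : i + segment]) for i in range(len(s) - segment + 1)
    )


def extended_minus10_at_ratio(
    placement: BoxPlacement, promoter: Promoter, ext_len: int = 4
) -> float | None:
    """AT fraction of the ``ext_len`` bases immediately upstream of the -10 box.

    Returns ``None`` (missing, never 0) when fewer than ``ext_len`` bases
    exist upstream of the box.
    """
    start = placement.minus10.start
    if start - ext_len < 0:
        return None
    return _at_fraction(promoter.sequence[start - ext_len : start])


def sigma_feature_block(
    promoter: Promoter, sigma_pssms: dict[str, tuple[PSSM, PSSM]]
) -> dict[str, SigmaFeatureBlock | None]:
    """Compute one :class:`SigmaFeatureBlock` per configured sigma factor.

    Hamming distances are computed between the placed box sequence and the
    PSSM consensus.  A sigma factor whose boxes cannot be placed (insufficient
    upstream sequence) maps to ``None`` rather than being dropped.
    """
    blocks: dict[str, SigmaFeatureBlock | None] = {}
    for name, (p10, p35) in sigma_pssms.items():
        try:
            placement = locate_boxes(promoter, p10, p35)
        except ValueError:
            blocks[name] = None
            continue
        blocks[name] = SigmaFeatureBlock(
            sigma_name=name,
            minus10_score=placement.minus10.score,
            minus35_score=placement.minus35.score,
            minus10_hamming=hamming(placement.minus10.site_sequence, p10.consensus),
            minus35_hamming=hamming(placement.minus35.site_sequence, p35.consensus),
            spacer_length=placement.spacer_length,
            spacer_at_ratio=spacer_at_ratio(placement),
            extended_minus10_at_ratio=extended_minus10_at_ratio(placement, promoter),
            minus10_distance=placement.minus10_distance,
            minus35_distance=placement.minus35_distance,
        )
    return blocks
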