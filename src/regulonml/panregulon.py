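"""Cross-strain pan-regulon reconstruction by exact transcription-unit mapping.

A transcription unit (TU) from a reference strain is located in another
strain's genome by exact substring search on both strands: exactly one
occurrence is a unique match (with locus), none means absent, several mean
ambiguous (excluded from pan-regulon membership).  Exact matching replaces a
full aligner because inexact alignments are discarded anyway.

Per-strain regulated-TU sets are partitioned into the pan-regulon classes:
core (regulated in every strain), unique (in exactly one), accessory (the
rest, i.e. in at least two but not all).  Helpers relate ChIP peak
signal-to-noise ratios, motif scores and expression responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import Genome, reverse_complement

__all__ = [
    "TUMapping",
    "PanRegulon",
    "map_tu",
    "build_pan_regulon",
    "sn_grouping",
    "expression_response",
    "score_response_correlation",
]

MIN_TU_LENGTH = 20  # guard against spurious exact matches


@dataclass(frozen=True)
class TUMapping:
    """Result of mapping one TU sequence onto one strain genome."""

    tu_id: str
    strain: str
    status: str  # "unique-match", "ambiguous", "absent"
    locus: tuple[int, int, str] | None = None  # (start, end, strand), 0-based half-open


@dataclass(frozen=True)
class PanRegulon:
    """Core/accessory/unique partition of regulated TUs across strains."""

    strains: tuple[str, ...]
    regulated_tus: dict[str, frozenset[str]]
    core: frozenset[str]
    accessory: frozenset[str]
    unique: frozenset[str]
    sn_ratios: dict[str, float] = field(default_factory=dict)
    motif_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # the three classes must partition the union of regulated TUs
        union = frozenset().union(*self.regulated_tus.values())
        parts = [self.core, self.accessory, self.unique]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("pan-regulon classes are not disjoint")
        if self.core | self.accessory | self.unique != union:
            raise ValueError("pan-regulon classes do not cover all regulated TUs")


def _find_all(needle: str, haystack: str) -> list[int]:
    out = []
    start = haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def map_tu(tu_sequence: str, genome: Genome, tu_id: str = "", ) -> TUMapping:
    """Exact-match a TU sequence against a genome on both strands.

    A palindromic hit (a self-reverse-complementary TU at one locus) counts
    once.  Sequences shorter than ``MIN_TU_LENGTH`` raise: short probes make
    chance exact matches likely.
    """
    tu_sequence = tu_sequence.upper()
    if len(tu_sequence) < MIN_TU_LENGTH:
        raise ValueError(
            f"TU sequence of {len(tu_sequence)} bp is shorter than the "
            f"{MIN_TU_LENGTH} bp guard"
        )
    L = len(tu_sequence)
    hits: list[tuple[int, int, str]] = [
        (s, s + L, "+") for s in _find_all(tu_sequence, genome.sequence)
    ]
    rc = reverse_complement(tu_sequence)
    if rc != tu_sequence:
        hits += [(s, s + L, "-") for s in _find_all(rc, genome.sequence)]
    if not hits:
        return TUMapping(tu_id=tu_id, strain=genome.id, status="absent")
    if len(hits) > 1:
        return TUMapping(tu_id=tu_id, strain=genome.id, status="ambiguous")
    return TUMapping(tu_id=tu_id, strain=genome.id, status="unique-match", locus=hits[0])


def build_pan_regulon(
    per_strain_regulated: Mapping[str, set[str] | frozenset[str]],
    sn_ratios: Mapping[str, float] | None = None,
    motif_scores: Mapping[str, float] | None = None,
) -> PanRegulon:
    """Partition per-strain regulated-TU sets into core/accessory/unique."""
    strains = tuple(per_strain_regulated)
    if len(strains) < 2:
        raise ValueError("pan-regulon needs >= 2 strains")
    sets = {s: frozenset(tus) for s, tus in per_strain_regulated.items()}
    union = frozenset().union(*sets.values())
    if not union:
        raise ValueError("no regulated TUs in any strain")
    presence = {tu: sum(tu in sets[s] for s in strains) for tu in union}
    core = frozenset(t for t, n in presence.items() if n == len(strains))
    unique = frozenset(t for t, n in presence.items() if n == 1)
    accessory = union - core - unique
    return PanRegulon(
        strains=strains,
        regulated_tus=sets,
        core=core,
        accessory=accessory,
        unique=unique,
        sn_ratios=dict(sn_ratios or {}),
        motif_scores=dict(motif_scores or {}),
    )


def sn_grouping(
    sn: Mapping[str, float], cutoff: float = 10.0
) -> tuple[frozenset[str], frozenset[str]]:
    """Split genes into high and low ChIP signal-to-noise at a cutoff.

    The boundary value (S/N exactly equal to the cutoff) is assigned to the
    high group.
    """
    for g, v in sn.items():
        if v < 0:
            raise ValueError(f"negative S/N ratio for {g}: {v}")
    high = frozenset(g for g, v in sn.items() if v >= cutoff)
    low = frozenset(sn) - high
    return high, low


def expression_response(
    tpm_experiment: float, tpm_control: float, pseudocount: float = 1.0
) -> float:
    """Expression change log2((tpm_exp + c) / (tpm_ctrl + c))."""
    if tpm_experiment < 0 or tpm_control < 0:
        raise ValueError("TPM values must be >= 0")
    return float(np.log2((tpm_experiment + pseudocount) / (tpm_control + pseudocount)))


def score_response_correlation(
    scores: Sequence[float], responses: Sequence[float]
) -> tuple[float | None, float | None]:
    """Spearman rank correlation between motif scores and expression responses.

    Returns ``(rho, p)``; with a constant input vector rho is undefined and
    both are ``None``.  Requires at least 10 paired observations.
    """
    scores = np.asarray(scores, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if scores.shape != responses.shape:
        raise ValueError("scores and responses must align")
    if scores.size < 10:
        raise ValueError("need >= 10 paired observations")
    if np.ptp(scores) == 0 or np.ptp(responses) == 0:
        return None, None
    rho, p = stats.spearmanr(scores, responses)
    return float(rho), float(p)
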