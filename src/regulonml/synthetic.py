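"""Synthetic promoter, regulon, strain-family and expression generators.

Every downstream stage of the package — motif scanning, sigma/shape feature
assembly, regulon classification, pan-regulon reconstruction — is exercised
on data produced here, with a known planted signal.  Positive promoters carry
one binding site sampled from a planted letter-probability matrix of
controlled total information content, inserted at a uniform position inside a
TSS-relative planting window; negatives are i.i.d. background sequence with a
configurable GC fraction.  Labels may be flipped at a configurable rate after
planting, emulating mis-assignment in inferred regulons.  Strain families
embed transcription units (TUs) verbatim into multiple genomes with a
designed core/accessory/unique conservation pattern and a site-strength
gradient (core strongest).  All generators are pure functions of
(config, seed): the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Genome, Promoter, Regulon, write_genome, write_motifs, write_regulons, write_tss_gff3
from .motifs import ALPHABET, BASE_INDEX
from .shape import ALL_PARAMS, ShapeTable, all_pentamers

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "StrainFamily",
    "generate_pwm",
    "generate_regulon_dataset",
    "generate_strain_family",
    "generate_expression_response",
    "generate_pentamer_table",
    "write_regulon_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for all synthetic generators.

    The defaults are the conditions the package is characterized under:
    500 promoters of 200 bp (150 up / 50 down of the TSS), 40 regulon
    members carrying one planted 10 bp site of ~12 bits total information
    inside [-100, -20) of the TSS, uniform base composition, no label noise,
    and a 4-strain family.
    """

    seed: int = 0
    n_promoters: int = 500
    promoter_upstream: int = 150
    promoter_downstream: int = 50
    n_positives: int = 40
    motif_length: int = 10
    motif_information: float = 12.0
    planting_window: tuple[int, int] = (-100, -20)
    gc_background: float = 0.5
    label_noise: float = 0.0
    multi_gene_probs: tuple[float, ...] = (0.7, 0.2, 0.1)  # P(1, 2, 3 genes per TU)
    # strain-family settings
    n_strains: int = 4
    n_tus: int = 12
    tu_length: int = 80
    core_fraction: float = 0.4
    accessory_fraction: float = 0.3
    unique_fraction: float = 0.3
    unique_information_factor: float = 0.35  # weaker sites in unique TUs
    genome_spacer: int = 60  # background bp between embedded TUs
    # expression response
    expression_noise_sd: float = 0.5

    @property
    def promoter_length(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    def __post_init__(self) -> None:
        for name in ("gc_background", "label_noise", "core_fraction",
                     "accessory_fraction", "unique_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.core_fraction + self.accessory_fraction + self.unique_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"core+accessory+unique fractions sum to {total}, must be 1"
            )
        if self.n_positives >= self.n_promoters:
            raise ValueError("n_positives must be < n_promoters")
        a, b = self.planting_window
        if b - a > self.promoter_length:
            raise ValueError("planting_window longer than the promoter")
        if b - a < self.motif_length:
            raise ValueError("planting_window shorter than the motif")
        if not abs(sum(self.multi_gene_probs) - 1.0) < 1e-9:
            raise ValueError("multi_gene_probs must sum to 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset."""

    planted_pwm: np.ndarray
    planted_positions: dict[str, int]  # promoter id -> site start offset rel. TSS
    true_labels: pd.Series  # pre-noise labels, indexed by promoter id
    strain_partition: dict[str, frozenset[str]] | None = None
    true_response_slope: float | None = None


@dataclass(frozen=True)
class StrainFamily:
    """A synthetic multi-strain genome family with embedded TUs."""

    genomes: dict[str, Genome]
    tu_sequences: dict[str, str]
    tu_strains: dict[str, frozenset[str]]  # designed presence
    truth: SyntheticTruth
    tu_site_scores: dict[str, float]  # planted-site strength proxy (bits)


# ---------------------------------------------------------------------------
# PWM generation with controlled information content
# ---------------------------------------------------------------------------

def _column_entropy(x: float) -> float:
    """Entropy (bits) of the column (x, (1-x)/3, (1-x)/3, (1-x)/3)."""
    if x >= 1.0:
        return 0.0
    rest = (1.0 - x) / 3.0
    h = -x * math.log2(x) if x > 0 else 0.0
    h += -3.0 * rest * math.log2(rest) if rest > 0 else 0.0
    return h


def _solve_column(info_target: float) -> float:
    """Consensus probability x such that 2 - H(column) = info_target (bits)."""
    lo, hi = 0.25, 1.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if 2.0 - _column_entropy(mid) < info_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_pwm(length: int, information: float, seed: int) -> np.ndarray:
    """Random letter-probability matrix with a target total information content.

    Each column concentrates probability on a randomly chosen consensus base
    so that its information (2 - entropy, uniform background) equals
    ``information / length``; the total therefore lands within the 5%
    contract tolerance of the request.

    Raises if ``information`` is infeasible: it must lie in [0, 2*length].
    """
    if length < 4:
        raise ValueError(f"motif length {length} < 4")
    if not 0.0 <= information <= 2.0 * length:
        raise ValueError(
            f"information {information} bits infeasible for length {length}: "
            f"must be within [0, {2.0 * length}]"
        )
    rng = np.random.default_rng(seed)
    per_col = information / length
    pwm = np.empty((length, 4))
    for i in range(length):
        consensus = int(rng.integers(0, 4))
        if per_col <= 1e-12:
            pwm[i] = 0.25
            continue
        x = _solve_column(per_col)
        pwm[i] = (1.0 - x) / 3.0
        pwm[i, consensus] = x
    return pwm


def pwm_information(pwm: np.ndarray) -> float:
    """Total information content in bits against a uniform background."""
    p = np.asarray(pwm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return float((2.0 + plogp.sum(axis=1)).sum())


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(ALPHABET))[rng.choice(4, size=n, p=probs)])


def _sample_site(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join(ALPHABET[rng.choice(4, p=row)] for row in pwm)


# ---------------------------------------------------------------------------
# Regulon dataset
# ---------------------------------------------------------------------------

def generate_regulon_dataset(
    config: SyntheticConfig,
) -> tuple[list[Promoter], pd.Series, SyntheticTruth]:
    """Generate promoters with planted sites, regulon labels and ground truth.

    Positives carry one site sampled from the planted PWM at a position
    uniform in ``planting_window`` (site fully inside the window); negatives
    are pure background.  ``label_noise`` flips that fraction of labels after
    planting.  Promoter group structure (some TUs carrying several genes) is
    carried on :class:`Promoter.gene_ids`; the group id for cross-validation
    is the TU id.

    Returns ``(promoters, labels, truth)`` with labels indexed by promoter id.
    """
    rng = np.random.default_rng(config.seed)
    pwm = generate_pwm(config.motif_length, config.motif_information,
                       seed=int(rng.integers(0, 2**31 - 1)))
    a, b = config.planting_window
    lo = config.promoter_upstream + a
    hi = config.promoter_upstream + b - config.motif_length
    if lo < 0 or hi + config.motif_length > config.promoter_length:
        raise ValueError("planting_window does not fit inside the promoter")

    positive_idx = set(
        rng.choice(config.n_promoters, size=config.n_positives, replace=False).tolist()
    )
    promoters: list[Promoter] = []
    planted: dict[str, int] = {}
    labels = {}
    gene_counter = 0
    n_genes_choices = np.arange(1, len(config.multi_gene_probs) + 1)
    for i in range(config.n_promoters):
        tu_id = f"TU{i:04d}"
        n_genes = int(rng.choice(n_genes_choices, p=config.multi_gene_probs))
        gene_ids = tuple(f"g{gene_counter + j:05d}" for j in range(n_genes))
        gene_counter += n_genes
        seq = list(_random_sequence(rng, config.promoter_length, config.gc_background))
        if i in positive_idx:
            start = int(rng.integers(lo, hi + 1))
            site = _sample_site(rng, pwm)
            seq[start : start + config.motif_length] = site
            planted[tu_id] = start - config.promoter_upstream
        promoters.append(
            Promoter(
                tu_id=tu_id,
                gene_ids=gene_ids,
                tss=config.promoter_upstream + i * config.promoter_length,
                strand="+",
                sequence="".join(seq),
                upstream=config.promoter_upstream,
                downstream=config.promoter_downstream,
            )
        )
        labels[tu_id] = 1 if i in positive_idx else 0

    true_labels = pd.Series(labels, name="label")
    observed = true_labels.copy()
    n_flip = int(round(config.label_noise * config.n_promoters))
    if n_flip:
        flip = rng.choice(config.n_promoters, size=n_flip, replace=False)
        ids = observed.index.to_numpy()[flip]
        observed.loc[ids] = 1 - observed.loc[ids]

    truth = SyntheticTruth(
        planted_pwm=pwm,
        planted_positions=planted,
        true_labels=true_labels,
    )
    return promoters, observed, truth


# ---------------------------------------------------------------------------
# Multi-strain family
# ---------------------------------------------------------------------------

def generate_strain_family(config: SyntheticConfig, max_retries: int = 20) -> StrainFamily:
    """Generate a strain family with a designed core/accessory/unique TU partition.

    Core TUs are embedded verbatim in every strain, accessory TUs in at least
    2 but fewer than all strains, unique TUs in exactly one; each embedded TU
    occurs exactly once per genome (verified on both strands; the genome is
    rebuilt on collision, erroring after bounded retries).  Core TUs carry
    consensus planted sites, accessory TUs PWM-sampled sites, and unique TUs
    sites from an information-degraded PWM, producing the designed
    core > accessory > unique site-strength gap.
    """
    if config.n_strains < 2:
        raise ValueError("strain family needs n_strains >= 2")
    rng = np.random.default_rng(config.seed + 1)
    pwm = generate_pwm(config.motif_length, config.motif_information,
                       seed=int(rng.integers(0, 2**31 - 1)))
    weak_pwm = generate_pwm(
        config.motif_length,
        config.motif_information * config.unique_information_factor,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    consensus = "".join(ALPHABET[i] for i in pwm.argmax(axis=1))

    n_core = max(1, int(round(config.core_fraction * config.n_tus)))
    n_unique = max(1, int(round(config.unique_fraction * config.n_tus)))
    n_acc = config.n_tus - n_core - n_unique
    if config.n_strains == 2:
        n_core += n_acc  # accessory (>=2 and <2 strains) is impossible
        n_acc = 0
    if n_acc < 0:
        raise ValueError("n_tus too small for the requested fractions")

    strains = [f"strain{s + 1}" for s in range(config.n_strains)]
    tu_sequences: dict[str, str] = {}
    tu_strains: dict[str, frozenset[str]] = {}
    tu_scores: dict[str, float] = {}
    classes: dict[str, str] = {}

    def make_tu(tag: str, idx: int, site: str) -> str:
        tu_id = f"{tag}{idx:02d}"
        body = list(_random_sequence(rng, config.tu_length, config.gc_background))
        pos = int(rng.integers(0, config.tu_length - config.motif_length + 1))
        body[pos : pos + config.motif_length] = site
        tu_sequences[tu_id] = "".join(body)
        return tu_id

    for i in range(n_core):
        tu = make_tu("core", i, consensus)
        tu_strains[tu] = frozenset(strains)
        classes[tu] = "core"
    for i in range(n_acc):
        tu = make_tu("acc", i, _sample_site(rng, pwm))
        size = int(rng.integers(2, config.n_strains))  # in [2, n_strains-1]
        members = rng.choice(config.n_strains, size=size, replace=False)
        tu_strains[tu] = frozenset(strains[m] for m in members)
        classes[tu] = "accessory"
    for i in range(n_unique):
        tu = make_tu("uniq", i, _sample_site(rng, weak_pwm))
        tu_strains[tu] = frozenset([strains[i % config.n_strains]])
        classes[tu] = "unique"

    # ensure TU sequences are pairwise distinct
    if len(set(tu_sequences.values())) != len(tu_sequences):
        raise RuntimeError("TU sequence collision; choose a longer tu_length")

    from .motifs import build_pssm, scan_sequence

    pssm = build_pssm(probabilities=pwm, name="planted", pseudocount=0.5)
    for tu, seq in tu_sequences.items():
        tu_scores[tu] = scan_sequence(pssm, seq).score

    def build_genome(strain: str, attempt_seed: int) -> Genome:
        g_rng = np.random.default_rng(attempt_seed)
        present = [tu for tu in tu_sequences if strain in tu_strains[tu]]
        order = list(g_rng.permutation(present))
        parts = [_random_sequence(g_rng, config.genome_spacer, config.gc_background)]
        for tu in order:
            parts.append(tu_sequences[tu])
            parts.append(_random_sequence(g_rng, config.genome_spacer, config.gc_background))
        return Genome(id=strain, sequence="".join(parts))

    def occurrences(needle: str, haystack: str) -> int:
        from .genome_io import reverse_complement

        n = 0
        for probe in {needle, reverse_complement(needle)}:
            start = haystack.find(probe)
            while start != -1:
                n += 1
                start = haystack.find(probe, start + 1)
        return n

    genomes: dict[str, Genome] = {}
    for s_i, strain in enumerate(strains):
        for attempt in range(max_retries):
            g = build_genome(strain, config.seed + 1000 * (s_i + 1) + attempt)
            ok = all(
                occurrences(tu_sequences[tu], g.sequence)
                == (1 if strain in tu_strains[tu] else 0)
                for tu in tu_sequences
            )
            if ok:
                genomes[strain] = g
                break
        else:
            raise RuntimeError(
                f"could not embed TUs collision-free in {strain} "
                f"after {max_retries} attempts"
            )

    partition = {
        "core": frozenset(t for t, c in classes.items() if c == "core"),
        "accessory": frozenset(t for t, c in classes.items() if c == "accessory"),
        "unique": frozenset(t for t, c in classes.items() if c == "unique"),
    }
    truth = SyntheticTruth(
        planted_pwm=pwm,
        planted_positions={},
        true_labels=pd.Series(dtype=int),
        strain_partition=partition,
    )
    return StrainFamily(
        genomes=genomes,
        tu_sequences=tu_sequences,
        tu_strains=tu_strains,
        truth=truth,
        tu_site_scores=tu_scores,
    )


# ---------------------------------------------------------------------------
# Expression response
# ---------------------------------------------------------------------------

def generate_expression_response(
    scores: Sequence[float], slope: float, noise_sd: float, seed: int
) -> np.ndarray:
    """Expression change monotone in motif score: slope * z(score) + noise.

    The score vector is standardized so ``slope`` reads as the response (in
    log-expression-change units) per standard deviation of motif score.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    rng = np.random.default_rng(seed)
    return slope * z + rng.normal(0.0, noise_sd, size=s.size)


# ---------------------------------------------------------------------------
# Pentamer shape-table fixture
# ---------------------------------------------------------------------------

# Plausible parameter ranges (translations in Angstrom, angles in degrees).
_SHAPE_RANGES: dict[str, tuple[float, float]] = {
    "MGW": (2.8, 6.2),
    "ProT": (-16.0, -1.0),
    "Buckle": (-10.0, 10.0),
    "Shear": (-0.5, 0.5),
    "Stretch": (-0.3, 0.3),
    "Stagger": (-0.5, 0.5),
    "Opening": (-5.0, 3.0),
    "Roll": (-8.0, 8.0),
    "HelT": (30.0, 40.0),
    "Shift": (-0.6, 0.6),
    "Slide": (-1.2, 0.8),
    "Rise": (3.1, 3.6),
    "Tilt": (-5.0, 5.0),
}


def generate_pentamer_table(seed: int) -> ShapeTable:
    """Synthetic pentamer shape table: 1024 rows x 13 finite parameters.

    Values are drawn uniformly within parameter-specific plausible ranges;
    the table is a deterministic function of the seed.  It carries the format
    and statistical role of a published pentamer table, not its physics.
    """
    rng = np.random.default_rng(seed)
    pents = all_pentamers()
    data = {
        param: rng.uniform(lo, hi, size=len(pents))
        for param, (lo, hi) in _SHAPE_RANGES.items()
    }
    df = pd.DataFrame(data, index=pd.Index(pents, name="pentamer"))
    return ShapeTable(table=df[list(ALL_PARAMS)])


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def write_regulon_dataset(
    promoters: list[Promoter],
    labels: pd.Series,
    truth: SyntheticTruth,
    out_dir: str | Path,
    regulon_name: str = "planted",
) -> None:
    """Write a generated dataset as FASTA / GFF3 / MEME / TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(
        [Genome(id=p.tu_id, sequence=p.sequence) for p in promoters],
        out / "promoters.fasta",
    )
    write_tss_gff3(promoters, genome_id="synthetic", path=out / "tss.gff3")
    write_motifs([(f"{regulon_name}_pwm", truth.planted_pwm)], out / "planted_motif.meme")
    regulons = [
        Regulon(
            name=regulon_name,
            source="ICA",
            members=frozenset(
                g for p in promoters if labels[p.tu_id] == 1 for g in p.gene_ids
            ),
        )
    ]
    write_regulons(regulons, out / "regulons.tsv")
    groups = pd.DataFrame(
        {
            "promoter_id": [p.tu_id for p in promoters],
            "tu_id": [p.tu_id for p in promoters],
            "genes": [",".join(p.gene_ids) for p in promoters],
            "label": [int(labels[p.tu_id]) for p in promoters],
        }
    )
    groups.to_csv(out / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "promoter_id": list(truth.planted_positions),
            "planted_offset": list(truth.planted_positions.values()),
        }
    ).to_csv(out / "truth_positions.tsv", sep="\t", index=False)
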