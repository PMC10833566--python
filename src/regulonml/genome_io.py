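"""Genome, annotation, motif and regulon input/output.

Coordinates are 0-based, half-open everywhere inside the package. The two
interchange formats that disagree with that convention are converted at the
boundary: GFF3 (1-based, closed) and BED (0-based, half-open, i.e. native).

A :class:`Promoter` is a strand-aware sequence window around a transcription
start site (TSS).  The default window spans 150 bp upstream and 50 bp
downstream of the TSS, giving a 200 bp sequence with the TSS base at index
``upstream``; on the minus strand the stored sequence is reverse-complemented
so that the index always increases in the direction of transcription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

__all__ = [
    "Genome",
    "Promoter",
    "Regulon",
    "read_genome",
    "read_genomes",
    "write_genome",
    "reverse_complement",
    "extract_promoter",
    "read_motifs",
    "write_motifs",
    "read_regulons",
    "write_regulons",
    "read_sites",
    "write_sites",
    "read_sn_table",
    "write_tss_gff3",
    "read_tss_gff3",
]


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class Genome:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        _validate_alphabet(self.sequence, where=self.id)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Promoter:
    """Strand-aware promoter window around a TSS.

    ``sequence`` has length ``upstream + downstream`` with the TSS base at
    index ``upstream``, oriented in the direction of transcription.
    """

    tu_id: str
    gene_ids: tuple[str, ...]
    tss: int
    strand: str
    sequence: str
    upstream: int = 150
    downstream: int = 50

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != self.upstream + self.downstream:
            raise ValueError(
                f"promoter {self.tu_id}: sequence length {len(self.sequence)} "
                f"!= upstream + downstream = {self.upstream + self.downstream}"
            )

    @property
    def promoter_id(self) -> str:
        return self.tu_id

    @property
    def tss_index(self) -> int:
        """Index of the TSS base within ``sequence``."""
        return self.upstream

    @property
    def contains_n(self) -> bool:
        return "N" in self.sequence


@dataclass(frozen=True)
class Regulon:
    """A regulator's gene set, from ICA inference or ChIP experiments."""

    name: str
    source: str  # "ICA" or "ChIP"
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"regulon {self.name}: empty member set")


def _validate_alphabet(sequence: str, where: str = "sequence") -> None:
    bad = set(sequence) - VALID_BASES
    if bad:
        pos = next(i for i, c in enumerate(sequence) if c in bad)
        raise AlphabetError(
            f"{where}: illegal character {sequence[pos]!r} at position {pos + 1}"
        )


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genomes(path: str | Path) -> list[Genome]:
    """Read all records of a FASTA file as :class:`Genome` objects.

    Sequences are uppercased; characters outside {A,C,G,T,N} raise
    :class:`AlphabetError` with the offending character and 1-based position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [Genome(id=r.id, sequence=str(r.seq).upper()) for r in records]


def read_genome(path: str | Path) -> Genome:
    """Read a single-record FASTA file; concatenation is never silent."""
    genomes = read_genomes(path)
    if len(genomes) > 1:
        raise ValueError(
            f"{path}: {len(genomes)} records; use read_genomes() for multi-FASTA"
        )
    return genomes[0]


def write_genome(genomes: Genome | Iterable[Genome], path: str | Path) -> None:
    if isinstance(genomes, Genome):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def extract_promoter(
    genome: Genome,
    tss: int,
    strand: str,
    window: tuple[int, int] = (150, 50),
    tu_id: str = "",
    gene_ids: Sequence[str] = (),
) -> Promoter:
    """Extract the strand-aware promoter window around a TSS.

    On the plus strand the window is ``genome[tss - upstream, tss + downstream)``.
    On the minus strand it is the reverse complement of
    ``genome[tss - downstream + 1, tss + upstream + 1)``, so that the TSS base
    sits at index ``upstream`` and indices increase with transcription in both
    cases.  A window that does not fit inside the genome raises; there is no
    silent truncation.
    """
    upstream, downstream = window
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0 or end > genome.length:
        raise ValueError(
            f"promoter window [{start}, {end}) exceeds genome "
            f"'{genome.id}' bounds [0, {genome.length})"
        )
    seq = genome.sequence[start:end]
    if strand == "-":
        seq = reverse_complement(seq)
    if "N" in seq:
        warnings.warn(f"promoter {tu_id or tss} contains N bases", stacklevel=2)
    return Promoter(
        tu_id=tu_id or f"TU_{tss}{strand}",
        gene_ids=tuple(gene_ids),
        tss=tss,
        strand=strand,
        sequence=seq,
        upstream=upstream,
        downstream=downstream,
    )


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_motifs(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read letter-probability matrices from a minimal MEME motif file.

    Returns ``(name, matrix)`` pairs where ``matrix`` has shape (length, 4)
    in A, C, G, T order.  Each row must sum to 1 within 1e-4; violations
    raise with the motif name and line number.
    """
    motifs: list[tuple[str, np.ndarray]] = []
    name = None
    rows: list[list[float]] = []
    expected_w = None

    def _flush(lineno: int) -> None:
        nonlocal name, rows, expected_w
        if name is None:
            return
        mat = np.asarray(rows, dtype=float)
        if expected_w is not None and mat.shape[0] != expected_w:
            raise ValueError(
                f"{path}: motif {name}: {mat.shape[0]} rows, header says w={expected_w} "
                f"(near line {lineno})"
            )
        for i, s in enumerate(mat.sum(axis=1)):
            if abs(s - 1.0) > 1e-4:
                raise ValueError(
                    f"{path}: motif {name}: row {i + 1} sums to {s:.6f}, not 1 "
                    f"(near line {lineno})"
                )
        motifs.append((name, mat))
        name, rows, expected_w = None, [], None

    last_lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            last_lineno = lineno
            line = raw.strip()
            if line.startswith("MOTIF"):
                _flush(lineno)
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: MOTIF line without a name")
                name = parts[1]
            elif line.startswith("letter-probability"):
                compact = line.replace(" ", "")
                if "w=" in compact:
                    num = ""
                    for c in compact[compact.index("w=") + 2 :]:
                        if c.isdigit():
                            num += c
                        else:
                            break
                    expected_w = int(num) if num else None
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                vals = [float(t) for t in line.split()]
                if len(vals) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: motif {name}: expected 4 columns, got {len(vals)}"
                    )
                rows.append(vals)
    _flush(last_lineno)
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def write_motifs(
    motifs: Iterable[tuple[str, np.ndarray]],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write letter-probability matrices in minimal MEME motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {background[0]:.5f} C {background[1]:.5f} "
            f"G {background[2]:.5f} T {background[3]:.5f}\n\n"
        )
        for name, mat in motifs:
            mat = np.asarray(mat, dtype=float)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
                f"nsites= 20 E= 0\n"
            )
            for row in mat:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Regulons, binding sites, S/N tables
# ---------------------------------------------------------------------------

def read_regulons(
    path: str | Path, known_genes: set[str] | None = None
) -> list[Regulon]:
    """Read a regulon table (``regulon<TAB>source<TAB>gene_id``).

    Duplicate (regulon, gene) rows are collapsed with a warning.  Gene ids not
    in ``known_genes`` (when given) are reported in a warning, never silently
    dropped — they stay in the member set.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"regulon", "source", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if df["gene_id"].isna().any() or (df["gene_id"].astype(str).str.len() == 0).any():
        raise ValueError(f"{path}: empty gene_id in regulon table")
    ndup = df.duplicated(subset=["regulon", "gene_id"]).sum()
    if ndup:
        warnings.warn(f"{path}: collapsed {ndup} duplicate (regulon, gene) rows")
        df = df.drop_duplicates(subset=["regulon", "gene_id"])
    if known_genes is not None:
        unknown = set(df["gene_id"]) - known_genes
        if unknown:
            warnings.warn(
                f"{path}: {len(unknown)} gene ids not in annotation: "
                f"{sorted(unknown)[:5]}..."
            )
    out = []
    for (name, source), grp in df.groupby(["regulon", "source"], sort=True):
        out.append(Regulon(name=name, source=source, members=frozenset(grp["gene_id"])))
    return out


def write_regulons(regulons: Iterable[Regulon], path: str | Path) -> None:
    rows = [
        {"regulon": r.name, "source": r.source, "gene_id": g}
        for r in regulons
        for g in sorted(r.members)
    ]
    pd.DataFrame(rows, columns=["regulon", "source", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_sites(path: str | Path) -> pd.DataFrame:
    """Read a BED6 binding-site table (0-based, half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"{path}: empty/negative interval {bad['name']}")
    df["length"] = df["end"] - df["start"]
    return df


def write_sites(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_sn_table(path: str | Path) -> dict[str, float]:
    """Read a ``gene_id<TAB>sn_ratio`` table into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "sn_ratio"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, sn_ratio")
    if (df["sn_ratio"] < 0).any():
        raise ValueError(f"{path}: negative S/N ratio")
    return dict(zip(df["gene_id"], df["sn_ratio"].astype(float)))


# ---------------------------------------------------------------------------
# GFF3 (1-based closed at the boundary only)
# ---------------------------------------------------------------------------

def write_tss_gff3(promoters: Iterable[Promoter], genome_id: str, path: str | Path) -> None:
    """Write TSS/TU records as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in promoters:
            start1 = p.tss + 1  # 0-based -> 1-based; single-base feature
            attrs = f"ID={p.tu_id};genes={','.join(p.gene_ids)}"
            fh.write(
                f"{genome_id}\tregulonml\tTSS\t{start1}\t{start1}\t.\t{p.strand}\t.\t{attrs}\n"
            )


def read_tss_gff3(path: str | Path) -> pd.DataFrame:
    """Read TSS records back to the internal 0-based convention."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    df = df[df["type"] == "TSS"].copy()
    df["tss"] = df["start"] - 1  # back to 0-based
    df["tu_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    df["genes"] = df["attributes"].str.extract(r"genes=([^;]*)")
    return df[["seqid", "tss", "strand", "tu_id", "genes"]].reset_index(drop=True)
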