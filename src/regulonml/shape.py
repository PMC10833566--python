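"""DNA shape profiles from a pentamer lookup table.

Structural (shape) parameters of double-helical DNA can be predicted from
sequence alone using a table of precomputed values for all 4^5 = 1024
pentamers.  Seven parameters describe a single base pair (intra-base-pair:
minor groove width MGW, propeller twist ProT, Buckle, Shear, Stretch,
Stagger, Opening) and six describe the step between adjacent base pairs
(inter-base-pair: Roll, helix twist HelT, Shift, Slide, Rise, Tilt).

A pentamer window slides along the sequence.  For intra parameters each
pentamer assigns a value to its central base; for inter parameters each
pentamer assigns its value to the two central steps, and steps covered by two
adjacent pentamers are averaged.  Boundary positions without full pentamer
coverage are excluded rather than padded, so an L-mer yields vectors of
length L-4 (intra) and L-3 (inter).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import Promoter
from .motifs import MotifHit

INTRA_PARAMS = ("MGW", "ProT", "Buckle", "Shear", "Stretch", "Stagger", "Opening")
INTER_PARAMS = ("Roll", "HelT", "Shift", "Slide", "Rise", "Tilt")
ALL_PARAMS = INTRA_PARAMS + INTER_PARAMS

SUMMARY_STATS = ("max", "min", "range", "mean")

__all__ = [
    "INTRA_PARAMS",
    "INTER_PARAMS",
    "ALL_PARAMS",
    "ShapeTable",
    "ShapeSummary",
    "shape_vector",
    "summarize",
    "shape_block_at_site",
    "all_pentamers",
]


def all_pentamers() -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=5)]


@dataclass(frozen=True)
class ShapeTable:
    """Pentamer -> 13-parameter lookup table.

    ``table`` is a DataFrame indexed by pentamer with one column per shape
    parameter; exactly 1024 rows, all values finite.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) != 1024:
            raise ValueError(f"shape table has {len(self.table)} rows, expected 1024")
        missing = set(ALL_PARAMS) - set(self.table.columns)
        if missing:
            raise ValueError(f"shape table missing parameters: {sorted(missing)}")
        if not np.isfinite(self.table[list(ALL_PARAMS)].to_numpy()).all():
            raise ValueError("shape table contains non-finite values")

    def lookup(self, pentamer: str, parameter: str) -> float:
        return float(self.table.at[pentamer, parameter])

    def column(self, parameter: str) -> dict[str, float]:
        return self.table[parameter].to_dict()

    def write_tsv(self, path: str | Path) -> None:
        out = self.table[list(ALL_PARAMS)].copy()
        out.index.name = "pentamer"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ShapeTable":
        df = pd.read_csv(path, sep="\t", index_col="pentamer")
        return cls(table=df)


@dataclass(frozen=True)
class ShapeSummary:
    """Four-number summary of one shape vector."""

    max: float
    min: float
    range: float
    mean: float


def shape_vector(sequence: str, table: ShapeTable, parameter: str) -> np.ndarray:
    """Per-position shape profile of one parameter along a sequence.

    Intra-base-pair parameters cover positions 2..L-3 (0-based; length L-4);
    inter-base-pair parameters cover steps 1..L-3 between adjacent bases
    (length L-3), with interior steps averaged over the two pentamers that
    cover them.  N bases are rejected: shape is undefined without a concrete
    pentamer.
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L < 5:
        raise ValueError(f"sequence length {L} < 5: no pentamer coverage")
    if set(sequence) - set("ACGT"):
        bad = next(c for c in sequence if c not in "ACGT")
        raise ValueError(f"shape undefined for base {bad!r} in sequence")
    if parameter not in ALL_PARAMS:
        raise ValueError(f"unknown shape parameter {parameter!r}")

    lut = table.column(parameter)
    pent_values = np.array(
        [lut[sequence[p : p + 5]] for p in range(L - 4)]
    )  # value of pentamer starting at p

    if parameter in INTRA_PARAMS:
        # pentamer starting at p predicts the central base p+2
        return pent_values

    # inter: pentamer starting at p contributes to steps p+1 and p+2
    sums = np.zeros(L - 1)
    counts = np.zeros(L - 1)
    for p in range(L - 4):
        for step in (p + 1, p + 2):
            sums[step] += pent_values[p]
            counts[step] += 1
    covered = counts > 0
    return sums[covered] / counts[covered]


def summarize(vector: np.ndarray) -> ShapeSummary:
    """Maximum, minimum, range and mean of a shape vector."""
    v = np.asarray(vector, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty shape vector")
    vmax, vmin = float(v.max()), float(v.min())
    return ShapeSummary(max=vmax, min=vmin, range=vmax - vmin, mean=float(v.mean()))


def shape_block_at_site(
    promoter: Promoter,
    hit: MotifHit,
    table: ShapeTable,
    flank: int = 0,
) -> dict[str, float] | None:
    """13 x 4 shape feature block at a matched binding site.

    The hit window, extended by ``flank`` bp on each side, is padded by 2 bp
    of promoter context so every site position has full pentamer coverage.
    Sites closer than 2 bp (+ flank) to the promoter edge yield ``None``
    (missing block, imputed downstream), as do windows containing N.

    Returns a flat mapping ``{parameter}_{stat}`` -> value with
    13 parameters x 4 summary statistics = 52 entries.
    """
    site_len = len(hit.site_sequence)
    start = hit.start - flank - 2
    end = hit.start + site_len + flank + 2
    if start < 0 or end > len(promoter.sequence):
        return None
    window = promoter.sequence[start:end]
    if "N" in window:
        return None
    block: dict[str, float] = {}
    for param in ALL_PARAMS:
        vec = shape_vector(window, table, param)
        s = summarize(vec)
        block[f"{param}_max"] = s.max
        block[f"{param}_min"] = s.min
        block[f"{param}_range"] = s.range
        block[f"{param}_mean"] = s.mean
    return block
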