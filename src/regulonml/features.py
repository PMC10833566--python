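"""Per-promoter feature matrix assembly and LDA dimensionality reduction.

The feature matrix has one row per promoter (grouped by transcription unit
id) and named columns: per-motif best-window scores and hit distances to the
TSS, strand direction, sigma-factor architecture features (optionally
projected to one LDA coordinate per sigma factor), and DNA-shape summary
features at each motif's best hit (optionally one LDA coordinate per TF).
Missing values (unplaceable boxes, edge-clipped shape windows) are imputed by
column median, then every column is z-standardized.

The LDA projections are fitted on the full dataset against the relevant
regulon labels, which leaks label information into the features; this mirrors
common practice for such engineered features but inflates cross-validation
estimates.  A strict mode (``strict_lda`` in the classifier) refits the
projections inside training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import Promoter, Regulon
from .motifs import PSSM, MotifHit, scan
from .shape import ShapeTable, shape_block_at_site
from .sigma import sigma_feature_block

__all__ = [
    "LDAProjection",
    "FeatureMatrix",
    "AssemblyConfig",
    "fit_lda",
    "assemble",
    "write_matrix",
    "read_matrix",
    "promoter_labels",
]


@dataclass(frozen=True)
class LDAProjection:
    """A fitted linear discriminant direction over a named feature block.

    ``weights`` is the unit-norm direction proportional to
    ``(S_w + shrinkage * diag(S_w))^-1 (mu1 - mu0)`` with pooled within-class
    covariance ``S_w``, oriented so the positive class projects higher.
    """

    feature_names: tuple[str, ...]
    weights: np.ndarray
    offset: float
    shrinkage: float
    positive_class: str

    def project(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature dimension mismatch")
        return X @ self.weights + self.offset


def fit_lda(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    shrinkage: float = 0.1,
    positive_class: str = "positive",
) -> LDAProjection:
    """Fit a two-class LDA direction with diagonal shrinkage.

    Solves ``(S_w + shrinkage * diag(S_w)) w = mu1 - mu0`` and normalizes
    ``w`` to unit length.  With ``shrinkage = 0`` a singular pooled
    covariance raises with advice to add shrinkage.
    """
    names: tuple[str, ...]
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = tuple(f"f{i}" for i in range(X.shape[1]))
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 2:
        raise ValueError("LDA needs >= 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("LDA needs both classes present")

    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    d0 = X[y == 0] - mu0
    d1 = X[y == 1] - mu1
    sw = (d0.T @ d0 + d1.T @ d1) / max(1, len(y) - 2)
    reg = sw + shrinkage * np.diag(np.diag(sw))
    try:
        w = np.linalg.solve(reg, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; refit with shrinkage > 0"
        ) from exc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate LDA direction (identical class means)")
    w = w / norm
    if w @ mu1 < w @ mu0:  # orientation convention
        w = -w
    offset = -float(w @ (mu0 + mu1) / 2.0)
    return LDAProjection(
        feature_names=names,
        weights=w,
        offset=offset,
        shrinkage=shrinkage,
        positive_class=positive_class,
    )


@dataclass(frozen=True)
class AssemblyConfig:
    """Knobs of feature-matrix assembly."""

    search_window: tuple[int, int] = (-150, 50)
    strands: str = "both"
    use_lda: bool = True
    shrinkage: float = 0.1
    shape_flank: int = 0
    # map TF motif name -> regulon providing labels for its shape LDA;
    # defaults to the motif's own name.
    shape_lda_labels: Mapping[str, str] = field(default_factory=dict)


@dataclass
class FeatureMatrix:
    """Promoters x features with labels, groups and assembly metadata.

    ``X`` is imputed and z-standardized; ``raw`` keeps the pre-imputation
    engineered columns (including LDA source blocks) for strict-mode
    cross-validation refits.  ``lda_blocks`` maps each projection column to
    its source columns and label regulon.
    """

    X: pd.DataFrame
    labels: pd.DataFrame
    groups: pd.Series
    raw: pd.DataFrame | None = None
    lda_blocks: dict[str, tuple[tuple[str, ...], str]] = field(default_factory=dict)
    motif_score_columns: tuple[str, ...] = ()
    dropped_columns: tuple[str, ...] = ()

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def motif_only(self) -> "FeatureMatrix":
        """Restrict to ChIP/ICA/DR motif score columns (motif-only models)."""
        cols = [c for c in self.motif_score_columns if c in self.X.columns]
        return FeatureMatrix(
            X=self.X[cols].copy(),
            labels=self.labels,
            groups=self.groups,
            raw=None,
            lda_blocks={},
            motif_score_columns=tuple(cols),
        )


def promoter_labels(
    promoters: Sequence[Promoter], regulons: Sequence[Regulon]
) -> pd.DataFrame:
    """Binary promoter-level membership: positive if ANY gene is a member."""
    idx = [p.promoter_id for p in promoters]
    data = {}
    for r in regulons:
        data[r.name] = [
            int(any(g in r.members for g in p.gene_ids)) for p in promoters
        ]
    return pd.DataFrame(data, index=idx)


def _impute_standardize(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    filled = df.fillna(df.median(numeric_only=True))
    sd = filled.std(ddof=0)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature column(s): "
                      f"{constant[:4]}...")
        filled = filled.drop(columns=constant)
        sd = sd.drop(index=constant)
    z = (filled - filled.mean()) / sd
    return z, constant


def assemble(
    promoters: Sequence[Promoter],
    tf_pssms: Sequence[PSSM],
    sigma_pssms: Mapping[str, tuple[PSSM, PSSM]],
    shape_table: ShapeTable | None,
    regulons: Sequence[Regulon] | pd.DataFrame,
    config: AssemblyConfig = AssemblyConfig(),
) -> FeatureMatrix:
    """Assemble the engineered feature matrix for a set of promoters.

    For every promoter: each TF/DR motif is scanned over the search window
    (score + hit distance to TSS recorded); sigma blocks are computed and,
    when a regulon named after the sigma factor is supplied, reduced to one
    LDA coordinate; DNA shape summaries are computed at each TF's best hit
    and likewise reduced per TF; strand direction is added.  Missing values
    are median-imputed and all columns z-standardized.

    ``regulons`` may be :class:`Regulon` objects (labels derived per
    promoter) or an already-binary promoter x regulon DataFrame.
    """
    if len({p.promoter_id for p in promoters}) != len(promoters):
        raise ValueError("duplicate promoter ids")
    idx = [p.promoter_id for p in promoters]
    if isinstance(regulons, pd.DataFrame):
        labels = regulons.loc[idx].astype(int)
    else:
        labels = promoter_labels(promoters, regulons)
    if len(labels) != len(promoters):
        raise ValueError("promoter/label mismatch")

    rows: list[dict[str, float]] = []
    hits: dict[str, list[MotifHit]] = {p.name: [] for p in tf_pssms}
    for p in promoters:
        row: dict[str, float] = {"strand_direction": 1.0 if p.strand == "+" else -1.0}
        for pssm in tf_pssms:
            hit = scan(pssm, p, search_window=config.search_window,
                       strands=config.strands)
            hits[pssm.name].append(hit)
            row[f"{pssm.name}_score"] = hit.score
            row[f"{pssm.name}_dist"] = float(hit.distance_to_tss)
        for name, block in sigma_feature_block(p, dict(sigma_pssms)).items():
            if block is None:
                for key in (f"{name}_m10_score",):
                    row[key] = np.nan
            else:
                for key, val in block.to_dict().items():
                    row[key] = np.nan if val is None else float(val)
        if shape_table is not None:
            for pssm in tf_pssms:
                blk = shape_block_at_site(
                    p, hits[pssm.name][-1], shape_table, flank=config.shape_flank
                )
                if blk is None:
                    blk = {}
                for param_stat in _shape_columns():
                    row[f"{pssm.name}_{param_stat}"] = blk.get(param_stat, np.nan)
        rows.append(row)

    raw = pd.DataFrame(rows, index=idx)
    lda_blocks: dict[str, tuple[tuple[str, ...], str]] = {}

    if config.use_lda:
        filled = raw.fillna(raw.median(numeric_only=True))
        # per-sigma LDA against a matching sigmulon, when provided
        for name in sigma_pssms:
            src = tuple(c for c in raw.columns if c.startswith(f"{name}_"))
            if name in labels.columns and len(src) >= 2:
                proj = fit_lda(filled[list(src)], labels[name],
                               shrinkage=config.shrinkage, positive_class=name)
                raw[f"{name}_lda"] = proj.project(filled[list(src)])
                raw = raw.drop(columns=list(src))
                lda_blocks[f"{name}_lda"] = (src, name)
        # per-TF shape LDA against the TF's regulon
        if shape_table is not None:
            for pssm in tf_pssms:
                label_name = config.shape_lda_labels.get(pssm.name, pssm.name)
                src = tuple(
                    f"{pssm.name}_{c}" for c in _shape_columns()
                    if f"{pssm.name}_{c}" in raw.columns
                )
                if label_name in labels.columns and len(src) >= 2:
                    proj = fit_lda(filled[list(src)], labels[label_name],
                                   shrinkage=config.shrinkage,
                                   positive_class=label_name)
                    raw[f"{pssm.name}_shape_lda"] = proj.project(filled[list(src)])
                    raw = raw.drop(columns=list(src))
                    lda_blocks[f"{pssm.name}_shape_lda"] = (src, label_name)

    X, dropped = _impute_standardize(raw)
    groups = pd.Series(
        [p.tu_id for p in promoters], index=idx, name="tu_id"
    )
    motif_cols = tuple(
        f"{p.name}_score" for p in tf_pssms if f"{p.name}_score" in X.columns
    )
    # keep the full pre-imputation engineered columns for strict-mode refits
    raw_full = pd.DataFrame(rows, index=idx)
    return FeatureMatrix(
        X=X,
        labels=labels,
        groups=groups,
        raw=raw_full,
        lda_blocks=lda_blocks,
        motif_score_columns=motif_cols,
        dropped_columns=tuple(dropped),
    )


def _shape_columns() -> list[str]:
    from .shape import ALL_PARAMS, SUMMARY_STATS

    return [f"{p}_{s}" for p in ALL_PARAMS for s in SUMMARY_STATS]


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the feature matrix and a sibling labels TSV.

    ``<path>`` holds ``promoter_id``, ``tu_id`` and the feature columns;
    ``<path>.labels.tsv`` holds ``promoter_id<TAB>regulon<TAB>label``.
    Values survive a round trip to 1e-9 and write->read->write is
    byte-identical.
    """
    path = Path(path)
    out = matrix.X.copy()
    out.insert(0, "tu_id", matrix.groups)
    out.index.name = "promoter_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    stacked = (
        matrix.labels[sorted(matrix.labels.columns)]
        .rename_axis("promoter_id")
        .melt(ignore_index=False, var_name="regulon", value_name="label")
        .reset_index()
    )
    stacked.to_csv(_labels_path(path), sep="\t", index=False)


def _labels_path(path: Path) -> Path:
    return path.with_name(path.name + ".labels.tsv")


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="promoter_id")
    if "tu_id" not in df.columns:
        raise ValueError(f"{path}: missing tu_id column")
    groups = df["tu_id"].astype(str)
    X = df.drop(columns=["tu_id"])
    lp = _labels_path(path)
    if not lp.exists():
        raise ValueError(f"{path}: missing labels file {lp}")
    lab = pd.read_csv(lp, sep="\t")
    if not {"promoter_id", "regulon", "label"}.issubset(lab.columns):
        raise ValueError(f"{lp}: expected columns promoter_id, regulon, label")
    labels = lab.pivot(index="promoter_id", columns="regulon", values="label")
    labels = labels.loc[X.index].astype(int)
    labels.columns.name = None
    motif_cols = tuple(c for c in X.columns if c.endswith("_score"))
    return FeatureMatrix(
        X=X, labels=labels, groups=groups, motif_score_columns=motif_cols
    )
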