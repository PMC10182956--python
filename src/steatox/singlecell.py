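"""Single-cell analytics: cleaning, gating, PCA, subpopulation summaries.

The per-cell feature matrix (from the imaging SQLite export or CSV) is
cleaned of constant and missing-value columns, split into hepatocyte- and
cholangiocyte-like populations by the 5000 px^2 cytoplasm-area gate,
reduced by standardized PCA with per-cell endpoint overlays, and
summarized per subpopulation with notched-boxplot statistics (median,
quartiles, and the conventional median +/- 1.58*IQR/sqrt(n) notch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "AREA_GATE_PX2",
    "CleaningReport",
    "clean_matrix",
    "gate_cell_types",
    "run_pca",
    "summarize_subpopulations",
]

#: cytoplasm-area threshold separating hepatocyte-like (< gate) from
#: cholangiocyte-like (> gate) cells; cells exactly at the gate are
#: assigned to hepatocytes (documented tie rule)
AREA_GATE_PX2 = 5000.0


@dataclass(frozen=True)
class CleaningReport:
    dropped_constant: tuple
    dropped_missing: tuple
    dropped_rows: int


def clean_matrix(
    matrix: pd.DataFrame,
    max_column_missing: float = 0.05,
    id_columns: tuple = ("cell_id", "well", "plate_id", "chemical",
                         "concentration"),
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop constant and missing-value columns, then incomplete rows.

    Feature columns with more than ``max_column_missing`` missing values
    are dropped entirely; remaining rows with any missing value are then
    removed. Identifier/metadata columns are never treated as features.
    Idempotent: cleaning a cleaned matrix changes nothing. Raises if
    nothing survives.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows")
    feats = [c for c in matrix.columns if c not in id_columns]
    const = [c for c in feats if matrix[c].nunique(dropna=True) <= 1]
    kept = [c for c in feats if c not in const]
    too_missing = [c for c in kept
                   if matrix[c].isna().mean() > max_column_missing]
    kept = [c for c in kept if c not in too_missing]
    if not kept:
        raise ValueError("cleaning removed every feature column")
    out = matrix[[c for c in matrix.columns
                  if c in id_columns or c in kept]]
    complete = out[kept].notna().all(axis=1)
    dropped_rows = int((~complete).sum())
    out = out[complete]
    if out.empty:
        raise ValueError("cleaning removed every row")
    if const or too_missing or dropped_rows:
        logger.info("cleaning dropped %d constant cols, %d sparse cols, "
                    "%d rows", len(const), len(too_missing), dropped_rows)
    return out.reset_index(drop=True), CleaningReport(
        tuple(const), tuple(too_missing), dropped_rows)


def gate_cell_types(
    matrix: pd.DataFrame,
    area_column: str = "cytoplasm_area_px2",
    gate: float = AREA_GATE_PX2,
) -> pd.Series:
    """Label cells hepatocyte/cholangiocyte by the cytoplasm-area gate.

    Area below the gate (or exactly at it, by the documented tie rule)
    is hepatocyte-like; above is cholangiocyte-like. A pure threshold
    function: permuting rows permutes labels identically.
    """
    if area_column not in matrix.columns:
        raise KeyError(f"column {area_column!r} not present")
    area = matrix[area_column]
    if area.isna().any():
        raise ValueError("area column contains missing values; clean first")
    return pd.Series(np.where(area <= gate, "hepatocyte", "cholangiocyte"),
                     index=matrix.index, name="cell_type")


def run_pca(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    feature_columns: list[str] | None = None,
    overlay_columns: tuple = ("droplet_size_px2", "mito_intensity",
                              "oxstress_intensity"),
) -> dict:
    """Standardized PCA of the cleaned feature matrix.

    Features are scaled to zero mean and unit variance (the feature
    families span very different numeric ranges), components are capped
    at the matrix rank, and component signs are fixed so each loading
    vector's largest-magnitude entry is positive — making the
    decomposition reproducible bit for bit. Returns scores, loadings,
    explained variance ratios, and any requested per-cell overlay
    columns (droplet size, Mitotracker, CellROX) aligned with the
    scores for plotting.
    """
    if feature_columns is None:
        feature_columns = [c for c in matrix.columns
                           if matrix[c].dtype.kind in "fi"
                           and c != "cell_id"]
    X = matrix[feature_columns].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; clean first")
    Xs = StandardScaler().fit_transform(X)
    rank = int(np.linalg.matrix_rank(Xs))
    k = min(n_components or rank, rank, Xs.shape[1], Xs.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xs)
    comps = pca.components_
    # sign convention: largest-|loading| entry of each component positive
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    out = {
        "scores": pd.DataFrame(scores, columns=cols, index=matrix.index),
        "loadings": pd.DataFrame(comps.T, index=feature_columns,
                                 columns=cols),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    overlays = [c for c in overlay_columns if c in matrix.columns]
    if overlays:
        out["overlays"] = matrix[overlays].copy()
    return out


def summarize_subpopulations(
    matrix: pd.DataFrame,
    labels: pd.Series,
    value_column: str,
    grouping: list[str] | None = None,
) -> pd.DataFrame:
    """Notched-boxplot statistics of one measure per subpopulation group.

    Groups by cell-type label plus any extra ``grouping`` columns (e.g.
    concentration); reports n, median, quartiles, and the notch interval
    median +/- 1.58*IQR/sqrt(n). Empty groups are omitted with a log
    entry. Invariant to row and column order.
    """
    df = matrix.copy()
    df["_label"] = labels.to_numpy()
    keys = ["_label"] + (grouping or [])
    rows = []
    for key, grp in df.groupby(keys, dropna=False):
        vals = grp[value_column].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            logger.info("omitting empty group %r", key)
            continue
        med = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        notch = 1.58 * iqr / np.sqrt(vals.size)
        rec = {"cell_type": key[0] if isinstance(key, tuple) else key,
               "n": int(vals.size), "median": med,
               "q1": float(q1), "q3": float(q3),
               "notch_low": med - notch, "notch_high": med + notch}
        if grouping:
            extras = key[1:] if isinstance(key, tuple) else ()
            rec.update(dict(zip(grouping, extras)))
        rows.append(rec)
    if not rows:
        raise ValueError("no non-empty groups")
    return pd.DataFrame(rows)
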