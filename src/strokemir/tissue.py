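"""Tissue expression profiling: per-tissue averaging and cross-tissue z-scores.

Works on a quantile-normalized samples-by-miRNA expression matrix of the kind
shipped by human miRNA tissue atlases.  Samples are first averaged within
tissue, then each miRNA column is standardized across tissues so that
tissue-specific expression stands out.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class TissueError(ValueError):
    pass


def read_matrix(path) -> pd.DataFrame:
    """Tab-separated matrix: first column sample ids, header of miRNA names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise TissueError("matrix labels must be unique")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise TissueError("matrix values must be finite")
    return df.astype(float)


def read_tissue_map(path) -> dict[str, str]:
    """Two-column tab-separated sample -> tissue map."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise TissueError("tissue map needs two columns (sample, tissue)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def collapse_by_tissue(matrix: pd.DataFrame, tissue_of_sample: dict[str, str]) -> pd.DataFrame:
    """Average sample rows belonging to the same tissue (one row per tissue)."""
    unmapped = [s for s in matrix.index if s not in tissue_of_sample]
    if unmapped:
        raise TissueError(f"samples without a tissue assignment: {unmapped}")
    tissues = matrix.index.map(tissue_of_sample)
    collapsed = matrix.groupby(tissues, sort=True).mean()
    collapsed.index.name = "tissue"
    return collapsed


def zscore_across_tissues(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each miRNA column across tissues ((x - mean)/sd, sd ddof=1).

    Constant columns carry no tissue signal and are mapped to all zeros with
    a warning rather than dividing by zero.
    """
    if len(matrix) < 2:
        raise TissueError("z-scores need >= 2 tissues")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant expression columns set to zero z-score: "
            f"{list(matrix.columns[constant])}", RuntimeWarning, stacklevel=2,
        )
    z = (matrix - mean) / sd.replace(0.0, np.nan)
    z.loc[:, constant] = 0.0
    return z


def tissue_zscores(matrix: pd.DataFrame, tissue_of_sample: dict[str, str]) -> pd.DataFrame:
    """Collapse to tissue means, then z-score across tissues."""
    return zscore_across_tissues(collapse_by_tissue(matrix, tissue_of_sample))
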