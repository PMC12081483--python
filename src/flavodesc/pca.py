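"""PCA of descriptor matrices and chemical-similarity ranking.

Molecules are standardized feature-wise (unit-variance scaling), projected
onto principal components, and ranked by
Euclidean distance to a reference molecule in the retained score space. The
sign of each component is fixed so that its largest-magnitude loading is
positive, making scores deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PcaResult:
    """Scores (molecules x components), loadings (features x components)
    and per-component explained-variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column and scale nonconstant columns to unit variance.

    Population sd (ddof=0) is used, matching the scaling sklearn's PCA
    pipeline conventions assume; constant columns become all-zero (with a
    warning) rather than NaN.
    """
    if matrix.isna().any().any():
        raise ValueError("missing values in descriptor matrix")
    if len(matrix) < 2:
        raise ValueError("standardization requires at least 2 rows")
    X = matrix.astype(float)
    centered = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0.0
    if constant.any():
        log.warning(
            "zero-variance columns set to zero: %s",
            list(matrix.columns[constant]),
        )
    sd = sd.where(~constant, 1.0)
    return centered / sd


def pca_fit(matrix: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Fit a PCA on an already-standardized descriptor matrix."""
    n, p = matrix.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)="
            f"{min(n - 1, p)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy(float))
    loadings = model.components_.T  # features x components
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
    )


def similarity_rank(scores: pd.DataFrame, reference_id: str) -> list[tuple[str, float]]:
    """Molecules ordered by Euclidean distance to the reference in score
    space, nearest first; the reference itself is excluded."""
    if reference_id not in scores.index:
        raise KeyError(f"reference {reference_id!r} not among scored molecules")
    ref = scores.loc[reference_id].to_numpy(float)
    out = []
    for mol, row in scores.iterrows():
        if mol == reference_id:
            continue
        out.append((str(mol), float(np.linalg.norm(row.to_numpy(float) - ref))))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
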