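"""Standardization, collinearity screening and correlation-matrix PCA.

The ordination workflow is: z-score variables, iteratively drop
variables whose variance inflation factor exceeds a threshold, run a
PCA on the correlation matrix, retain axes whose variance proportion
exceeds the broken-stick expectation, and screen variables against
retained axis scores with Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PcaResult",
    "AxisCorrelationTable",
    "zscore",
    "vif_eliminate",
    "pca_correlation",
    "broken_stick",
    "axis_variable_correlations",
    "select_trait_assemblage",
]


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample (ddof=1) SD 1."""
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        raise ValueError(f"constant column(s) cannot be z-scored: {constant}")
    return (matrix - mu) / sd


def _vif_single(X: np.ndarray, j: int) -> float:
    """VIF_j = 1/(1 - R^2) from regressing column j on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant column encountered in VIF computation")
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_eliminate(
    matrix: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the worst-VIF variable while it exceeds `threshold`.

    Returns the retained variable ids (original column order) and a log
    with one row per elimination step recording every VIF at that step.
    Perfect collinearity gives an infinite VIF and is removed first.
    Ties break on the lexicographically smallest variable id.
    """
    if matrix.shape[1] < 2:
        raise ValueError("VIF elimination needs at least two variables")
    retained = list(matrix.columns)
    log_rows: list[dict] = []
    step = 0
    while len(retained) >= 2:
        if matrix.shape[0] <= len(retained):
            raise ValueError(
                "need more observations than variables at each VIF regression step"
            )
        X = matrix[retained].to_numpy(dtype=float)
        vifs = {v: _vif_single(X, j) for j, v in enumerate(retained)}
        worst_val = max(vifs.values())
        if not worst_val > threshold:
            log_rows.append({"step": step, "removed": None, **vifs})
            break
        worst = min(v for v, val in vifs.items() if val == worst_val)
        log_rows.append({"step": step, "removed": worst, **vifs})
        retained.remove(worst)
        step += 1
    return retained, pd.DataFrame(log_rows)


def broken_stick(n_components: int) -> np.ndarray:
    """Expected ordered proportions b_k = (1/p) * sum_{i=k..p} 1/i."""
    p = int(n_components)
    if p < 1:
        raise ValueError("broken stick needs at least one component")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


@dataclass
class PcaResult:
    """Eigendecomposition of a correlation matrix with broken-stick retention."""

    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    scores: pd.DataFrame  # observations x axes
    loadings: pd.DataFrame  # variables x axes (eigenvectors)
    broken_stick_expectations: np.ndarray
    retained_axes: np.ndarray  # boolean mask

    @property
    def n_retained(self) -> int:
        return int(self.retained_axes.sum())

    def retained_axis_labels(self) -> list[str]:
        return list(self.scores.columns[self.retained_axes])


def pca_correlation(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA on the correlation matrix of `matrix`.

    Scores are the z-scored data projected onto unit eigenvectors, so
    total inertia equals the number of variables.  Eigenvector signs are
    fixed so the loading of largest absolute value on each axis is
    positive, making results reproducible across runs and BLAS builds.
    """
    if matrix.shape[0] < 3:
        raise ValueError("correlation PCA needs at least three observations")
    if matrix.shape[1] < 2:
        raise ValueError("correlation PCA needs at least two variables")
    Z = zscore(matrix) if standardize else matrix.copy()
    corr = np.corrcoef(Z.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: dominant loading positive on every axis
    for k in range(eigvec.shape[1]):
        dom = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[dom, k] < 0:
            eigvec[:, k] *= -1
    p = matrix.shape[1]
    proportions = eigval / p
    bstick = broken_stick(p)
    axes = [f"axis{k + 1}" for k in range(p)]
    scores = pd.DataFrame(Z.to_numpy(dtype=float) @ eigvec, index=matrix.index, columns=axes)
    loadings = pd.DataFrame(eigvec, index=matrix.columns, columns=axes)
    return PcaResult(
        eigenvalues=eigval,
        variance_proportions=proportions,
        scores=scores,
        loadings=loadings,
        broken_stick_expectations=bstick,
        retained_axes=proportions > bstick,
    )


@dataclass
class AxisCorrelationTable:
    """Pearson r and two-sided p per (variable, axis), flagged at alpha."""

    table: pd.DataFrame  # columns: variable, axis, r, p, significant
    alpha: float


def axis_variable_correlations(
    pca: PcaResult,
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    axes: list[str] | None = None,
) -> AxisCorrelationTable:
    """Correlate every variable with every retained axis score.

    Two-sided p from the exact t distribution with n-2 degrees of
    freedom; no multiple-test correction is applied.
    """
    if not matrix.index.equals(pca.scores.index):
        raise ValueError("matrix rows do not align with PCA scores")
    if matrix.shape[0] < 4:
        raise ValueError("need at least four observations for axis correlations")
    if axes is None:
        axes = pca.retained_axis_labels()
    rows = []
    for axis in axes:
        s = pca.scores[axis].to_numpy()
        for var in matrix.columns:
            r, p = stats.pearsonr(matrix[var].to_numpy(dtype=float), s)
            rows.append(
                {"variable": var, "axis": axis, "r": float(r), "p": float(p),
                 "significant": bool(p <= alpha)}
            )
    return AxisCorrelationTable(pd.DataFrame(rows), alpha=alpha)


def select_trait_assemblage(table: AxisCorrelationTable, axis: str) -> list[str]:
    """Variables significantly correlated with one axis, in table order."""
    sub = table.table[table.table["axis"] == axis]
    if sub.empty:
        raise ValueError(f"axis {axis!r} absent from correlation table")
    picked = list(sub.loc[sub["significant"], "variable"])
    if not picked:
        raise ValueError(f"no variable significantly correlated with {axis!r}")
    return picked
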