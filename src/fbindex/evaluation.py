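"""Control-vs-pain multivariate analysis of the 20-characteristic ethogram.

Implements the grouped feature matrix (control = every control-group row
plus every pre-treatment row from the other groups; pain = the 2, 3 and 6 h
rows from the fin clip, PIT tag and acid lip groups), correlation-matrix PCA
with explained-variance reporting, and the two sampling-adequacy statistics
that justify a PCA on correlated behavioural characteristics:

* Kaiser-Meyer-Olkin (KMO): sum of squared off-diagonal correlations over
  that sum plus the squared anti-image partial correlations.
* Bartlett's test of sphericity: chi2 = -(n - 1 - (2p + 5)/6) ln det(R) on
  p(p-1)/2 degrees of freedom against the identity correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "PAIN_GROUPS",
    "PAIN_WINDOWS",
    "PCAResult",
    "build_groups",
    "pca",
    "kmo",
    "bartlett_sphericity",
]

#: Treatment groups whose post-treatment rows define the pain class.
PAIN_GROUPS: frozenset[str] = frozenset(
    {"fin_clip", "pit_tag", "acid_1", "acid_5", "acid_10", "acid_10_top"}
)
#: Observation windows contributing to the pain class.
PAIN_WINDOWS: frozenset[str] = frozenset({"2h", "3h", "6h"})


def build_groups(
    feature_table: pd.DataFrame,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Label rows control/pain and drop the rest.

    ``feature_table`` needs ``fish_id``, ``group`` and ``window`` columns
    plus the feature columns.  Control rows are all rows of the control
    group plus every group's pre-treatment row; pain rows are the 2, 3 and
    6 h rows of the invasive-treatment groups.  Sham post-treatment rows and
    1 h rows are excluded from both classes.  Returns (features, labels) in
    deterministic (fish_id, window) order.
    """
    required = {"fish_id", "group", "window"}
    missing = required - set(feature_table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")

    df = feature_table.copy()
    is_control = (df["group"] == "control") | (df["window"] == "pre")
    is_pain = df["group"].isin(PAIN_GROUPS) & df["window"].isin(PAIN_WINDOWS)
    df["label"] = np.where(is_control, "control", np.where(is_pain, "pain", ""))
    df = df[df["label"] != ""].sort_values(["fish_id", "window"], kind="mergesort")
    df = df.reset_index(drop=True)
    X = df[list(feature_names)].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing cells in feature columns {bad}")
    return X, df["label"]


@dataclass
class PCAResult:
    """Eigenstructure of the (correlation-matrix) PCA."""

    eigenvalues: np.ndarray          # non-increasing
    pct_variance: np.ndarray         # 100 * eigenvalue / total, sums to 100
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame           # unit-norm eigenvectors, columns PC1..
    scores: np.ndarray               # observations projected on the components
    n_report: int = 3

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(len(self.eigenvalues))],
            "eigenvalue": self.eigenvalues,
            "pct_variance": self.pct_variance,
            "cumulative_pct": self.cumulative_pct,
        })


def _as_matrix(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns]
    arr = np.asarray(matrix, dtype=float)
    return arr, [f"var{i + 1}" for i in range(arr.shape[1])]


def _correlation(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, int]:
    X, names = _as_matrix(matrix)
    sd = X.std(axis=0, ddof=1)
    dead = [names[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance columns under standardization: {dead}")
    return np.corrcoef(X, rowvar=False), X.shape[0]


def pca(
    matrix: pd.DataFrame | np.ndarray,
    standardize: bool = True,
    n_report: int = 3,
) -> PCAResult:
    """Principal component analysis via eigendecomposition.

    With ``standardize`` (default) the decomposition is of the column
    correlation matrix — the convention under which the KMO and Bartlett
    diagnostics apply — otherwise of the covariance matrix.  Explained
    variance is reported pre-rotation (rotation-invariant).  Each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    X, names = _as_matrix(matrix)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations for PCA")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dead = [names[i] for i in np.flatnonzero(sd == 0)]
        if dead:
            raise ValueError(f"zero-variance columns under standardization: {dead}")
        Z = (X - X.mean(axis=0)) / sd
        C = np.corrcoef(X, rowvar=False)
    else:
        Z = X - X.mean(axis=0)
        C = np.cov(X, rowvar=False)

    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude loading positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip

    total = eigvals.sum()
    pct = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    loadings = pd.DataFrame(eigvecs, index=names,
                            columns=[f"PC{i + 1}" for i in range(p)])
    return PCAResult(
        eigenvalues=eigvals,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        loadings=loadings,
        scores=Z @ eigvecs,
        n_report=n_report,
    )


def kmo(matrix: pd.DataFrame | np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where r are the
    observed correlations and q the anti-image partial correlations obtained
    from the inverse correlation matrix, q_ij = -u_ij / sqrt(u_ii u_jj).
    When the correlation matrix is singular (e.g. fewer rows than columns)
    the pseudo-inverse is used with a warning.
    """
    R, n_rows = _correlation(matrix)
    p = R.shape[0]
    if n_rows <= p or np.linalg.matrix_rank(R) < p:
        warnings.warn("correlation matrix singular or near-singular; using pseudo-inverse",
                      stacklevel=2)
        U = np.linalg.pinv(R)
    else:
        U = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(U), np.diag(U)))
    Q = -U / d
    off = ~np.eye(p, dtype=bool)
    r2 = float((R[off] ** 2).sum())
    q2 = float((Q[off] ** 2).sum())
    return r2 / (r2 + q2)


def bartlett_sphericity(matrix: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    Returns (chi-square, degrees of freedom, p-value); df = p(p-1)/2 and
    chi2 = -(n - 1 - (2p + 5)/6) ln det(R).
    """
    R, n = _correlation(matrix)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("non-positive determinant of the correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval
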