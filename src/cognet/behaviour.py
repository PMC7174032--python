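"""Cognitive-score preprocessing and rotated principal component analysis.

Task scores are detrended for cubic age effects by ordinary least squares,
mapped through a rank-based inverse-normal (Blom) transform, and summarised
by PCA of the correlation matrix with Kaiser retention (eigenvalue > 1) and
varimax rotation. On the six-task battery this yields a two-component
solution separating working-memory tasks (MKL, PAL, SOS) from reasoning
tasks (FTM, OOO, HTT).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

TASKS = ("MKL", "PAL", "SOS", "FTM", "OOO", "HTT")
WM_TASKS = ("MKL", "PAL", "SOS")
RSN_TASKS = ("FTM", "OOO", "HTT")


def detrend_age(
    scores: np.ndarray | pd.DataFrame, age: np.ndarray, degree: int = 3
) -> np.ndarray | pd.DataFrame:
    """Residualize each score column on {1, age, ..., age^degree} by OLS."""
    values = np.asarray(scores, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    age = np.asarray(age, dtype=float)
    if values.shape[0] < 5:
        raise ValueError("at least 5 subjects are required for age detrending")
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite")
    design = np.vander(age, degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "age polynomial design is rank deficient (constant or repeated ages)"
        )
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    if isinstance(scores, pd.DataFrame):
        return pd.DataFrame(resid, index=scores.index, columns=scores.columns)
    return resid if np.asarray(scores).ndim > 1 else resid[:, 0]


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8) -> np.ndarray:
    """Rank-based inverse-normal transform, Blom offsets by default.

    Maps value with (average, for ties) rank r among n to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``; strictly monotone in the
    input. With the Blom offset 3/8 the denominator is n + 1/4.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        return np.column_stack(
            [inverse_normal_transform(values[:, j], offset) for j in range(values.shape[1])]
        )
    n = values.size
    if n < 3:
        raise ValueError("inverse normal transform requires n >= 3")
    if np.all(values == values[0]):
        raise ValueError("all values equal: ranks are degenerate")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings per component with an
    orthogonal rotation, using the classic iterative pairwise (planar)
    algorithm: each factor pair is rotated by the analytically optimal
    angle, and sweeps repeat until no pair moves by more than ``tol``
    radians. With ``normalize`` the rows are Kaiser-normalized by their
    communalities during rotation.

    Returns the rotated loadings and the rotation matrix R (loadings @ R).
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    h = np.sqrt((L**2).sum(axis=1)) if normalize else np.ones(p)
    h = np.where(h > 0, h, 1.0)
    A = L / h[:, None]
    R = np.eye(k)
    for _ in range(max_iter):
        max_phi = 0.0
        for j in range(k - 1):
            for l in range(j + 1, k):
                x, y = A[:, j], A[:, l]
                u = x * x - y * y
                v = 2.0 * x * y
                num = 2.0 * (p * (u @ v) - u.sum() * v.sum())
                den = p * (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                A[:, [j, l]] = A[:, [j, l]] @ rot
                R[:, [j, l]] = R[:, [j, l]] @ rot
                max_phi = max(max_phi, abs(phi))
        if max_phi < tol:
            break
    return A * h[:, None], R


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    sq = np.asarray(loadings) ** 2
    return float((sq.var(axis=0)).sum())


class VarimaxPCA(TransformerMixin, BaseEstimator):
    """PCA of the correlation matrix with Kaiser retention and varimax rotation.

    Columns are standardized internally; components with unrotated eigenvalue
    greater than 1 are retained (Kaiser convention, applied prior to rotation)
    and varimax-rotated; component scores are obtained by regression of the
    standardized data on the rotated loadings. Each rotated component is
    sign-flipped so its largest-magnitude loading is positive, and components
    are ordered by post-rotation explained variance.

    Parameters
    ----------
    kaiser : bool
        Apply the eigenvalue > 1 retention rule (default). When False,
        ``n_components`` is used.
    n_components : int or None
        Fixed number of components when ``kaiser`` is False (default: all).
    rotate : bool
        Apply varimax rotation (default True).
    tol : float
        Rotation convergence tolerance.

    Attributes
    ----------
    loadings_ : ndarray (n_tasks, n_retained)
        Rotated component loadings (correlations of tasks with components).
    eigenvalues_ : ndarray
        All unrotated eigenvalues of the correlation matrix.
    explained_variance_pre_ : ndarray
        Percent variance per retained component before rotation.
    explained_variance_post_ : ndarray
        Percent variance per component after rotation.
    n_components_ : int
        Number of retained components.
    component_scores_ : ndarray (n_subjects, n_retained)
        Regression-method scores of the training data, zero mean.
    """

    def __init__(
        self,
        kaiser: bool = True,
        n_components: int | None = None,
        rotate: bool = True,
        tol: float = 1e-6,
    ) -> None:
        self.kaiser = kaiser
        self.n_components = n_components
        self.rotate = rotate
        self.tol = tol

    def fit(self, X: np.ndarray | pd.DataFrame, y=None) -> "VarimaxPCA":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n <= p:
            warnings.warn("fewer subjects than recommended (n <= n_tasks)")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("zero-variance column: cannot standardize")
        Z = (X - self.mean_) / self.scale_
        corr = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        self.eigenvalues_ = eigval
        if self.kaiser:
            keep = int(np.sum(eigval > 1.0))
            keep = max(keep, 1)
        else:
            keep = self.n_components or p
        raw = eigvec[:, :keep] * np.sqrt(np.maximum(eigval[:keep], 0.0))
        self.explained_variance_pre_ = 100.0 * eigval[:keep] / p
        if keep < 2:
            if self.rotate:
                warnings.warn(
                    "fewer than 2 retained components: returning unrotated solution"
                )
            rotated = raw
        elif self.rotate:
            rotated, _ = varimax(raw, tol=self.tol)
        else:
            rotated = raw
        # sign convention and ordering by post-rotation variance
        flip = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(rotated.shape[1])])
        flip = np.where(flip == 0, 1.0, flip)
        rotated = rotated * flip
        ss = (rotated**2).sum(axis=0)
        order = np.argsort(ss)[::-1]
        rotated = rotated[:, order]
        self.loadings_ = rotated
        self.explained_variance_post_ = 100.0 * ss[order] / p
        self.n_components_ = rotated.shape[1]
        self.communalities_ = (rotated**2).sum(axis=1)
        # regression-method scoring weights: R^-1 Lambda
        self.score_weights_ = np.linalg.solve(corr, rotated)
        self.n_features_in_ = p
        self.component_scores_ = Z @ self.score_weights_
        return self

    def transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.score_weights_


def pca_varimax(
    scores: np.ndarray | pd.DataFrame, kaiser: bool = True
) -> VarimaxPCA:
    """Fit a :class:`VarimaxPCA` on preprocessed scores."""
    return VarimaxPCA(kaiser=kaiser).fit(scores)


def preprocess_scores(
    scores: pd.DataFrame, age: np.ndarray, degree: int = 3
) -> pd.DataFrame:
    """Age-detrend then inverse-normal-transform each task column."""
    resid = detrend_age(scores, age, degree=degree)
    out = {c: inverse_normal_transform(np.asarray(resid[c])) for c in resid.columns}
    return pd.DataFrame(out, index=scores.index)


def label_components(
    loadings: np.ndarray, tasks: Sequence[str] = TASKS
) -> dict[str, int]:
    """Map component indices to 'wm'/'rsn' by which task family loads higher.

    The working-memory component is the one with the larger mean absolute
    loading over MKL/PAL/SOS; the reasoning component over FTM/OOO/HTT.
    Requires at least two components.
    """
    loadings = np.asarray(loadings)
    if loadings.shape[1] < 2:
        raise ValueError("need at least two components to label")
    wm_idx = [tasks.index(t) for t in WM_TASKS]
    rs_idx = [tasks.index(t) for t in RSN_TASKS]
    wm_mean = np.abs(loadings[wm_idx]).mean(axis=0)
    rs_mean = np.abs(loadings[rs_idx]).mean(axis=0)
    # assign the component that most favours WM tasks to 'wm'
    diff = wm_mean - rs_mean
    wm_comp = int(np.argmax(diff))
    rs_comp = int(np.argmin(diff))
    if wm_comp == rs_comp:
        rs_comp = 1 - wm_comp
    return {"wm": wm_comp, "rsn": rs_comp}
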