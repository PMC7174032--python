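"""Canonical correlation of cognitive components with connectome degree.

The whole-connectome analysis asks, in a data-driven way, how many latent
modes relate behaviour to dysconnectivity: nodal degree centrality over all
90 regions is reduced by PCA to the components capturing 90% of its
variance, those component scores are entered into a canonical correlation
analysis (CCA) against the cognitive component scores, and the significance
of each canonical mode is assessed against a null distribution built by
shuffling the subject correspondence (permuting the rows of one block) and
refitting — 10,000 times by default. Modes are interpreted by
back-projection (correlating canonical variates with raw task scores and
raw node degrees) and overfit is gauged by a train/held-out subsampling
routine compared with its permuted reference.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

_COND_LIMIT = 1e10


def reduce_degrees(
    node_degrees: np.ndarray, variance: float = 0.90
) -> tuple[np.ndarray, PCA]:
    """PCA-reduce standardized node degrees to >= ``variance`` of variance.

    Returns the component scores (subjects x k) and the fitted PCA; k is the
    smallest number of unrotated components whose cumulative explained
    variance reaches the target.
    """
    X = np.asarray(node_degrees, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two subjects")
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA().fit(Z)
    k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), variance) + 1)
    k = min(k, Z.shape[1])
    scores = pca.transform(Z)[:, :k]
    pca.n_retained_ = k
    return scores, pca


def _cca_core(Xc: np.ndarray, Yc: np.ndarray):
    """Classical CCA of two centred blocks via QR + SVD."""
    Qx, Rx = np.linalg.qr(Xc)
    Qy, Ry = np.linalg.qr(Yc)
    cx = np.linalg.cond(Rx)
    cy = np.linalg.cond(Ry)
    if not np.isfinite(cx) or not np.isfinite(cy) or max(cx, cy) > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "within-set covariance is numerically singular "
            f"(condition numbers {cx:.3g}, {cy:.3g})"
        )
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    k = min(Xc.shape[1], Yc.shape[1])
    a = solve_triangular(Rx, U[:, :k])
    b = solve_triangular(Ry, Vt.T[:, :k])
    return np.clip(s[:k], 0.0, 1.0), a, b, Qx, Qy


class PermutationCCA(BaseEstimator):
    """CCA with per-mode permutation nulls, sklearn-style.

    ``fit(X, Y)`` computes the canonical decomposition of the two blocks
    (modes = min of the two column counts) and, when ``n_permutations`` > 0,
    a per-mode null distribution by permuting the row order of ``Y`` and
    refitting; ``p_m = (1 + #{null rho_m >= rho_m}) / (n_permutations + 1)``.

    Attributes
    ----------
    correlations_ : ndarray (k,)
        Canonical correlations, non-increasing, in [0, 1].
    x_weights_, y_weights_ : ndarray
        Canonical weight vectors (columns) for each block.
    x_variates_, y_variates_ : ndarray (n, k)
        In-sample canonical variates U = Xc a, V = Yc b.
    null_ : ndarray (n_permutations, k)
        Permutation null canonical correlations.
    pvalues_ : ndarray (k,)
        Per-mode permutation p-values.
    """

    def __init__(self, n_permutations: int = 10_000, random_state: int | None = None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PermutationCCA":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        rho, a, b, Qx, Qy = _cca_core(Xc, Yc)
        self.correlations_ = rho
        self.x_weights_ = a
        self.y_weights_ = b
        self.x_variates_ = Xc @ a
        self.y_variates_ = Yc @ b
        self.n_modes_ = rho.size
        if self.n_permutations:
            if self.n_permutations < 100:
                warnings.warn("fewer than 100 permutations: p-values are coarse")
            self.null_ = self._permutation_null(Qx, Qy)
            exceed = (self.null_ >= rho[None, :]).sum(axis=0)
            self.pvalues_ = (1.0 + exceed) / (self.n_permutations + 1.0)
        return self

    def _permutation_null(self, Qx: np.ndarray, Qy: np.ndarray) -> np.ndarray:
        """Null canonical correlations by permuting Y's row order.

        Row permutation of the centred Y block permutes the rows of its
        orthonormal QR factor, so each draw only needs the singular values of
        Qx.T P Qy — computed in vectorized batches.
        """
        rng = np.random.default_rng(self.random_state)
        n = Qx.shape[0]
        k = self.n_modes_
        out = np.empty((self.n_permutations, k))
        chunk = 1000
        for start in range(0, self.n_permutations, chunk):
            b = min(chunk, self.n_permutations - start)
            perms = rng.permuted(
                np.broadcast_to(np.arange(n), (b, n)).copy(), axis=1
            )
            M = np.einsum("np,bnq->bpq", Qx, Qy[perms])
            s = np.linalg.svd(M, compute_uv=False)
            out[start : start + b] = s[:, :k]
        return out

    def transform(self, X: np.ndarray, Y: np.ndarray):
        """Project new rows with the trained weights (training centring)."""
        check_is_fitted(self, "x_weights_")
        U = (np.asarray(X, float) - self.x_mean_) @ self.x_weights_
        V = (np.asarray(Y, float) - self.y_mean_) @ self.y_weights_
        return U, V


def cca_fit(X: np.ndarray, Y: np.ndarray) -> PermutationCCA:
    """Canonical decomposition only (no permutations)."""
    return PermutationCCA(n_permutations=0).fit(X, Y)


def cca_permutation_test(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 10_000, seed: int | None = None
) -> PermutationCCA:
    """CCA with per-mode permutation p-values."""
    return PermutationCCA(n_permutations=n_perm, random_state=seed).fit(X, Y)


def back_project(
    result: PermutationCCA, raw_tasks: np.ndarray, raw_degrees: np.ndarray
) -> dict[str, np.ndarray]:
    """Pearson loadings of canonical variates on raw inputs.

    For each mode m, correlates U_m with every raw task column and V_m with
    every raw node-degree column. Zero-variance raw columns get NaN.
    """
    check_is_fitted(result, "x_variates_")

    def _loadings(variates: np.ndarray, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        vc = variates - variates.mean(axis=0)
        rc = raw - raw.mean(axis=0)
        v_sd = vc.std(axis=0)
        r_sd = rc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (rc.T @ vc) / raw.shape[0] / np.outer(r_sd, v_sd)
        corr[r_sd == 0, :] = np.nan
        return corr  # (n_raw_cols, n_modes)

    return {
        "task_loadings": _loadings(result.x_variates_, raw_tasks),
        "degree_loadings": _loadings(result.y_variates_, raw_degrees),
    }


def subsample_generalization(
    X: np.ndarray,
    Y: np.ndarray,
    train_fractions: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9),
    n_iter: int = 1000,
    seed: int | None = None,
    min_test: int = 5,
) -> dict[str, np.ndarray]:
    """Held-out canonical correlation versus training fraction.

    For each fraction and iteration, a random subsample trains the CCA and
    the trained weights are applied to the held-out rows; the held-out
    correlation per mode is averaged over iterations. The whole procedure is
    repeated with the rows of ``Y`` permuted (fresh permutation per
    iteration) as the overfit reference.

    Returns a dict with 'fractions', 'observed' and 'permuted' arrays of
    shape (n_fractions, n_modes).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    k = min(X.shape[1], Y.shape[1])
    fractions = np.asarray(train_fractions, dtype=float)
    if np.any(fractions >= 1.0) or np.any(fractions <= 0.0):
        raise ValueError("train fractions must lie strictly in (0, 1)")
    observed = np.zeros((fractions.size, k))
    permuted = np.zeros((fractions.size, k))

    def _heldout_rho(Xa: np.ndarray, Ya: np.ndarray, train: np.ndarray, test: np.ndarray):
        model = PermutationCCA(n_permutations=0).fit(Xa[train], Ya[train])
        U, V = model.transform(Xa[test], Ya[test])
        rho = np.empty(k)
        for m in range(k):
            u, v = U[:, m], V[:, m]
            if u.std() == 0 or v.std() == 0:
                rho[m] = np.nan
            else:
                rho[m] = np.corrcoef(u, v)[0, 1]
        return rho

    for fi, f in enumerate(fractions):
        n_train = int(round(f * n))
        if n - n_train < min_test:
            raise ValueError(
                f"train fraction {f} leaves fewer than {min_test} held-out subjects"
            )
        acc_obs = np.zeros(k)
        acc_perm = np.zeros(k)
        for _ in range(n_iter):
            order = rng.permutation(n)
            train, test = order[:n_train], order[n_train:]
            acc_obs += _heldout_rho(X, Y, train, test)
            Yp = Y[rng.permutation(n)]
            acc_perm += _heldout_rho(X, Yp, train, test)
        observed[fi] = acc_obs / n_iter
        permuted[fi] = acc_perm / n_iter
    return {"fractions": fractions, "observed": observed, "permuted": permuted}
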