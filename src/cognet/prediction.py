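"""Kernel ridge prediction of cognitive components from nodal measures.

Nodal graph measures of one subnetwork are the features, a cognitive
component score the target. The model is kernel ridge regression in the
dual (alpha = (K + lambda I)^-1 y on centred data, linear kernel by
default), with the ridge penalty chosen by nested cross-validation: inner
5-fold CV selects lambda by mean squared error, outer 5-fold CV yields
out-of-fold predictions that are pooled into a single Pearson r between
predicted and observed scores. Model significance comes from permutation of
the target (the full nested procedure is rerun per permutation — the
feature kernels and fold assignment are target-independent, so their
eigendecompositions are computed once and reused). With the linear kernel,
primal weights w = X^T alpha per outer fold, averaged across folds, give a
per-node contribution map.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

DEFAULT_ALPHAS = tuple(np.logspace(-3, 3, 13))


def _kernel(A: np.ndarray, B: np.ndarray, kernel: str, gamma: float | None) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        g = gamma if gamma is not None else 1.0 / A.shape[1]
        sq = ((A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2 * A @ B.T)
        return np.exp(-g * np.maximum(sq, 0.0))
    raise ValueError(f"unknown kernel {kernel!r}")


def krr_fit_predict(
    features: np.ndarray,
    target: np.ndarray,
    lam: float,
    test_features: np.ndarray | None = None,
    kernel: str = "linear",
    gamma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dual kernel ridge fit; returns predictions and dual coefficients.

    The target is centred on its training mean; alpha = (K + lam I)^-1 y_c.
    Predictions are for ``test_features`` when given, otherwise in-sample.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if lam <= 0:
        raise ValueError("the ridge penalty must be positive")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("features and target must be finite")
    K = _kernel(X, X, kernel, gamma)
    y_mean = y.mean()
    try:
        s, U = np.linalg.eigh(K)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "kernel system is singular "
            f"(condition estimate {np.linalg.cond(K + lam * np.eye(K.shape[0])):.3g})"
        ) from err
    s = np.maximum(s, 0.0)  # clip tiny negative roundoff of the PSD kernel
    t = U.T @ (y - y_mean)
    alpha = U @ (t / (s + lam))
    # predictions drop numerically-null kernel modes: their exact-arithmetic
    # contribution to K alpha is zero, but at tiny lam the roundoff in s is
    # amplified by 1/lam if kept
    keep = s > s.max() * 1e-12 if s.max() > 0 else np.zeros_like(s, dtype=bool)
    alpha_pred = U[:, keep] @ (t[keep] / (s[keep] + lam))
    Kq = K if test_features is None else _kernel(
        np.asarray(test_features, dtype=float), X, kernel, gamma
    )
    return Kq @ alpha_pred + y_mean, alpha


class _FoldCache:
    """Target-independent quantities for one training/validation split."""

    __slots__ = ("train", "test", "s", "U", "K_test")

    def __init__(self, X: np.ndarray, train: np.ndarray, test: np.ndarray,
                 kernel: str, gamma: float | None, standardize: bool):
        Xtr = X[train]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            Xte = (X[test] - mu) / sd
        else:
            Xte = X[test]
        K = _kernel(Xtr, Xtr, kernel, gamma)
        self.s, self.U = np.linalg.eigh(K)
        self.K_test = _kernel(Xte, Xtr, kernel, gamma)
        self.train = train
        self.test = test

    def predict_grid(self, y: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        """Validation predictions for every ridge penalty at once.

        ``y`` is the globally centred target; no per-fold intercept is fit
        (see :class:`NestedKernelRidgeCV`).
        """
        t = self.U.T @ y[self.train]
        coefs = self.U @ (t[:, None] / (self.s[:, None] + alphas[None, :]))
        return self.K_test @ coefs

    def dual_coef(self, y: np.ndarray, alpha: float) -> np.ndarray:
        t = self.U.T @ y[self.train]
        return self.U @ (t / (self.s + alpha))


class NestedKernelRidgeCV(RegressorMixin, BaseEstimator):
    """Kernel ridge regression evaluated by nested cross-validation.

    ``fit(X, y)`` runs the full nested procedure: outer folds are held out
    entirely; within each outer training set, inner folds select the ridge
    penalty minimizing mean validation MSE; the model refit on the outer
    training set predicts the held-out fold. Features are standardized
    inside each training fold only (no leakage).

    The target is centred once, globally, and no per-fold intercept is fit.
    The intended targets are cognitive component scores, which are zero-mean
    by construction; per-fold intercepts would re-introduce a systematic
    negative bias in the pooled out-of-fold correlation (training-fold and
    held-out-fold means are anti-correlated), so the pooled r would not be
    centred on zero under the null.

    Attributes
    ----------
    cv_predictions_ : ndarray (n,)
        Pooled out-of-fold predictions, aligned with the input rows.
    r_ : float
        Pearson correlation between out-of-fold predictions and the target.
    r2_ : float
        Squared pooled correlation (descriptive).
    mse_, norm_mse_ : float
        Out-of-fold mean squared error, and MSE divided by the target
        variance (so ~1 means no better than the mean).
    alpha_per_fold_ : list of float
        Ridge penalty chosen in each outer fold.
    weights_ : ndarray (n_features,)
        Linear-kernel primal weights averaged across outer folds.
    weight_ranking_ : ndarray
        Feature indices sorted by decreasing \\|weight\\|.
    """

    def __init__(
        self,
        alphas: tuple[float, ...] = DEFAULT_ALPHAS,
        outer_k: int = 5,
        inner_k: int = 5,
        kernel: str = "linear",
        gamma: float | None = None,
        standardize: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.alphas = alphas
        self.outer_k = outer_k
        self.inner_k = inner_k
        self.kernel = kernel
        self.gamma = gamma
        self.standardize = standardize
        self.random_state = random_state

    def _build_cache(self, X: np.ndarray) -> None:
        rng = np.random.RandomState(self.random_state)
        outer = KFold(n_splits=self.outer_k, shuffle=True, random_state=rng)
        self._outer: list[_FoldCache] = []
        self._inner: list[list[_FoldCache]] = []
        n = X.shape[0]
        for tr, te in outer.split(np.arange(n)):
            if te.size < 2 or tr.size < 2:
                raise ValueError("cross-validation fold with fewer than 2 subjects")
            self._outer.append(
                _FoldCache(X, tr, te, self.kernel, self.gamma, self.standardize)
            )
            inner = KFold(n_splits=self.inner_k, shuffle=True, random_state=rng)
            folds = []
            for tr2, va2 in inner.split(np.arange(tr.size)):
                if va2.size < 2:
                    raise ValueError("inner fold with fewer than 2 subjects")
                folds.append(
                    _FoldCache(
                        X, tr[tr2], tr[va2], self.kernel, self.gamma, self.standardize
                    )
                )
            self._inner.append(folds)

    def _run(self, y: np.ndarray):
        """One pass of nested CV for a given target (cache reused)."""
        alphas = np.asarray(self.alphas, dtype=float)
        n = y.shape[0]
        preds = np.empty(n)
        chosen = []
        duals = []
        for outer, inner_folds in zip(self._outer, self._inner):
            sse = np.zeros(alphas.size)
            for f in inner_folds:
                p = f.predict_grid(y, alphas)
                sse += ((p - y[f.test][:, None]) ** 2).sum(axis=0)
            best = int(np.argmin(sse))
            lam = float(alphas[best])
            dual = outer.dual_coef(y, lam)
            preds[outer.test] = outer.K_test @ dual
            chosen.append(lam)
            duals.append(dual)
        return preds, chosen, duals

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NestedKernelRidgeCV":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("features and target must be finite")
        if np.any(np.asarray(self.alphas) <= 0):
            raise ValueError("ridge penalties must be positive")
        self._X = X
        self._build_cache(X)
        self._y_offset = float(y.mean())
        preds, chosen, duals = self._run(y - self._y_offset)
        preds = preds + self._y_offset
        self.cv_predictions_ = preds
        self.alpha_per_fold_ = chosen
        self._duals = duals
        self.y_ = y
        self.r_ = self._pooled_r(preds, y)
        self.r2_ = self.r_**2
        self.mse_ = float(np.mean((preds - y) ** 2))
        var = float(np.var(y))
        self.norm_mse_ = self.mse_ / var if var > 0 else np.nan
        self.fold_test_indices_ = [f.test for f in self._outer]
        if self.kernel == "linear":
            self._set_weights(X)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _pooled_r(preds: np.ndarray, y: np.ndarray) -> float:
        if preds.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(preds, y)[0, 1])

    def _set_weights(self, X: np.ndarray) -> None:
        w = np.zeros(X.shape[1])
        for outer, dual in zip(self._outer, self._duals):
            Xtr = X[outer.train]
            if self.standardize:
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0, ddof=0)
                sd = np.where(sd > 0, sd, 1.0)
                Xtr = (Xtr - mu) / sd
            w += Xtr.T @ dual
        self.weights_ = w / len(self._outer)
        self.weight_ranking_ = np.argsort(-np.abs(self.weights_), kind="stable")

    def score_target(self, y: np.ndarray) -> float:
        """Pooled out-of-fold r for a (possibly permuted) target, cache reused."""
        check_is_fitted(self, "cv_predictions_")
        y = np.asarray(y, dtype=float).ravel()
        preds, _, _ = self._run(y - y.mean())
        return self._pooled_r(preds, y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict with a model refit on all data at the median chosen penalty."""
        check_is_fitted(self, "cv_predictions_")
        lam = float(np.median(self.alpha_per_fold_))
        Xtr = self._X
        if self.standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            X = (np.asarray(X, dtype=float) - mu) / sd
        preds, _ = krr_fit_predict(
            Xtr, self.y_, lam, test_features=X, kernel=self.kernel, gamma=self.gamma
        )
        return preds


def nested_cv(
    features: np.ndarray,
    target: np.ndarray,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int | None = None,
) -> NestedKernelRidgeCV:
    """Run nested-CV kernel ridge and return the fitted estimator."""
    return NestedKernelRidgeCV(
        alphas=alphas, outer_k=outer_k, inner_k=inner_k, random_state=seed
    ).fit(features, target)


def permutation_pvalue(
    features: np.ndarray,
    target: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    model: NestedKernelRidgeCV | None = None,
) -> tuple[float, NestedKernelRidgeCV, np.ndarray]:
    """Permutation p-value for the pooled out-of-fold correlation.

    The target is permuted ``n_perm`` times and the full nested CV is rerun
    for each draw; ``p = (1 + #{null r >= observed r}) / (n_perm + 1)``.
    Returns (p, fitted model, null r distribution).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    y = np.asarray(target, dtype=float).ravel()
    if model is None:
        model = NestedKernelRidgeCV(random_state=seed)
    if not hasattr(model, "cv_predictions_"):
        model.fit(features, y)
    rng = np.random.default_rng(seed)
    null = np.array([model.score_target(y[rng.permutation(y.size)]) for _ in range(n_perm)])
    p = (1.0 + np.sum(null >= model.r_)) / (n_perm + 1.0)
    return float(p), model, null


def compute_weights(model: NestedKernelRidgeCV) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature primal weights and |weight| ranking (linear kernel only)."""
    check_is_fitted(model, "cv_predictions_")
    if model.kernel != "linear":
        raise ValueError("primal weights are only defined for the linear kernel")
    return model.weights_, model.weight_ranking_
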