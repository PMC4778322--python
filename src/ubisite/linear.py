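"""Class-weighted linear baselines on the continuous segment-PCP features.

Three families share one results surface:

* logistic regression — class-weighted maximum likelihood for
  ``logit P(y=1|x) = b0 + b.x`` with an optional small ridge term;
* linear SVM — class-weighted hinge loss, ``min 0.5||w||^2 + C sum cw(y_i)
  hinge_i``; the signed distance to the hyperplane is the ranking score;
* LASSO — squared-error fit of the 0/1 label with an L1 constraint
  ``sum|b_k| <= s`` (or the penalized equivalent); the fitted value is the
  ranking score.

All three consume standardized features (mean 0 / variance 1 per column,
fitted on the training data; zero-variance columns map to zeros).  Class
weights default to inverse class frequency ``cw(c) = N/(2 N_c)``, which is
exactly 1 on balanced data and counteracts the majority class otherwise;
LASSO, being a plain least-squares fit, is left unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import Lasso, LogisticRegression, lars_path
from sklearn.svm import LinearSVC


class ConvergenceError(RuntimeError):
    pass


@dataclass
class StandardizeParams:
    mean: np.ndarray
    scale: np.ndarray  # population std; zero-variance columns get scale 1


def standardize_columns(X) -> tuple[np.ndarray, StandardizeParams]:
    """Per-column mean-0/variance-1 transform fitted on ``X`` (training data)."""
    arr = np.asarray(X, dtype=float)
    mean = arr.mean(axis=0)
    scale = arr.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    params = StandardizeParams(mean=mean, scale=scale)
    return (arr - mean) / scale, params


def apply_standardization(params: StandardizeParams, X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    return (arr - params.mean) / params.scale


def inverse_frequency_weights(y: np.ndarray) -> dict[int, float]:
    """cw(c) = N / (2 N_c); equals 1 for both classes when balanced."""
    n = len(y)
    return {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}


def _resolve_class_weight(mode, y: np.ndarray):
    if mode is None or mode == "none":
        return None
    if mode in ("auto", "balanced"):
        return inverse_frequency_weights(y)
    if isinstance(mode, dict):
        return mode
    raise ValueError(f"unknown class_weight mode {mode!r}")


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if hasattr(X, "X"):  # SegmentPCPMatrix
        X = X.X
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


@dataclass
class LinearResults:
    """Fitted linear model: weights, intercept and ranking scores."""

    model: "LinearClassifierBase"
    family: str  # lr | svm | lasso
    coef_: pd.Series
    intercept_: float
    standardization: Optional[StandardizeParams]
    diagnostics: dict = field(default_factory=dict)

    def _design(self, X) -> np.ndarray:
        arr, _ = _as_array(X)
        if self.standardization is not None:
            arr = apply_standardization(self.standardization, arr)
        return arr

    def decision(self, X) -> np.ndarray:
        """Linear score b0 + b.x on the (standardized) feature scale."""
        return self._design(X) @ self.coef_.to_numpy() + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        if self.family != "lr":
            raise AttributeError("predict_proba is defined for logistic regression only")
        p1 = expit(self.decision(X))
        return np.column_stack([1 - p1, p1])

    def score_samples(self, X) -> np.ndarray:
        """Family-specific AUROC ranking score (probability, margin or fit)."""
        if self.family == "lr":
            return expit(self.decision(X))
        return self.decision(X)

    def summary(self) -> str:
        nz = int((self.coef_ != 0).sum())
        lines = [
            f"Linear model ({self.family})",
            f"  features: {len(self.coef_)} ({nz} nonzero)   intercept: {self.intercept_:.4f}",
            f"  ||b||_1 = {np.abs(self.coef_).sum():.4f}",
        ]
        for k, v in self.diagnostics.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)


class LinearClassifierBase:
    family = "linear"

    def __init__(self, X, y, standardize: bool = True, class_weight="auto"):
        self._arr, self.columns = _as_array(X)
        if hasattr(y, "to_numpy"):
            y = y.to_numpy()
        self.y = np.asarray(y, dtype=int)
        if len(self.y) != len(self._arr):
            raise ValueError("X and y length mismatch")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        self.standardize = standardize
        self.class_weight = class_weight

    def _prepared(self) -> tuple[np.ndarray, Optional[StandardizeParams]]:
        if self.standardize:
            return standardize_columns(self._arr)
        return self._arr, None


class LogisticModel(LinearClassifierBase):
    """Class-weighted logistic regression (maximum likelihood, optional ridge)."""

    family = "lr"

    def __init__(self, X, y, ridge: float = 1e-8, max_iter: int = 5000,
                 tol: float = 1e-10, **kwargs):
        super().__init__(X, y, **kwargs)
        if ridge < 0:
            raise ValueError("ridge must be >= 0")
        self.ridge = float(ridge)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    def fit(self) -> LinearResults:
        Xs, params = self._prepared()
        cw = _resolve_class_weight(self.class_weight, self.y)
        # C = inf gives the pure (unpenalized) class-weighted MLE
        est = LogisticRegression(
            C=(1.0 / self.ridge if self.ridge > 0 else np.inf), solver="lbfgs",
            max_iter=self.max_iter, tol=self.tol, class_weight=cw,
        )
        est.fit(Xs, self.y)
        n_iter = int(np.max(est.n_iter_))
        if n_iter >= self.max_iter:
            raise ConvergenceError(
                f"logistic regression did not converge in {self.max_iter} iterations"
                f" (ridge={self.ridge}); consider a larger ridge"
            )
        return LinearResults(
            model=self, family="lr",
            coef_=pd.Series(est.coef_[0], index=self.columns),
            intercept_=float(est.intercept_[0]),
            standardization=params,
            diagnostics={"n_iter": n_iter, "ridge": self.ridge, "class_weight": cw or "none"},
        )


class LinearSVM(LinearClassifierBase):
    """Class-weighted linear support vector machine (hinge loss)."""

    family = "svm"

    def __init__(self, X, y, C: float = 1.0, max_iter: int = 100000,
                 tol: float = 1e-6, **kwargs):
        super().__init__(X, y, **kwargs)
        if C <= 0:
            raise ValueError("C must be > 0")
        self.C = float(C)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    def fit(self) -> LinearResults:
        Xs, params = self._prepared()
        cw = _resolve_class_weight(self.class_weight, self.y)
        est = LinearSVC(
            C=self.C, loss="hinge", dual=True, class_weight=cw,
            max_iter=self.max_iter, tol=self.tol,
        )
        est.fit(Xs, self.y)
        if est.n_iter_ >= self.max_iter:
            raise ConvergenceError(
                f"linear SVM did not converge in {self.max_iter} iterations"
            )
        return LinearResults(
            model=self, family="svm",
            coef_=pd.Series(est.coef_[0], index=self.columns),
            intercept_=float(est.intercept_[0]),
            standardization=params,
            diagnostics={"C": self.C, "class_weight": cw or "none"},
        )


class LassoModel(LinearClassifierBase):
    """Squared-loss LASSO of the 0/1 label; intercept unpenalized.

    Exactly one tuning mode applies: a fixed L1 bound ``s`` (solved on the
    LARS path), a fixed penalty ``lam`` (coordinate descent), or - the
    default - a penalty grid with inner stratified cross-validation selecting
    by training-fold AUROC.
    """

    family = "lasso"

    def __init__(self, X, y, s: float | None = None, lam: float | None = None,
                 lambda_grid=None, inner_folds: int = 3, seed: int = 0,
                 standardize: bool = True, class_weight="none"):
        super().__init__(X, y, standardize=standardize, class_weight="none")
        if s is not None and lam is not None:
            raise ValueError("specify at most one of s (L1 bound) and lam (penalty)")
        if s is not None and s < 0:
            raise ValueError("s must be >= 0")
        if lam is not None and lam < 0:
            raise ValueError("lam must be >= 0")
        self.s = s
        self.lam = lam
        self.lambda_grid = lambda_grid
        self.inner_folds = int(inner_folds)
        self.seed = int(seed)

    def _fit_bound(self, Xs: np.ndarray, yf: np.ndarray) -> tuple[np.ndarray, float]:
        ybar = float(yf.mean())
        if self.s == 0:
            return np.zeros(Xs.shape[1]), ybar
        # LARS gives the exact piecewise-linear LASSO path; the L1 norm is
        # linear within a segment, so interpolate the knot solutions at s.
        mu = Xs.mean(axis=0)
        Xc = Xs - mu
        _, _, coefs = lars_path(Xc, yf - ybar, method="lasso")
        norms = np.abs(coefs).sum(axis=0)
        if self.s >= norms[-1]:
            coef = coefs[:, -1]
        else:
            hi = int(np.searchsorted(norms, self.s))
            lo = max(hi - 1, 0)
            span = norms[hi] - norms[lo]
            frac = 0.0 if span == 0 else (self.s - norms[lo]) / span
            coef = coefs[:, lo] + frac * (coefs[:, hi] - coefs[:, lo])
        intercept = ybar - coef @ mu
        return coef, intercept

    def _fit_penalty(self, Xs, yf, lam) -> tuple[np.ndarray, float]:
        if lam == 0:
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(yf)), Xs]), yf, rcond=None
            )
            return coef[1:], float(coef[0])
        est = Lasso(alpha=lam, fit_intercept=True, max_iter=100000, tol=1e-6)
        est.fit(Xs, yf)
        return est.coef_, float(est.intercept_)

    def _select_penalty(self, Xs, yf) -> float:
        from .evaluate import auroc, stratified_folds  # local: avoids module cycle

        n = len(yf)
        resid = yf - yf.mean()
        lam_max = np.abs(Xs.T @ resid).max() / n if Xs.size else 1.0
        grid = (
            np.asarray(self.lambda_grid, dtype=float)
            if self.lambda_grid is not None
            else lam_max * np.logspace(0, -3, 8)
        )
        folds = stratified_folds(self.y, k=self.inner_folds, seed=self.seed)
        best_lam, best_auc = float(grid[0]), -np.inf
        for lam in grid:
            aucs = []
            for f in range(self.inner_folds):
                tr, te = folds != f, folds == f
                if len(np.unique(self.y[te])) < 2 or len(np.unique(self.y[tr])) < 2:
                    continue
                coef, icpt = self._fit_penalty(Xs[tr], yf[tr], lam)
                aucs.append(auroc(Xs[te] @ coef + icpt, self.y[te]))
            mean_auc = float(np.mean(aucs)) if aucs else 0.5
            if mean_auc > best_auc + 1e-12:
                best_lam, best_auc = float(lam), mean_auc
        return best_lam

    def fit(self) -> LinearResults:
        Xs, params = self._prepared()
        yf = self.y.astype(float)
        diagnostics: dict = {}
        if self.s is not None:
            coef, intercept = self._fit_bound(Xs, yf)
            diagnostics["s"] = self.s
        else:
            lam = self.lam if self.lam is not None else self._select_penalty(Xs, yf)
            coef, intercept = self._fit_penalty(Xs, yf, lam)
            diagnostics["lambda"] = lam
            if self.lam is None:
                diagnostics["lambda_selected_by"] = f"{self.inner_folds}-fold inner CV (AUROC)"
        return LinearResults(
            model=self, family="lasso",
            coef_=pd.Series(coef, index=self.columns),
            intercept_=float(intercept),
            standardization=params,
            diagnostics=diagnostics,
        )
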