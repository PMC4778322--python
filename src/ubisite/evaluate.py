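"""Stratified cross-validation, AUROC and method-comparison statistics.

AUROC is computed as the Mann-Whitney statistic with average ranks (the
probability that a random positive outscores a random negative, ties counted
half), which equals the trapezoidal area under the ROC curve.  Stratified
folds are formed by shuffling each class with a seeded generator and dealing
round-robin, so per-fold class counts deviate from proportionality by at most
one record.

Two methods are compared across datasets by the mean relative AUROC
improvement ("outperformance percent", mean over datasets of
``100 (a_d - b_d)/b_d``) and by a paired two-sided t-test on the per-dataset
AUROCs (datasets are the pairing unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .features import (
    DiscretizedMatrix,
    SegmentPCPMatrix,
    discretize_equal_interval,
    discretize_with_edges,
)

BAYES_METHODS = ("nb", "fsnb", "manb", "ebmc")
LINEAR_METHODS = ("lr", "svm", "lasso")
ALL_METHODS = BAYES_METHODS + LINEAR_METHODS

DEFAULT_CV_SEED = 42


def stratified_folds(labels, k: int = 5, seed: int = DEFAULT_CV_SEED) -> np.ndarray:
    """Fold index per record; within each class, shuffled then dealt round-robin."""
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present for stratified folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=np.int64)
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            import warnings

            warnings.warn(
                f"class {c} has only {len(idx)} records for {k} folds; "
                "some folds will lack this class",
                stacklevel=2,
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


def auroc(scores, labels) -> float:
    """Average-rank Mann-Whitney AUROC in [0, 1]; ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def sensitivity_at_fpr(scores, labels, fpr: float = 0.10) -> float:
    """True-positive rate at the strictest threshold with FPR <= ``fpr``."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("sensitivity undefined: both classes must be present")
    fpr_arr, tpr_arr, _ = roc_curve(y, np.asarray(scores, dtype=float),
                                    drop_intermediate=False)
    ok = fpr_arr <= fpr + 1e-12
    return float(tpr_arr[ok].max())


@dataclass
class CVResult:
    """Per-fold AUROCs of one method under one fold assignment."""

    method: str
    fold_aurocs: list[float]
    mean_auroc: float
    seed: int
    k: int
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        per_fold = ", ".join(f"{a:.4f}" for a in self.fold_aurocs)
        return (
            f"{self.method.upper()}: {self.k}-fold CV mean AUROC = "
            f"{self.mean_auroc:.4f}  (folds: {per_fold}; seed {self.seed})"
        )


def _build_model(method: str, X, y, config: dict, n_bins: int):
    from . import bayes, linear  # local import: model modules import auroc above

    method = method.lower()
    if method == "nb":
        return bayes.NaiveBayes(X, y, n_bins=n_bins,
                                pseudocount=config.get("pseudocount", 1.0))
    if method == "fsnb":
        return bayes.FeatureSelectionNB(
            X, y, n_bins=n_bins, score=config.get("score", "k2"),
            ess=config.get("ess", 1.0), pseudocount=config.get("pseudocount", 1.0))
    if method == "manb":
        return bayes.ModelAveragedNB(
            X, y, n_bins=n_bins, arc_prior=config.get("arc_prior", 0.5),
            score=config.get("score", "k2"), ess=config.get("ess", 1.0),
            pseudocount=config.get("pseudocount", 1.0))
    if method == "ebmc":
        return bayes.EBMC(
            X, y, n_bins=n_bins, ess=config.get("ess", 1.0),
            max_children=config.get("max_children"),
            max_parents=config.get("max_parents", 2),
            pseudocount=config.get("pseudocount", 1.0))
    if method == "lr":
        return linear.LogisticModel(
            X, y, ridge=config.get("ridge", 1e-8),
            class_weight=config.get("class_weight", "auto"))
    if method == "svm":
        return linear.LinearSVM(
            X, y, C=config.get("C", 1.0),
            class_weight=config.get("class_weight", "auto"))
    if method == "lasso":
        return linear.LassoModel(
            X, y, s=config.get("s"), lam=config.get("lam"),
            lambda_grid=config.get("lambda_grid"),
            inner_folds=config.get("inner_folds", 3),
            seed=config.get("lasso_seed", 0))
    raise ValueError(f"unknown method {method!r}; expected one of {ALL_METHODS}")


def cross_validate(
    method: str,
    continuous: SegmentPCPMatrix | None = None,
    discretized: DiscretizedMatrix | None = None,
    k: int = 5,
    seed: int = DEFAULT_CV_SEED,
    refit_discretization: bool = False,
    **config,
) -> CVResult:
    """Stratified k-fold CV of one method; returns per-fold and mean AUROC.

    Bayesian methods consume the discretized matrix, linear methods the
    continuous one (standardized per training fold inside the model).  With
    ``refit_discretization`` the equal-interval bin edges are re-fitted on
    each training fold from the continuous matrix (leakage-free variant); by
    default the supplied full-data discretization is used.
    """
    method = method.lower()
    is_bayes = method in BAYES_METHODS
    if is_bayes:
        if discretized is None:
            if continuous is None:
                raise ValueError("Bayesian methods need a discretized (or continuous) matrix")
            discretized = discretize_equal_interval(continuous)
        y = discretized.y.to_numpy()
        n_bins = discretized.n_bins
    else:
        if continuous is None:
            raise ValueError("regression methods need the continuous matrix")
        y = continuous.y.to_numpy()
        n_bins = discretized.n_bins if discretized is not None else 3
    if refit_discretization and is_bayes and continuous is None:
        raise ValueError("refit_discretization requires the continuous matrix")

    folds = stratified_folds(y, k=k, seed=seed)
    fold_aurocs: list[float] = []
    for f in range(k):
        tr = folds != f
        te = folds == f
        if is_bayes:
            if refit_discretization:
                sub = SegmentPCPMatrix(X=continuous.X.iloc[tr], y=continuous.y.iloc[tr])
                disc_tr = discretize_equal_interval(sub, n_bins=n_bins)
                Xtr, ytr = disc_tr.X, y[tr]
                sub_te = SegmentPCPMatrix(X=continuous.X.iloc[te], y=continuous.y.iloc[te])
                Xte = discretize_with_edges(sub_te, disc_tr.edges, n_bins=n_bins).X
            else:
                Xtr, ytr = discretized.X.iloc[tr], y[tr]
                Xte = discretized.X.iloc[te]
        else:
            Xtr, ytr = continuous.X.iloc[tr], y[tr]
            Xte = continuous.X.iloc[te]
        res = _build_model(method, Xtr, ytr, config, n_bins).fit()
        fold_aurocs.append(auroc(res.score_samples(Xte), y[te]))
    return CVResult(
        method=method,
        fold_aurocs=fold_aurocs,
        mean_auroc=float(np.mean(fold_aurocs)),
        seed=seed,
        k=k,
        config=dict(config, refit_discretization=refit_discretization),
    )


def outperformance_pct(aucs_a, aucs_b) -> float:
    """Mean over datasets of the relative AUROC improvement of a over b, x100."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("inputs must be equal-length non-empty vectors")
    if (b <= 0).any():
        raise ValueError("baseline AUROCs must be positive")
    return float(np.mean(100.0 * (a - b) / b))


def paired_t_test(a, b) -> tuple[float, float]:
    """Paired two-sided t-test on per-dataset AUROCs; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or a.shape != b.shape:
        raise ValueError("need at least 2 pairs of equal length")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t statistic undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class ComparisonReport:
    """Outperformance/t-test rows for method pairs over dataset groups."""

    table: pd.DataFrame  # columns: pair, group, outperformance_pct, t, p
    auc_inputs: pd.DataFrame

    def summary(self) -> str:
        return self.table.to_string(index=False,
                                    float_format=lambda v: f"{v:.4f}")


def compare_methods(
    auc_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    groups: Mapping[str, Sequence],
) -> ComparisonReport:
    """Compute outperformance % and paired t-tests from a datasets x methods AUROC table."""
    rows = []
    for a_m, b_m in pairs:
        for gname, members in groups.items():
            sub = auc_table.loc[list(members)]
            op = outperformance_pct(sub[a_m], sub[b_m])
            t, p = paired_t_test(sub[a_m], sub[b_m])
            rows.append({
                "pair": f"{a_m}:{b_m}", "group": gname,
                "outperformance_pct": op, "t": t, "p": p,
            })
    return ComparisonReport(table=pd.DataFrame(rows), auc_inputs=auc_table.copy())
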