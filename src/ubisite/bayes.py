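"""Bayesian classifiers over discretized segment-PCP features.

Four predictors share the same discrete machinery (:mod:`ubisite.scoring`)
and the same model/results idiom: a model object is built from a feature
matrix and labels, ``fit()`` estimates structure and parameters and returns a
results object exposing ``predict_proba`` (the posterior probability of each
class, used directly as the ranking score for AUROC) and ``summary()``.

* :class:`NaiveBayes` — all features are children of the binary target T;
  P(T|x) ~ P(T) * prod_i P(x_i|T), normalized.
* :class:`FeatureSelectionNB` (FSNB) — greedy forward selection of the NB
  feature set by the Cooper-Herskovits (K2) network score; the search stops
  when no addition strictly increases the score.  Because the score
  decomposes over families and the candidate family (X_i with parent T) does
  not change as other features enter, each feature's score gain is constant
  and the greedy order is the descending order of positive gains.
* :class:`ModelAveragedNB` (MANB) — exact Bayesian model averaging over all
  2^n feature-inclusion subsets.  With independent arc priors the average
  factorizes per feature into arc-posterior weights
  ``w_i = p*m1_i / (p*m1_i + (1-p)*m0_i)`` (computed in log space), giving
  P(t|x) ~ P(t) * prod_i [w_i P(x_i|t) + (1-w_i) P(x_i)] in O(n).
* :class:`EBMC` — greedy target-centric structure search with the BDeu
  score: grow the set of variables that best predict T (scored as parents of
  T), convert it to the statistically equivalent form in which the variables
  are children of T (chained so the conversion is exact), then grow a
  separate parent set of T; phases alternate until no move improves the
  score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .features import DEFAULT_N_BINS, DiscretizedMatrix
from .scoring import (
    CPT,
    bdeu_log_score,
    count_table,
    fit_cpt,
    k2_log_score,
    target_family_score,
)

TARGET = "__target__"

_SCORE_FUNCS = {"k2": k2_log_score, "bdeu": bdeu_log_score}


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DiscretizedMatrix):
        return X.X
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


class DiscreteBayesModel:
    """Shared constructor/validation for the discrete Bayesian classifiers."""

    def __init__(self, X, y=None, n_bins: int = DEFAULT_N_BINS, pseudocount: float = 1.0):
        if isinstance(X, DiscretizedMatrix) and y is None:
            y = X.y
            n_bins = X.n_bins
        self.X = _as_frame(X).astype(np.int64)
        self.y = np.asarray(y, dtype=np.int64)
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        classes = np.unique(self.y)
        if not np.array_equal(classes, np.array([0, 1])):
            raise ValueError(
                "labels must contain both classes 0 and 1 (AUROC is undefined otherwise)"
            )
        if (self.X.to_numpy() < 0).any() or (self.X.to_numpy() >= n_bins).any():
            raise ValueError(f"feature values outside declared arity {n_bins}")
        self.n_bins = int(n_bins)
        self.pseudocount = float(pseudocount)
        self.features = list(self.X.columns)
        self.arities = {f: self.n_bins for f in self.features}
        self.arities[TARGET] = 2

    @classmethod
    def from_matrix(cls, matrix: DiscretizedMatrix, **kwargs):
        return cls(matrix.X, matrix.y, n_bins=matrix.n_bins, **kwargs)

    def _data(self) -> pd.DataFrame:
        data = self.X.copy()
        data[TARGET] = self.y
        return data

    def _fit_prior(self) -> np.ndarray:
        ct = count_table(self._data(), TARGET, [], self.arities)
        return fit_cpt(ct, self.pseudocount).table[0]

    def _fit_feature_cpts(self, features: Sequence[str]) -> np.ndarray:
        """log P(x_f = b | T = t) stacked as (n_features, 2, n_bins)."""
        data = self._data()
        out = np.empty((len(features), 2, self.n_bins))
        for i, f in enumerate(features):
            cpt = fit_cpt(count_table(data, f, [TARGET], self.arities), self.pseudocount)
            out[i] = cpt.table  # rows indexed by the T configuration
        return np.log(out)


def _check_values(Xarr: np.ndarray, n_bins: int) -> None:
    if (Xarr < 0).any() or (Xarr >= n_bins).any():
        raise ValueError(f"feature value outside declared arity {n_bins}")


def _select_columns(X, features: Sequence[str], n_bins: int) -> np.ndarray:
    frame = _as_frame(X)
    missing = [f for f in features if f not in frame.columns]
    if missing:
        raise KeyError(f"rows do not supply model features: {missing}")
    arr = frame[list(features)].to_numpy(dtype=np.int64)
    _check_values(arr, n_bins)
    return arr


@dataclass
class BayesResults:
    """Base results: class prior + posterior evaluation over rows."""

    model: DiscreteBayesModel
    class_prior: np.ndarray  # (2,)

    def predict_log_proba(self, X) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, X) -> np.ndarray:
        logp = self.predict_log_proba(X)
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def score_samples(self, X) -> np.ndarray:
        """Posterior probability of class 1, the AUROC ranking score."""
        return self.predict_proba(X)[:, 1]

    def summary(self) -> str:
        raise NotImplementedError


@dataclass
class NaiveBayesResults(BayesResults):
    features: list[str] = field(default_factory=list)
    log_cpts: np.ndarray | None = None  # (F, 2, B)

    def predict_log_proba(self, X) -> np.ndarray:
        logp = np.tile(np.log(self.class_prior), (len(_as_frame(X)), 1))
        if self.features:
            arr = _select_columns(X, self.features, self.model.n_bins)
            fidx = np.arange(len(self.features))
            for t in (0, 1):
                logp[:, t] += self.log_cpts[fidx[None, :], t, arr].sum(axis=1)
        return logp

    def summary(self) -> str:
        lines = [
            "Naive Bayes classifier",
            f"  records: {len(self.model.y)}   features: {len(self.features)}"
            f"   bins: {self.model.n_bins}   pseudocount: {self.model.pseudocount}",
            f"  class prior P(T=1) = {self.class_prior[1]:.4f}",
        ]
        return "\n".join(lines)


class NaiveBayes(DiscreteBayesModel):
    def fit(self) -> NaiveBayesResults:
        return NaiveBayesResults(
            model=self,
            class_prior=self._fit_prior(),
            features=list(self.features),
            log_cpts=self._fit_feature_cpts(self.features),
        )


@dataclass
class FSNBResults(NaiveBayesResults):
    selection_order: list[str] = field(default_factory=list)
    score_trace: list[float] = field(default_factory=list)  # total network score
    gains: pd.Series | None = None

    def summary(self) -> str:
        lines = [
            "Feature-selection naive Bayes (greedy K2/BDeu forward search)",
            f"  records: {len(self.model.y)}   candidates: {len(self.model.features)}"
            f"   selected: {len(self.selection_order)}",
            f"  class prior P(T=1) = {self.class_prior[1]:.4f}",
            f"  selected (in order): {', '.join(self.selection_order) or '(none)'}",
        ]
        return "\n".join(lines)


class FeatureSelectionNB(DiscreteBayesModel):
    """NB over a feature subset grown greedily by a Bayesian network score."""

    def __init__(self, X, y=None, score: str = "k2", ess: float = 1.0, **kwargs):
        super().__init__(X, y, **kwargs)
        if score not in _SCORE_FUNCS:
            raise ValueError(f"score must be one of {sorted(_SCORE_FUNCS)}")
        self.score = score
        self.ess = float(ess)

    def _family_score(self, data, child, parents) -> float:
        if self.score == "bdeu":
            return bdeu_log_score(data, child, parents, self.arities, self.ess)
        return k2_log_score(data, child, parents, self.arities)

    def fit(self) -> FSNBResults:
        data = self._data()
        base = self._family_score(data, TARGET, [])
        gains = {}
        for f in self.features:
            m1 = self._family_score(data, f, [TARGET])
            m0 = self._family_score(data, f, [])
            gains[f] = m1 - m0
            base += m0
        gains = pd.Series(gains)
        # Family decomposition makes each gain independent of the rest of the
        # selection, so greedy == take positive gains in descending order
        # (ties broken by original column order).
        order = np.lexsort((np.arange(len(gains)), -gains.to_numpy()))
        selected: list[str] = []
        trace = [base]
        for i in order:
            g = float(gains.iloc[i])
            if g <= 0:
                break
            selected.append(str(gains.index[i]))
            trace.append(trace[-1] + g)
        return FSNBResults(
            model=self,
            class_prior=self._fit_prior(),
            features=selected,
            log_cpts=self._fit_feature_cpts(selected),
            selection_order=selected,
            score_trace=trace,
            gains=gains,
        )


@dataclass
class MANBResults(BayesResults):
    features: list[str] = field(default_factory=list)
    arc_weights: np.ndarray | None = None  # (F,) posterior P(arc T->X_i | data)
    cond_cpts: np.ndarray | None = None  # (F, 2, B) P(x|t)
    marg_cpts: np.ndarray | None = None  # (F, B)   P(x)

    def predict_log_proba(self, X) -> np.ndarray:
        arr = _select_columns(X, self.features, self.model.n_bins)
        n = arr.shape[0]
        logp = np.tile(np.log(self.class_prior), (n, 1))
        fidx = np.arange(len(self.features))
        marg = self.marg_cpts[fidx[None, :], arr]  # (n, F)
        w = self.arc_weights[None, :]
        for t in (0, 1):
            cond = self.cond_cpts[fidx[None, :], t, arr]
            logp[:, t] += np.log(w * cond + (1.0 - w) * marg).sum(axis=1)
        return logp

    def summary(self) -> str:
        w = pd.Series(self.arc_weights, index=self.features)
        top = w.sort_values(ascending=False).head(5)
        lines = [
            "Model-averaged naive Bayes (exact averaging over feature subsets)",
            f"  records: {len(self.model.y)}   features: {len(self.features)}",
            f"  class prior P(T=1) = {self.class_prior[1]:.4f}",
            "  top arc posteriors: "
            + ", ".join(f"{k}={v:.3f}" for k, v in top.items()),
        ]
        return "\n".join(lines)


class ModelAveragedNB(DiscreteBayesModel):
    """Exact Bayesian model averaging over all 2^n NB feature subsets.

    Each feature's arc (T -> X_i) carries an independent prior ``arc_prior``;
    the subset average collapses to per-feature arc-posterior weights, so the
    fit and the posterior are both O(n) rather than O(2^n).
    """

    def __init__(self, X, y=None, arc_prior: float = 0.5, score: str = "k2",
                 ess: float = 1.0, **kwargs):
        super().__init__(X, y, **kwargs)
        if not 0.0 < arc_prior < 1.0:
            raise ValueError(f"arc_prior must lie strictly in (0, 1), got {arc_prior}")
        if score not in _SCORE_FUNCS:
            raise ValueError(f"score must be one of {sorted(_SCORE_FUNCS)}")
        self.arc_prior = float(arc_prior)
        self.score = score
        self.ess = float(ess)

    def _marginal_scores(self) -> tuple[np.ndarray, np.ndarray]:
        data = self._data()
        m1 = np.empty(len(self.features))
        m0 = np.empty(len(self.features))
        for i, f in enumerate(self.features):
            if self.score == "bdeu":
                m1[i] = bdeu_log_score(data, f, [TARGET], self.arities, self.ess)
                m0[i] = bdeu_log_score(data, f, [], self.arities, self.ess)
            else:
                m1[i] = k2_log_score(data, f, [TARGET], self.arities)
                m0[i] = k2_log_score(data, f, [], self.arities)
        return m1, m0

    def fit(self) -> MANBResults:
        m1, m0 = self._marginal_scores()
        logit_prior = np.log(self.arc_prior) - np.log1p(-self.arc_prior)
        weights = expit(logit_prior + m1 - m0)
        data = self._data()
        marg = np.empty((len(self.features), self.n_bins))
        for i, f in enumerate(self.features):
            marg[i] = fit_cpt(count_table(data, f, [], self.arities), self.pseudocount).table[0]
        return MANBResults(
            model=self,
            class_prior=self._fit_prior(),
            features=list(self.features),
            arc_weights=weights,
            cond_cpts=np.exp(self._fit_feature_cpts(self.features)),
            marg_cpts=marg,
        )


def chain_child_cpts(
    data: pd.DataFrame,
    target: str,
    variables: Sequence[str],
    arities,
    pseudocount: float,
) -> list[CPT]:
    """CPTs of the statistically equivalent children-of-target form.

    A model in which ``variables`` point at the target is converted to one in
    which the target points at them; exact equivalence requires each variable
    to be conditioned on the earlier ones as well (a chain), so variable j's
    CPT has parents (target, variables[0..j-1]).
    """
    cpts = []
    for j, v in enumerate(variables):
        parents = [target, *variables[:j]]
        cpts.append(fit_cpt(count_table(data, v, parents, arities), pseudocount))
    return cpts


@dataclass
class EBMCResults(BayesResults):
    children: list[str] = field(default_factory=list)  # chain order
    parents: list[str] = field(default_factory=list)
    child_cpts: list[CPT] = field(default_factory=list)
    target_cpt: CPT | None = None  # P(T | parents); None when parents == []
    score_trace: list[list[float]] = field(default_factory=list)  # per accepted phase

    def predict_log_proba(self, X) -> np.ndarray:
        frame = _as_frame(X)
        n = len(frame)
        model: EBMC = self.model  # type: ignore[assignment]
        if self.parents:
            pvals = _select_columns(frame, self.parents, model.n_bins)
            t_rows = self.target_cpt.lookup(pvals)  # (n, 2)
            logp = np.log(t_rows)
        else:
            logp = np.tile(np.log(self.class_prior), (n, 1))
        for j, cpt in enumerate(self.child_cpts):
            child = self.children[j]
            earlier = self.children[:j]
            cvals = _select_columns(frame, [child], model.n_bins)[:, 0]
            evals = (
                _select_columns(frame, earlier, model.n_bins)
                if earlier
                else np.empty((n, 0), dtype=np.int64)
            )
            for t in (0, 1):
                pv = np.column_stack([np.full(n, t, dtype=np.int64), evals])
                rows = cpt.lookup(pv)
                logp[:, t] += np.log(rows[np.arange(n), cvals])
        return logp

    def summary(self) -> str:
        lines = [
            "Efficient Bayesian multivariate classifier (BDeu greedy search)",
            f"  records: {len(self.model.y)}   candidates: {len(self.model.features)}",
            f"  children of target (chain order): {', '.join(self.children) or '(none)'}",
            f"  parents of target: {', '.join(self.parents) or '(none)'}",
            f"  class prior P(T=1) = {self.class_prior[1]:.4f}",
        ]
        return "\n".join(lines)


class EBMC(DiscreteBayesModel):
    """Greedy target-centric Bayesian classifier with BDeu scoring.

    Phase A greedily grows the set of variables that best predict the target
    (scored as a candidate parent set of T via the target family score); on
    stall the set is converted to the statistically equivalent
    children-of-target chain.  Phase B then greedily adds further variables
    as true parents of T (bounded by ``max_parents``).  The phases alternate
    until neither finds a strictly score-improving move.
    """

    _EPS = 1e-12

    def __init__(self, X, y=None, ess: float = 1.0, max_children: int | None = None,
                 max_parents: int = 2, **kwargs):
        super().__init__(X, y, **kwargs)
        if ess <= 0:
            raise ValueError(f"ess must be > 0, got {ess}")
        if max_parents < 0 or (max_children is not None and max_children < 0):
            raise ValueError("max_children and max_parents must be >= 0")
        self.ess = float(ess)
        self.max_children = max_children
        self.max_parents = int(max_parents)

    def _chain_capacity_ok(self, n_children: int) -> bool:
        # next child's CPT has 2 * B^n_children rows; keep it dense-able
        return 2 * (self.n_bins ** n_children) * self.n_bins <= 500_000

    def fit(self) -> EBMCResults:
        data = self._data()
        remaining = list(self.features)
        children: list[str] = []
        parents: list[str] = []
        traces: list[list[float]] = []

        def tfs(pset):
            return target_family_score(data, TARGET, pset, self.arities, self.ess)

        changed = True
        while changed:
            changed = False
            # --- Phase A: grow predictors of T, then convert to children ---
            block: list[str] = []
            current = tfs(parents + block)
            trace = [current]
            while remaining:
                if self.max_children is not None and len(children) + len(block) >= self.max_children:
                    break
                if not self._chain_capacity_ok(len(children) + len(block)):
                    break
                scores = np.array([tfs(parents + block + [v]) for v in remaining])
                best = int(np.argmax(scores))  # first max -> lowest column index
                if scores[best] > current + self._EPS:
                    block.append(remaining.pop(best))
                    current = float(scores[best])
                    trace.append(current)
                else:
                    break
            if block:
                children.extend(block)
                traces.append(trace)
                changed = True
            # --- Phase B: grow true parents of T ---
            currentB = tfs(parents)
            traceB = [currentB]
            while remaining and len(parents) < self.max_parents:
                scores = np.array([tfs(parents + [v]) for v in remaining])
                best = int(np.argmax(scores))
                if scores[best] > currentB + self._EPS:
                    parents.append(remaining.pop(best))
                    currentB = float(scores[best])
                    traceB.append(currentB)
                    changed = True
                else:
                    break
            if len(traceB) > 1:
                traces.append(traceB)

        child_cpts = chain_child_cpts(data, TARGET, children, self.arities, self.pseudocount)
        target_cpt = (
            fit_cpt(count_table(data, TARGET, parents, self.arities), self.pseudocount)
            if parents
            else None
        )
        return EBMCResults(
            model=self,
            class_prior=self._fit_prior(),
            children=children,
            parents=parents,
            child_cpts=child_cpts,
            target_cpt=target_cpt,
            score_trace=traces,
        )
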