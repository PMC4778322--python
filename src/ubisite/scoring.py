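"""Count tables, Dirichlet-smoothed CPTs and Bayesian family scores.

Every Bayesian classifier here is parameterized by families (a child variable
plus a parent set) over discrete variables with *declared* arities: features
carry the global bin count (3 by default) and the target is binary, so states
unseen in a training fold still occupy rows of the conditional probability
tables.

Two marginal-likelihood family scores are provided, both in natural log:

* the Cooper-Herskovits (K2) score,
  ``prod_j (r-1)!/(N_j+r-1)! * prod_k N_jk!``, under unit Dirichlet priors;
* the BDeu score with equivalent sample size ``ess``, which spreads
  ``ess`` uniformly over the child's ``q*r`` parameter cells and satisfies
  likelihood equivalence.

Parent configurations are enumerated in mixed-radix order over declared
arities (first parent most significant).  Count tables are stored sparsely:
a configuration never observed contributes exactly zero to either score, so
scores stay computable when ``q`` is combinatorially large.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

_MAX_DENSE_CELLS = 2_000_000


@dataclass
class CountTable:
    """Sparse joint counts N_jk for one family (child given parent config)."""

    child: str
    parents: tuple[str, ...]
    r: int  # child arity
    parent_arities: tuple[int, ...]
    q: int  # number of parent configurations (product of arities)
    counts: dict[int, np.ndarray]  # config index -> length-r integer counts

    def n_j(self, j: int) -> int:
        c = self.counts.get(j)
        return 0 if c is None else int(c.sum())

    @property
    def total(self) -> int:
        return sum(int(c.sum()) for c in self.counts.values())


def config_indices(parent_values: np.ndarray, parent_arities: Sequence[int]) -> np.ndarray:
    """Mixed-radix configuration index per record (first parent most significant)."""
    n = parent_values.shape[0]
    idx = np.zeros(n, dtype=np.int64)
    for p, arity in enumerate(parent_arities):
        col = parent_values[:, p]
        if (col < 0).any() or (col >= arity).any():
            raise ValueError(
                f"value outside declared arity {arity} in parent column {p}"
            )
        idx = idx * arity + col
    return idx


def count_table(
    data: pd.DataFrame,
    child: str,
    parents: Sequence[str],
    arities: Mapping[str, int],
) -> CountTable:
    """Exact joint counts of ``child`` under each configuration of ``parents``."""
    for name in [child, *parents]:
        if name not in data.columns:
            raise KeyError(f"unknown column {name!r}")
        if name not in arities:
            raise KeyError(f"no declared arity for column {name!r}")
    r = int(arities[child])
    parent_arities = tuple(int(arities[p]) for p in parents)
    q = 1
    for a in parent_arities:
        q *= a
    child_vals = data[child].to_numpy(dtype=np.int64)
    if len(child_vals) and ((child_vals < 0).any() or (child_vals >= r).any()):
        raise ValueError(f"child {child!r} has values outside declared arity {r}")
    if parents:
        if q > 2**62:
            raise ValueError("parent configuration space too large to index")
        pv = data[list(parents)].to_numpy(dtype=np.int64)
        idx = config_indices(pv, parent_arities)
    else:
        idx = np.zeros(len(child_vals), dtype=np.int64)
    counts: dict[int, np.ndarray] = {}
    for j, k in zip(idx, child_vals):
        row = counts.get(j)
        if row is None:
            row = np.zeros(r, dtype=np.int64)
            counts[int(j)] = row
        row[k] += 1
    return CountTable(
        child=child,
        parents=tuple(parents),
        r=r,
        parent_arities=parent_arities,
        q=q,
        counts=counts,
    )


def k2_log_score_from_counts(ct: CountTable) -> float:
    """log of prod_j [(r-1)!/(N_j+r-1)!] * prod_k N_jk!  (zero for empty data)."""
    r = ct.r
    total = 0.0
    for row in ct.counts.values():
        n_j = int(row.sum())
        total += gammaln(r) - gammaln(n_j + r) + gammaln(row + 1).sum()
    return float(total)


def k2_log_score(
    data: pd.DataFrame,
    child: str,
    parents: Sequence[str],
    arities: Mapping[str, int],
) -> float:
    return k2_log_score_from_counts(count_table(data, child, parents, arities))


def bdeu_log_score_from_counts(ct: CountTable, ess: float = 1.0) -> float:
    if ess <= 0:
        raise ValueError(f"ess must be > 0, got {ess}")
    a_jk = ess / (ct.q * ct.r)
    a_j = ess / ct.q
    total = 0.0
    for row in ct.counts.values():
        n_j = int(row.sum())
        total += gammaln(a_j) - gammaln(a_j + n_j)
        total += (gammaln(a_jk + row) - gammaln(a_jk)).sum()
    return float(total)


def bdeu_log_score(
    data: pd.DataFrame,
    child: str,
    parents: Sequence[str],
    arities: Mapping[str, int],
    ess: float = 1.0,
) -> float:
    return bdeu_log_score_from_counts(count_table(data, child, parents, arities), ess)


def target_family_score(
    data: pd.DataFrame,
    target: str,
    parents: Sequence[str],
    arities: Mapping[str, int],
    ess: float = 1.0,
) -> float:
    """BDeu family score of the target given a candidate parent set.

    This is the quantity the EBMC greedy structure search maximizes: how well
    the candidate set predicts the target, marginalizing over parameters.
    """
    return bdeu_log_score(data, target, parents, arities, ess)


@dataclass
class CPT:
    """Dense conditional probability table P(child = k | parent config j)."""

    child: str
    parents: tuple[str, ...]
    r: int
    parent_arities: tuple[int, ...]
    table: np.ndarray  # shape (q, r); rows sum to 1
    pseudocount: float

    @property
    def q(self) -> int:
        return self.table.shape[0]

    def log_table(self) -> np.ndarray:
        return np.log(self.table)

    def lookup(self, parent_values: np.ndarray) -> np.ndarray:
        """Rows of the table for an (n, n_parents) array of parent values."""
        if self.parents:
            idx = config_indices(
                np.asarray(parent_values, dtype=np.int64), self.parent_arities
            )
        else:
            idx = np.zeros(len(parent_values), dtype=np.int64)
        return self.table[idx]


def fit_cpt(ct: CountTable, pseudocount: float = 1.0) -> CPT:
    """Dirichlet-smoothed CPT: P(k|j) = (N_jk + a) / (N_j + r*a).

    With ``pseudocount`` 0, a parent configuration with no observations has an
    undefined row and a ``ValueError`` is raised.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if ct.q * ct.r > _MAX_DENSE_CELLS:
        raise ValueError(
            f"CPT for {ct.child!r} given {ct.parents} has {ct.q}x{ct.r} cells; too large"
        )
    table = np.full((ct.q, ct.r), pseudocount, dtype=float)
    for j, row in ct.counts.items():
        table[j] += row
    denom = table.sum(axis=1, keepdims=True)
    if (denom == 0).any():
        raise ValueError(
            f"CPT for {ct.child!r}: unobserved parent configuration with pseudocount 0"
        )
    return CPT(
        child=ct.child,
        parents=ct.parents,
        r=ct.r,
        parent_arities=ct.parent_arities,
        table=table / denom,
        pseudocount=pseudocount,
    )
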