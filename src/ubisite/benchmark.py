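"""Reference AUROC benchmark for the seven methods on six literature datasets.

A published seven-method comparison evaluated EBMC, NB, FSNB, MANB, SVM, LR
and LASSO by stratified five-fold CV on six segment-PCP ubiquitination
datasets: three balanced sets (1-3) and three unbalanced sets (4-6), four of
which (2-5) are large-scale (> 3500 segments).  The printed mean AUROCs are
kept here as the worked input for the comparison statistics
(:func:`ubisite.evaluate.compare_methods`): feeding them through
outperformance % and the paired t-test reproduces the published
method-comparison table for the cells computed from the printed precision.

The AUROCs themselves are *inputs*, not anything this package recomputes --
the underlying datasets are external downloads.  Cells that the original
analysis derived from unrounded per-fold AUROCs (the "Balanced" group and
the EBMC:SVM "All" cell) do not reproduce exactly from these 4-decimal
values; see docs/methods.md.
"""

from __future__ import annotations

import pandas as pd

from .evaluate import ComparisonReport, compare_methods

#: Mean 5-fold CV AUROC per dataset (rows) and method (columns), as printed.
REFERENCE_AUROCS = pd.DataFrame(
    {
        "EBMC": [0.6714, 0.6467, 0.6667, 0.6646, 0.6373, 0.6001],
        "NB": [0.5289, 0.5330, 0.5141, 0.6036, 0.5505, 0.5134],
        "FSNB": [0.5613, 0.5582, 0.5633, 0.6193, 0.5637, 0.4838],
        "MANB": [0.5545, 0.5502, 0.5192, 0.6108, 0.5804, 0.5690],
        "SVM": [0.6597, 0.6035, 0.6102, 0.6670, 0.6763, 0.5758],
        "LR": [0.7244, 0.6410, 0.6476, 0.7200, 0.7235, 0.5546],
        "LASSO": [0.6933, 0.6041, 0.6129, 0.5000, 0.5000, 0.5000],
    },
    index=pd.Index([1, 2, 3, 4, 5, 6], name="dataset"),
)

#: Dataset groups used in the published comparison.
GROUPS = {
    "All": [1, 2, 3, 4, 5, 6],
    "Balanced": [1, 2, 3],
    "UnBalanced": [4, 5, 6],
    "Large-scale": [2, 3, 4, 5],
}

#: Method pairs reported in the published comparison (EBMC vs the rest).
PAIRS = [("EBMC", m) for m in ("NB", "FSNB", "MANB", "SVM", "LR", "LASSO")]


def reference_comparison() -> ComparisonReport:
    """EBMC-versus-each-method comparison statistics from the reference table."""
    return compare_methods(REFERENCE_AUROCS, PAIRS, GROUPS)
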