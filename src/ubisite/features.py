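"""Segment-PCP feature matrices: per-segment property averaging and binning.

The feature value of a segment for one physicochemical property is the
arithmetic mean of that property over the segment's standard residues.
Padding (``-``) and non-standard letters (B, J, O, U, X, Z, ...) carry no
property value and are excluded from both numerator and denominator, which
makes the features invariant to the amount of padding.

For the discrete Bayesian classifiers every feature column is cut into
``n_bins`` equal-width intervals over its observed range (three by default):
value v in a column with range [mn, mx] maps to ``floor((v - mn)/width)``
with ``width = (mx - mn)/n_bins``; the maximum maps into the top bin and a
constant column maps to bin 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aaindex import AA_ORDER
from .segments import SegmentRecord

DEFAULT_N_BINS = 3


@dataclass
class SegmentPCPMatrix:
    """Real-valued segments x properties table plus the aligned 0/1 labels."""

    X: pd.DataFrame  # rows: segment ids, columns: PCP accessions
    y: pd.Series  # 0/1, aligned with X rows

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise ValueError("labels length must equal row count")


@dataclass
class DiscretizedMatrix:
    """Integer-binned twin of a :class:`SegmentPCPMatrix` with its bin edges."""

    X: pd.DataFrame  # integer bins in {0..n_bins-1}
    y: pd.Series
    n_bins: int
    edges: pd.DataFrame  # per-column: min, max, width

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise ValueError("labels length must equal row count")


def average_pcp_features(
    segments: list[SegmentRecord], aa_pcp: pd.DataFrame
) -> SegmentPCPMatrix:
    """Average each property over the standard residues of each segment.

    ``aa_pcp`` is the AA-PCP matrix (properties x 20 AA columns).  Raises
    ``ValueError`` when a segment contains no standard residue at all.
    """
    if not segments:
        raise ValueError("no segments supplied")
    if list(aa_pcp.columns) != list(AA_ORDER):
        aa_pcp = aa_pcp[list(AA_ORDER)]
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    counts = np.zeros((len(segments), 20), dtype=float)
    for r, seg in enumerate(segments):
        for ch in seg.segment:
            i = aa_index.get(ch)
            if i is not None:
                counts[r, i] += 1
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = segments[int(np.argmax(totals == 0))]
        raise ValueError(
            f"segment {bad.row_id!r} has no standard residues; cannot average"
        )
    # mean over residues == composition-weighted mean of property values
    values = (counts @ aa_pcp.to_numpy().T) / totals[:, None]
    ids = pd.Index([s.row_id for s in segments], name="segment_id")
    X = pd.DataFrame(values, index=ids, columns=aa_pcp.index.copy())
    y = pd.Series([s.label for s in segments], index=ids, name="label")
    return SegmentPCPMatrix(X=X, y=y)


def _fit_edges(X: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    mn = X.min(axis=0)
    mx = X.max(axis=0)
    width = (mx - mn) / n_bins
    return pd.DataFrame({"min": mn, "max": mx, "width": width})


def _apply_edges(X: pd.DataFrame, edges: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    vals = X.to_numpy(dtype=float)
    mn = edges["min"].to_numpy()
    width = edges["width"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        bins = np.floor((vals - mn[None, :]) / width[None, :])
    bins = np.where(np.isfinite(bins), bins, 0.0)  # constant columns -> bin 0
    bins = np.clip(bins, 0, n_bins - 1).astype(np.int64)
    return pd.DataFrame(bins, index=X.index, columns=X.columns)


def discretize_equal_interval(
    matrix: SegmentPCPMatrix, n_bins: int = DEFAULT_N_BINS
) -> DiscretizedMatrix:
    """Bin every column of the segment-PCP matrix into equal-width intervals."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    edges = _fit_edges(matrix.X, n_bins)
    return DiscretizedMatrix(
        X=_apply_edges(matrix.X, edges, n_bins),
        y=matrix.y.copy(),
        n_bins=n_bins,
        edges=edges,
    )


def discretize_with_edges(
    matrix: SegmentPCPMatrix, edges: pd.DataFrame, n_bins: int = DEFAULT_N_BINS
) -> DiscretizedMatrix:
    """Bin with pre-fitted edges (out-of-range values clipped into end bins).

    Used for leakage-free per-training-fold discretization.
    """
    return DiscretizedMatrix(
        X=_apply_edges(matrix.X, edges, n_bins),
        y=matrix.y.copy(),
        n_bins=n_bins,
        edges=edges,
    )


def write_feature_table(matrix, path, header_lines: list[str] | None = None) -> None:
    """Write a (continuous or discretized) matrix as TSV: id, features..., label."""
    df = matrix.X.copy()
    df["label"] = matrix.y
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_feature_table(path) -> SegmentPCPMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    y = df.pop("label").astype(int)
    return SegmentPCPMatrix(X=df, y=y)


def read_discretized_table(path, edges_path=None, n_bins: int = DEFAULT_N_BINS) -> DiscretizedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    y = df.pop("label").astype(int)
    if edges_path is not None:
        edges = pd.read_json(edges_path, orient="index")
    else:
        edges = pd.DataFrame(
            {"min": df.min(), "max": df.max(), "width": np.nan}, index=df.columns
        )
    return DiscretizedMatrix(X=df.astype(np.int64), y=y, n_bins=n_bins, edges=edges)
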