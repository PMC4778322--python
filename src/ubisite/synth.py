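"""Synthetic inputs with controlled signal for every pipeline stage.

Three generators emulate the pipeline's real inputs without any download:

* :func:`generate_aaindex` — a well-formed AAindex1 property file, with a
  controllable fraction of entries carrying one ``NA`` (to exercise the
  incomplete-entry filter);
* :func:`generate_protein_set` — FASTA proteins drawn from a background
  residue distribution with a chosen lysine density, plus the K positions;
* :func:`generate_labeled_segments` — labelled K-centered segments in which
  the positive class carries a planted residue-composition signal: each
  positive flank residue is, with probability ``delta``, drawn uniformly
  from the top half (10 residues) of a randomly chosen informative
  property's value ranking instead of from the background.  ``delta = 0``
  gives a null dataset (positives and negatives identically distributed);
  larger ``delta`` shifts the informative properties' segment averages
  upward in positives, so detectability is monotone in ``delta``.

Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aaindex import AA_ORDER, PCPEntry, write_aaindex1
from .segments import ProteinRecord, SegmentRecord

#: Residue background: uniform over the 20 codes unless a table is given.
UNIFORM_BACKGROUND = pd.Series(1.0 / 20, index=list(AA_ORDER))


@dataclass
class SignalSpec:
    """Study conditions for one labelled-segment dataset."""

    n_segments: int = 500
    positive_fraction: float = 0.5
    window: int = 27
    n_informative: int = 3
    delta: float = 0.8  # probability mass shifted toward high-property residues
    seed: int = 0
    background: pd.Series = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie strictly in (0, 1)")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        if self.delta > 0 and self.n_informative < 1:
            raise ValueError("delta > 0 requires at least one informative property")


def generate_aaindex(
    n_entries: int, na_fraction: float = 0.0, seed: int = 0
) -> tuple[str, list[PCPEntry]]:
    """AAindex1-format text with ``round(na_fraction * n_entries)`` NA-bearing entries.

    Values are standard-normal draws rounded to three decimals (the writer's
    printed precision, so the text round-trips exactly through the parser).
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    if not 0.0 <= na_fraction <= 1.0:
        raise ValueError("na_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_na = round(na_fraction * n_entries)
    na_entries = set(rng.choice(n_entries, size=n_na, replace=False).tolist())
    entries = []
    for i in range(n_entries):
        vals = np.round(rng.normal(size=20), 3)
        values: dict[str, float | None] = {aa: float(v) for aa, v in zip(AA_ORDER, vals)}
        if i in na_entries:
            values[AA_ORDER[int(rng.integers(20))]] = None
        entries.append(
            PCPEntry(
                accession=f"SYN{i + 1:04d}",
                description=f"synthetic physicochemical index {i + 1} (seed {seed})",
                values=values,
            )
        )
    return write_aaindex1(entries), entries


def generate_protein_set(
    n_proteins: int,
    length_range: tuple[int, int] = (50, 200),
    k_density: float = 0.05,
    seed: int = 0,
    background: pd.Series | None = None,
) -> tuple[list[ProteinRecord], dict[str, list[int]]]:
    """Random proteins plus the 1-based positions of every K residue.

    Each position is K with probability ``k_density``, otherwise a draw from
    the (renormalized, K-free) background distribution.
    """
    if not 0.0 <= k_density <= 1.0:
        raise ValueError("k_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bg = (background if background is not None else UNIFORM_BACKGROUND).copy()
    bg = bg.drop("K", errors="ignore")
    bg = bg / bg.sum()
    others = np.array(list(bg.index))
    proteins: list[ProteinRecord] = []
    k_positions: dict[str, list[int]] = {}
    lo, hi = length_range
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        is_k = rng.random(length) < k_density
        seq = np.where(is_k, "K", rng.choice(others, size=length, p=bg.to_numpy()))
        pid = f"synprot{i + 1:03d}"
        proteins.append(ProteinRecord(id=pid, sequence="".join(seq)))
        k_positions[pid] = [int(p) + 1 for p in np.flatnonzero(is_k)]
    return proteins, k_positions


def informative_flank_distribution(
    aa_pcp: pd.DataFrame, informative: list[str], delta: float,
    background: pd.Series = UNIFORM_BACKGROUND,
) -> pd.Series:
    """Per-residue distribution of positive-class flanks under the tilt.

    Mixture: with probability ``delta`` pick one informative property
    uniformly and then a residue uniformly from its 10 top-valued residues;
    otherwise draw from the background.
    """
    dist = (1.0 - delta) * background.reindex(list(AA_ORDER)).fillna(0.0)
    for acc in informative:
        top10 = aa_pcp.loc[acc].nlargest(10).index
        dist[top10] += delta / (len(informative) * 10.0)
    return dist / dist.sum()


def generate_labeled_segments(
    spec: SignalSpec, aa_pcp: pd.DataFrame
) -> tuple[list[SegmentRecord], list[str]]:
    """Labelled K-centered segments with a planted class signal.

    Returns the segments (shuffled order) and the accessions of the
    informative properties (ground truth for feature-recovery checks).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_informative > len(aa_pcp):
        raise ValueError("more informative properties requested than available")
    informative = (
        [str(a) for a in rng.choice(aa_pcp.index, size=spec.n_informative, replace=False)]
        if spec.n_informative
        else []
    )
    background = spec.background.reindex(list(AA_ORDER)).fillna(0.0)
    background = background / background.sum()
    pos_dist = (
        informative_flank_distribution(aa_pcp, informative, spec.delta, background)
        if spec.delta > 0
        else background
    )
    n_pos = round(spec.positive_fraction * spec.n_segments)
    labels = np.zeros(spec.n_segments, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    half = (spec.window - 1) // 2
    aas = np.array(list(AA_ORDER))
    segments = []
    for i, lab in enumerate(labels):
        dist = pos_dist if lab == 1 else background
        flanks = rng.choice(aas, size=2 * half, p=dist.to_numpy())
        seg = "".join(flanks[:half]) + "K" + "".join(flanks[half:])
        segments.append(
            SegmentRecord(segment=seg, protein_id=f"syn{i + 1}", k_position=half + 1,
                          label=int(lab))
        )
    return segments, informative
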