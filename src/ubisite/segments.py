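"""FASTA reading and extraction of K-centered sequence segments.

A candidate ubiquitination site is a lysine (K) residue; the unit of
prediction is the fixed-length window of sequence centered on it.  Every K in
a protein yields one segment; windows that overrun the protein ends are padded
with ``-``.  A segment is labelled 1 when its central K position appears in
the protein's annotated (experimentally ubiquitinated) positions, 0 otherwise.
Coordinates are 1-based throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aaindex import AA_ORDER

STANDARD_AA = frozenset(AA_ORDER)
GAP = "-"

#: Default window length (residues), centered on the K.
DEFAULT_WINDOW = 27


@dataclass
class ProteinRecord:
    id: str
    sequence: str


@dataclass
class SegmentRecord:
    """A K-centered window with provenance and a 0/1 ubiquitination label."""

    segment: str
    protein_id: str
    k_position: int  # 1-based position of the central K in the source protein
    label: int

    def __post_init__(self):
        if len(self.segment) % 2 == 0:
            raise ValueError(f"segment length must be odd, got {len(self.segment)}")
        if self.segment[len(self.segment) // 2] != "K":
            raise ValueError(f"segment {self.segment!r} is not K-centered")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def row_id(self) -> str:
        return f"{self.protein_id}:{self.k_position}"


def read_fasta(source) -> list[ProteinRecord]:
    """Read a FASTA stream/path into protein records (sequences upper-cased).

    Raises ``ValueError`` for text before the first ``>`` header, an empty
    sequence, or duplicate ids.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    records: list[ProteinRecord] = []
    ids: set[str] = set()
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError("FASTA format error: sequence data before the first '>' header")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise ValueError(f"protein {rec.id!r} has an empty sequence")
        if rec.id in ids:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        ids.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], handle_or_path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    if hasattr(handle_or_path, "write"):
        SeqIO.write(seqrecs, handle_or_path, "fasta")
    else:
        with open(handle_or_path, "w") as fh:
            SeqIO.write(seqrecs, fh, "fasta")


def extract_k_segments(
    protein: ProteinRecord,
    window: int = DEFAULT_WINDOW,
    positive_positions: Iterable[int] = (),
) -> list[SegmentRecord]:
    """Extract one window per K residue of ``protein``.

    ``window`` must be odd and >= 3.  ``positive_positions`` are 1-based
    positions of annotated ubiquitination sites; each must point at a K in the
    sequence, else a validation error names the protein and position.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    positives = set(positive_positions)
    seq = protein.sequence
    for pos in positives:
        if not (1 <= pos <= len(seq)) or seq[pos - 1] != "K":
            raise ValueError(
                f"protein {protein.id!r}: annotated position {pos} does not point at a K"
            )
    half = (window - 1) // 2
    padded = GAP * half + seq + GAP * half
    segments = []
    for idx, aa in enumerate(seq, start=1):
        if aa != "K":
            continue
        # idx-1+half is the K's index in the padded sequence
        start = idx - 1
        segments.append(
            SegmentRecord(
                segment=padded[start : start + window],
                protein_id=protein.id,
                k_position=idx,
                label=int(idx in positives),
            )
        )
    return segments


def extract_dataset(
    proteins: Iterable[ProteinRecord],
    annotations: Mapping[str, Iterable[int]],
    window: int = DEFAULT_WINDOW,
) -> list[SegmentRecord]:
    """Extract segments for every protein; ``annotations`` maps id -> positive K positions."""
    out: list[SegmentRecord] = []
    for prot in proteins:
        out.extend(extract_k_segments(prot, window, annotations.get(prot.id, ())))
    return out


def segments_to_frame(segments: Iterable[SegmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.segment, s.protein_id, s.k_position, s.label) for s in segments],
        columns=["segment", "protein_id", "k_position", "label"],
    )


def write_segment_table(segments, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        segments_to_frame(segments).to_csv(fh, sep="\t", index=False)


def read_segment_table(path) -> list[SegmentRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    return [
        SegmentRecord(
            segment=row.segment,
            protein_id=str(row.protein_id),
            k_position=int(row.k_position),
            label=int(row.label),
        )
        for row in df.itertuples(index=False)
    ]
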