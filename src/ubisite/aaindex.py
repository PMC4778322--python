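"""AAindex1 flat-file parsing and the amino-acid x property (AA-PCP) matrix.

AAindex1 is the flat-file database of amino-acid property indices: each entry
carries one real value per amino acid (a physicochemical property, PCP) and is
terminated by a ``//`` line.  The ``I`` section lists the 20 values in two rows
of ten, in the fixed column order

    row 1:  A  R  N  D  C  Q  E  G  H  I
    row 2:  L  K  M  F  P  S  T  W  Y  V

with the literal token ``NA`` marking a missing value.  Only the ``H``
(accession), ``D`` (description) and ``I`` (values) fields are interpreted
here; the remaining fields (``R A T J C``) are bibliographic or correlation
metadata and are ignored.

Entries with any missing value cannot contribute a complete feature column and
are dropped when building the :func:`build_aa_pcp_matrix` table; with the full
AAindex release (544 entries, 13 incomplete) this leaves 531 usable properties.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical one-letter amino-acid order used throughout the package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_I_ROW1 = "ARNDCQEGHI"
_I_ROW2 = "LKMFPSTWYV"

#: Header of the I section as printed by AAindex1.
_I_HEADER = "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"


class AAindexParseError(ValueError):
    """Raised when an AAindex1 stream violates the flat-file grammar."""


@dataclass
class PCPEntry:
    """One AAindex1 entry: an accession, a description and 20 AA values.

    ``values`` maps each one-letter code in :data:`AA_ORDER` to a float or to
    ``None`` for a missing (``NA``) value.
    """

    accession: str
    description: str = ""
    values: dict[str, float | None] = field(default_factory=dict)

    @property
    def is_complete(self) -> bool:
        return all(self.values.get(a) is not None for a in AA_ORDER)

    def value_array(self) -> np.ndarray:
        """Values in :data:`AA_ORDER` order; missing values become NaN."""
        return np.array(
            [np.nan if self.values[a] is None else self.values[a] for a in AA_ORDER]
        )


def _parse_value_row(tokens: list[str], accession: str, lineno: int) -> list[float | None]:
    out: list[float | None] = []
    for tok in tokens:
        if tok == "NA":
            out.append(None)
            continue
        try:
            out.append(float(tok))
        except ValueError as exc:
            raise AAindexParseError(
                f"entry {accession!r}, line {lineno}: bad value token {tok!r}"
            ) from exc
    return out


def parse_aaindex1(source) -> list[PCPEntry]:
    """Parse AAindex1 text (str, ``pathlib.Path`` or text handle) into entries.

    Raises :class:`AAindexParseError` on a malformed entry (no ``H`` line,
    wrong number of ``I`` values, or a non-numeric non-``NA`` token), naming
    the offending accession and line.
    """
    if isinstance(source, Path):
        source = source.read_text()
    elif hasattr(source, "read"):
        source = source.read()
    lines = io.StringIO(source).read().splitlines()

    entries: list[PCPEntry] = []
    seen: set[str] = set()
    accession: str | None = None
    description_parts: list[str] = []
    values: list[float | None] | None = None
    in_field = ""
    i_rows_pending = 0

    for lineno, line in enumerate(lines, start=1):
        if line.strip() == "//":
            if accession is None:
                raise AAindexParseError(f"line {lineno}: entry terminator without an H line")
            if values is None or i_rows_pending:
                raise AAindexParseError(
                    f"entry {accession!r}, line {lineno}: missing or incomplete I section"
                )
            if accession in seen:
                raise AAindexParseError(f"duplicate accession {accession!r} at line {lineno}")
            seen.add(accession)
            order = _I_ROW1 + _I_ROW2
            entries.append(
                PCPEntry(
                    accession=accession,
                    description=" ".join(description_parts),
                    values={aa: v for aa, v in zip(order, values)},
                )
            )
            accession, description_parts, values, in_field = None, [], None, ""
            continue
        if not line.strip():
            continue
        if i_rows_pending:
            tokens = line.split()
            if len(tokens) != 10:
                raise AAindexParseError(
                    f"entry {accession!r}, line {lineno}: expected 10 I values, got {len(tokens)}"
                )
            assert values is not None
            values.extend(_parse_value_row(tokens, accession or "?", lineno))
            i_rows_pending -= 1
            continue
        key = line[0]
        body = line[2:].strip() if len(line) > 2 else ""
        if key == " ":
            if in_field == "D":
                description_parts.append(line.strip())
            continue  # continuation of an uninterpreted field
        in_field = key
        if key == "H":
            if accession is not None:
                raise AAindexParseError(
                    f"line {lineno}: H line inside entry {accession!r} (missing '//'?)"
                )
            accession = body
            if not accession:
                raise AAindexParseError(f"line {lineno}: empty accession on H line")
        elif key == "D":
            description_parts.append(body)
        elif key == "I":
            if accession is None:
                raise AAindexParseError(f"line {lineno}: I section before any H line")
            values = []
            i_rows_pending = 2
        # other fields (R, A, T, J, C, ...) are opaque metadata

    if accession is not None:
        raise AAindexParseError(f"entry {accession!r}: stream ended without '//' terminator")
    return entries


def write_aaindex1(entries: list[PCPEntry]) -> str:
    """Serialize entries back to AAindex1 text (H, D, I fields only).

    Values are printed with three decimals, so parse(write(x)) == x holds for
    entries whose values carry at most three decimal places (as produced by
    :mod:`ubisite.synth`).
    """
    out: list[str] = []
    for e in entries:
        out.append(f"H {e.accession}")
        if e.description:
            out.append(f"D {e.description}")
        out.append(_I_HEADER)
        for row_aas in (_I_ROW1, _I_ROW2):
            cells = []
            for aa in row_aas:
                v = e.values.get(aa)
                cells.append("      NA" if v is None else f"{v:8.3f}")
            out.append(" " + "".join(cells))
        out.append("//")
    return "\n".join(out) + ("\n" if out else "")


def build_aa_pcp_matrix(entries: list[PCPEntry], drop_incomplete: bool = True) -> pd.DataFrame:
    """Assemble the AA-PCP matrix: one row per retained property, 20 AA columns.

    Entries containing any missing value are excluded when ``drop_incomplete``
    is on (the default); source-file row order is preserved.  Raises
    ``ValueError`` if no entry survives (empty feature space) or if an
    incomplete entry would be retained with ``drop_incomplete`` off.
    """
    retained = [e for e in entries if e.is_complete or not drop_incomplete]
    if not retained:
        raise ValueError("no AAindex entries retained: empty feature space")
    if not drop_incomplete and any(not e.is_complete for e in retained):
        raise ValueError("incomplete entries present; the AA-PCP matrix cannot hold NA cells")
    mat = pd.DataFrame(
        [e.value_array() for e in retained],
        index=pd.Index([e.accession for e in retained], name="accession"),
        columns=list(AA_ORDER),
    )
    return mat


def read_aa_pcp_matrix(path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    mat.index.name = "accession"
    return mat


def write_aa_pcp_matrix(mat: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        mat.to_csv(fh, sep="\t")
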