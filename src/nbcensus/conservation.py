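"""Per-column conservation scoring of a protein multiple alignment.

Conservation of a column is the modal-residue fraction: the count of the
most frequent residue divided by the number of scored sequences.  Gaps
never count as the modal residue; by default they are also excluded from
the denominator (a config switch includes them as mismatches).  Columns
scoring above mean + 1 SD (over non-all-gap columns) are flagged as
highly conserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ColumnStats", "column_conservation", "is_conserved_across", "conservation_table"]

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class ColumnStats:
    column: int              # 0-based column index
    conservation: float      # modal-residue fraction in [0, 1]
    flagged: bool            # above mean + 1 SD
    modal_residue: str       # most frequent residue ('' for all-gap columns)
    n_scored: int            # sequences counted in the denominator


def _check_alignment(alignment: list[str]) -> int:
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return lengths.pop()


def _column_fraction(column: str, gaps_in_denominator: bool) -> tuple[float, str, int]:
    residues = [c.upper() for c in column if c.upper() not in GAP_CHARS and c != " "]
    n_gaps = len(column) - len(residues)
    if not residues:
        return 0.0, "", (len(column) if gaps_in_denominator else 0)
    modal, count = Counter(residues).most_common(1)[0]
    denom = len(residues) + (n_gaps if gaps_in_denominator else 0)
    return count / denom, modal, denom


def column_conservation(
    alignment: list[str], gaps_in_denominator: bool = False
) -> list[ColumnStats]:
    """Score every column; flag those above mean + 1 SD."""
    ncol = _check_alignment(alignment)
    raw = [
        _column_fraction("".join(s[i] for s in alignment), gaps_in_denominator)
        for i in range(ncol)
    ]
    scored = [f for f, modal, _ in raw if modal]
    mean = float(np.mean(scored)) if scored else 0.0
    sd = float(np.std(scored, ddof=0)) if scored else 0.0
    threshold = mean + sd
    return [
        ColumnStats(
            column=i,
            conservation=f,
            flagged=bool(modal) and f > threshold,
            modal_residue=modal,
            n_scored=n,
        )
        for i, (f, modal, n) in enumerate(raw)
    ]


def is_conserved_across(alignment: list[str], column: int, required: str = "all") -> bool:
    """True iff every scored sequence carries the modal residue.

    With ``required='all'`` (the only mode) gaps still break complete
    conservation: a column with any gap is not fully conserved.
    """
    _check_alignment(alignment)
    col = "".join(s[column] for s in alignment)
    residues = [c.upper() for c in col]
    if any(c in GAP_CHARS for c in residues):
        return False
    return len(set(residues)) == 1


def conservation_table(
    stats: list[ColumnStats], numbering_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """TSV-ready table: column (1-based), conservation, flag, optional label."""
    rows = []
    for s in stats:
        row = {
            "column": s.column + 1,
            "conservation": round(s.conservation, 4),
            "flagged": int(s.flagged),
            "modal_residue": s.modal_residue,
        }
        if numbering_map is not None:
            row["generic"] = numbering_map.get(str(s.column + 1), "")
        rows.append(row)
    return pd.DataFrame(rows)
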