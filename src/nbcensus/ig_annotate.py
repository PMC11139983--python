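"""Anchor-based framework/CDR annotation for VHH (nanobody) sequences.

A single-domain antibody sequence is tiled into FR1-CDR1-FR2-CDR2-FR3-
CDR3-FR4 using the conserved immunoglobulin anchors rather than a full
renumbering scheme ("IMGT-lite"):

* Cys1 — the first conserved cysteine, near position 22;
* the FR2 tryptophan motif W[YVF]RQ;
* the FR3 motif RF[TS]IS (fuzzy, one mismatch allowed);
* Cys2 — the last cysteine before FR4;
* the FR4 W-G-x-G motif.

CDR3 runs from the residue after Cys2 up to (not including) the FR4
tryptophan.  CDR1 is the window from four residues after Cys1 to the FR2
anchor; CDR2 the window from 14 residues after the FR2 tryptophan to one
before the FR3 anchor.  All spans are 0-based half-open over the input
sequence; reports use 1-based inclusive numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = ["CdrAnnotation", "AnnotationError", "annotate_cdrs", "cdr3_length", "annotation_table"]

_FR2_MOTIF = re.compile(r"W[YVF]RQ")
_FR4_MOTIF = re.compile(r"WG.G")
_FR3_ANCHOR = "RFTIS"

# fixed offsets of the anchor-based windows (see module docstring)
_CDR1_OFFSET = 4      # residues after Cys1 where CDR1 starts
_FR2_LEN = 14         # FR2 length from the W[YVF]RQ tryptophan


class AnnotationError(ValueError):
    """Annotation failure with a machine-readable reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class CdrAnnotation:
    """Framework/CDR spans over a VHH sequence (0-based half-open)."""

    sequence: str
    fr1: tuple[int, int]
    cdr1: tuple[int, int]
    fr2: tuple[int, int]
    cdr2: tuple[int, int]
    fr3: tuple[int, int]
    cdr3: tuple[int, int]
    fr4: tuple[int, int]
    cys1: int
    cys2: int
    fr4_trp: int

    def __post_init__(self):
        spans = [self.fr1, self.cdr1, self.fr2, self.cdr2, self.fr3, self.cdr3, self.fr4]
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if b != c:
                raise ValueError("spans must tile the annotated region contiguously")
            if a > b or c > d:
                raise ValueError("spans must be non-decreasing")
        if self.cdr3[0] != self.cys2 + 1:
            raise ValueError("CDR3 must begin immediately after the second cysteine")
        if self.fr4[0] != self.fr4_trp:
            raise ValueError("FR4 must begin at the anchor tryptophan")

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        return {
            "FR1": self.fr1, "CDR1": self.cdr1, "FR2": self.fr2, "CDR2": self.cdr2,
            "FR3": self.fr3, "CDR3": self.cdr3, "FR4": self.fr4,
        }

    @property
    def anchor_positions(self) -> dict[str, int]:
        return {"cys1": self.cys1, "cys2": self.cys2, "fr4_trp": self.fr4_trp}

    def region_of(self, index: int) -> str:
        """Region name ('FR1'..'FR4') containing a 0-based sequence index."""
        for name, (a, b) in self.spans.items():
            if a <= index < b:
                return name
        raise IndexError(f"index {index} outside annotated region")

    def cdr3_sequence(self) -> str:
        a, b = self.cdr3
        return self.sequence[a:b]


def _fuzzy_find(seq: str, motif: str, start: int, max_mismatch: int = 1) -> int:
    """Leftmost index >= start where motif matches with <= max_mismatch substitutions."""
    m = len(motif)
    for i in range(start, len(seq) - m + 1):
        if sum(a != b for a, b in zip(seq[i:i + m], motif)) <= max_mismatch:
            return i
    return -1


def annotate_cdrs(sequence: str) -> CdrAnnotation:
    """Locate FR/CDR spans in a VHH sequence from its conserved anchors.

    Raises :class:`AnnotationError` with a reason code when an anchor is
    missing, mirroring the census practice of excluding structures whose
    fold cannot be validated.
    """
    seq = sequence.strip().rstrip(".").upper()
    if not (90 <= len(seq) <= 160):
        raise AnnotationError("length_out_of_range", f"{len(seq)} residues")

    cys1 = seq.find("C")
    if cys1 < 0 or cys1 > 40:
        raise AnnotationError("missing_cys_anchor", "no first conserved cysteine")

    m2 = _FR2_MOTIF.search(seq, cys1 + 1)
    if not m2:
        raise AnnotationError("missing_fr2_anchor", "no W[YVF]RQ motif")
    fr2_w = m2.start()

    fr4_m = _FR4_MOTIF.search(seq, fr2_w + _FR2_LEN)
    if not fr4_m:
        raise AnnotationError("missing_fr4_anchor", "no W-G-x-G motif")
    fr4_trp = fr4_m.start()

    cys2 = seq.rfind("C", cys1 + 1, fr4_trp)
    if cys2 < 0:
        raise AnnotationError("missing_cys_anchor", "no second conserved cysteine")

    fr3_anchor = _fuzzy_find(seq, _FR3_ANCHOR, fr2_w + _FR2_LEN)
    if fr3_anchor < 0 or fr3_anchor >= cys2:
        raise AnnotationError("missing_fr3_anchor", "no RF[TS]IS-like motif")

    cdr1 = (cys1 + _CDR1_OFFSET, fr2_w)
    cdr2 = (fr2_w + _FR2_LEN, fr3_anchor - 1)
    cdr3 = (cys2 + 1, fr4_trp)
    if cdr1[0] >= cdr1[1] or cdr2[0] >= cdr2[1]:
        raise AnnotationError("degenerate_cdr_window", "anchors too close together")

    return CdrAnnotation(
        sequence=seq,
        fr1=(0, cdr1[0]),
        cdr1=cdr1,
        fr2=(fr2_w, cdr2[0]),
        cdr2=cdr2,
        fr3=(cdr2[1], cdr3[0]),
        cdr3=cdr3,
        fr4=(fr4_trp, len(seq)),
        cys1=cys1,
        cys2=cys2,
        fr4_trp=fr4_trp,
    )


def cdr3_length(annotation: CdrAnnotation) -> int:
    """Number of residues in the CDR3 span."""
    a, b = annotation.cdr3
    return b - a


def annotation_table(annotations: dict[str, CdrAnnotation]) -> pd.DataFrame:
    """Human-readable report: one row per input, 1-based inclusive spans."""
    rows = []
    for label, ann in annotations.items():
        row: dict[str, object] = {"label": label}
        for name, (a, b) in ann.spans.items():
            row[name] = f"{a + 1}-{b}" if b > a else "-"
        row["cdr3_seq"] = ann.cdr3_sequence()
        row["cys1"] = ann.cys1 + 1
        row["cys2"] = ann.cys2 + 1
        row["fr4_trp"] = ann.fr4_trp + 1
        rows.append(row)
    return pd.DataFrame(rows)
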