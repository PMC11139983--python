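"""Backbone secondary structure from hydrogen-bond geometry.

Implements the Kabsch-Sander electrostatic model used by DSSP: an amide
hydrogen is placed on each backbone nitrogen from the preceding peptide
plane, the donor-acceptor energy

    E = 27.888 * (1/r(O,N) + 1/r(C,H) - 1/r(O,H) - 1/r(C,N))  kcal/mol

is evaluated for every residue pair, and a bond is recorded when
E < -0.5 kcal/mol.  Assignment uses a reduced four-letter alphabet:

    H  alpha-helix (runs of consecutive i -> i+4 turns)
    E  extended strand (bridges grown into ladders of length >= 2)
    T  isolated 3/4/5-turn
    C  everything else

Priority H > E > T > C.  Residues with incomplete backbones are excluded
from bonding and labeled C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structio import Chain

__all__ = [
    "BackboneResidue",
    "HBond",
    "Hairpin",
    "Q_COUPLING",
    "HBOND_CUTOFF",
    "backbone_from_chain",
    "place_amide_hydrogens",
    "hbond_energy",
    "compute_hbonds",
    "assign_ss",
    "detect_hairpin",
]

Q_COUPLING = 27.888       # kcal*A/mol, Kabsch-Sander q1*q2*f
HBOND_CUTOFF = -0.5       # kcal/mol; bonds must be more negative
CLAMP_ENERGY = -9.9       # sentinel for clashing geometry
_BREAK_DIST = 2.5         # A, max C(i-1)-N(i) for a continuous peptide
_NH_LENGTH = 1.00         # A, placed amide H


@dataclass
class BackboneResidue:
    """Backbone heavy atoms of one residue, plus the placed amide H."""

    name: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None = None
    chain_break: bool = False    # no continuous peptide to the previous residue


@dataclass(frozen=True)
class HBond:
    """Backbone H-bond: N-H of ``donor`` to C=O of ``acceptor``."""

    donor: int
    acceptor: int
    energy: float
    clamped: bool = False

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")
        if abs(self.donor - self.acceptor) < 2:
            raise ValueError("sequence-adjacent pairs are not hydrogen bonds")
        if self.energy >= HBOND_CUTOFF:
            raise ValueError(f"stored bonds require E < {HBOND_CUTOFF} kcal/mol")


@dataclass
class Hairpin:
    """Antiparallel two-strand ladder descriptor (0-based half-open spans)."""

    strand1: tuple[int, int] | None = None
    strand2: tuple[int, int] | None = None
    n_cross_hbonds: int = 0
    n_bridges: int = 0

    @property
    def is_empty(self) -> bool:
        return self.strand1 is None


def backbone_from_chain(chain: Chain) -> list[BackboneResidue | None]:
    """Extract N/CA/C/O per residue; ``None`` marks incomplete backbones."""
    out: list[BackboneResidue | None] = []
    for res in chain:
        try:
            out.append(
                BackboneResidue(
                    name=res.name,
                    n=res.atom("N").coords,
                    ca=res.atom("CA").coords,
                    c=res.atom("C").coords,
                    o=res.atom("O").coords,
                )
            )
        except KeyError:
            warnings.warn(
                f"residue {res.name} {res.id} missing backbone atoms; labeled C",
                stacklevel=2,
            )
            out.append(None)
    return out


def place_amide_hydrogens(backbone: list[BackboneResidue | None]) -> list[BackboneResidue | None]:
    """Place amide hydrogens in-place and return the backbone.

    H(i) lies 1.00 A from N(i) along the bisector of the N-C(i-1) and
    N-O(i-1) directions.  No hydrogen on the first residue, on proline,
    or across a chain break (C(i-1)-N(i) >= 2.5 A).
    """
    for i, res in enumerate(backbone):
        if res is None:
            continue
        res.h = None
        prev = backbone[i - 1] if i > 0 else None
        if prev is None:
            res.chain_break = i > 0
            continue
        if np.linalg.norm(res.n - prev.c) >= _BREAK_DIST:
            res.chain_break = True
            continue
        res.chain_break = False
        if res.name.upper() == "PRO":
            continue
        v1 = res.n - prev.c
        v2 = res.n - prev.o
        u = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        res.h = res.n + _NH_LENGTH * u / np.linalg.norm(u)
    return backbone


def hbond_energy(donor: BackboneResidue, acceptor: BackboneResidue) -> tuple[float, bool]:
    """Kabsch-Sander donor->acceptor energy in kcal/mol.

    Returns ``(energy, clamped)``; geometry with any inter-atom distance
    below 0.5 A is clashing input and yields the sentinel energy.
    """
    if donor.h is None:
        raise ValueError("donor has no placed amide hydrogen")
    r_on = np.linalg.norm(acceptor.o - donor.n)
    r_ch = np.linalg.norm(acceptor.c - donor.h)
    r_oh = np.linalg.norm(acceptor.o - donor.h)
    r_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return CLAMP_ENERGY, True
    e = Q_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(e), False


def compute_hbonds(backbone: list[BackboneResidue | None]) -> list[HBond]:
    """All backbone H-bonds with E < -0.5 kcal/mol.

    Per DSSP convention at most the two lowest-energy acceptors are kept
    for each donor.
    """
    n = len(backbone)
    per_donor: dict[int, list[HBond]] = {}
    for i in range(n):
        don = backbone[i]
        if don is None or don.h is None:
            continue
        cands = []
        for j in range(n):
            if abs(i - j) < 2:
                continue
            acc = backbone[j]
            if acc is None:
                continue
            e, clamped = hbond_energy(don, acc)
            if e < HBOND_CUTOFF:
                cands.append(HBond(donor=i, acceptor=j, energy=e, clamped=clamped))
        cands.sort(key=lambda b: b.energy)
        per_donor[i] = cands[:2]
    return [b for bonds in per_donor.values() for b in bonds]


def _bond_set(hbonds: list[HBond]) -> set[tuple[int, int]]:
    """(acceptor, donor) pairs: hb(i, j) means C=O(i) accepts from N-H(j)."""
    return {(b.acceptor, b.donor) for b in hbonds}


def _bridges(hbonds: list[HBond], n: int) -> dict[tuple[int, int], str]:
    """Kabsch-Sander bridge patterns; returns {(i, j): 'P'|'A'} with i < j."""
    hb = _bond_set(hbonds)
    out: dict[tuple[int, int], str] = {}
    for i in range(1, n - 1):
        for j in range(i + 2, n - 1):
            para = ((i - 1, j) in hb and (j, i + 1) in hb) or \
                   ((j - 1, i) in hb and (i, j + 1) in hb)
            anti = ((i, j) in hb and (j, i) in hb) or \
                   ((i - 1, j + 1) in hb and (j - 1, i + 1) in hb)
            if anti:
                out[(i, j)] = "A"
            elif para:
                out[(i, j)] = "P"
    return out


def _ladders(bridges: dict[tuple[int, int], str]) -> list[list[tuple[int, int]]]:
    """Group bridges into ladders of consecutive bridges of one type."""
    remaining = dict(bridges)
    ladders = []
    for (i, j), typ in sorted(bridges.items()):
        if (i, j) not in remaining:
            continue
        ladder = [(i, j)]
        del remaining[(i, j)]
        step = (1, -1) if typ == "A" else (1, 1)
        ci, cj = i, j
        while True:
            nxt = (ci + step[0], cj + step[1])
            if remaining.get(nxt) == typ:
                ladder.append(nxt)
                del remaining[nxt]
                ci, cj = nxt
            else:
                break
        ladders.append(ladder)
    return ladders


def assign_ss(backbone: list[BackboneResidue | None], hbonds: list[HBond]) -> str:
    """Reduced-alphabet secondary structure string (one char per residue)."""
    n = len(backbone)
    hb = _bond_set(hbonds)
    labels = ["C"] * n

    # n-turns: C=O(i) accepts from N-H(i+k)
    turn4_start = [((i, i + 4) in hb) for i in range(n)]
    is_helix = [False] * n
    for i in range(n - 5):
        if turn4_start[i] and turn4_start[i + 1]:
            for k in range(i + 1, i + 5):
                is_helix[k] = True

    is_turn = [False] * n
    for k in (3, 4, 5):
        for i in range(n - k):
            if (i, i + k) in hb:
                for t in range(i + 1, i + k):
                    is_turn[t] = True

    bridges = _bridges(hbonds, n)
    is_strand = [False] * n
    for ladder in _ladders(bridges):
        if len(ladder) >= 2:
            for i, j in ladder:
                is_strand[i] = True
                is_strand[j] = True

    for i in range(n):
        if backbone[i] is None:
            labels[i] = "C"
        elif is_helix[i]:
            labels[i] = "H"
        elif is_strand[i]:
            labels[i] = "E"
        elif is_turn[i]:
            labels[i] = "T"
    return "".join(labels)


def detect_hairpin(
    ss: str,
    hbonds: list[HBond],
    cdr3_span: tuple[int, int],
) -> Hairpin:
    """Longest antiparallel ladder whose strands both touch the CDR3 window.

    The window runs from six residues before the CDR3 start through the
    last CDR3 residue, allowing hairpin stems that begin in FR3 while
    excluding the FR4 anchor strand.  ``n_cross_hbonds`` counts mutual
    (reciprocal) bonds between the two strands.
    """
    a, b = cdr3_span
    window = range(max(0, a - 6), b)
    n = len(ss)
    bridges = _bridges(hbonds, n)
    best: Hairpin = Hairpin()
    hb = _bond_set(hbonds)
    for ladder in _ladders(bridges):
        if len(ladder) < 2:
            continue
        typ = bridges[ladder[0]]
        if typ != "A":
            continue
        s1 = sorted(i for i, _ in ladder)
        s2 = sorted(j for _, j in ladder)
        span1 = (s1[0], s1[-1] + 1)
        span2 = (s2[0], s2[-1] + 1)
        if not (set(range(*span1)) & set(window) and set(range(*span2)) & set(window)):
            continue
        mutual = sum(
            1
            for i in range(*span1)
            for j in range(*span2)
            if (i, j) in hb and (j, i) in hb
        )
        if len(ladder) > best.n_bridges:
            best = Hairpin(
                strand1=span1, strand2=span2, n_cross_hbonds=mutual, n_bridges=len(ladder)
            )
    return best
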