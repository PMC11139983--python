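"""Synthetic inputs with ground truth known by construction.

Four generators cover every input the pipeline consumes:

* :func:`gen_scaffold` / :func:`gen_census` — idealized nanobody-like
  domains.  A two-layer framework of antiparallel beta-strand pairs is
  assembled from an ideal-geometry strand template (NeRF chain extension
  with fixed internal coordinates) and a frozen rigid pair transform
  whose designed cross-strand Kabsch-Sander bonds score -2.5 kcal/mol.
  The CDR3 loop is built in one of three conformations: a protruding
  two-strand hairpin (extended), a loop packed against the FR2/CDR2 face
  (folded), or a minimal tight turn (short).
* :func:`gen_toy_complex` — a two-chain complex with an exact planted
  number of interatomic contacts.
* :func:`gen_bret` — Gaddum-model competitive-antagonism titration
  families with additive Gaussian noise.
* :func:`gen_alignment` — alignments with a prescribed per-column
  conservation profile.

Every generator is a pure function of its spec and seed.

Coordinate jitter emulates the low-frequency structural variation seen
between independently solved structures of one fold: rigid Gaussian
displacements of whole structural units (strand pairs, loops) at the
nominal sd, plus a small independent per-atom component (sd/5).  Fully
independent per-atom noise of the same amplitude would shred backbone
hydrogen bonds — something no ensemble of correctly folded structures
exhibits — so it is deliberately not what ``jitter_sd`` means here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import VUN701
from .ig_annotate import CdrAnnotation, annotate_cdrs
from .structio import Atom, Chain, Residue, Structure

__all__ = [
    "ScaffoldSpec",
    "Scaffold",
    "BretSpec",
    "gen_scaffold",
    "gen_census",
    "gen_toy_complex",
    "gen_bret",
    "gen_alignment",
]

# ---------------------------------------------------------------------------
# ideal strand template (NeRF chain extension, fixed internal coordinates)

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -137.97427385027777, 133.35391126049862, 180.0
_TEMPLATE_LEN = 8

# rigid transform mapping the template strand onto its antiparallel
# H-bond partner (designed mutual rungs at template residues 1/3/5/7)
_PAIR_ROT = np.array(
    [
        [-0.40606278658536, -0.910249596181001, 0.080985714807346],
        [-0.910135191490431, 0.394845709636075, -0.125502186405901],
        [0.082261452462313, -0.124669716588708, -0.988782339650381],
    ]
)
_PAIR_TRANS = np.array([25.026891515935773, 16.870355999808062, 6.007379567293232])

_BB_KEYS = ("N", "CA", "C", "O")


def _nerf(a, b, c, r, theta_deg, chi_deg):
    theta, chi = np.deg2rad(theta_deg), np.deg2rad(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(chi), r * np.sin(theta) * np.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_template(n: int = _TEMPLATE_LEN) -> dict[str, np.ndarray]:
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    CA[0] = [_B_N_CA, 0.0, 0.0]
    ang = np.deg2rad(180 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        if i > 0:
            N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, _PSI)
            CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
            C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, _PHI)
        O[i] = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, _PSI + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _canonical_pair() -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Template strand and its partner in a canonical frame.

    x runs along the strand axis (template N->C), y toward the partner,
    z normal to the pair; the pair centroid sits at the origin.
    """
    t = _build_template()
    p = {k: v @ _PAIR_ROT.T + _PAIR_TRANS for k, v in t.items()}
    e1 = t["CA"][-1] - t["CA"][0]
    e1 /= np.linalg.norm(e1)
    d = p["CA"].mean(axis=0) - t["CA"].mean(axis=0)
    e2 = d - (d @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    basis = np.stack([e1, e2, e3], axis=1)
    origin = np.vstack([t["CA"], p["CA"]]).mean(axis=0)
    tc = {k: (v - origin) @ basis for k, v in t.items()}
    pc = {k: (v - origin) @ basis for k, v in p.items()}
    return tc, pc


_CT, _CP = _canonical_pair()

# framework unit placements (translations in the global frame).  Units are
# spaced so no Kabsch-Sander bond forms between different units.
_UNIT_OFFSETS = {
    "P1": np.array([0.0, 0.0, 0.0]),       # FR1 pair, sheet layer A
    "P2": np.array([0.0, 11.0, 0.0]),      # FR3 pair, sheet layer A
    "P3": np.array([0.0, 5.5, 10.0]),      # FR3/FR4 pair, sheet layer B
    "S3": np.array([0.0, 16.5, 10.0]),     # FR2 strand (unpaired), layer B
}
_DOMAIN_CENTER = np.array([0.0, 8.25, 5.0])

# fixed framework pieces of the scaffold sequence (VUN701 numbering)
_FR1 = VUN701[0:25]
_CDR1 = VUN701[25:35]
_FR2 = VUN701[35:49]
_CDR2 = VUN701[49:65]
_FR3 = VUN701[65:95]
_FR4 = VUN701[109:120]
_CDR3_ALPHABET = "ARNDEQHIKLMSTFV"   # no C/W (anchors), no G/P (backbone rules)

_MODE_LENGTHS = {"short": (5, 6, 7), "extended": (14, 16, 18), "folded": (13, 14, 13)}
_STEM_LEN = 6          # hairpin strand residues per side (extended mode)


@dataclass(frozen=True)
class ScaffoldSpec:
    """Specification of one synthetic nanobody-like scaffold."""

    cdr3_mode: str                  # 'short' | 'extended' | 'folded'
    cdr3_length: int | None = None  # default: mode-typical length
    seed: int = 0
    jitter_sd: float = 0.3          # A

    def __post_init__(self):
        if self.cdr3_mode not in ("short", "extended", "folded"):
            raise ValueError(f"unknown cdr3_mode {self.cdr3_mode!r}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        length = self.cdr3_length
        if length is not None:
            if self.cdr3_mode == "short" and length > 7:
                raise ValueError("short mode forces cdr3_length <= 7")
            if self.cdr3_mode == "extended" and length < 10:
                raise ValueError("extended mode needs cdr3_length >= 10")
            if self.cdr3_mode == "folded" and length < 8:
                raise ValueError("folded mode needs cdr3_length >= 8")
            if length < 1:
                raise ValueError("cdr3_length must be positive")

    @property
    def length(self) -> int:
        if self.cdr3_length is not None:
            return self.cdr3_length
        return _MODE_LENGTHS[self.cdr3_mode][1]


@dataclass
class Scaffold:
    """A generated scaffold plus its ground truth."""

    structure: Structure
    annotation: CdrAnnotation
    true_class: str                      # 'short' | 'extended' | 'folded_back'
    designed_strand_residues: list[int]  # 0-based indices expected to label E
    designed_coil_residues: list[int]    # 0-based indices expected not to label E
    designed_rungs: int                  # mutual cross-strand bonds in the CDR3 hairpin
    spec: ScaffoldSpec = None


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, t: float) -> np.ndarray:
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _catmull_rom(points: np.ndarray, n_out: int) -> np.ndarray:
    """n_out interior samples of a Catmull-Rom spline through points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two waypoints")
    # pad endpoints
    ext = np.vstack([2 * pts[0] - pts[1], pts, 2 * pts[-1] - pts[-2]])
    ts = np.linspace(0.0, 1.0, n_out + 2)[1:-1]
    out = []
    nseg = len(pts) - 1
    for t in ts:
        s = min(int(t * nseg), nseg - 1)
        u = t * nseg - s
        p0, p1, p2, p3 = ext[s], ext[s + 1], ext[s + 2], ext[s + 3]
        out.append(
            0.5
            * (
                (2 * p1)
                + (-p0 + p2) * u
                + (2 * p0 - 5 * p1 + 4 * p2 - p3) * u ** 2
                + (-p0 + 3 * p1 - 3 * p2 + p3) * u ** 3
            )
        )
    return np.array(out)


def _loop_backbone(ca_path: np.ndarray) -> dict[str, np.ndarray]:
    """Approximate backbone atoms along a CA path (coil geometry)."""
    n = len(ca_path)
    N = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    for i, ca in enumerate(ca_path):
        prev_ca = ca_path[i - 1] if i > 0 else ca - np.array([1.0, 0.0, 0.0]) * 3.8
        next_ca = ca_path[i + 1] if i < n - 1 else ca + (ca - prev_ca)
        tau = next_ca - prev_ca
        tau /= max(np.linalg.norm(tau), 1e-9)
        away = ca - _DOMAIN_CENTER
        nu = away - (away @ tau) * tau
        nn = np.linalg.norm(nu)
        nu = nu / nn if nn > 1e-9 else np.array([0.0, 0.0, 1.0])
        N[i] = ca - 1.25 * tau + 0.45 * nu
        C[i] = ca + 1.25 * tau + 0.45 * nu
        O[i] = C[i] + 1.231 * nu
    return {"N": N, "CA": np.asarray(ca_path, float), "C": C, "O": O}


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # standard virtual-CB construction from backbone geometry
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _shift(unit: dict[str, np.ndarray], offset: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v + offset for k, v in unit.items()}


def _subset(unit: dict[str, np.ndarray], sl: slice) -> dict[str, np.ndarray]:
    return {k: v[sl] for k, v in unit.items()}


def _scaffold_sequence(mode: str, length: int, rng: np.random.Generator) -> tuple[str, str]:
    cdr3 = "".join(rng.choice(list(_CDR3_ALPHABET), size=length))
    seq = _FR1 + _CDR1 + _FR2 + _CDR2 + _FR3 + cdr3 + _FR4
    return seq, cdr3


def gen_scaffold(spec: ScaffoldSpec) -> Scaffold:
    """Build one scaffold with CDR3 in the requested conformation.

    The returned annotation is the construction ground truth; it equals
    what :func:`nbcensus.ig_annotate.annotate_cdrs` recovers from the
    sequence (a tested invariant).
    """
    length = spec.length
    if spec.cdr3_mode == "folded" and length < 5:
        raise ValueError("folded mode infeasible below 5 residues")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _mode_id(spec.cdr3_mode), length]))
    seq, _ = _scaffold_sequence(spec.cdr3_mode, length, rng)
    annotation = annotate_cdrs(seq)
    a, b = annotation.cdr3
    w = annotation.fr4_trp

    # --- strand slots: global residue span -> (unit, template-or-partner, slice)
    slots = {
        "A1a": ((2, 10), "P1", _CT, slice(0, 8)),
        "A1b": ((15, 23), "P1", _CP, slice(0, 8)),
        "S3": ((41, 49), "S3", _CT, slice(0, 8)),
        "A2a": ((66, 74), "P2", _CT, slice(0, 8)),
        "A2b": ((77, 85), "P2", _CP, slice(0, 8)),
        "A3a": ((87, 95), "P3", _CT, slice(0, 8)),
        "A3b": ((w + 2, w + 10), "P3", _CP, slice(0, 8)),
    }
    paired_slots = ["A1a", "A1b", "A2a", "A2b", "A3a", "A3b"]

    n_res = len(seq)
    coords = {k: np.full((n_res, 3), np.nan) for k in _BB_KEYS}
    unit_of = np.full(n_res, -1, dtype=int)     # rigid-jitter unit id per residue
    unit_ids = {name: i for i, name in enumerate(["P1", "P2", "P3", "S3", "HP"])}
    next_unit = len(unit_ids)

    for name, ((s0, s1), unit, src, sl) in slots.items():
        placed = _shift(_subset(src, sl), _UNIT_OFFSETS[unit])
        for k in _BB_KEYS:
            coords[k][s0:s1] = placed[k]
        unit_of[s0:s1] = unit_ids[unit]

    # --- CDR3 by mode
    hairpin_spans: list[tuple[int, int]] = []
    designed_rungs = 0
    anchor_in = coords["CA"][94]          # Cys2 (last residue of slot A3a)
    anchor_out = coords["CA"][w + 2]      # first residue of the FR4 strand
    if spec.cdr3_mode == "extended":
        # fixed stem length so all extended scaffolds share one hairpin
        # geometry; the turn absorbs the length variation
        m = min(_STEM_LEN, (length - 2) // 2)
        hp_off = (
            _UNIT_OFFSETS["P3"]
            + (_CT["CA"][-1] - _CT["CA"][0])
            + np.array([3.4, 0.0, 0.0])
        )
        s1_placed = _shift(_subset(_CT, slice(0, m)), hp_off)
        s2_placed = _shift(_subset(_CP, slice(_TEMPLATE_LEN - m, _TEMPLATE_LEN)), hp_off)
        n_turn = length - 2 * m
        for k in _BB_KEYS:
            coords[k][a:a + m] = s1_placed[k]
            coords[k][a + m + n_turn:b] = s2_placed[k]
        unit_of[a:b] = unit_ids["HP"]
        if n_turn:
            tip_dir = np.array([1.0, 0.0, 0.0])
            p0 = s1_placed["CA"][-1]
            p2 = s2_placed["CA"][0]
            ctrl = 0.5 * (p0 + p2) + (2.5 + 0.8 * n_turn) * tip_dir
            path = np.array(
                [_bezier(p0, ctrl, p2, (i + 1) / (n_turn + 1)) for i in range(n_turn)]
            )
            turn_bb = _loop_backbone(path)
            for k in _BB_KEYS:
                coords[k][a + m:a + m + n_turn] = turn_bb[k]
        hairpin_spans = [(a, a + m), (a + m + n_turn, b)]
        # mutual rungs at odd template index i with partner index 8-i in range
        designed_rungs = sum(
            1
            for i in range(1, m, 2)
            if _TEMPLATE_LEN - i >= _TEMPLATE_LEN - m
        )
    elif spec.cdr3_mode == "folded":
        # explicit CA path: fixed 3-residue entry and exit segments plus a
        # centered run packed on the FR2-strand face; only the run length
        # varies with CDR3 length, so the path shape is length-invariant
        s3_mid = 0.5 * (coords["CA"][44] + coords["CA"][45])
        face_y, face_z = s3_mid[1], s3_mid[2] + 4.7
        n_hug = length - 6
        # head-anchored: the run always starts at the +x end of the face,
        # so corresponding positions superpose across CDR3 lengths
        hug = np.array(
            [
                [s3_mid[0] + (3.5 - k) * 3.36, face_y, face_z]
                for k in range(n_hug)
            ]
        )
        entry = np.array(
            [
                anchor_in + np.array([1.5, 2.5, 2.0]),
                [11.5, 11.5, 13.0],
                [hug[0][0] + 2.8, face_y - 2.0, face_z - 0.8],
            ]
        )
        exit_ = np.array(
            [
                [hug[-1][0] - 2.8, face_y - 2.0, face_z - 0.8],
                [9.0, 10.0, 12.0],
                anchor_out + np.array([-1.5, 2.5, 2.0]),
            ]
        )
        path = np.vstack([entry, hug, exit_])
        bb = _loop_backbone(path)
        for k in _BB_KEYS:
            coords[k][a:b] = bb[k]
        unit_of[a:b] = unit_ids["HP"]
    else:  # short
        p0 = anchor_in + np.array([2.0, -1.5, 0.0])
        p2 = anchor_out + np.array([-2.0, -1.5, 0.0])
        ctrl = 0.5 * (p0 + p2) + np.array([2.0, -7.0, 0.5])
        path = np.array([_bezier(p0, ctrl, p2, (i + 1) / (length + 1)) for i in range(length)])
        bb = _loop_backbone(path)
        for k in _BB_KEYS:
            coords[k][a:b] = bb[k]
        unit_of[a:b] = unit_ids["HP"]

    # --- loops: every residue still unplaced
    loop_runs = []
    i = 0
    while i < n_res:
        if np.isnan(coords["CA"][i, 0]):
            j = i
            while j < n_res and np.isnan(coords["CA"][j, 0]):
                j += 1
            loop_runs.append((i, j))
            i = j
        else:
            i += 1
    for s0, s1 in loop_runs:
        prev_ca = coords["CA"][s0 - 1] if s0 > 0 else None
        next_ca = coords["CA"][s1] if s1 < n_res else None
        if prev_ca is None:
            prev_ca = next_ca + np.array([-3.8 * (s1 - s0 + 1), 0.0, 0.0])
        if next_ca is None:
            next_ca = prev_ca + np.array([3.8 * (s1 - s0 + 1), 0.0, 0.0])
        mid = 0.5 * (prev_ca + next_ca)
        away = mid - _DOMAIN_CENTER
        nrm = np.linalg.norm(away)
        away = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        ctrl = mid + away * (3.0 + 0.35 * (s1 - s0))
        path = np.array(
            [_bezier(prev_ca, ctrl, next_ca, (k + 1) / (s1 - s0 + 1)) for k in range(s1 - s0)]
        )
        bb = _loop_backbone(path)
        for k in _BB_KEYS:
            coords[k][s0:s1] = bb[k]
        unit_of[s0:s1] = next_unit
        next_unit += 1

    # --- jitter: rigid per-unit displacement + small per-atom component
    if spec.jitter_sd > 0:
        unit_shift = rng.normal(0.0, spec.jitter_sd, size=(next_unit, 3))
        for k in _BB_KEYS:
            coords[k] += unit_shift[unit_of]
            coords[k] += rng.normal(0.0, spec.jitter_sd / 5.0, size=coords[k].shape)

    # --- assemble Structure (N, CA, C, O, CB except glycine)
    three = _one_to_three
    residues = []
    for i, letter in enumerate(seq):
        atoms = [
            Atom("N", "N", coords["N"][i]),
            Atom("CA", "C", coords["CA"][i]),
            Atom("C", "C", coords["C"][i]),
            Atom("O", "O", coords["O"][i]),
        ]
        if letter != "G":
            cb = _virtual_cb(coords["N"][i], coords["CA"][i], coords["C"][i])
            atoms.append(Atom("CB", "C", cb))
        residues.append(Residue(name=three[letter], number=i + 1, atoms=atoms))
    structure = Structure(
        label=f"syn_{spec.cdr3_mode}_{length}_{spec.seed}",
        chains=[Chain(id="A", residues=residues)],
    )

    designed_strand = [
        s + k for name in paired_slots for s, _ in [slots[name][0]] for k in range(1, 8)
    ]
    designed_strand += [
        idx
        for s0, s1 in hairpin_spans
        for idx in range(s0 + 1, s1)
    ]
    strand_like = set()
    for name in (*paired_slots, "S3"):
        s0, s1 = slots[name][0]
        strand_like.update(range(s0, s1))
    for s0, s1 in hairpin_spans:
        strand_like.update(range(s0, s1))
    designed_coil = [
        i for s0, s1 in loop_runs for i in range(s0, s1) if i not in strand_like
    ]
    true_class = {"short": "short", "extended": "extended", "folded": "folded_back"}[
        spec.cdr3_mode
    ]
    return Scaffold(
        structure=structure,
        annotation=annotation,
        true_class=true_class,
        designed_strand_residues=designed_strand,
        designed_coil_residues=designed_coil,
        designed_rungs=designed_rungs,
        spec=spec,
    )


def _mode_id(mode: str) -> int:
    return {"short": 0, "extended": 1, "folded": 2}[mode]


_one_to_three = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def gen_census(
    n_per_class: int | None = 10,
    seed: int = 0,
    jitter_sd: float = 0.3,
    proportions: dict[str, int] | None = None,
) -> tuple[list[Scaffold], pd.DataFrame]:
    """A labeled synthetic census population.

    With ``n_per_class`` a balanced population is produced; with
    ``proportions`` (class -> count, e.g. the published 66/25/9 split)
    the requested counts are honored exactly.  Lengths cycle through
    mode-typical values; seeds derive from ``seed``.
    """
    counts = (
        dict(proportions)
        if proportions is not None
        else {"folded": n_per_class, "extended": n_per_class, "short": n_per_class}
    )
    scaffolds = []
    rows = []
    idx = 0
    for mode in ("folded", "extended", "short"):
        for k in range(counts.get(mode, 0)):
            lengths = _MODE_LENGTHS[mode]
            spec = ScaffoldSpec(
                cdr3_mode=mode,
                cdr3_length=lengths[k % len(lengths)],
                seed=seed * 100003 + idx,
                jitter_sd=jitter_sd,
            )
            sc = gen_scaffold(spec)
            label = f"SYN_{mode.upper()}_{k:03d}"
            sc.structure.label = label
            scaffolds.append(sc)
            rows.append(
                {
                    "label": label,
                    "true_class": sc.true_class,
                    "cdr3_length": spec.length,
                    "seed": spec.seed,
                    "jitter_sd": jitter_sd,
                }
            )
            idx += 1
    return scaffolds, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy complexes with planted contacts

_TOY_RADII = {"C": 1.70, "N": 1.55, "O": 1.52}


def gen_toy_complex(
    n_planted_contacts: int, seed: int = 0, slack: float = 0.5
) -> tuple[Structure, pd.DataFrame]:
    """Two-chain complex with exactly ``n_planted_contacts`` atom-pair contacts.

    Planted pairs sit 0.25 A inside the vdW + slack cutoff; every other
    cross-chain pair sits at least 1.0 A outside it.  Returns the
    structure and the planted-contact ledger.
    """
    if n_planted_contacts < 0:
        raise ValueError("n_planted_contacts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_planted_contacts]))
    n_a = max(n_planted_contacts, 4)
    spacing = 9.0
    elements = list(_TOY_RADII)

    res_a, res_b, ledger = [], [], []
    for i in range(n_a):
        el = elements[int(rng.integers(len(elements)))]
        pos = np.array([i * spacing, 0.0, 0.0])
        res_a.append(
            Residue(name="UNK", number=i + 1, atoms=[Atom(el, el, pos)], is_het=False)
        )
    for i in range(n_a):
        el = elements[int(rng.integers(len(elements)))]
        ra = _TOY_RADII[res_a[i].atoms[0].element]
        rb = _TOY_RADII[el]
        planted = i < n_planted_contacts
        gap = (ra + rb + slack - 0.25) if planted else (ra + rb + slack + 1.0)
        pos = np.array([i * spacing, 0.0, gap])
        res_b.append(Residue(name="UNK", number=i + 1, atoms=[Atom(el, el, pos)]))
        if planted:
            ledger.append(
                {
                    "res_a": i + 1,
                    "res_b": i + 1,
                    "element_a": res_a[i].atoms[0].element,
                    "element_b": el,
                    "distance": round(gap, 3),
                }
            )
    structure = Structure(
        label=f"toy_{n_planted_contacts}_{seed}",
        chains=[Chain(id="A", residues=res_a), Chain(id="B", residues=res_b)],
    )
    return structure, pd.DataFrame(ledger, columns=["res_a", "res_b", "element_a", "element_b", "distance"])


# ---------------------------------------------------------------------------
# Gaddum-model BRET dose-response families


@dataclass(frozen=True)
class BretSpec:
    """Competitive-antagonism titration family (Gaddum model).

    Defaults emulate a beta-arrestin recruitment assay: agonist EC50 in
    the low nanomolar range, antagonist K_B of 18.2 nM, agonist grid
    10 pM - 100 uM in half-log steps, duplicates on three plates.
    """

    ec50: float = 3.3e-9
    k_b: float = 18.2e-9
    antagonist_concs: tuple[float, ...] = (
        0.0, 1e-8, 3.16e-8, 1e-7, 3.16e-7, 1e-6, 3.16e-6, 1e-5, 3.16e-5,
    )
    top: float = 1.0
    bottom: float = 0.0
    noise_sd: float = 0.02
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.ec50 <= 0 or self.k_b <= 0:
            raise ValueError("ec50 and k_b must be positive")
        if any(c < 0 for c in self.antagonist_concs):
            raise ValueError("antagonist concentrations must be >= 0")


def gaddum_response(
    agonist: np.ndarray, antagonist: float, ec50: float, k_b: float,
    top: float = 1.0, bottom: float = 0.0,
) -> np.ndarray:
    """Surmountable competitive antagonism: EC50 scales by (1 + [B]/K_B)."""
    shifted = ec50 * (1.0 + antagonist / k_b)
    return bottom + (top - bottom) / (1.0 + shifted / np.asarray(agonist, float))


def gen_bret(spec: BretSpec) -> pd.DataFrame:
    """Simulated titration family as a tidy dose-response table.

    Columns: concentration_M, response, curve_id, antagonist_conc_M,
    replicate.  Agonist grid: 10 pM to 100 uM in half-log steps.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    agonist = 10.0 ** np.arange(-11.0, -3.99, 0.5)
    rows = []
    for b in spec.antagonist_concs:
        mean = gaddum_response(agonist, b, spec.ec50, spec.k_b, spec.top, spec.bottom)
        for rep in range(spec.n_replicates):
            noisy = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
            for x, y in zip(agonist, noisy):
                rows.append(
                    {
                        "concentration_M": x,
                        "response": y,
                        "curve_id": f"B={b:.3e}",
                        "antagonist_conc_M": b,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alignments with a prescribed conservation profile

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def gen_alignment(
    profile: np.ndarray, n_seqs: int, seed: int = 0
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Alignment whose columns follow a conservation probability profile.

    Per column a modal residue is drawn once; each sequence carries it
    with the profile probability, otherwise a uniformly drawn different
    residue.  Returns FASTA-style records and the *realized* per-column
    modal fraction (which is what a conservation scorer should report).
    """
    profile = np.asarray(profile, dtype=float)
    if np.any((profile < 0) | (profile > 1)):
        raise ValueError("profile values must lie in [0, 1]")
    if n_seqs < 2:
        raise ValueError("need at least two sequences")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_seqs, len(profile)]))
    ncol = len(profile)
    cols = []
    for p in profile:
        modal = _AA20[int(rng.integers(20))]
        others = [c for c in _AA20 if c != modal]
        col = [
            modal if rng.random() < p else others[int(rng.integers(19))]
            for _ in range(n_seqs)
        ]
        cols.append(col)
    seqs = ["".join(cols[j][i] for j in range(ncol)) for i in range(n_seqs)]
    realized = np.array(
        [max(col.count(c) for c in set(col)) / n_seqs for col in cols]
    )
    records = [(f"synthetic_seq_{i}", s) for i, s in enumerate(seqs)]
    return records, realized
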