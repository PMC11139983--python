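"""Framework superposition, all-vs-all RMSD, and CDR3 classification.

The census compares nanobody domains by least-squares (Kabsch)
superposition on framework C-alpha positions; the reported distance by
default covers the whole domain, so divergent CDR3 placements dominate
the matrix.  Average-linkage hierarchical clustering of the matrix and a
rule-based classifier both partition CDR3 conformations into the three
canonical classes: short, extended, folded-back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import contacts as _contacts
from .ig_annotate import CdrAnnotation, cdr3_length
from .secstruct import Hairpin
from .structio import Structure

__all__ = [
    "SuperpositionResult",
    "RmsdMatrix",
    "Cdr3Features",
    "Cdr3Class",
    "ClassThresholds",
    "kabsch_superpose",
    "framework_rmsd",
    "build_rmsd_matrix",
    "cluster_matrix",
    "cdr3_features",
    "classify_cdr3",
]

MIN_FRAMEWORK_MATCH = 40   # matched framework C-alphas required for a comparison


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper (det = +1)
    translation: np.ndarray   # 3-vector, A
    rmsd: float               # A, after transform

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_p: np.ndarray, coords_q: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of P onto Q.

    SVD-based with reflection correction; requires n >= 3 paired points
    of rank >= 2.
    """
    P = np.asarray(coords_p, dtype=float)
    Q = np.asarray(coords_q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -5.0
_aligner.extend_gap_score = -0.5


def _ungapped_columns(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Index pairs of aligned, ungapped columns of a global alignment."""
    if not seq_a or not seq_b:
        return []
    aln = _aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def _ca_coords(structure: Structure) -> np.ndarray:
    """Per-residue C-alpha coordinates of the first polymer chain (NaN if absent)."""
    chain = next(c for c in structure.chains if not c.het)
    out = np.full((len(chain), 3), np.nan)
    for i, res in enumerate(chain):
        if res.has_atom("CA"):
            out[i] = res.atom("CA").coords
    return out


def framework_rmsd(
    struct_a: Structure,
    annot_a: CdrAnnotation,
    struct_b: Structure,
    annot_b: CdrAnnotation,
    report_whole_domain: bool = True,
) -> float:
    """C-alpha RMSD after superposition on matched framework positions.

    Framework regions are sequence-aligned region-by-region and ungapped
    columns define the fit.  The reported RMSD covers, by default, the
    whole domain (so CDR divergence contributes): framework columns plus
    CDR columns paired anchor-symmetrically — position k from each CDR
    start and position k from each CDR end, which is sequence-independent
    and respects the loops' two-anchor geometry.  With
    ``report_whole_domain=False`` only the framework columns used in the
    fit are reported.
    """
    ca_a, ca_b = _ca_coords(struct_a), _ca_coords(struct_b)

    fit_pairs: list[tuple[int, int]] = []
    for region in ("FR1", "FR2", "FR3", "FR4"):
        (a0, a1), (b0, b1) = annot_a.spans[region], annot_b.spans[region]
        for i, j in _ungapped_columns(annot_a.sequence[a0:a1], annot_b.sequence[b0:b1]):
            fit_pairs.append((a0 + i, b0 + j))
    fit_pairs = [
        (i, j)
        for i, j in fit_pairs
        if i < len(ca_a) and j < len(ca_b)
        and np.isfinite(ca_a[i]).all() and np.isfinite(ca_b[j]).all()
    ]
    if len(fit_pairs) < MIN_FRAMEWORK_MATCH:
        raise ValueError(
            f"only {len(fit_pairs)} matched framework C-alphas "
            f"(need >= {MIN_FRAMEWORK_MATCH})"
        )

    P = np.array([ca_a[i] for i, _ in fit_pairs])
    Q = np.array([ca_b[j] for _, j in fit_pairs])
    sup = kabsch_superpose(P, Q)
    if not report_whole_domain:
        return sup.rmsd

    all_pairs = list(fit_pairs)
    for region in ("CDR1", "CDR2", "CDR3"):
        (a0, a1), (b0, b1) = annot_a.spans[region], annot_b.spans[region]
        la, lb = a1 - a0, b1 - b0
        shared = min(la, lb)
        n_head = shared // 2 + shared % 2
        n_tail = shared // 2
        for k in range(n_head):
            all_pairs.append((a0 + k, b0 + k))
        for k in range(n_tail):
            all_pairs.append((a1 - 1 - k, b1 - 1 - k))
    all_pairs = [
        (i, j)
        for i, j in all_pairs
        if i < len(ca_a) and j < len(ca_b)
        and np.isfinite(ca_a[i]).all() and np.isfinite(ca_b[j]).all()
    ]
    Pw = sup.apply(np.array([ca_a[i] for i, _ in all_pairs]))
    Qw = np.array([ca_b[j] for _, j in all_pairs])
    return float(np.sqrt(((Pw - Qw) ** 2).sum() / len(all_pairs)))


@dataclass
class RmsdMatrix:
    """Symmetric all-vs-all RMSD matrix with masked (failed) entries."""

    labels: list[str]
    values: np.ndarray                      # (n, n) A; NaN where masked
    mask_reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        finite = np.isfinite(v)
        if not np.all(np.abs(v.T[finite.T & finite] - v[finite & finite.T]) < 1e-6):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def build_rmsd_matrix(
    entries: list[tuple[str, Structure, CdrAnnotation]],
    report_whole_domain: bool = True,
) -> RmsdMatrix:
    """Pairwise framework RMSD over annotatable structures; failures masked."""
    if len(entries) < 2:
        raise ValueError("need at least 2 annotatable structures")
    n = len(entries)
    labels = [label for label, _, _ in entries]
    values = np.zeros((n, n))
    reasons: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = framework_rmsd(
                    entries[i][1], entries[i][2], entries[j][1], entries[j][2],
                    report_whole_domain=report_whole_domain,
                )
            except ValueError as exc:
                r = np.nan
                reasons[(labels[i], labels[j])] = str(exc)
            values[i, j] = values[j, i] = r
    return RmsdMatrix(labels=labels, values=values, mask_reasons=reasons)


def cluster_matrix(matrix: RmsdMatrix, k: int = 3) -> dict[str, int]:
    """Average-linkage agglomerative clustering of the RMSD matrix.

    Structures involved in masked pairs are dropped (greedily, most-masked
    first) until the remaining matrix is complete; they are absent from
    the returned label -> cluster-id mapping.
    """
    if k > len(matrix.labels):
        raise ValueError(f"k={k} exceeds {len(matrix.labels)} structures")
    keep = list(range(len(matrix.labels)))
    values = matrix.values
    while True:
        sub = values[np.ix_(keep, keep)]
        bad = np.isnan(sub).sum(axis=1)
        if not bad.any():
            break
        keep.pop(int(np.argmax(bad)))
        if len(keep) < k:
            raise ValueError("too many masked pairs to cluster")
    sub = values[np.ix_(keep, keep)]
    if len(keep) == 1:
        return {matrix.labels[keep[0]]: 1}
    Z = linkage(squareform(sub, checks=False), method="average")
    assignments = fcluster(Z, t=k, criterion="maxclust")
    return {matrix.labels[i]: int(c) for i, c in zip(keep, assignments)}


@dataclass(frozen=True)
class Cdr3Features:
    """Geometric descriptors of one CDR3 loop."""

    length: int
    n_cross_hbonds: int
    protrusion: float                 # A beyond the framework envelope
    framework_contact_fraction: float

    def __post_init__(self):
        if not np.isfinite(self.protrusion):
            raise ValueError("protrusion must be finite")
        if not 0.0 <= self.framework_contact_fraction <= 1.0:
            raise ValueError("framework_contact_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ClassThresholds:
    """Tunable decision thresholds for the three-class CDR3 rule."""

    l_short: int = 7            # residues; at or below -> short
    min_protrusion: float = 5.0  # A; extended must protrude at least this far
    max_contact_fraction: float = 0.3
    min_cross_hbonds: int = 2


@dataclass(frozen=True)
class Cdr3Class:
    label: str                  # 'short' | 'extended' | 'folded_back'
    rationale: str

    def __post_init__(self):
        if self.label not in ("short", "extended", "folded_back"):
            raise ValueError(f"unknown class {self.label!r}")


def cdr3_features(
    structure: Structure,
    annotation: CdrAnnotation,
    ss: str,
    hairpin: Hairpin,
    slack: float = _contacts.DEFAULT_SLACK,
) -> Cdr3Features:
    """Compute the classifier's geometric descriptors.

    Protrusion is the maximum CDR3 C-alpha distance from the framework
    C-alpha centroid minus the 95th percentile of framework distances to
    that centroid.  The contact fraction counts CDR3 residues (excluding
    the three adjacent to each anchor) with at least one heavy-atom
    contact to FR2/CDR2-side framework residues.
    """
    chain = next(c for c in structure.chains if not c.het)
    ca = _ca_coords(structure)

    fw_idx = [
        i
        for region in ("FR1", "FR2", "FR3", "FR4")
        for i in range(*annotation.spans[region])
        if i < len(ca) and np.isfinite(ca[i]).all()
    ]
    a, b = annotation.cdr3
    cdr3_idx = [i for i in range(a, b) if i < len(ca) and np.isfinite(ca[i]).all()]
    fw = ca[fw_idx]
    centroid = fw.mean(axis=0)
    fw_d = np.linalg.norm(fw - centroid, axis=1)
    envelope = float(np.percentile(fw_d, 95))
    if cdr3_idx:
        protrusion = float(np.max(np.linalg.norm(ca[cdr3_idx] - centroid, axis=1)) - envelope)
    else:
        protrusion = 0.0

    # FR2/CDR2-side framework selection
    side_idx = set(range(*annotation.spans["FR2"])) | set(range(*annotation.spans["CDR2"]))
    side_refs = [
        _contacts.AtomRef(chain.id, r.name, r.id, at)
        for i, r in enumerate(chain)
        if i in side_idx
        for at in r.atoms
    ]
    core = [i for i in range(a + 3, b - 3)]
    frac = 0.0
    if core and side_refs:
        touching = 0
        for i in core:
            if i >= len(chain.residues):
                continue
            res = chain.residues[i]
            refs = [_contacts.AtomRef(chain.id, res.name, res.id, at) for at in res.atoms]
            if not refs:
                continue
            cmap = _contacts.find_contacts(refs, side_refs, slack=slack)
            if len(cmap) > 0:
                touching += 1
        frac = touching / len(core)

    return Cdr3Features(
        length=cdr3_length(annotation),
        n_cross_hbonds=hairpin.n_cross_hbonds,
        protrusion=protrusion,
        framework_contact_fraction=frac,
    )


def classify_cdr3(
    features: Cdr3Features, thresholds: ClassThresholds | None = None
) -> Cdr3Class:
    """Three-class CDR3 rule: short by length, extended by hairpin
    geometry, folded-back otherwise."""
    t = thresholds or ClassThresholds()
    if features.length <= t.l_short:
        return Cdr3Class(
            "short", f"length {features.length} <= {t.l_short}"
        )
    if (
        features.n_cross_hbonds >= t.min_cross_hbonds
        and features.protrusion >= t.min_protrusion
        and features.framework_contact_fraction <= t.max_contact_fraction
    ):
        return Cdr3Class(
            "extended",
            f"hairpin with {features.n_cross_hbonds} cross-strand bonds, "
            f"protrusion {features.protrusion:.1f} A, "
            f"contact fraction {features.framework_contact_fraction:.2f}",
        )
    return Cdr3Class(
        "folded_back",
        f"no protruding hairpin (bonds {features.n_cross_hbonds}, "
        f"protrusion {features.protrusion:.1f} A, "
        f"contact fraction {features.framework_contact_fraction:.2f})",
    )
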