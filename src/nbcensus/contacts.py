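"""Interatomic contact detection and interface fingerprinting.

A heavy-atom pair (a, b) across two disjoint selections is a contact when

    d(a, b) <= r(a) + r(b) + slack

with element van-der-Waals radii and a default slack of 0.5 A (boundary
inclusive).  Pairs closer than 1.9 A are treated as covalent cross-links
(e.g. disulfides), flagged and excluded from the count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ig_annotate import CdrAnnotation
from .structio import Atom, Chain, Residue, Structure

__all__ = [
    "DEFAULT_RADII",
    "AtomRef",
    "ContactMap",
    "InterfaceFingerprint",
    "find_contacts",
    "total_contacts",
    "residue_pair_contacts",
    "average_contacts",
    "fingerprint",
    "measure_distance",
    "read_numbering_map",
    "chain_selection",
]

#: Element-level van-der-Waals radii in Angstrom.  Values are the standard
#: Bondi-style set; unknown elements fall back to carbon.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
FALLBACK_RADIUS = 1.70
COVALENT_CUTOFF = 1.9     # A; closer cross-selection pairs are bonds, not contacts
DEFAULT_SLACK = 0.5       # A


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    table = DEFAULT_RADII if table is None else table
    return table.get(element.upper(), FALLBACK_RADIUS)


@dataclass(frozen=True)
class AtomRef:
    """An atom located within its chain/residue context."""

    chain_id: str
    res_name: str
    res_id: str        # author number + insertion code
    atom: Atom

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.res_id)


@dataclass
class Contact:
    a: AtomRef
    b: AtomRef
    distance: float


@dataclass
class ContactMap:
    """Atom-pair contacts between two selections, plus flagged covalent pairs."""

    contacts: list[Contact] = field(default_factory=list)
    covalent_flagged: list[Contact] = field(default_factory=list)
    slack: float = DEFAULT_SLACK

    def __len__(self) -> int:
        return len(self.contacts)

    def per_residue_pair(self) -> dict[tuple[tuple[str, str], tuple[str, str]], int]:
        out: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
        for c in self.contacts:
            key = (c.a.key, c.b.key)
            out[key] = out.get(key, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_a": c.a.chain_id, "res_a": c.a.res_id, "resname_a": c.a.res_name,
                "atom_a": c.a.atom.name,
                "chain_b": c.b.chain_id, "res_b": c.b.res_id, "resname_b": c.b.res_name,
                "atom_b": c.b.atom.name,
                "distance": round(c.distance, 3),
            }
            for c in self.contacts
        ]
        return pd.DataFrame(
            rows,
            columns=["chain_a", "res_a", "resname_a", "atom_a",
                     "chain_b", "res_b", "resname_b", "atom_b", "distance"],
        )


def chain_selection(structure: Structure, chain_id: str, het: bool = False) -> list[AtomRef]:
    """All atoms of one chain as located references."""
    chain = structure.chain(chain_id, het=het)
    return [
        AtomRef(chain_id=chain.id, res_name=r.name, res_id=r.id, atom=a)
        for r in chain
        for a in r.atoms
    ]


def find_contacts(
    selection_a: list[AtomRef],
    selection_b: list[AtomRef],
    radius_table: dict[str, float] | None = None,
    slack: float = DEFAULT_SLACK,
) -> ContactMap:
    """All-pairs contact search between two disjoint atom selections.

    Hydrogens should be stripped beforehand (:func:`structio.strip_hydrogens`);
    any present are ignored here as a safety net.
    """
    sel_a = [r for r in selection_a if not r.atom.is_hydrogen]
    sel_b = [r for r in selection_b if not r.atom.is_hydrogen]
    if not sel_a or not sel_b:
        raise ValueError("contact search requires two non-empty selections")

    xyz_a = np.array([r.atom.coords for r in sel_a])
    xyz_b = np.array([r.atom.coords for r in sel_b])
    rad_a = np.array([vdw_radius(r.atom.element, radius_table) for r in sel_a])
    rad_b = np.array([vdw_radius(r.atom.element, radius_table) for r in sel_b])

    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    cutoff = rad_a[:, None] + rad_b[None, :] + slack
    pairs = np.argwhere(d <= cutoff)

    cmap = ContactMap(slack=slack)
    for i, j in pairs:
        contact = Contact(a=sel_a[i], b=sel_b[j], distance=float(d[i, j]))
        if d[i, j] < COVALENT_CUTOFF:
            cmap.covalent_flagged.append(contact)
        else:
            cmap.contacts.append(contact)
    return cmap


def total_contacts(cmap: ContactMap) -> int:
    """Number of atom-pair contacts in the map."""
    return len(cmap)


def residue_pair_contacts(cmap: ContactMap) -> int:
    """Number of distinct residue-residue pairs in contact."""
    return len(cmap.per_residue_pair())


def average_contacts(cmaps: list[ContactMap], residue_pairs: bool = False) -> float:
    """Arithmetic mean contact total across complexes."""
    if not cmaps:
        raise ValueError("need at least one contact map")
    counter = residue_pair_contacts if residue_pairs else total_contacts
    return float(np.mean([counter(m) for m in cmaps]))


@dataclass
class InterfaceFingerprint:
    """Per-receptor-position contact counts, partitioned by ligand region."""

    positions: pd.DataFrame   # columns: res_id, generic, total, + one column per region

    def total(self) -> int:
        return int(self.positions["total"].sum())


def read_numbering_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV (author residue number -> generic label), e.g. GPCRdb."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("numbering map needs two tab-separated columns")
    mapping = dict(zip(df[0].str.strip(), df[1].str.strip()))
    labels = [v for v in mapping.values() if v]
    if len(set(labels)) != len(labels):
        raise ValueError("numbering map must be injective on mapped positions")
    return mapping


def fingerprint(
    cmap: ContactMap,
    receptor_chain: str,
    numbering_map: dict[str, str] | None = None,
    ligand_annotation: CdrAnnotation | None = None,
    ligand_chain_start: int = 1,
) -> InterfaceFingerprint:
    """Contact counts along receptor positions, partitioned by ligand CDR.

    The receptor is whichever side of the map matches ``receptor_chain``.
    With a :class:`CdrAnnotation` for the ligand, each contact is
    attributed to the CDR containing the ligand residue (framework
    contacts pool into "FR"); without one, all counts fall in a single
    "ligand" bucket.  ``ligand_chain_start`` is the author number of the
    first annotated ligand residue.
    """
    sides = {c.a.chain_id for c in cmap.contacts} | {c.b.chain_id for c in cmap.contacts}
    if cmap.contacts and receptor_chain not in sides:
        raise KeyError(f"receptor chain {receptor_chain!r} absent from contact map")

    def split(contact: Contact) -> tuple[AtomRef, AtomRef]:
        if contact.a.chain_id == receptor_chain:
            return contact.a, contact.b
        return contact.b, contact.a

    regions: list[str] = (
        ["CDR1", "CDR2", "CDR3", "FR"] if ligand_annotation is not None else ["ligand"]
    )
    counts: dict[str, dict[str, int]] = {}
    for contact in cmap.contacts:
        rec, lig = split(contact)
        bucket = "ligand"
        if ligand_annotation is not None:
            try:
                idx = int(lig.res_id) - ligand_chain_start
                region = ligand_annotation.region_of(idx)
            except (ValueError, IndexError):
                region = "FR"
            bucket = region if region.startswith("CDR") else "FR"
        row = counts.setdefault(rec.res_id, {r: 0 for r in regions})
        row[bucket] += 1

    def sort_key(res_id: str):
        num = "".join(ch for ch in res_id if ch.isdigit() or ch == "-")
        return (int(num) if num else 0, res_id)

    rows = []
    for res_id in sorted(counts, key=sort_key):
        row: dict[str, object] = {"res_id": res_id}
        row["generic"] = (numbering_map or {}).get(res_id, "")
        row.update(counts[res_id])
        row["total"] = sum(counts[res_id].values())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["res_id", "generic", *regions, "total"])
    return InterfaceFingerprint(positions=df)


def measure_distance(
    structure: Structure,
    a: tuple[str, int, str],
    b: tuple[str, int, str],
) -> float:
    """Euclidean distance between two named atoms.

    Each endpoint is (chain id, author residue number, atom name).  A
    missing atom raises ``KeyError`` carrying the nearest atom name in
    that residue as a suggestion.
    """

    def locate(spec: tuple[str, int, str]) -> np.ndarray:
        chain_id, resnum, atom_name = spec
        chain = structure.chain(chain_id)
        res = chain.residue(resnum)
        try:
            return res.atom(atom_name).coords
        except KeyError:
            names = [at.name for at in res.atoms]
            import difflib

            close = difflib.get_close_matches(atom_name, names, n=1, cutoff=0.4)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            raise KeyError(
                f"no atom {atom_name!r} in {chain_id}/{resnum} {res.name}{hint}"
            ) from None

    return float(np.linalg.norm(locate(a) - locate(b)))
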