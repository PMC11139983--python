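"""Macromolecular structure and sequence I/O.

Defines the lightweight coordinate model (Atom / Residue / Chain /
Structure) consumed by every other module, and readers/writers for legacy
PDB and FASTA.  PDB parsing and writing are delegated to gemmi; on top of
that this module applies the census conventions: one model per Structure,
altloc resolved to the highest-occupancy conformer (ties broken by file
order), waters dropped, and HETATM ligands kept in their own chain
grouping.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterator

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "PdbError",
    "read_pdb",
    "write_pdb",
    "strip_hydrogens",
    "extract_sequence",
    "read_fasta",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
# HETATM residues that are nonetheless part of the polypeptide
_POLYMER_HET = {"MSE", "SEC", "PYL", "MLY", "PTR", "SEP", "TPO", "CSO", "HYP"}


class PdbError(ValueError):
    """Raised for unreadable or structurally empty PDB input."""


@dataclass(frozen=True)
class Atom:
    """A single atom: name, element symbol, coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")
        if not (0.0 <= self.occupancy <= 1.0 or math.isnan(self.occupancy)):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue: 3-letter name, author number + insertion code, atoms."""

    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_het: bool = False

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def id(self) -> str:
        return f"{self.number}{self.icode}"


@dataclass
class Chain:
    """Ordered residues sharing one chain identifier."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    het: bool = False

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"{self.id}/{number}{icode}")


@dataclass
class Structure:
    """One model of a macromolecular structure."""

    label: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 1

    def __post_init__(self):
        if not any(len(c) for c in self.chains):
            raise ValueError("Structure must contain at least one non-empty chain")

    def chain(self, chain_id: str, het: bool = False) -> Chain:
        for c in self.chains:
            if c.id == chain_id and c.het == het:
                return c
        raise KeyError(chain_id)

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())


def _infer_element(atom_name: str) -> str:
    """PDB v3 element inference for blank element columns.

    Names are right-justified starting in column 13 for two-letter
    elements; a leading digit (as in '1HB2') marks a hydrogen.
    """
    name = atom_name.strip()
    if not name:
        return "X"
    if name[0].isdigit():
        return "H"
    two = name[:2].upper()
    if two in ("FE", "ZN", "MG", "MN", "CU", "NI", "CO", "SE", "BR", "CL", "NA", "CA"):
        # ambiguous with calcium Calpha: treat 'CA' as carbon inside residues
        if two != "CA":
            return two.capitalize()
    return name[0].upper()


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by file order."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        else:
            occ_old = best[a.name].occupancy
            occ_new = a.occupancy
            if not math.isnan(occ_new) and (math.isnan(occ_old) or occ_new > occ_old):
                best[a.name] = a
    return [replace(best[n], altloc="") for n in order]


def read_pdb(path: str | os.PathLike, model_index: int = 1, label: str | None = None) -> Structure:
    """Read one model from a PDB file into the census coordinate model.

    Parameters
    ----------
    path : path to a legacy-format PDB file.
    model_index : 1-based model number for multi-model (NMR) files.
    label : structure label; defaults to the file stem.

    Waters are excluded; other HETATM residues are kept in a separate
    chain grouping (``Chain.het`` is True) under the same chain id.
    Altlocs are resolved to the highest-occupancy conformer, ties broken
    by file order.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise PdbError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PdbError(f"unparseable PDB file {path}: {exc}") from None
    if len(st) == 0:
        raise PdbError(f"{path}: no ATOM records")
    st.setup_entities()
    if model_index < 1 or model_index > len(st):
        raise PdbError(
            f"{path}: requested model {model_index} but file has {len(st)} model(s)"
        )
    model = st[model_index - 1]

    chains: list[Chain] = []
    for gchain in model:
        polymer = Chain(id=gchain.name)
        het = Chain(id=gchain.name, het=True)
        for gres in gchain:
            if gres.name in _WATER_NAMES:
                continue
            atoms = []
            for ga in gres:
                el = ga.element.name if ga.element and ga.element.name != "X" else ""
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=el or _infer_element(ga.name),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        altloc=ga.altloc or "",
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                    )
                )
            res = Residue(
                name=gres.name,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                atoms=_resolve_altlocs(atoms),
                is_het=gres.het_flag == "H" and gres.name not in _POLYMER_HET,
            )
            (het if res.is_het else polymer).residues.append(res)
        if polymer.residues:
            chains.append(polymer)
        if het.residues:
            chains.append(het)
    if not any(c.residues for c in chains):
        raise PdbError(f"{path}: no ATOM records after filtering")
    return Structure(
        label=label or os.path.splitext(os.path.basename(path))[0],
        chains=chains,
        model_index=model_index,
    )


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write the structure back to a legacy PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.label
    model = gemmi.Model("1")
    done: dict[str, gemmi.Chain] = {}
    for chain in structure.chains:
        gchain = done.get(chain.id)
        if gchain is None:
            gchain = gemmi.Chain(chain.id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.is_het else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        if chain.id not in done:
            done[chain.id] = gchain
    for gchain in done.values():
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def strip_hydrogens(structure: Structure) -> Structure:
    """Return a copy with every hydrogen/deuterium atom removed."""
    chains = []
    for chain in structure.chains:
        residues = []
        for res in chain:
            heavy = [a for a in res.atoms if not a.is_hydrogen]
            residues.append(replace(res, atoms=heavy))
        chains.append(Chain(id=chain.id, residues=residues, het=chain.het))
    return Structure(label=structure.label, chains=chains, model_index=structure.model_index)


def extract_sequence(chain: Chain, selenomet_as_met: bool = True) -> str:
    """One-letter sequence of a chain in residue order.

    Nonstandard residues map to 'X'; MSE maps to 'M' by default
    (selenomethionine), or to 'X' when ``selenomet_as_met`` is False.
    """
    if len(chain) == 0:
        raise ValueError(f"chain {chain.id} is empty")
    custom = {"MSE": "M"} if selenomet_as_met else {"MSE": "X"}
    out = []
    for res in chain:
        letter = seq1(res.name.capitalize(), custom_map=custom, undef_code="X")
        out.append(letter if len(letter) == 1 else "X")
    return "".join(out)


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as (header, sequence) pairs, order-preserving."""
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in (">", ";"):
            raise ValueError(f"{path}: malformed FASTA, does not start with '>'")
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        records.append((rec.description, str(rec.seq)))
    return records
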