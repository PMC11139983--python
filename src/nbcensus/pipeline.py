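"""Orchestration of the census, interface, and pharmacology stages.

Each ``run_*`` function is a deterministic library entry point consumed
by the command-line interface, the analysis drivers, and the tests.  All
artifacts are plain TSV/CSV plus a JSON manifest (config echo, input
hashes) sufficient to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import contacts as _contacts
from . import pharm as _pharm
from .ig_annotate import AnnotationError, annotate_cdrs, cdr3_length
from .secstruct import (
    assign_ss,
    backbone_from_chain,
    compute_hbonds,
    detect_hairpin,
    place_amide_hydrogens,
)
from .shapecompare import (
    ClassThresholds,
    RmsdMatrix,
    build_rmsd_matrix,
    cdr3_features,
    classify_cdr3,
    cluster_matrix,
)
from .structio import Structure, extract_sequence, strip_hydrogens

logger = logging.getLogger("nbcensus")

__all__ = [
    "RunConfig",
    "CensusReport",
    "InterfaceResult",
    "run_census",
    "run_interface",
    "run_pharm",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Census thresholds and knobs; defaults match the module defaults."""

    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    k_clusters: int = 3
    contact_slack: float = _contacts.DEFAULT_SLACK
    report_whole_domain: bool = True
    seed: int = 0

    def validate(self) -> None:
        t = self.thresholds
        if min(t.l_short, t.min_protrusion, t.max_contact_fraction, t.min_cross_hbonds) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")


@dataclass
class CensusReport:
    """Per-structure census rows plus summary proportions and exclusions."""

    table: pd.DataFrame
    proportions_all: dict[str, float]
    proportions_nonredundant: dict[str, float]
    exclusions: pd.DataFrame
    matrix: RmsdMatrix | None

    @property
    def n_classified(self) -> int:
        return len(self.table)


def run_census(
    structures: list[tuple[str, Structure]],
    config: RunConfig | None = None,
) -> CensusReport:
    """Full census: annotate -> secondary structure -> features ->
    classify -> RMSD matrix -> cluster.

    Unannotatable or geometrically unusable inputs are excluded with a
    reason code, never fatal.  Structures with identical sequences share
    one representative (lexicographically lowest label) in the
    non-redundant matrix and proportions.
    """
    config = config or RunConfig()
    config.validate()

    rows = []
    exclusions = []
    entries = {}
    for label, structure in sorted(structures, key=lambda kv: kv[0]):
        try:
            chain = next(c for c in structure.chains if not c.het)
            seq = extract_sequence(chain)
            annotation = annotate_cdrs(seq)
            backbone = place_amide_hydrogens(backbone_from_chain(chain))
            hbonds = compute_hbonds(backbone)
            ss = assign_ss(backbone, hbonds)
            hairpin = detect_hairpin(ss, hbonds, annotation.cdr3)
            feats = cdr3_features(
                structure, annotation, ss, hairpin, slack=config.contact_slack
            )
            cls = classify_cdr3(feats, config.thresholds)
        except AnnotationError as exc:
            exclusions.append({"label": label, "reason": exc.reason, "detail": str(exc)})
            logger.warning("excluded %s: %s", label, exc)
            continue
        except Exception as exc:  # noqa: BLE001 - census must survive bad inputs
            exclusions.append({"label": label, "reason": "processing_error", "detail": str(exc)})
            logger.warning("excluded %s: %s", label, exc)
            continue
        entries[label] = (structure, annotation, seq)
        rows.append(
            {
                "label": label,
                "cdr3_length": feats.length,
                "n_cross_hbonds": feats.n_cross_hbonds,
                "protrusion": round(feats.protrusion, 2),
                "framework_contact_fraction": round(feats.framework_contact_fraction, 3),
                "cdr3_class": cls.label,
                "rationale": cls.rationale,
            }
        )
    if not rows:
        raise ValueError("no classifiable structures")
    table = pd.DataFrame(rows)

    # redundancy: identical sequences collapse onto one representative
    by_seq: dict[str, str] = {}
    for label in table["label"]:
        seq = entries[label][2]
        if seq not in by_seq or label < by_seq[seq]:
            by_seq[seq] = label
    representatives = set(by_seq.values())
    table["representative"] = table["label"].isin(representatives)

    matrix = None
    clusters: dict[str, int] = {}
    rep_entries = [
        (label, entries[label][0], entries[label][1])
        for label in table.loc[table["representative"], "label"]
    ]
    if len(rep_entries) >= 2:
        matrix = build_rmsd_matrix(rep_entries, report_whole_domain=config.report_whole_domain)
        k = min(config.k_clusters, len(rep_entries))
        clusters = cluster_matrix(matrix, k=k)
    table["cluster"] = [clusters.get(label, -1) for label in table["label"]]

    def _props(sub: pd.DataFrame) -> dict[str, float]:
        if len(sub) == 0:
            return {}
        return (sub["cdr3_class"].value_counts(normalize=True)).round(6).to_dict()

    return CensusReport(
        table=table,
        proportions_all=_props(table),
        proportions_nonredundant=_props(table[table["representative"]]),
        exclusions=pd.DataFrame(exclusions, columns=["label", "reason", "detail"]),
        matrix=matrix,
    )


@dataclass
class InterfaceResult:
    fingerprint: _contacts.InterfaceFingerprint
    contact_map: _contacts.ContactMap
    total_atom_contacts: int
    total_residue_pairs: int


def run_interface(
    structure: Structure,
    receptor_chain: str,
    ligand_chain: str,
    numbering_map: dict[str, str] | None = None,
    ligand_annotation=None,
    ligand_chain_start: int = 1,
    slack: float = _contacts.DEFAULT_SLACK,
) -> InterfaceResult:
    """Contact fingerprint of one receptor-ligand complex.

    Hydrogens are stripped first.  Chain selections pool polymer and
    HETATM residues sharing the chain id, so small-molecule ligands kept
    in the receptor's author chain are still addressable.
    """
    stripped = strip_hydrogens(structure)

    def selection(chain_id: str):
        refs = []
        for c in stripped.chains:
            if c.id == chain_id:
                for r in c:
                    refs.extend(
                        _contacts.AtomRef(c.id, r.name, r.id, a) for a in r.atoms
                    )
        if not refs:
            raise KeyError(f"chain {chain_id!r} not found")
        return refs

    cmap = _contacts.find_contacts(
        selection(receptor_chain), selection(ligand_chain), slack=slack
    )
    fp = _contacts.fingerprint(
        cmap,
        receptor_chain,
        numbering_map=numbering_map,
        ligand_annotation=ligand_annotation,
        ligand_chain_start=ligand_chain_start,
    )
    return InterfaceResult(
        fingerprint=fp,
        contact_map=cmap,
        total_atom_contacts=_contacts.total_contacts(cmap),
        total_residue_pairs=_contacts.residue_pair_contacts(cmap),
    )


def run_pharm(
    data: pd.DataFrame | str | os.PathLike,
    mode: str,
    agonist_conc: float | None = None,
    agonist_ec50: float | None = None,
) -> pd.DataFrame:
    """Dose-response analysis of a tidy CSV/DataFrame.

    Schema: columns ``concentration_M``, ``response``; optional
    ``curve_id`` and ``antagonist_conc_M``.  Modes:

    * ``agonist`` — one rising fixed-slope fit per curve_id;
    * ``competition`` — falling fits; with ``agonist_conc`` and
      ``agonist_ec50`` the Cheng-Prusoff K_B / pK_B are added;
    * ``schild`` — rising fits per antagonist concentration (0 = control)
      followed by Schild regression.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.read_csv(data)
    required = {"concentration_M", "response"}
    missing = required - set(data.columns)
    if missing or len(data) == 0:
        raise ValueError(
            f"dose-response schema violation: missing columns {sorted(missing)}"
            if missing
            else "dose-response schema violation: empty table"
        )
    if mode not in ("agonist", "competition", "schild"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode in ("agonist", "competition"):
        direction = "agonist" if mode == "agonist" else "antagonist"
        if "curve_id" not in data.columns:
            data = data.assign(curve_id="curve0")
        rows = []
        for curve_id, grp in data.groupby("curve_id", sort=True):
            fit = _pharm.fit_fixed_slope(
                grp["concentration_M"].to_numpy(), grp["response"].to_numpy(), direction
            )
            row = {
                "curve_id": curve_id,
                "direction": direction,
                "bottom": fit.bottom,
                "top": fit.top,
                "midpoint_M": fit.midpoint,
                "p_midpoint": _pharm.p_value_log(fit.midpoint),
                "converged": fit.converged,
                "reliable": fit.reliable,
            }
            if mode == "competition" and agonist_conc is not None and agonist_ec50 is not None:
                comp = _pharm.cheng_prusoff(fit.midpoint, agonist_conc, agonist_ec50)
                row["k_b_M"] = comp.k_b
                row["p_kb"] = comp.p_kb
            rows.append(row)
        return pd.DataFrame(rows)

    # schild
    if "antagonist_conc_M" not in data.columns:
        raise ValueError("schild mode requires an antagonist_conc_M column")
    curves = {}
    for bconc, grp in data.groupby("antagonist_conc_M", sort=True):
        curves[float(bconc)] = _pharm.fit_fixed_slope(
            grp["concentration_M"].to_numpy(), grp["response"].to_numpy(), "agonist"
        )
    if 0.0 not in curves:
        raise ValueError("schild mode requires a control family at antagonist_conc_M = 0")
    control = curves.pop(0.0)
    result = _pharm.schild_fit(control, curves)
    rows = [
        {
            "antagonist_conc_M": b,
            "ec50_M": curves[b].ec50,
            "dose_ratio": r,
        }
        for b, r in zip(result.antagonist_concs, result.dose_ratios)
    ]
    df = pd.DataFrame(rows)
    df["schild_slope"] = result.slope
    df["pa2"] = result.pa2
    df["k_b_M"] = result.k_b
    df["p_kb"] = _pharm.p_value_log(result.k_b)
    df["slope_ok"] = result.slope_ok
    df["control_ec50_M"] = control.ec50
    return df


def write_manifest(outdir: str | os.PathLike, config: dict, inputs: list[str]) -> str:
    """JSON manifest with config echo and input file hashes."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    hashes = {}
    for path in inputs:
        try:
            with open(path, "rb") as fh:
                hashes[os.path.basename(path)] = hashlib.sha256(fh.read()).hexdigest()
        except OSError:
            hashes[os.path.basename(path)] = "unreadable"

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        return str(obj)

    manifest = {"config": config, "inputs": hashes, "package": "nbcensus 0.1.0"}
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_default, sort_keys=True)
    return path
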