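"""Shared fixtures: inline PDB text, synthetic scaffolds, titration data."""

import numpy as np
import pytest
from hypothesis import settings

from nbcensus import synthetic_data as sd

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def atom_line(serial, name, alt, res, chain, num, xyz, occ=1.0, el=None, record="ATOM"):
    x, y, z = xyz
    el = el or name[0]
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{alt:1s}{res:<3s} {chain}{num:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {el:>2s}\n"
    )


@pytest.fixture
def one_residue_pdb(tmp_path):
    text = (
        atom_line(1, "N", "", "GLY", "A", 1, (1.0, 2.0, 3.0), el="N")
        + atom_line(2, "CA", "", "GLY", "A", 1, (2.458, 2.0, 3.0), el="C")
        + atom_line(3, "C", "", "GLY", "A", 1, (3.0, 3.3, 3.0), el="C")
        + atom_line(4, "O", "", "GLY", "A", 1, (2.5, 4.4, 3.0), el="O")
        + "END\n"
    )
    path = tmp_path / "one.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    text = (
        "MODEL        1\n"
        + atom_line(1, "CA", "", "ALA", "A", 1, (1.0, 0.0, 0.0), el="C")
        + "ENDMDL\nMODEL        2\n"
        + atom_line(1, "CA", "", "ALA", "A", 1, (9.0, 0.0, 0.0), el="C")
        + "ENDMDL\nEND\n"
    )
    path = tmp_path / "two_model.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    text = (
        atom_line(1, "N", "", "ALA", "A", 1, (0.0, 0.0, 0.0), el="N")
        + atom_line(2, "CA", "A", "ALA", "A", 1, (1.0, 0.0, 0.0), occ=0.6, el="C")
        + atom_line(3, "CA", "B", "ALA", "A", 1, (2.0, 0.0, 0.0), occ=0.4, el="C")
        + "END\n"
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def hydrogen_pdb(tmp_path):
    lines = [
        atom_line(1, "N", "", "ALA", "A", 1, (0.0, 0.0, 0.0), el="N"),
        atom_line(2, "CA", "", "ALA", "A", 1, (1.5, 0.0, 0.0), el="C"),
        atom_line(3, "C", "", "ALA", "A", 1, (2.2, 1.3, 0.0), el="C"),
        atom_line(4, "O", "", "ALA", "A", 1, (1.7, 2.4, 0.0), el="O"),
        atom_line(5, "CB", "", "ALA", "A", 1, (2.0, -1.2, 0.8), el="C"),
        atom_line(6, "H", "", "ALA", "A", 1, (-0.5, 0.8, 0.0), el="H"),
        atom_line(7, "HA", "", "ALA", "A", 1, (1.8, -0.5, -0.9), el="H"),
        atom_line(8, "HB1", "", "ALA", "A", 1, (2.9, -1.0, 1.3), el="H"),
    ]
    path = tmp_path / "hydro.pdb"
    path.write_text("".join(lines) + "END\n")
    return path


@pytest.fixture(scope="session")
def scaffolds_clean():
    """One scaffold per CDR3 mode, no jitter."""
    return {
        mode: sd.gen_scaffold(sd.ScaffoldSpec(cdr3_mode=mode, seed=3, jitter_sd=0.0))
        for mode in ("short", "extended", "folded")
    }


@pytest.fixture(scope="session")
def scaffolds_jittered():
    """One scaffold per CDR3 mode at the default 0.3 A jitter."""
    return {
        mode: sd.gen_scaffold(sd.ScaffoldSpec(cdr3_mode=mode, seed=4, jitter_sd=0.3))
        for mode in ("short", "extended", "folded")
    }


@pytest.fixture(scope="session")
def small_census():
    """Six scaffolds, two per class, jitter 0.3."""
    return sd.gen_census(n_per_class=2, seed=9, jitter_sd=0.3)


def brute_force_hbonds(backbone):
    """Independent O(n^2) Kabsch-Sander recomputation (two best per donor)."""
    from nbcensus.secstruct import HBOND_CUTOFF, Q_COUPLING

    out = []
    n = len(backbone)
    for i in range(n):
        don = backbone[i]
        if don is None or don.h is None:
            continue
        cands = []
        for j in range(n):
            if abs(i - j) < 2 or backbone[j] is None:
                continue
            acc = backbone[j]
            r_on = float(np.linalg.norm(acc.o - don.n))
            r_ch = float(np.linalg.norm(acc.c - don.h))
            r_oh = float(np.linalg.norm(acc.o - don.h))
            r_cn = float(np.linalg.norm(acc.c - don.n))
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                e = -9.9
            else:
                e = Q_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < HBOND_CUTOFF:
                cands.append((e, i, j))
        cands.sort()
        out.extend((i, j, e) for e, i, j in cands[:2])
    return sorted(out)
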