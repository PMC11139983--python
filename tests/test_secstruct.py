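"""Kabsch-Sander hydrogen bonds and reduced secondary structure."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nbcensus.secstruct import (
    BackboneResidue,
    HBond,
    assign_ss,
    backbone_from_chain,
    compute_hbonds,
    detect_hairpin,
    hbond_energy,
    place_amide_hydrogens,
)

from conftest import brute_force_hbonds


def _nerf(a, b, c, r, theta_deg, chi_deg):
    """Independent internal-coordinate atom placement for test fixtures."""
    theta, chi = np.deg2rad(theta_deg), np.deg2rad(chi_deg)
    bc = (c - b) / np.linalg.norm(c - b)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta), r * np.sin(theta) * np.cos(chi),
                  r * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_chain(n, phi, psi, names=None):
    """Ideal-geometry backbone with uniform torsions (test-local builder)."""
    N = np.zeros((n, 3)); CA = np.zeros((n, 3)); C = np.zeros((n, 3)); O = np.zeros((n, 3))
    CA[0] = [1.458, 0.0, 0.0]
    ang = np.deg2rad(180 - 111.2)
    C[0] = CA[0] + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        if i > 0:
            N[i] = _nerf(N[i-1], CA[i-1], C[i-1], 1.329, 116.2, psi)
            CA[i] = _nerf(CA[i-1], C[i-1], N[i], 1.458, 121.7, 180.0)
            C[i] = _nerf(C[i-1], N[i], CA[i], 1.525, 111.2, phi)
        O[i] = _nerf(N[i], CA[i], C[i], 1.231, 120.8, psi + 180.0)
    names = names or ["ALA"] * n
    return [BackboneResidue(name=names[i], n=N[i], ca=CA[i], c=C[i], o=O[i])
            for i in range(n)]


class TestHydrogenPlacement:
    def test_bisector_formula_matches_hand_computation(self):
        bb = place_amide_hydrogens(build_chain(3, -139, 135))
        i = 1
        v1 = bb[i].n - bb[i-1].c
        v2 = bb[i].n - bb[i-1].o
        u = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        expected = bb[i].n + u / np.linalg.norm(u)
        np.testing.assert_allclose(bb[i].h, expected, atol=1e-6)

    def test_nh_length_exactly_one(self):
        bb = place_amide_hydrogens(build_chain(6, -57, -47))
        for res in bb:
            if res.h is not None:
                assert np.linalg.norm(res.h - res.n) == pytest.approx(1.0, abs=1e-12)

    def test_no_h_on_first_residue_or_proline(self):
        bb = place_amide_hydrogens(build_chain(4, -139, 135,
                                               names=["ALA", "PRO", "ALA", "ALA"]))
        assert bb[0].h is None
        assert bb[1].h is None
        assert bb[2].h is not None

    def test_chain_break_flags_residue(self):
        bb = build_chain(4, -139, 135)
        for res in bb[2:]:
            for attr in ("n", "ca", "c", "o"):
                setattr(res, attr, getattr(res, attr) + np.array([50.0, 0, 0]))
        bb = place_amide_hydrogens(bb)
        assert bb[2].h is None and bb[2].chain_break


class TestEnergy:
    def test_long_range_energy_vanishes(self):
        bb = place_amide_hydrogens(build_chain(2, -139, 135))
        far = BackboneResidue(
            name="ALA",
            n=np.array([50.0, 0, 0]), ca=np.array([51.5, 0, 0]),
            c=np.array([52.2, 1.3, 0]), o=np.array([51.7, 2.4, 0]),
        )
        e, clamped = hbond_energy(bb[1], far)
        assert abs(e) < 0.05 and not clamped

    def test_clashing_geometry_clamped(self):
        bb = place_amide_hydrogens(build_chain(2, -139, 135))
        clash = BackboneResidue(
            name="ALA", n=bb[1].n + 10, ca=bb[1].ca + 10,
            c=bb[1].h + np.array([0.1, 0, 0]), o=bb[1].h,
        )
        e, clamped = hbond_energy(bb[1], clash)
        assert clamped and e == -9.9

    def test_designed_antiparallel_pair_bonds(self, scaffolds_clean):
        """The generator's designed hairpin geometry scores below -0.5
        in both directions (mutual bonds present)."""
        sc = scaffolds_clean["extended"]
        chain = sc.structure.chains[0]
        bb = place_amide_hydrogens(backbone_from_chain(chain))
        hbonds = compute_hbonds(bb)
        directed = {(b.donor, b.acceptor) for b in hbonds}
        a, bnd = sc.annotation.cdr3
        mutual = [
            (i, j)
            for (i, j) in directed
            if (j, i) in directed and a <= i < bnd and a <= j < bnd
        ]
        assert len(mutual) >= 2 * sc.designed_rungs  # each rung contributes both directions
        for b in hbonds:
            assert b.energy < -0.5

    def test_rigid_motion_invariance(self, scaffolds_clean):
        from scipy.spatial.transform import Rotation

        chain = scaffolds_clean["short"].structure.chains[0]
        bb1 = place_amide_hydrogens(backbone_from_chain(chain))
        R = Rotation.from_euler("xyz", [31.0, -57.0, 112.0], degrees=True).as_matrix()
        t = np.array([13.0, -7.0, 4.0])
        bb2 = []
        for res in backbone_from_chain(chain):
            bb2.append(
                BackboneResidue(
                    name=res.name, n=res.n @ R.T + t, ca=res.ca @ R.T + t,
                    c=res.c @ R.T + t, o=res.o @ R.T + t,
                )
            )
        bb2 = place_amide_hydrogens(bb2)
        e1 = {(b.donor, b.acceptor): b.energy for b in compute_hbonds(bb1)}
        e2 = {(b.donor, b.acceptor): b.energy for b in compute_hbonds(bb2)}
        assert e1.keys() == e2.keys()
        for key in e1:
            assert e1[key] == pytest.approx(e2[key], abs=1e-9)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("mode", ["short", "extended", "folded"])
    def test_hbond_list_matches_oracle(self, scaffolds_jittered, mode):
        chain = scaffolds_jittered[mode].structure.chains[0]
        bb = place_amide_hydrogens(backbone_from_chain(chain))
        ours = sorted((b.donor, b.acceptor, b.energy) for b in compute_hbonds(bb))
        oracle = brute_force_hbonds(bb)
        assert [(d, a) for d, a, _ in ours] == [(d, a) for d, a, _ in oracle]
        np.testing.assert_allclose(
            [e for _, _, e in ours], [e for _, _, e in oracle], atol=1e-12
        )


class TestAssignment:
    def test_isolated_extended_strand_is_coil(self):
        bb = place_amide_hydrogens(build_chain(8, -139, 135))
        hbonds = compute_hbonds(bb)
        assert all(ch == "C" for ch in assign_ss(bb, hbonds))

    def test_ideal_alpha_helix_interior_is_h(self):
        bb = place_amide_hydrogens(build_chain(12, -57, -47))
        hbonds = compute_hbonds(bb)
        # i -> i+4 bonds must exist (verified against the energy formula by
        # the brute-force oracle equivalence above)
        assert any(b.donor - b.acceptor == 4 for b in hbonds)
        ss = assign_ss(bb, hbonds)
        assert set(ss[2:9]) == {"H"}

    def test_scaffold_strand_and_coil_labels(self, scaffolds_jittered):
        for mode, sc in scaffolds_jittered.items():
            chain = sc.structure.chains[0]
            bb = place_amide_hydrogens(backbone_from_chain(chain))
            ss = assign_ss(bb, compute_hbonds(bb))
            strand_hits = sum(ss[i] == "E" for i in sc.designed_strand_residues)
            assert strand_hits >= 0.8 * len(sc.designed_strand_residues), mode
            assert all(ss[i] != "E" for i in sc.designed_coil_residues), mode

    def test_missing_backbone_labeled_c(self, scaffolds_clean):
        from dataclasses import replace as dc_replace

        chain = scaffolds_clean["short"].structure.chains[0]
        target = chain.residues[5]
        chain.residues[5] = dc_replace(
            target, atoms=[a for a in target.atoms if a.name != "O"]
        )
        with pytest.warns(UserWarning, match="missing backbone"):
            bb = backbone_from_chain(chain)
        assert bb[5] is None
        ss = assign_ss(place_amide_hydrogens(bb), compute_hbonds(bb))
        assert ss[5] == "C"
        chain.residues[5] = target   # session fixture: restore


class TestHairpin:
    def test_extended_scaffold_has_hairpin(self, scaffolds_jittered):
        sc = scaffolds_jittered["extended"]
        chain = sc.structure.chains[0]
        bb = place_amide_hydrogens(backbone_from_chain(chain))
        hbonds = compute_hbonds(bb)
        hp = detect_hairpin(assign_ss(bb, hbonds), hbonds, sc.annotation.cdr3)
        assert not hp.is_empty
        assert hp.n_cross_hbonds >= 2
        a, b = sc.annotation.cdr3
        assert hp.strand1[0] >= a - 6 and hp.strand2[1] <= b + 2

    def test_folded_scaffold_has_no_hairpin(self, scaffolds_jittered):
        sc = scaffolds_jittered["folded"]
        chain = sc.structure.chains[0]
        bb = place_amide_hydrogens(backbone_from_chain(chain))
        hbonds = compute_hbonds(bb)
        hp = detect_hairpin(assign_ss(bb, hbonds), hbonds, sc.annotation.cdr3)
        assert hp.is_empty or hp.n_cross_hbonds < 2


class TestHBondInvariants:
    @given(d=st.integers(0, 50), a=st.integers(0, 50))
    def test_stored_bond_constraints(self, d, a):
        if d == a or abs(d - a) < 2:
            with pytest.raises(ValueError):
                HBond(donor=d, acceptor=a, energy=-1.0)
        else:
            bond = HBond(donor=d, acceptor=a, energy=-1.0)
            assert bond.energy < -0.5

    def test_weak_bond_rejected(self):
        with pytest.raises(ValueError):
            HBond(donor=0, acceptor=5, energy=-0.4)
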