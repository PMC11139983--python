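"""Kabsch superposition, RMSD matrix, clustering, CDR3 classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nbcensus import synthetic_data as sd
from nbcensus.pipeline import RunConfig, run_census
from nbcensus.shapecompare import (
    Cdr3Features,
    ClassThresholds,
    RmsdMatrix,
    build_rmsd_matrix,
    classify_cdr3,
    cluster_matrix,
    framework_rmsd,
    kabsch_superpose,
)

POINTS4 = np.array(
    [[0.0, 0.0, 0.0], [1.9, 0.2, -0.4], [0.7, 2.3, 0.5], [-0.8, 1.1, 1.9]]
)


def grid_rmsd_oracle(P, Q, coarse=20.0):
    """Brute-force minimal RMSD: Euler-angle grid then local refinement.

    Independent of the SVD route: explicit rotation search with optimal
    translation (centroid matching) at each candidate.
    """
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(angles):
        R = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return float(np.sqrt(((Pc @ R.T - Qc) ** 2).sum() / len(P)))

    grid = np.arange(-180.0, 180.0, coarse)
    best = min(
        (rmsd_of((a, b, c)), (a, b, c))
        for a in grid
        for b in np.arange(-90.0, 90.1, coarse)
        for c in grid
    )
    res = minimize(
        rmsd_of, best[1], method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-14, maxiter=20000),
    )
    return float(res.fun)


class TestKabsch:
    def test_identical_sets_zero_rmsd(self):
        sup = kabsch_superpose(POINTS4, POINTS4)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_applied_rigid_motion(self):
        R = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        t = np.array([3.0, -2.0, 7.0])
        moved = POINTS4 @ R.T + t
        sup = kabsch_superpose(POINTS4, moved)
        assert sup.rmsd < 1e-8
        np.testing.assert_allclose(sup.rotation, R, atol=1e-8)
        np.testing.assert_allclose(sup.translation, t, atol=1e-8)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(5)
        Q = POINTS4 + rng.normal(0, 0.4, POINTS4.shape)
        sup = kabsch_superpose(POINTS4, Q)
        np.testing.assert_allclose(
            sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8
        )
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(17)
        Q = POINTS4 + rng.normal(0, 0.35, POINTS4.shape)
        sup = kabsch_superpose(POINTS4, Q)
        assert sup.rmsd == pytest.approx(grid_rmsd_oracle(POINTS4, Q), abs=1e-6)

    def test_matches_independent_svd_superimposer(self):
        from Bio.SVDSuperimposer import SVDSuperimposer

        rng = np.random.default_rng(23)
        Q = POINTS4 + rng.normal(0, 0.5, POINTS4.shape)
        sup = kabsch_superpose(POINTS4, Q)
        ref = SVDSuperimposer()
        ref.set(Q, POINTS4)   # Biopython fits the second onto the first
        ref.run()
        assert sup.rmsd == pytest.approx(float(ref.get_rms()), abs=1e-9)

    @given(
        angles=st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
        shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    )
    def test_rmsd_invariant_under_common_rigid_motion(self, angles, shift):
        rng = np.random.default_rng(3)
        Q = POINTS4 + rng.normal(0, 0.3, POINTS4.shape)
        base = kabsch_superpose(POINTS4, Q).rmsd
        R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        t = np.asarray(shift)
        moved = kabsch_superpose(POINTS4 @ R.T + t, Q @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [POINTS4[:2], np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])],
        ids=["too_few", "collinear"],
    )
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            kabsch_superpose(bad, bad + 1.0)


class TestFrameworkRmsd:
    def test_self_comparison_is_zero(self, scaffolds_jittered):
        sc = scaffolds_jittered["extended"]
        r = framework_rmsd(sc.structure, sc.annotation, sc.structure, sc.annotation)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_scaffolds_identical(self):
        a = sd.gen_scaffold(sd.ScaffoldSpec("extended", seed=12, jitter_sd=0.3))
        b = sd.gen_scaffold(sd.ScaffoldSpec("extended", seed=12, jitter_sd=0.3))
        assert framework_rmsd(a.structure, a.annotation, b.structure, b.annotation) < 0.1

    def test_between_class_dominates_within_class(self):
        ext1 = sd.gen_scaffold(sd.ScaffoldSpec("extended", cdr3_length=14, seed=1, jitter_sd=0.3))
        ext2 = sd.gen_scaffold(sd.ScaffoldSpec("extended", cdr3_length=14, seed=2, jitter_sd=0.3))
        fold = sd.gen_scaffold(sd.ScaffoldSpec("folded", cdr3_length=14, seed=3, jitter_sd=0.3))
        within = framework_rmsd(ext1.structure, ext1.annotation, ext2.structure, ext2.annotation)
        between = framework_rmsd(ext1.structure, ext1.annotation, fold.structure, fold.annotation)
        assert between >= 2.0
        assert between >= 5.0 * within

    def test_too_few_matched_framework_positions_refused(self, scaffolds_jittered):
        from nbcensus.structio import Chain, Structure

        sc = scaffolds_jittered["short"]
        # truncated domain: only FR1 survives -> < 40 framework C-alphas
        stub = Structure(
            label="stub",
            chains=[Chain(id="A", residues=sc.structure.chains[0].residues[:30])],
        )
        with pytest.raises(ValueError, match="matched framework"):
            framework_rmsd(stub, sc.annotation, stub, sc.annotation)


class TestMatrix:
    def test_identical_structures_zero_matrix(self, scaffolds_jittered):
        sc = scaffolds_jittered["folded"]
        entries = [(f"s{i}", sc.structure, sc.annotation) for i in range(3)]
        m = build_rmsd_matrix(entries)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-9)

    def test_matrix_matches_direct_pairwise_calls(self, small_census):
        scaffolds, _ = small_census
        entries = [(s.structure.label, s.structure, s.annotation) for s in scaffolds]
        m = build_rmsd_matrix(entries)
        # invariants
        assert np.allclose(m.values, m.values.T, atol=1e-6)
        assert np.allclose(np.diag(m.values), 0.0)
        # spot-check against direct recomputation
        for i, j in [(0, 1), (2, 5), (3, 4)]:
            direct = framework_rmsd(
                entries[i][1], entries[i][2], entries[j][1], entries[j][2]
            )
            assert m.values[i, j] == pytest.approx(direct, abs=1e-9)

    def test_within_class_smaller_than_between(self, small_census):
        scaffolds, truth = small_census
        entries = [(s.structure.label, s.structure, s.annotation) for s in scaffolds]
        m = build_rmsd_matrix(entries)
        classes = dict(zip(truth["label"], truth["true_class"]))
        within, between = [], []
        for i, j in itertools.combinations(range(len(entries)), 2):
            (within if classes[m.labels[i]] == classes[m.labels[j]] else between).append(
                m.values[i, j]
            )
        assert max(within) < min(between)

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            RmsdMatrix(labels=["a", "b"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestClustering:
    @staticmethod
    def exhaustive_partition_oracle(values, k=3):
        """Minimal within-cluster pairwise-sum over all k-partitions."""
        n = len(values)
        best = None
        for assignment in itertools.product(range(k), repeat=n):
            if len(set(assignment)) != k:
                continue
            cost = sum(
                values[i, j]
                for i, j in itertools.combinations(range(n), 2)
                if assignment[i] == assignment[j]
            )
            if best is None or cost < best[0]:
                best = (cost, assignment)
        return best[1]

    def test_recovers_ground_truth_partition(self, small_census):
        scaffolds, truth = small_census
        entries = [(s.structure.label, s.structure, s.annotation) for s in scaffolds]
        m = build_rmsd_matrix(entries)
        got = cluster_matrix(m, k=3)
        oracle = self.exhaustive_partition_oracle(m.values, k=3)
        truth_map = dict(zip(truth["label"], truth["true_class"]))

        def as_partition(labels_to_ids):
            groups = {}
            for lbl, cid in labels_to_ids.items():
                groups.setdefault(cid, set()).add(lbl)
            return {frozenset(g) for g in groups.values()}

        got_p = as_partition(got)
        oracle_p = as_partition({m.labels[i]: c for i, c in enumerate(oracle)})
        truth_p = as_partition({lbl: truth_map[lbl] for lbl in m.labels})
        assert got_p == oracle_p == truth_p

    def test_k_extremes(self, small_census):
        scaffolds, _ = small_census
        entries = [(s.structure.label, s.structure, s.annotation) for s in scaffolds]
        m = build_rmsd_matrix(entries)
        assert set(cluster_matrix(m, k=1).values()) == {1}
        assert len(set(cluster_matrix(m, k=len(entries)).values())) == len(entries)
        with pytest.raises(ValueError):
            cluster_matrix(m, k=len(entries) + 1)


class TestClassification:
    def test_rule_boundaries(self):
        t = ClassThresholds()
        short = Cdr3Features(length=7, n_cross_hbonds=5, protrusion=20.0,
                             framework_contact_fraction=0.0)
        assert classify_cdr3(short, t).label == "short"
        ext = Cdr3Features(length=8, n_cross_hbonds=2, protrusion=5.0,
                           framework_contact_fraction=0.3)
        assert classify_cdr3(ext, t).label == "extended"
        for breaker in (
            dict(n_cross_hbonds=1), dict(protrusion=4.9),
            dict(framework_contact_fraction=0.31),
        ):
            feats = Cdr3Features(
                **{
                    "length": 8, "n_cross_hbonds": 2, "protrusion": 5.0,
                    "framework_contact_fraction": 0.3, **breaker,
                }
            )
            assert classify_cdr3(feats, t).label == "folded_back"

    def test_rationale_names_fired_rule(self):
        feats = Cdr3Features(length=5, n_cross_hbonds=0, protrusion=0.0,
                             framework_contact_fraction=0.0)
        assert "length" in classify_cdr3(feats).rationale

    def test_feature_invariants(self):
        with pytest.raises(ValueError):
            Cdr3Features(length=10, n_cross_hbonds=0, protrusion=np.inf,
                         framework_contact_fraction=0.0)
        with pytest.raises(ValueError):
            Cdr3Features(length=10, n_cross_hbonds=0, protrusion=0.0,
                         framework_contact_fraction=1.2)

    def test_balanced_census_full_recovery_and_agreement(self, small_census):
        """Classifier and clustering agree with truth on the balanced census."""
        from sklearn.metrics import adjusted_rand_score

        scaffolds, truth = small_census
        report = run_census(
            [(s.structure.label, s.structure) for s in scaffolds], RunConfig()
        )
        merged = report.table.merge(truth, on="label")
        assert (merged["cdr3_class"] == merged["true_class"]).all()
        assert adjusted_rand_score(merged["true_class"], merged["cluster"]) == 1.0
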