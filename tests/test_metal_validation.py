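"""Bond-valence scores Q_v, Q_c, Q_e and site validation thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import znsite as z
from znsite.metal_validation import (BondValenceVector, DEFAULT_CONFIG,
                                     coordination_sphere)

from conftest import donor_structure, random_rotation, transform_structure

TET_DIRS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                    dtype=float) / math.sqrt(3)


def vectors_at(dirs, magnitude, occ=1.0, b=20.0):
    """Bond-valence vectors along given directions with donor bookkeeping."""
    out = []
    for i, d in enumerate(np.atleast_2d(dirs)):
        donor = donor_structure(
            [("CYS", "SG", "S", 2.3 * np.asarray(d), occ, b)]
        ).find_residue(("A", 1, "")).atoms[0]
        out.append(BondValenceVector(magnitude, np.asarray(d, float), donor))
    return out


class TestBondValence:
    @pytest.mark.parametrize("d, element, expected", [
        (2.09, "S", 1.0),                     # d = R0(Zn-S)
        (2.30, "S", math.exp((2.09 - 2.30) / 0.37)),   # 0.5665
        (2.10, "N", math.exp((1.77 - 2.10) / 0.37)),   # 0.4099
        (1.704, "O", 1.0),
    ])
    def test_exponential_form(self, d, element, expected):
        assert z.bond_valence(d, element) == pytest.approx(expected, rel=1e-6)

    def test_reference_values(self):
        assert z.bond_valence(2.30, "S") == pytest.approx(0.5669, abs=1e-4)
        assert z.bond_valence(2.10, "N") == pytest.approx(0.4099, abs=1e-4)

    def test_unknown_pair_raises(self):
        with pytest.raises(KeyError):
            z.bond_valence(2.0, "S", metal="XX")

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            z.bond_valence(0.0, "S")


class TestCoordinationSphere:
    def test_four_tetrahedral_sg(self):
        entries = [("CYS", "SG", "S", 2.3 * d) for d in TET_DIRS]
        sphere = coordination_sphere(donor_structure(entries), np.zeros(3))
        assert len(sphere) == 4
        for v in sphere:
            assert v.magnitude == pytest.approx(0.5669, abs=1e-4)
            assert np.linalg.norm(v.direction) == pytest.approx(1.0)

    def test_empty_when_no_donors_in_cutoff(self):
        st_ = donor_structure([("CYS", "SG", "S", [4.0, 0, 0])])
        assert coordination_sphere(st_, np.zeros(3)) == []

    def test_carbon_excluded(self):
        st_ = donor_structure([("ALA", "CB", "C", [2.0, 0, 0])])
        assert coordination_sphere(st_, np.zeros(3)) == []

    def test_one_donor_per_residue(self):
        # two atoms of the same residue: only the closest counts
        from znsite.structure_io import AtomRecord, Chain, Residue, Structure
        res = Residue("GLU", 1, "", "A")
        res.atoms.append(AtomRecord(1, "OE1", "", "GLU", "A", 1, "",
                                    np.array([2.0, 0, 0]), 1.0, 20.0, "O", False))
        res.atoms.append(AtomRecord(2, "OE2", "", "GLU", "A", 1, "",
                                    np.array([2.4, 0, 0]), 1.0, 20.0, "O", False))
        st_ = Structure("t", [Chain("A", [res])])
        sphere = coordination_sphere(st_, np.zeros(3))
        assert len(sphere) == 1 and sphere[0].donor.name == "OE1"


class TestQValence:
    @pytest.mark.parametrize("s, v_ox, expected", [
        (2.0, 2.0, 1.0),
        (1.0, 2.0, 0.5),   # two-ligand optimum
        (4.0, 2.0, 0.5),
    ])
    def test_values(self, s, v_ox, expected):
        assert z.q_valence([s], v_ox) == pytest.approx(expected)

    def test_zero_sum_scores_zero(self):
        assert z.q_valence([], 2.0) == 0.0

    def test_negative_valence_rejected(self):
        with pytest.raises(ValueError):
            z.q_valence([-0.1], 2.0)

    @given(st.lists(st.floats(0.01, 2.0), min_size=1, max_size=6),
           st.floats(0.5, 4.0))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_and_permutation_invariant(self, vals, v_ox):
        q = z.q_valence(vals, v_ox)
        assert 0.0 <= q <= 1.0
        assert q == pytest.approx(z.q_valence(vals[::-1], v_ox))


class TestQCompleteness:
    def test_tetrahedral_cancels(self):
        vecs = vectors_at(TET_DIRS, 0.5665)
        assert z.q_completeness(vecs) == pytest.approx(1.0, abs=1e-9)

    def test_two_ligand_valence_sum_normalization(self):
        a = math.radians(109.47)
        dirs = [[0, 0, 1], [math.sin(a), 0, math.cos(a)]]
        vecs = vectors_at(dirs, 0.5)
        # resultant 2*0.5*cos(54.735 deg) = 0.577
        assert z.q_completeness(vecs, "valence_sum") == pytest.approx(0.423, abs=2e-3)

    def test_two_ligand_oxidation_state_normalization(self):
        a = math.radians(109.47)
        dirs = [[0, 0, 1], [math.sin(a), 0, math.cos(a)]]
        vecs = vectors_at(dirs, 0.5)
        assert z.q_completeness(vecs, "oxidation_state", 2.0) == \
            pytest.approx(0.71, abs=5e-3)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(3, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        vecs = vectors_at(dirs, 0.6)
        rot = random_rotation(rng)
        rotated = vectors_at(dirs @ rot.T, 0.6)
        assert z.q_completeness(vecs) == pytest.approx(
            z.q_completeness(rotated), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            z.q_completeness([])


class TestQEnvironment:
    def test_identity_case(self):
        vecs = vectors_at(TET_DIRS, 0.5, occ=1.0, b=30.0)
        assert z.q_environment(1.0, 30.0, vecs) == pytest.approx(1.0)

    def test_b_factor_mismatch(self):
        vecs = vectors_at(TET_DIRS, 0.5, occ=1.0, b=15.0)
        assert z.q_environment(1.0, 30.0, vecs) == pytest.approx(0.5)

    def test_low_metal_occupancy(self):
        # occupancy factor min(2*0.4, 1) = 0.8 times the product-ratio
        # factor min(0.4/1.0, 1.0/0.4) = 0.4
        vecs = vectors_at(TET_DIRS, 0.5, occ=1.0, b=20.0)
        assert z.q_environment(0.4, 20.0, vecs) == pytest.approx(0.32)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            z.q_environment(1.0, 20.0, [])


class TestValidateSite:
    def test_ideal_cys4_site_passes(self):
        entries = [("CYS", "SG", "S", 2.3 * d) for d in TET_DIRS]
        scores = z.validate_site(donor_structure(entries), np.zeros(3))
        # sum V = 4 * 0.5665 = 2.266 -> Qv = min(1.133, 0.883) = 0.883
        assert scores.q_valence == pytest.approx(0.883, abs=2e-3)
        assert scores.q_completeness == pytest.approx(1.0, abs=1e-6)
        assert scores.q_environment == pytest.approx(1.0, abs=1e-6)
        assert scores.n_ligands == 4 and scores.passed

    def test_two_ligand_thresholds(self):
        # n = 2 passes at the relaxed thresholds 0.25 / 0.355 / 0.5
        thr2 = DEFAULT_CONFIG.thresholds["2"]
        assert thr2 == (0.25, 0.355, 0.5)
        a = math.radians(109.47)
        entries = [("CYS", "SG", "S", [0, 0, 2.1]),
                   ("CYS", "SG", "S",
                    2.1 * np.array([math.sin(a), 0, math.cos(a)]))]
        scores = z.validate_site(donor_structure(entries), np.zeros(3))
        assert scores.n_ligands == 2
        assert scores.passed  # near-optimal two-ligand geometry

    def test_single_donor_never_passes(self):
        st_ = donor_structure([("CYS", "SG", "S", [0, 0, 2.1])])
        scores = z.validate_site(st_, np.zeros(3))
        assert scores.n_ligands == 1 and not scores.passed

    def test_scores_bounded_under_random_geometries(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 7))
            dirs = rng.normal(size=(n, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            radii = rng.uniform(1.8, 2.5, n)
            entries = [("CYS", "SG", "S", r * d,
                        float(rng.uniform(0.2, 1.0)),
                        float(rng.uniform(5.0, 60.0)))
                       for r, d in zip(radii, dirs)]
            s = z.validate_site(donor_structure(entries), np.zeros(3))
            for q in (s.q_valence, s.q_completeness, s.q_environment):
                assert 0.0 <= q <= 1.0

    def test_radial_outward_move_never_increases_valence_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            dirs = rng.normal(size=(4, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            radii = rng.uniform(2.0, 2.4, 4)
            def vsum(rr):
                entries = [("CYS", "SG", "S", r * d) for r, d in zip(rr, dirs)]
                sphere = coordination_sphere(donor_structure(entries), np.zeros(3))
                return sum(v.magnitude for v in sphere)
            moved = radii.copy()
            moved[0] += rng.uniform(0.0, 0.3)
            assert vsum(moved) <= vsum(radii) + 1e-12
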