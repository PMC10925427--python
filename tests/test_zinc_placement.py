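"""Subgroup placement strategies: recovery, oracles, equivariance."""

import itertools
import math

import numpy as np
import pytest

import znsite as z
from znsite.zinc_placement import (ANGLE_TARGETS, CIRCLE_RADIUS,
                                   closest_pair_midpoint, ring_centroid)
from znsite.structure_io import Residue, AtomRecord

from conftest import (ALL_SUBGROUPS, random_rotation, single_site,
                      transform_structure)


class TestRecovery:
    @pytest.mark.parametrize("subgroup", ALL_SUBGROUPS)
    def test_noise_free_recovery_within_015(self, subgroup, make_site):
        structure, zn, _ = make_site(subgroup, seed=1)
        placed = z.place_zinc(single_site(structure, subgroup))
        assert np.linalg.norm(placed.zinc_position - zn) <= 0.15

    @pytest.mark.parametrize("subgroup, strategy", [
        ("CC", "a"), ("CH", "b"), ("HH", "c"),
        ("HHH", "d"), ("CH3_mixed", "e"), ("CH4", "f"),
    ])
    def test_dispatch(self, subgroup, strategy, make_site):
        structure, _, _ = make_site(subgroup, seed=0)
        placed = z.place_zinc(single_site(structure, subgroup))
        assert placed.placement_strategy == strategy


def exhaustive_circle_scan(site):
    """Independent 3600-point scan of the two-ligand zinc locus."""
    l1, l2 = [ca.atom.position for ca in site.chosen_atoms]
    cb1, cb2 = [ca.residue.get_atom("CB").position for ca in site.chosen_atoms]
    t1, t2 = [ANGLE_TARGETS[ca.atom_role] for ca in site.chosen_atoms]
    e2 = (l1 + l2) / 2.0
    axis = (l2 - l1) / np.linalg.norm(l2 - l1)
    # Gram-Schmidt basis, intentionally different from the implementation's
    seed_vec = np.array([0.3, -0.7, 0.64])
    u = seed_vec - np.dot(seed_vec, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    def angle(p, vertex, q):
        a, b = p - vertex, q - vertex
        c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        return math.degrees(math.acos(np.clip(c, -1, 1)))

    best, best_score = None, math.inf
    for theta in np.linspace(0, 2 * math.pi, 3600, endpoint=False):
        p = e2 + CIRCLE_RADIUS * (math.cos(theta) * u + math.sin(theta) * v)
        if np.dot(p - l1, cb1 - l1) > 0 or np.dot(p - l2, cb2 - l2) > 0:
            continue
        s = (angle(p, l1, cb1) - t1) ** 2 + (angle(p, l2, cb2) - t2) ** 2
        if s < best_score:
            best, best_score = p, s
    return best


class TestPairStrategies:
    @pytest.mark.parametrize("subgroup", ["CC", "CH"])
    def test_agrees_with_exhaustive_scan(self, subgroup, make_site):
        structure, _, _ = make_site(subgroup, seed=4, noise_sd=0.05)
        site = single_site(structure, subgroup)
        placed = z.place_zinc(site)
        oracle = exhaustive_circle_scan(site)
        assert np.linalg.norm(placed.zinc_position - oracle) <= 0.05

    def test_mirror_symmetric_cc_lands_in_symmetry_plane(self, make_site):
        structure, zn, _ = make_site("CC", seed=0)
        site = single_site(structure, "CC")
        l1, l2 = [ca.atom.position for ca in site.chosen_atoms]
        axis = (l2 - l1) / np.linalg.norm(l2 - l1)
        placed = z.place_cc(site)
        # solution lies in the plane perpendicular to SG-SG at the midpoint
        assert abs(np.dot(placed.zinc_position - (l1 + l2) / 2, axis)) < 1e-6

    def test_result_on_distal_side_of_cb(self, make_site):
        structure, _, _ = make_site("CC", seed=2)
        site = single_site(structure, "CC")
        placed = z.place_cc(site)
        for ca in site.chosen_atoms:
            cb = ca.residue.get_atom("CB").position
            lig = ca.atom.position
            assert np.dot(placed.zinc_position - lig, cb - lig) <= 1e-9

    def test_missing_cb_falls_back_to_midpoint(self, make_site):
        structure, _, _ = make_site("CC", seed=0)
        for res in structure.residues():
            res.atoms = [a for a in res.atoms if a.name != "CB"]
        site = single_site(structure, "CC")
        placed = z.place_cc(site)
        l1, l2 = [ca.atom.position for ca in site.chosen_atoms]
        assert np.allclose(placed.zinc_position, (l1 + l2) / 2)
        assert any("fallback" in f for f in placed.flags)


def pentagon_residue(center, radius=1.3700, normal=(0, 0, 1.0)):
    """Idealized imidazole: regular pentagon of the five ring atoms."""
    normal = np.asarray(normal) / np.linalg.norm(normal)
    helper = np.array([1.0, 0, 0])
    u = helper - np.dot(helper, normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    res = Residue("HIS", 1, "", "A")
    circ = radius / (2 * math.sin(math.pi / 5))
    for i, name in enumerate(("CG", "ND1", "CE1", "NE2", "CD2")):
        ang = 2 * math.pi * i / 5
        pos = np.asarray(center) + circ * (math.cos(ang) * u + math.sin(ang) * v)
        res.atoms.append(AtomRecord(i + 1, name, "", "HIS", "A", 1, "",
                                    pos, 1.0, 20.0, name[0], False))
    return res


class TestRingCentroid:
    def test_regular_pentagon_center(self):
        center = np.array([3.0, -1.0, 2.0])
        res = pentagon_residue(center)
        assert np.allclose(ring_centroid(res), center, atol=1e-12)

    def test_translation_equivariance(self):
        res = pentagon_residue([0, 0, 0])
        g0 = ring_centroid(res)
        for a in res.atoms:
            a.position = a.position + np.array([1.0, 2.0, 3.0])
        assert np.allclose(ring_centroid(res) - g0, [1, 2, 3])

    def test_circumradius_of_ideal_imidazole(self):
        res = pentagon_residue([0, 0, 0])
        g = ring_centroid(res)
        expected = 1.37 / (2 * math.sin(math.radians(36)))
        for a in res.atoms:
            assert np.linalg.norm(a.position - g) == pytest.approx(expected,
                                                                   abs=1e-6)

    def test_missing_ring_atom_raises(self):
        res = pentagon_residue([0, 0, 0])
        res.atoms = res.atoms[:-1]
        with pytest.raises(z.PlacementError):
            ring_centroid(res)


class TestHHFamily:
    def test_intersecting_rays_recover_common_point(self, make_site):
        # generator aims both NE2 rays at the zinc: the placement is exact
        structure, zn, _ = make_site("HH", seed=3)
        placed = z.place_hh(single_site(structure, "HH"))
        assert np.linalg.norm(placed.zinc_position - zn) < 1e-9

    def test_swap_ring_labels_same_result(self, make_site):
        structure, _, _ = make_site("HH", seed=3)
        site = single_site(structure, "HH")
        p1 = z.place_hh(site)
        site.residues.reverse()
        site.chosen_atoms.reverse()
        p2 = z.place_hh(site)
        assert np.allclose(p1.zinc_position, p2.zinc_position, atol=1e-12)

    def test_hhh_mean_of_pairwise(self, make_site):
        structure, _, _ = make_site("HHH", seed=2, noise_sd=0.05)
        site = single_site(structure, "HHH")
        from znsite.zinc_placement import _hh_pair_position
        expected = np.mean([
            _hh_pair_position(r1, r2)
            for r1, r2 in itertools.combinations(site.residues, 2)], axis=0)
        assert np.allclose(z.place_hhh(site).zinc_position, expected)

    def test_hhh_threefold_symmetry_axis(self, make_site):
        # three ligands from the generator have C3 symmetry about the
        # missing tetrahedral vertex: the placement must lie on that axis
        structure, zn, _ = make_site("HHH", seed=0)
        placed = z.place_hhh(single_site(structure, "HHH"))
        axis = -np.array([-1.0, -1.0, 1.0]) / math.sqrt(3)  # -t4
        rel = placed.zinc_position - zn
        assert np.linalg.norm(rel - np.dot(rel, axis) * axis) < 1e-6

    def test_lipschitz_under_small_perturbation(self, make_site):
        structure, _, _ = make_site("HHH", seed=5)
        site = single_site(structure, "HHH")
        base = z.place_hhh(site).zinc_position
        res = site.residues[0]
        for a in res.atoms:
            a.position = a.position + np.array([0.1, 0.0, 0.0])
        moved = z.place_hhh(site).zinc_position
        assert np.linalg.norm(moved - base) <= 0.1 + 1e-9


class TestVoteAndCentroid:
    def test_closest_pair_midpoint_vote(self):
        cands = [np.zeros(3), np.array([0.1, 0, 0]), np.array([5.0, 0, 0])]
        assert np.allclose(closest_pair_midpoint(cands), [0.05, 0, 0])

    def test_coincident_candidates(self):
        p = np.array([1.0, 2.0, 3.0])
        assert np.allclose(closest_pair_midpoint([p, p, p + 4]), p)

    def test_mixed_ch3_ignores_rotamer_outlier(self, make_site):
        structure, zn, _ = make_site("CH3_mixed", seed=1)
        site = single_site(structure, "CH3_mixed")
        # displace one cysteine SG as a bad rotamer (still in-window)
        cys = next(ca for ca in site.chosen_atoms if ca.residue_kind == "CYS")
        cys.atom.position = cys.atom.position + np.array([0.0, 0.9, 0.0])
        placed = z.place_ch3_mixed(site)
        assert np.linalg.norm(placed.zinc_position - zn) <= 0.5

    def test_ch4_centroid(self):
        from conftest import donor_structure
        corners = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                           dtype=float) / math.sqrt(3) * 2.1
        st_ = donor_structure([("CYS", "SG", "S", c) for c in corners])
        sites = z.enumerate_sites(z.coordinating_atoms(st_))
        placed = z.place_ch4(sites[0])
        assert np.allclose(placed.zinc_position, [0, 0, 0], atol=1e-12)

    def test_unclassified_site_rejected(self, make_site):
        structure, _, _ = make_site("CC", seed=0)
        site = single_site(structure, "CC")
        site.subgroup = "XX"
        with pytest.raises(ValueError):
            z.place_zinc(site)


class TestEquivariance:
    @pytest.mark.parametrize("subgroup", ALL_SUBGROUPS)
    def test_rigid_motion_equivariance(self, subgroup, make_site):
        structure, _, _ = make_site(subgroup, seed=6, noise_sd=0.03)
        p0 = z.place_zinc(single_site(structure, subgroup)).zinc_position
        rng = np.random.default_rng(11)
        rot = random_rotation(rng)
        shift = rng.uniform(-20, 20, 3)
        moved = transform_structure(structure, rot, shift)
        p1 = z.place_zinc(single_site(moved, subgroup)).zinc_position
        assert np.linalg.norm(p1 - (rot @ p0 + shift)) < 1e-6
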