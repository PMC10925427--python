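"""Shared fixtures: generated coordination spheres, reference curves and a
trained CH2 ensemble (session-scoped — training is the slow part)."""

from __future__ import annotations

import copy

import numpy as np
import pytest

import znsite as z
from znsite import synthetic_fixtures as sf
from znsite.structure_io import AtomRecord, Chain, Residue, Structure

ALL_SUBGROUPS = ("CC", "CH", "HH", "HHH", "CH3_mixed", "CH4")


@pytest.fixture(scope="session")
def reference_curves() -> z.ReferenceCurves:
    """Group reference curves built from noise-free-ish generator sites."""
    sites = []
    for sub, group in (("HHH", "CH3"), ("CH3_mixed", "CH3"), ("CH4", "CH4")):
        for seed in range(3):
            st, zn, _ = sf.make_site_structure(
                sf.FixtureSpec(subgroup=sub, seed=seed, noise_sd=0.05))
            sites.append((st, zn, group))
    for sub in ("CC", "CH", "HH"):
        for seed in range(2):
            st, zn, _ = sf.make_site_structure(
                sf.FixtureSpec(subgroup=sub, seed=seed, noise_sd=0.05))
            sites.append((st, zn, "CH2"))
    return z.build_reference_curves(sites)


@pytest.fixture(scope="session")
def ch2_model() -> z.EnsembleModel:
    """Ensemble trained on features encoded from generated structures."""
    pos, neg = sf.make_encoded_ch2_dataset(40, seed=5)
    return z.train_ensemble(pos, neg, seed=5)


@pytest.fixture
def make_site():
    """Factory: (subgroup, **spec overrides) -> (structure, zn, labels)."""

    def build(subgroup: str, **kwargs):
        spec = sf.FixtureSpec(subgroup=subgroup, **kwargs)
        return sf.make_site_structure(spec)

    return build


def single_site(structure, subgroup=None):
    """The one candidate site enumerated from a fixture structure."""
    sites = z.enumerate_sites(z.coordinating_atoms(structure))
    if subgroup is not None:
        sites = [s for s in sites if s.subgroup == subgroup]
    assert len(sites) == 1, f"expected one site, got {len(sites)}"
    return sites[0]


def donor_structure(entries) -> Structure:
    """Minimal structure from (res_name, atom_name, element, position[,occ,b])."""
    chain = Chain("A")
    for i, entry in enumerate(entries):
        res_name, name, element, pos = entry[:4]
        occ = entry[4] if len(entry) > 4 else 1.0
        b = entry[5] if len(entry) > 5 else 20.0
        res = Residue(res_name, i + 1, "", "A")
        res.atoms.append(AtomRecord(i + 1, name, "", res_name, "A", i + 1,
                                    "", np.asarray(pos, float), occ, b,
                                    element, False))
        chain.residues.append(res)
    return Structure(id="test", chains=[chain])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_structure(structure: Structure, rot: np.ndarray,
                        shift: np.ndarray) -> Structure:
    """Rigid-body copy: positions -> rot @ p + shift."""
    out = copy.deepcopy(structure)
    for atom in out.atoms():
        atom.position = rot @ atom.position + shift
    return out
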