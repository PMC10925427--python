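"""Geometric enumeration of candidate zinc-binding sites.

Zinc in proteins is overwhelmingly coordinated by cysteine sulfur and
histidine ring nitrogens.  The search therefore considers SG from CYS and
ND1/NE2/CE1/CD2 from HIS (the ring carbons are admitted because deposited
rings are frequently flipped or mislabelled), requires every residue pair
of a site to present an atom pair within the 2.4-4.5 Å window, and rejects
Cys pairs whose SG-SG distance marks a disulfide bond (< 2.400 Å, the
upper confidence bound of the disulfide distance peak at
mu = 2.058 Å, sigma = 0.133, Z = 2.575).

Sites of 2-4 residues are grouped as CH2 / CH3 / CH4 (regulatory,
catalytic, structural zinc respectively) and subtyped by residue
composition: CC/CH/HH pairs, HHH vs mixed triples, CH4 quadruples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .structure_io import AtomRecord, Residue, Structure

__all__ = [
    "CoordAtom",
    "CandidateSite",
    "DISTANCE_WINDOW",
    "DISULFIDE_CUTOFF",
    "HIS_RING_ROLES",
    "coordinating_atoms",
    "is_disulfide",
    "enumerate_sites",
    "classify_subgroup",
]

DISTANCE_WINDOW = (2.4, 4.5)
DISULFIDE_CUTOFF = 2.400
HIS_RING_ROLES = ("ND1", "NE2", "CE1", "CD2")


@dataclass
class CoordAtom:
    """A candidate coordinating atom with its parent residue."""

    atom: AtomRecord
    residue: Residue
    residue_kind: str  # CYS or HIS
    atom_role: str     # SG / ND1 / NE2 / CE1 / CD2

    def residue_key(self) -> tuple:
        return self.residue.key()


@dataclass
class CandidateSite:
    """2-4 residues whose chosen atoms satisfy the pairwise window."""

    residues: list[Residue]
    chosen_atoms: list[CoordAtom]
    group: str       # CH2 / CH3 / CH4
    subgroup: str    # CC / CH / HH / HHH / CH3_mixed / CH4
    cross_chain: bool = False

    def residue_keys(self) -> frozenset:
        return frozenset(r.key() for r in self.residues)

    def composition(self) -> str:
        return "".join(sorted("C" if ca.residue_kind == "CYS" else "H"
                              for ca in self.chosen_atoms))


def coordinating_atoms(structure: Structure,
                       chains: Optional[Iterable[str]] = None,
                       ) -> list[CoordAtom]:
    """Every qualifying CYS SG / HIS ring atom, optionally chain-filtered.

    Residues flagged multi-conformational still contribute (prediction is
    allowed on them; only training-set extraction excludes them).
    Truncated side chains contribute whatever qualifying atoms remain.
    """
    selected = set(chains) if chains is not None else None
    out: list[CoordAtom] = []
    for res in structure.residues():
        if selected is not None and res.chain_id not in selected:
            continue
        if res.res_name == "CYS":
            sg = res.get_atom("SG")
            if sg is not None and not sg.is_hydrogen:
                out.append(CoordAtom(sg, res, "CYS", "SG"))
        elif res.res_name == "HIS":
            for role in HIS_RING_ROLES:
                a = res.get_atom(role)
                if a is not None:
                    out.append(CoordAtom(a, res, "HIS", role))
    return out


def is_disulfide(sg1: AtomRecord, sg2: AtomRecord) -> bool:
    """True iff two cysteine SG atoms are within covalent S-S distance."""
    if sg1.name != "SG" or sg2.name != "SG":
        raise ValueError("is_disulfide expects two SG atoms")
    return float(np.linalg.norm(sg1.position - sg2.position)) < DISULFIDE_CUTOFF


def _pair_in_window(ca1: CoordAtom, ca2: CoordAtom,
                    window: tuple[float, float]) -> bool:
    d = float(np.linalg.norm(ca1.atom.position - ca2.atom.position))
    if not (window[0] <= d <= window[1]):
        return False
    if ca1.atom_role == "SG" and ca2.atom_role == "SG" and is_disulfide(ca1.atom, ca2.atom):
        return False
    return True


def _residues_compatible(atoms1: Sequence[CoordAtom], atoms2: Sequence[CoordAtom],
                         window: tuple[float, float]) -> bool:
    """Residues are graph-compatible if ANY allowed atom pair is in-window."""
    return any(_pair_in_window(a, b, window)
               for a in atoms1 for b in atoms2)


def _choose_atoms(residue_atoms: list[list[CoordAtom]]) -> list[CoordAtom]:
    """Pick one coordinating atom per residue.

    CYS always contributes SG.  For HIS the atom minimizing the summed
    distance to the other residues' chosen atoms is selected, iterated to a
    fixed point (at most 3 passes).
    """
    chosen = []
    for atoms in residue_atoms:
        ne2 = next((a for a in atoms if a.atom_role == "NE2"), None)
        chosen.append(ne2 if ne2 is not None else atoms[0])
    for _ in range(3):
        changed = False
        for i, atoms in enumerate(residue_atoms):
            if len(atoms) == 1:
                continue
            others = [c.atom.position for j, c in enumerate(chosen) if j != i]

            def cost(ca: CoordAtom) -> float:
                return sum(float(np.linalg.norm(ca.atom.position - p))
                           for p in others)

            best = min(atoms, key=cost)
            if best is not chosen[i]:
                chosen[i] = best
                changed = True
        if not changed:
            break
    return chosen


def classify_subgroup(residue_kinds: Sequence[str]) -> tuple[str, str]:
    """Group (CH2/CH3/CH4) and subgroup from the residue composition."""
    n = len(residue_kinds)
    n_cys = sum(1 for k in residue_kinds if k == "CYS")
    if n == 2:
        sub = {2: "CC", 1: "CH", 0: "HH"}[n_cys]
        return "CH2", sub
    if n == 3:
        return "CH3", ("HHH" if n_cys == 0 else "CH3_mixed")
    if n == 4:
        return "CH4", "CH4"
    raise ValueError(f"site must have 2-4 residues, got {n}")


def enumerate_sites(atoms: Sequence[CoordAtom],
                    window: tuple[float, float] = DISTANCE_WINDOW,
                    ) -> list[CandidateSite]:
    """Enumerate candidate sites from the coordinating-atom pool.

    Builds a residue compatibility graph (edge when any allowed atom pair is
    in-window and not a disulfide), emits maximal cliques of size 2-4 plus
    every 4-subset of larger cliques, chooses one atom per residue, and
    keeps only sites whose chosen atoms satisfy the window pairwise.
    Subsets of an emitted larger residue set are suppressed.
    """
    by_res: dict[tuple, list[CoordAtom]] = {}
    for ca in atoms:
        by_res.setdefault(ca.residue_key(), []).append(ca)
    keys = sorted(by_res)
    g = nx.Graph()
    g.add_nodes_from(keys)
    for k1, k2 in itertools.combinations(keys, 2):
        if _residues_compatible(by_res[k1], by_res[k2], window):
            g.add_edge(k1, k2)

    candidate_sets: set[frozenset] = set()
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        if len(clique) <= 4:
            candidate_sets.add(frozenset(clique))
        else:
            for sub in itertools.combinations(sorted(clique), 4):
                candidate_sets.add(frozenset(sub))
    # suppress residue sets contained in a larger emitted set
    kept = [s for s in candidate_sets
            if not any(s < t for t in candidate_sets)]

    sites: list[CandidateSite] = []
    for keyset in sorted(kept, key=lambda s: sorted(s)):
        ordered = sorted(keyset)
        residue_atoms = [by_res[k] for k in ordered]
        chosen = _choose_atoms(residue_atoms)
        if not all(_pair_in_window(a, b, window)
                   for a, b in itertools.combinations(chosen, 2)):
            continue
        kinds = [c.residue_kind for c in chosen]
        group, subgroup = classify_subgroup(kinds)
        residues = [c.residue for c in chosen]
        sites.append(CandidateSite(
            residues=residues,
            chosen_atoms=chosen,
            group=group,
            subgroup=subgroup,
            cross_chain=len({r.chain_id for r in residues}) > 1,
        ))
    return sites
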