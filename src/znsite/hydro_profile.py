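"""Hydrophobicity-contrast and mean atomic-solvation radial profiles.

Buried metal sites show a characteristic radial arrangement: a hydrophilic
shell of N/O/S donors immediately around the ion, wrapped in a larger
hydrophobic carbon shell.  Around a putative zinc position this module
evaluates, at 21 radii from 2.00 to 7.00 Å (0.25 Å steps):

* the hydrophobicity contrast ``C(R)`` — the summed atomic solvation
  parameter of the outer shell (R/2 < r <= R) minus that of the inner ball
  (r <= R/2), positive when hydrophilic atoms sit inside and carbons
  outside, and
* the mean atomic solvation parameter over all atoms within R.

The per-atom solvation parameters (cal mol^-1 Å^-2) follow the classic
atom-class scale: carbon +16, neutral N/O -6, charged O -24, charged N
-50, sulfur +21.  Hydrogens score 0 and metals are excluded.

CH3/CH4 candidate sites are verified by the Pearson correlation of their
two curves against reference curves averaged over validated experimental
sites of the same group; the certainty is the clamped mean of the two
correlation coefficients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .structure_io import AtomRecord, Structure

__all__ = [
    "SolvationScale",
    "DEFAULT_SCALE",
    "PROFILE_RADII",
    "HydroProfile",
    "ReferenceCurves",
    "solvation_parameter",
    "contrast_at",
    "mean_solvation_at",
    "profile",
    "pearson_certainty",
    "build_reference_curves",
]

logger = logging.getLogger(__name__)

#: the 21-point radial grid in Å
PROFILE_RADII = np.round(np.arange(2.0, 7.0 + 1e-9, 0.25), 2)


@dataclass(frozen=True)
class SolvationScale:
    """Atomic solvation parameters per atom class (cal mol^-1 Å^-2)."""

    carbon: float = 16.0
    neutral_no: float = -6.0
    charged_o: float = -24.0
    charged_n: float = -50.0
    sulfur: float = 21.0


DEFAULT_SCALE = SolvationScale()

# side-chain atoms carrying formal charge at physiological pH
_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}


def solvation_parameter(atom: AtomRecord,
                        scale: SolvationScale = DEFAULT_SCALE) -> float:
    """Per-atom solvation parameter; hydrogens 0, metals excluded upstream."""
    el = atom.element.upper()
    if el in ("H", "D"):
        return 0.0
    if el == "C":
        return scale.carbon
    if el == "S":
        return scale.sulfur
    if el == "O":
        if (atom.res_name, atom.name) in _CHARGED_O or atom.name == "OXT":
            return scale.charged_o
        return scale.neutral_no
    if el == "N":
        if (atom.res_name, atom.name) in _CHARGED_N:
            return scale.charged_n
        return scale.neutral_no
    logger.warning("unknown element %r for solvation scale; using 0", el)
    return 0.0


def _profile_atoms(structure: Structure) -> list[AtomRecord]:
    return [a for a in structure.atoms()
            if not a.is_hydrogen and not a.is_metal]


def contrast_at(structure: Structure, center: np.ndarray, radius: float,
                scale: SolvationScale = DEFAULT_SCALE) -> float:
    """Hydrophobicity contrast C(R): outer-shell sum minus inner-ball sum."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    inner = outer = 0.0
    half = radius / 2.0
    for a in _profile_atoms(structure):
        r = float(np.linalg.norm(a.position - center))
        if r > radius:
            continue
        ds = solvation_parameter(a, scale)
        if r <= half:
            inner += ds
        else:
            outer += ds
    return outer - inner


def mean_solvation_at(structure: Structure, center: np.ndarray, radius: float,
                      scale: SolvationScale = DEFAULT_SCALE) -> float:
    """Mean solvation parameter over atoms within ``radius``; 0 if none."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    values = [solvation_parameter(a, scale) for a in _profile_atoms(structure)
              if float(np.linalg.norm(a.position - center)) <= radius]
    return float(np.mean(values)) if values else 0.0


@dataclass
class HydroProfile:
    radii: np.ndarray
    c_values: np.ndarray
    mean_sigma: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.c_values = np.asarray(self.c_values, dtype=float)
        self.mean_sigma = np.asarray(self.mean_sigma, dtype=float)
        if len(self.radii) != 21 or not np.allclose(self.radii, PROFILE_RADII):
            raise ValueError("profile must use the 21-point 2-7 Å grid")


def profile(structure: Structure, center: np.ndarray,
            scale: SolvationScale = DEFAULT_SCALE) -> HydroProfile:
    """Evaluate both curves on the 21-radius grid around ``center``.

    A single pass sorts atoms by distance so each radius is a cumulative
    lookup rather than a rescan.
    """
    center = np.asarray(center, dtype=float)
    atoms = _profile_atoms(structure)
    if atoms:
        dists = np.array([np.linalg.norm(a.position - center) for a in atoms])
        sigmas = np.array([solvation_parameter(a, scale) for a in atoms])
        order = np.argsort(dists)
        dists, sigmas = dists[order], sigmas[order]
        csum = np.concatenate([[0.0], np.cumsum(sigmas)])
        counts = np.arange(len(atoms) + 1)

        def upto(r: float) -> tuple[float, int]:
            i = int(np.searchsorted(dists, r, side="right"))
            return csum[i], counts[i]

        c_vals, means = [], []
        for r in PROFILE_RADII:
            total, n_total = upto(r)
            inner, _ = upto(r / 2.0)
            c_vals.append((total - inner) - inner)
            means.append(total / n_total if n_total else 0.0)
    else:
        c_vals = [0.0] * 21
        means = [0.0] * 21
    return HydroProfile(PROFILE_RADII.copy(), np.array(c_vals), np.array(means))


@dataclass
class ReferenceCurves:
    """Per-group mean profiles over validated experimental sites."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (C, mean_sigma)
    provenance: dict = field(default_factory=dict)

    def get(self, group: str) -> Optional[tuple[np.ndarray, np.ndarray]]:
        return self.curves.get(group)

    def to_json(self) -> str:
        payload = {
            "radii": PROFILE_RADII.tolist(),
            "provenance": self.provenance,
            "groups": {
                g: {"c": c.tolist(), "mean_sigma": m.tolist()}
                for g, (c, m) in self.curves.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceCurves":
        payload = json.loads(text)
        if not np.allclose(payload["radii"], PROFILE_RADII):
            raise ValueError("reference curves use a different radial grid")
        curves = {
            g: (np.asarray(v["c"], dtype=float),
                np.asarray(v["mean_sigma"], dtype=float))
            for g, v in payload["groups"].items()
        }
        return cls(curves=curves, provenance=payload.get("provenance", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceCurves":
        return cls.from_json(Path(path).read_text())


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0
    return float(stats.pearsonr(a, b)[0])


def pearson_certainty(p: HydroProfile,
                      ref: tuple[np.ndarray, np.ndarray]) -> float:
    """Certainty of a CH3/CH4 site from curve similarity to the reference.

    Mean of the Pearson correlations of the C-curves and of the mean-sigma
    curves, clamped to [0, 1].  Degenerate constant curves correlate 0.
    """
    ref_c, ref_m = np.asarray(ref[0], dtype=float), np.asarray(ref[1], dtype=float)
    if len(ref_c) != len(p.c_values) or len(ref_m) != len(p.mean_sigma):
        raise ValueError("profile and reference grids differ")
    r_c = _safe_pearson(p.c_values, ref_c)
    r_m = _safe_pearson(p.mean_sigma, ref_m)
    return float(min(max((r_c + r_m) / 2.0, 0.0), 1.0))


def build_reference_curves(
        sites: Sequence[tuple[Structure, np.ndarray, str]],
        scale: SolvationScale = DEFAULT_SCALE) -> ReferenceCurves:
    """Pointwise-mean reference curves per group from validated sites."""
    acc: dict[str, list[HydroProfile]] = {}
    for structure, center, group in sites:
        acc.setdefault(group, []).append(profile(structure, center, scale))
    curves = {
        g: (np.mean([p.c_values for p in ps], axis=0),
            np.mean([p.mean_sigma for p in ps], axis=0))
        for g, ps in acc.items()
    }
    return ReferenceCurves(curves=curves,
                           provenance={"n_sites": {g: len(ps) for g, ps in acc.items()}})
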