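"""Quantitative validation of modelled or predicted metal sites.

Three scores, each in [0, 1], summarize how well a metal site agrees with
coordination chemistry and with the experimental model:

* ``Q_v`` — agreement of the bond valence sum with the metal's expected
  oxidation state, ``min(S/V_ox, V_ox/S)`` with ``S = sum(V_i)``.
* ``Q_c`` — completeness/symmetry of the first coordination sphere from the
  vectorial cancellation of the bond valence vectors,
  ``1 - |sum(v_i)| / norm`` where the normalization is either the valence
  sum (3+ ligands) or the oxidation state (2 ligands; this normalization
  reproduces the two-ligand optimum of 0.71 and its half-threshold 0.355).
* ``Q_e`` — agreement of the metal's occupancy/B-factor with the
  valence-weighted environment averages.

Acceptance thresholds depend on the ligand count: for 3-4 ligands all three
scores must exceed 0.5 (half the optimum); for 2 ligands the optima shrink
(S_opt = 1, |v1+v2|_opt = 0.58) and the thresholds become
Q_v > 0.25, Q_c > 0.355, Q_e > 0.5.  Sites with fewer than two ligands
never pass.

Bond valences use the standard exponential parameterization
``V = exp((R0 - d)/b)`` with b = 0.37 Å and tabulated R0 per metal-donor
pair (Zn-O 1.704, Zn-N 1.77, Zn-S 2.09 Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure_io import AtomRecord, Structure

__all__ = [
    "BondValenceVector",
    "ValidationScores",
    "ValidationConfig",
    "DEFAULT_CONFIG",
    "bond_valence",
    "coordination_sphere",
    "q_valence",
    "q_completeness",
    "q_environment",
    "validate_site",
]

DONOR_ELEMENTS = ("N", "O", "S")


@dataclass(frozen=True)
class ValidationConfig:
    """Bond-valence parameters and acceptance thresholds.

    ``r0`` maps (metal, donor element) to R0 in Å; ``b`` is the universal
    softness constant.  ``thresholds`` maps a ligand-count class ('2' or
    '3+') to the (Q_v, Q_c, Q_e) cutoffs.
    """

    r0: dict = field(default_factory=lambda: {
        ("ZN", "O"): 1.704,
        ("ZN", "N"): 1.77,
        ("ZN", "S"): 2.09,
    })
    b: float = 0.37
    oxidation_state: dict = field(default_factory=lambda: {"ZN": 2.0})
    first_sphere_cutoff: float = 2.5
    thresholds: dict = field(default_factory=lambda: {
        "2": (0.25, 0.355, 0.5),
        "3+": (0.5, 0.5, 0.5),
    })


DEFAULT_CONFIG = ValidationConfig()


@dataclass
class BondValenceVector:
    """Bond valence of one coordination bond, directed metal -> donor."""

    magnitude: float
    direction: np.ndarray  # unit vector
    donor: AtomRecord

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * self.direction


@dataclass
class ValidationScores:
    q_valence: float
    q_completeness: float
    q_environment: float
    n_ligands: int
    passed: bool


def bond_valence(distance: float, donor_element: str, metal: str = "ZN",
                 config: ValidationConfig = DEFAULT_CONFIG) -> float:
    """Empirical bond valence exp((R0 - d)/b) for one metal-donor bond."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    key = (metal.upper(), donor_element.upper())
    if key not in config.r0:
        raise KeyError(f"no bond-valence parameters for pair {key}")
    return math.exp((config.r0[key] - distance) / config.b)


def coordination_sphere(structure: Structure, center: np.ndarray,
                        metal: str = "ZN",
                        cutoff: Optional[float] = None,
                        config: ValidationConfig = DEFAULT_CONFIG,
                        ) -> list[BondValenceVector]:
    """Collect first-sphere donor vectors around ``center``.

    One vector per N/O/S donor within the cutoff (default 2.5 Å), at most
    one atom per residue (the closest donor).  Metals and hydrogens never
    act as donors; waters contribute their O.
    """
    center = np.asarray(center, dtype=float)
    if cutoff is None:
        cutoff = config.first_sphere_cutoff
    best_per_residue: dict[tuple, tuple[float, AtomRecord]] = {}
    for res in structure.residues():
        for a in res.atoms:
            if a.element.upper() not in DONOR_ELEMENTS or a.is_metal:
                continue
            d = float(np.linalg.norm(a.position - center))
            if d <= 1e-6 or d > cutoff:
                continue
            key = res.key() + (res.res_name,)
            if key not in best_per_residue or d < best_per_residue[key][0]:
                best_per_residue[key] = (d, a)
    vectors = []
    for d, a in sorted(best_per_residue.values(), key=lambda t: t[0]):
        direction = (a.position - center) / d
        vectors.append(BondValenceVector(
            magnitude=bond_valence(d, a.element, metal, config),
            direction=direction,
            donor=a,
        ))
    return vectors


def q_valence(valences: Sequence[float], v_ox: float) -> float:
    """Agreement of the valence sum with the expected oxidation state."""
    if v_ox <= 0:
        raise ValueError("v_ox must be positive")
    if any(v < 0 for v in valences):
        raise ValueError("bond valences must be non-negative")
    s = float(sum(valences))
    if s == 0:
        return 0.0
    return min(s / v_ox, v_ox / s)


def q_completeness(vectors: Sequence[BondValenceVector],
                   normalization: str = "valence_sum",
                   v_ox: float = 2.0) -> float:
    """Vectorial completeness of the coordination sphere.

    ``valence_sum`` divides the resultant by sum(V_i); ``oxidation_state``
    divides by V_ox (the two-ligand convention).  Clamped to [0, 1].
    """
    if not vectors:
        raise ValueError("q_completeness requires at least one vector")
    if normalization not in ("valence_sum", "oxidation_state"):
        raise ValueError(f"unknown normalization {normalization!r}")
    resultant = float(np.linalg.norm(sum(v.vector for v in vectors)))
    total = float(sum(v.magnitude for v in vectors))
    if total == 0:
        raise ValueError("zero total valence")
    denom = total if normalization == "valence_sum" else v_ox
    return float(min(max(1.0 - resultant / denom, 0.0), 1.0))


def q_environment(o_m: float, b_m: float,
                  donors: Sequence[BondValenceVector]) -> float:
    """Occupancy/B-factor agreement between metal and environment.

    Environment averages are valence-weighted:
    O_e = sum(V_i O_i)/sum(V_i) and B_e likewise; the score is
    min(2 min(O_m, O_e), 1) * min((B_m O_m)/(B_e O_e), (B_e O_e)/(B_m O_m)).
    """
    if not donors:
        raise ValueError("q_environment requires at least one donor")
    if not (0 < o_m <= 1) or b_m <= 0:
        raise ValueError("metal occupancy must be in (0,1] and B-factor > 0")
    w = np.array([v.magnitude for v in donors])
    occ = np.array([v.donor.occupancy for v in donors])
    bfs = np.array([v.donor.b_factor for v in donors])
    o_e = float(np.sum(w * occ) / np.sum(w))
    b_e = float(np.sum(w * bfs) / np.sum(w))
    if o_e <= 0 or b_e <= 0:
        raise ValueError("environment occupancy and B-factor must be positive")
    occ_factor = min(2.0 * min(o_m, o_e), 1.0)
    ratio = (b_m * o_m) / (b_e * o_e)
    return float(occ_factor * min(ratio, 1.0 / ratio))


def validate_site(structure: Structure, center: np.ndarray,
                  metal: str = "ZN",
                  metal_atom: Optional[AtomRecord] = None,
                  config: ValidationConfig = DEFAULT_CONFIG,
                  ) -> ValidationScores:
    """Assemble the coordination sphere at ``center`` and score it.

    If ``metal_atom`` is given (a modelled ion) its occupancy/B-factor feed
    Q_e; for a bare predicted position, unit occupancy and the environment
    B-factor are assumed, making Q_e's experimental factor neutral.
    Sites with 0-1 ligands never pass.
    """
    metal = metal.upper()
    if metal not in config.oxidation_state:
        raise KeyError(f"no configured oxidation state for {metal}")
    v_ox = config.oxidation_state[metal]
    vectors = coordination_sphere(structure, center, metal, config=config)
    n = len(vectors)
    if n == 0:
        return ValidationScores(0.0, 0.0, 0.0, 0, False)
    valences = [v.magnitude for v in vectors]
    qv = q_valence(valences, v_ox)
    if n == 2:
        qc = q_completeness(vectors, "oxidation_state", v_ox)
        thr = config.thresholds["2"]
    else:
        qc = q_completeness(vectors, "valence_sum", v_ox)
        thr = config.thresholds["3+"]
    if metal_atom is not None:
        o_m, b_m = metal_atom.occupancy, metal_atom.b_factor
        if b_m <= 0:
            b_m = 1.0
        if o_m <= 0:
            o_m = 1.0
    else:
        w = np.array([v.magnitude for v in vectors])
        bfs = np.array([v.donor.b_factor for v in vectors])
        o_m = 1.0
        b_m = float(np.sum(w * bfs) / np.sum(w)) or 1.0
    try:
        qe = q_environment(o_m, b_m, vectors)
    except ValueError:
        qe = 0.0
    passed = n >= 2 and qv > thr[0] and qc > thr[1] and qe > thr[2]
    return ValidationScores(qv, qc, qe, n, passed)
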