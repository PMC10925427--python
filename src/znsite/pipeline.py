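"""End-to-end zinc-site prediction: search -> placement -> profiling ->
verification -> redundancy removal -> second-sphere annotation.

The hybrid verification dispatches by group: two-residue (CH2) candidates
go through the five-learner ensemble, three/four-residue (CH3/CH4)
candidates through the Pearson-correlation certainty against group
reference curves.  Candidates scoring at or below the 0.5 certainty
threshold are rejected.  Surviving zincs closer than 2.5 Å are merged
(higher ligand count, then higher certainty wins) — a threshold chosen so
genuinely dinuclear sites, whose inter-zinc distances concentrate between
3 and 4 Å, are preserved.  Metals already modelled in the input are
validated and cross-referenced to predictions by residue IoUR >= 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import candidate_search as cs
from . import ch2_classifier as ch2
from . import evaluation as ev
from . import hydro_profile as hp
from . import metal_validation as mv
from . import zinc_placement as zp
from .structure_io import AtomRecord, Structure, primary_conformer

__all__ = [
    "PredictionConfig",
    "PredictionReport",
    "ConfigurationError",
    "verify_sites",
    "remove_redundancy",
    "annotate_second_sphere",
    "predict_structure",
]

logger = logging.getLogger(__name__)


class ConfigurationError(RuntimeError):
    """A required model or reference artifact is missing."""


@dataclass
class PredictionConfig:
    distance_window: tuple[float, float] = cs.DISTANCE_WINDOW
    disulfide_cutoff: float = cs.DISULFIDE_CUTOFF
    redundancy_threshold: float = 2.5
    certainty_threshold: float = 0.5
    first_sphere_radius: float = 2.5
    second_sphere_radius: float = 4.0
    model_path: Optional[str] = None
    refs_path: Optional[str] = None
    chains: Optional[list[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.distance_window
        if not lo < hi:
            raise ValueError("distance window min must be below max")
        for name in ("disulfide_cutoff", "redundancy_threshold",
                     "certainty_threshold", "first_sphere_radius",
                     "second_sphere_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AuxiliaryLigand:
    atom: AtomRecord
    distance: float
    sphere: str  # "first" or "second"


@dataclass
class ExperimentalSiteReport:
    metal: AtomRecord
    scores: mv.ValidationScores
    ligand_residues: frozenset
    matched_prediction: Optional[int] = None  # index into verified sites
    iour: Optional[float] = None
    deviation: Optional[float] = None


@dataclass
class PredictionReport:
    verified: list[zp.PlacedSite]
    rejected: list[tuple[zp.PlacedSite, str]]
    auxiliary: dict[int, list[AuxiliaryLigand]]  # verified-site index -> ligands
    experimental: list[ExperimentalSiteReport]


def verify_sites(placed: Sequence[zp.PlacedSite],
                 model: Optional[ch2.EnsembleModel],
                 refs: Optional[hp.ReferenceCurves],
                 structure: Structure,
                 threshold: float = 0.5,
                 ) -> tuple[list[zp.PlacedSite], list[tuple[zp.PlacedSite, str]]]:
    """Assign certainties; split into verified and rejected lists."""
    groups = {p.site.group for p in placed}
    if "CH2" in groups and model is None:
        raise ConfigurationError("CH2 candidates present but no ensemble model")
    if ({"CH3", "CH4"} & groups) and refs is None:
        raise ConfigurationError("CH3/CH4 candidates present but no reference curves")
    verified, rejected = [], []
    for p in placed:
        prof = hp.profile(structure, p.zinc_position)
        if p.site.group == "CH2":
            fv = ch2.encode_features(p, prof)
            certainty, is_pos = ch2.ensemble_certainty(model, fv)
            p.certainty = certainty
            if is_pos and certainty > threshold:
                verified.append(p)
            else:
                rejected.append((p, "ensemble-vote"))
        else:
            ref = refs.get(p.site.group)
            if ref is None:
                raise ConfigurationError(
                    f"no reference curves for group {p.site.group}")
            p.certainty = hp.pearson_certainty(prof, ref)
            if p.certainty > threshold:
                verified.append(p)
            else:
                rejected.append((p, "profile-correlation"))
    return verified, rejected


def _rank_key(p: zp.PlacedSite) -> tuple:
    first = min(r.key() for r in p.site.residues)
    return (-len(p.site.residues), -(p.certainty or 0.0), first)


def remove_redundancy(sites: Sequence[zp.PlacedSite],
                      threshold: float = 2.5) -> list[zp.PlacedSite]:
    """Greedy merge of zincs closer than the redundancy threshold.

    Sites are kept in descending (ligand count, certainty) order; a site
    whose zinc lies within the threshold of an already-kept zinc is
    dropped.  Pairs at or beyond the threshold both survive, preserving
    dinuclear sites (typically 3-4 Å apart).
    """
    kept: list[zp.PlacedSite] = []
    for p in sorted(sites, key=_rank_key):
        if all(np.linalg.norm(p.zinc_position - q.zinc_position) >= threshold
               for q in kept):
            kept.append(p)
    return kept


def annotate_second_sphere(structure: Structure, site: zp.PlacedSite,
                           first_radius: float = 2.5,
                           second_radius: float = 4.0,
                           ) -> list[AuxiliaryLigand]:
    """Non-CH donor atoms around the predicted zinc.

    N/O/S atoms from residues other than cysteine/histidine (acidic side
    chains, waters, backbone donors of other residues) are labelled
    first-sphere (<= 2.5 Å) or second-sphere (<= 4.0 Å).
    """
    zn = np.asarray(site.zinc_position, dtype=float)
    out = []
    for res in structure.residues():
        if res.res_name in ("CYS", "HIS"):
            continue
        for a in res.atoms:
            if a.element.upper() not in ("N", "O", "S") or a.is_metal:
                continue
            d = float(np.linalg.norm(a.position - zn))
            if d <= first_radius:
                out.append(AuxiliaryLigand(a, d, "first"))
            elif d <= second_radius:
                out.append(AuxiliaryLigand(a, d, "second"))
    out.sort(key=lambda x: x.distance)
    return out


def _experimental_sites(structure: Structure,
                        config: PredictionConfig,
                        ) -> list[ExperimentalSiteReport]:
    reports = []
    for metal in structure.metal_atoms():
        try:
            scores = mv.validate_site(structure, metal.position,
                                      metal=metal.element, metal_atom=metal)
        except KeyError:
            # no oxidation state configured for this metal; validate as zinc
            scores = mv.validate_site(structure, metal.position,
                                      metal="ZN", metal_atom=metal)
        vectors = mv.coordination_sphere(structure, metal.position)
        residues = frozenset((v.donor.chain_id, v.donor.resseq, v.donor.icode)
                             for v in vectors if not v.donor.is_water)
        reports.append(ExperimentalSiteReport(
            metal=metal, scores=scores, ligand_residues=residues))
    return reports


def predict_structure(structure: Structure, config: PredictionConfig,
                      model: Optional[ch2.EnsembleModel] = None,
                      refs: Optional[hp.ReferenceCurves] = None,
                      ) -> PredictionReport:
    """Run the full prediction chain on one structure.

    Deterministic for a fixed input, config and model.  Experimentally
    modelled metals in the input are validated and cross-referenced to
    the predictions via residue IoUR >= 0.5.
    """
    if model is None and config.model_path:
        model = ch2.load_model(config.model_path)
    if refs is None and config.refs_path:
        refs = hp.ReferenceCurves.load(config.refs_path)

    work = primary_conformer(structure)
    atoms = cs.coordinating_atoms(work, chains=config.chains)
    candidates = cs.enumerate_sites(atoms, window=config.distance_window)
    logger.info("%s: %d coordinating atoms, %d candidate sites",
                structure.id, len(atoms), len(candidates))

    placed = []
    for site in candidates:
        try:
            placed.append(zp.place_zinc(site))
        except zp.PlacementError as exc:
            logger.info("placement failed for %s site: %s", site.subgroup, exc)

    verified, rejected = verify_sites(
        placed, model, refs, work, threshold=config.certainty_threshold)
    before = len(verified)
    verified = remove_redundancy(verified, config.redundancy_threshold)
    logger.info("%s: %d verified (%d redundant removed), %d rejected",
                structure.id, len(verified), before - len(verified),
                len(rejected))

    auxiliary = {
        i: annotate_second_sphere(work, p, config.first_sphere_radius,
                                  config.second_sphere_radius)
        for i, p in enumerate(verified)
    }

    experimental = _experimental_sites(work, config)
    for exp in experimental:
        best = None
        for i, p in enumerate(verified):
            keys = frozenset(r.key() for r in p.site.residues)
            score = ev.iour(keys, exp.ligand_residues)
            if score >= 0.5 and (best is None or score > best[1]):
                best = (i, score)
        if best is not None:
            exp.matched_prediction = best[0]
            exp.iour = best[1]
            exp.deviation = ev.deviation(
                verified[best[0]].zinc_position, exp.metal.position)

    return PredictionReport(verified=verified, rejected=rejected,
                            auxiliary=auxiliary, experimental=experimental)
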