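"""Ensemble verification of two-residue (CH2) candidate sites.

Two-ligand sites are the hardest to call from geometry alone: regulatory
zinc binds transiently and the same residue pair can just as well be an
apo pocket.  Verification therefore uses a 61-feature representation of
the site and a five-learner majority-vote ensemble:

* features — per ligand (canonical order by chain/resseq/icode): a CYS/HIS
  flag plus a 5-way one-hot of the coordinating atom (SG, ND1, NE2, CE1,
  CD2) [12]; coordinating-atom, CA-CA and CB-CB distances [3]; the four
  angles CA1-lig1-Zn, CA2-lig2-Zn, CB1-lig1-Zn, CB2-lig2-Zn in degrees
  [4]; and the 21-point C and mean-sigma profile curves [42].
* learners — logistic regression, decision tree, multilayer perceptron,
  RBF-kernel SVC, and a deeper feed-forward network, each wrapped with
  feature standardization and tuned by 10-fold cross-validation over a
  small grid.
* decision — positive when at least 3 of 5 learners assign probability
  > 0.5; the reported certainty is the mean of the five probabilities.

Negatives for training are candidate sites with no modelled metal within
4 Å of the predicted zinc that additionally fail the two-ligand validation
(Qc < 0.355 or Qv < 0.25).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, confusion_matrix,
                             roc_auc_score)
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import metal_validation as mv
from .hydro_profile import HydroProfile
from .structure_io import Structure
from .zinc_placement import PlacedSite

__all__ = [
    "N_FEATURES",
    "EncodingError",
    "EnsembleModel",
    "encode_features",
    "build_negative_set",
    "train_ensemble",
    "ensemble_certainty",
    "save_model",
    "load_model",
]

N_FEATURES = 61
_ROLES = ("SG", "ND1", "NE2", "CE1", "CD2")


class EncodingError(RuntimeError):
    """The site lacks the atoms needed for feature encoding."""


def _angle_deg(p1, vertex, p2) -> float:
    v1 = np.asarray(p1) - np.asarray(vertex)
    v2 = np.asarray(p2) - np.asarray(vertex)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(min(max(c, -1.0), 1.0))))


def encode_features(site: PlacedSite, profile: HydroProfile) -> np.ndarray:
    """61-vector for a placed CH2 site; a pure function of its geometry.

    Ligands are ordered canonically by (chain, resseq, icode) so that the
    encoding does not depend on enumeration order.
    """
    cand = site.site
    if cand.group != "CH2":
        raise EncodingError(f"feature encoding is defined for CH2 sites, got {cand.group}")
    ligands = sorted(cand.chosen_atoms, key=lambda ca: ca.residue_key())
    zn = np.asarray(site.zinc_position, dtype=float)

    fv: list[float] = []
    for ca in ligands:
        fv.append(1.0 if ca.residue_kind == "CYS" else 0.0)
        fv.extend(1.0 if ca.atom_role == role else 0.0 for role in _ROLES)

    l1, l2 = ligands
    cas, cbs = [], []
    for ca in ligands:
        a_ca = ca.residue.get_atom("CA")
        a_cb = ca.residue.get_atom("CB")
        if a_ca is None or a_cb is None:
            raise EncodingError(f"residue {ca.residue_key()} missing CA/CB")
        cas.append(a_ca.position)
        cbs.append(a_cb.position)

    fv.append(float(np.linalg.norm(l1.atom.position - l2.atom.position)))
    fv.append(float(np.linalg.norm(cas[0] - cas[1])))
    fv.append(float(np.linalg.norm(cbs[0] - cbs[1])))

    fv.append(_angle_deg(cas[0], l1.atom.position, zn))
    fv.append(_angle_deg(cas[1], l2.atom.position, zn))
    fv.append(_angle_deg(cbs[0], l1.atom.position, zn))
    fv.append(_angle_deg(cbs[1], l2.atom.position, zn))

    fv.extend(profile.c_values.tolist())
    fv.extend(profile.mean_sigma.tolist())
    out = np.asarray(fv, dtype=float)
    assert out.shape == (N_FEATURES,)
    return out


def subgroup_of(fv: np.ndarray) -> str:
    """CC/CH/HH label recovered from the two residue flags of a 61-vector."""
    n_cys = int(round(fv[0] + fv[6]))
    return {2: "CC", 1: "CH", 0: "HH"}[n_cys]


def build_negative_set(pairs: Sequence[tuple[Structure, PlacedSite]],
                       metal_exclusion_radius: float = 4.0,
                       ) -> list[PlacedSite]:
    """Select training negatives among placed CH2 candidates.

    A candidate qualifies when no modelled metal ion lies within 4 Å of
    its predicted zinc AND it fails the two-ligand validation criteria
    (Qc < 0.355, oxidation-state normalization, or Qv < 0.25).
    """
    negatives = []
    for structure, placed in pairs:
        if placed.site.group != "CH2":
            continue
        zn = np.asarray(placed.zinc_position, dtype=float)
        if any(np.linalg.norm(m.position - zn) < metal_exclusion_radius
               for m in structure.metal_atoms()):
            continue
        vectors = []
        for ca in placed.site.chosen_atoms:
            d = float(np.linalg.norm(ca.atom.position - zn))
            try:
                mag = mv.bond_valence(d, ca.atom.element)
            except KeyError:
                continue
            vectors.append(mv.BondValenceVector(
                magnitude=mag,
                direction=(ca.atom.position - zn) / d,
                donor=ca.atom,
            ))
        if len(vectors) < 2:
            negatives.append(placed)
            continue
        qv = mv.q_valence([v.magnitude for v in vectors], 2.0)
        qc = mv.q_completeness(vectors, "oxidation_state", 2.0)
        if qc < 0.355 or qv < 0.25:
            negatives.append(placed)
    return negatives


@dataclass
class EnsembleModel:
    """Five fitted base learners plus training metadata."""

    learners: dict  # name -> fitted sklearn Pipeline (scaler + estimator)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.learners) != 5:
            raise ValueError("ensemble requires exactly five base learners")


def _learner_grid(seed: int) -> dict:
    """The five base learners and their (deliberately small) CV grids."""
    return {
        "logistic_regression": (
            LogisticRegression(max_iter=2000, random_state=seed),
            {"est__C": [0.1, 1.0, 10.0]},
        ),
        "decision_tree": (
            DecisionTreeClassifier(random_state=seed),
            {"est__max_depth": [3, 6, None]},
        ),
        "mlp": (
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=800,
                          random_state=seed),
            {"est__alpha": [1e-4, 1e-2]},
        ),
        "svc": (
            # SVC margins calibrated to probabilities (Platt scaling)
            CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                   ensemble=False),
            {"est__estimator__C": [0.5, 2.0]},
        ),
        "fcnn": (
            MLPClassifier(hidden_layer_sizes=(64, 32), max_iter=800,
                          random_state=seed),
            {"est__alpha": [1e-4]},
        ),
    }


def train_ensemble(positives: np.ndarray, negatives: np.ndarray,
                   seed: int = 0, cv: int = 10) -> EnsembleModel:
    """Fit the five-learner ensemble on labelled 61-vectors.

    Data are split 70/30 stratified jointly on the class label and the
    CC/CH/HH subgroup (falling back to class-only stratification when a
    stratum has fewer than two members); features are standardized inside
    each learner's pipeline; hyperparameters are picked by ``cv``-fold
    cross-validation on the training split.  Held-out AUC, average
    precision and the confusion matrix are stored in the metadata.
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([positives, negatives])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    strata = np.array([f"{int(lbl)}|{subgroup_of(fv)}"
                       for fv, lbl in zip(X, y)])
    uniq, counts = np.unique(strata, return_counts=True)
    if counts.min() < 2:
        strata = y  # fall back to class-only stratification
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, random_state=seed, stratify=strata)

    learners = {}
    cv_results = {}
    for name, (est, grid) in _learner_grid(seed).items():
        pipe = Pipeline([("scale", StandardScaler()), ("est", est)])
        search = GridSearchCV(pipe, grid, cv=cv, scoring="roc_auc", n_jobs=1)
        search.fit(X_tr, y_tr)
        learners[name] = search.best_estimator_
        cv_results[name] = {
            "best_params": {k: (v if v is None or isinstance(v, (int, float, str))
                                else str(v))
                            for k, v in search.best_params_.items()},
            "best_cv_auc": float(search.best_score_),
        }

    probs = np.column_stack([
        m.predict_proba(X_te)[:, 1] for m in learners.values()])
    mean_prob = probs.mean(axis=1)
    votes = (probs > 0.5).sum(axis=1) >= 3
    metadata = {
        "seed": seed,
        "n_train": int(len(X_tr)),
        "n_test": int(len(X_te)),
        "cv_folds": cv,
        "cv_results": cv_results,
        "holdout_auc": float(roc_auc_score(y_te, mean_prob)),
        "holdout_ap": float(average_precision_score(y_te, mean_prob)),
        "holdout_confusion": confusion_matrix(y_te, votes.astype(int)).tolist(),
    }
    return EnsembleModel(learners=learners, metadata=metadata)


def ensemble_certainty(model: EnsembleModel,
                       fv: np.ndarray) -> tuple[float, bool]:
    """(certainty, is_positive) for one 61-vector.

    Positive iff >= 3 of the 5 learners assign probability > 0.5; the
    certainty is the clamped mean probability.  Invariant to learner order.
    """
    fv = np.asarray(fv, dtype=float).reshape(1, -1)
    probs = np.array([m.predict_proba(fv)[0, 1] for m in model.learners.values()])
    is_positive = bool((probs > 0.5).sum() >= 3)
    certainty = float(min(max(probs.mean(), 0.0), 1.0))
    return certainty, is_positive


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Serialize learners + a JSON metadata manifest to one archive."""
    joblib.dump({"metadata_json": json.dumps(model.metadata),
                 "learners": model.learners}, path)


def load_model(path: str | Path) -> EnsembleModel:
    payload = joblib.load(path)
    return EnsembleModel(learners=payload["learners"],
                         metadata=json.loads(payload["metadata_json"]))
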