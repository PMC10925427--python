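"""Site-matching and accuracy metrics for binding-site prediction.

Two matching schemes are implemented:

* **IoUR** — the intersection-over-union ratio of predicted vs actual
  ligand-residue sets (residues identified by chain/resseq/icode).  A
  greedy one-to-one assignment by descending IoUR with a 0.5 threshold
  defines true positives; unmatched predictions are false positives and
  unmatched actual sites false negatives.
* **distance** — a prediction within 5 Å of an experimental metal position
  is a true positive (assigned to its nearest actual site); unmatched
  predictions that are themselves within 5 Å of each other are clustered
  and count as a single false positive; actual sites with no prediction
  within the threshold are false negatives.

Per-pair positional deviations and the usual precision / recall / F1 /
accuracy summaries accompany both schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SiteMatchResult",
    "Metrics",
    "iour",
    "match_iour",
    "match_distance",
    "deviation",
    "classification_metrics",
]


@dataclass
class SiteMatchResult:
    pairs: list[tuple[int, int, float]]  # (predicted idx, actual idx, score)
    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None
    deviations: list[float] = field(default_factory=list)


def iour(predicted_residues: Sequence, actual_residues: Sequence) -> float:
    """|intersection| / |union| of two residue-identity sets; 0 when both empty."""
    p, a = set(predicted_residues), set(actual_residues)
    union = p | a
    if not union:
        return 0.0
    return len(p & a) / len(union)


def match_iour(predicted: Sequence[Sequence], actual: Sequence[Sequence],
               threshold: float = 0.5) -> SiteMatchResult:
    """Greedy one-to-one matching of residue sets by descending IoUR.

    Only pairs at or above the threshold participate; ties are broken
    toward the lowest-sorted actual site (its smallest residue key).
    TP + FN always equals the number of actual sites.
    """
    scored = []
    for i, p in enumerate(predicted):
        for j, a in enumerate(actual):
            s = iour(p, a)
            if s >= threshold:
                scored.append((s, i, j))
    # descending score; ties toward the lowest-keyed actual site
    actual_order = {j: tuple(sorted(actual[j])) for j in range(len(actual))}
    scored.sort(key=lambda t: (-t[0], actual_order[t[2]], t[1]))
    used_p: set[int] = set()
    used_a: set[int] = set()
    pairs = []
    for s, i, j in scored:
        if i in used_p or j in used_a:
            continue
        used_p.add(i)
        used_a.add(j)
        pairs.append((i, j, s))
    tp = len(pairs)
    return SiteMatchResult(
        pairs=pairs,
        tp=tp,
        fp=len(predicted) - tp,
        fn=len(actual) - tp,
    )


def deviation(predicted_zn: np.ndarray, actual_zn: np.ndarray) -> float:
    """Euclidean distance between predicted and experimental positions (Å)."""
    return float(np.linalg.norm(np.asarray(predicted_zn, dtype=float)
                                - np.asarray(actual_zn, dtype=float)))


def match_distance(predicted: Sequence[np.ndarray],
                   actual: Sequence[np.ndarray],
                   threshold: float = 5.0) -> SiteMatchResult:
    """Distance-threshold matching of 3-D positions.

    Every prediction within the threshold of some actual site is a TP
    (assigned to the nearest one) and contributes a deviation; leftover
    predictions are clustered at the same threshold so that a tight bundle
    of spurious predictions counts as one FP.
    """
    pairs = []
    devs = []
    unmatched_pred = []
    hit_actual: set[int] = set()
    for i, p in enumerate(predicted):
        if len(actual) == 0:
            unmatched_pred.append(i)
            continue
        dists = [deviation(p, a) for a in actual]
        j = int(np.argmin(dists))
        if dists[j] <= threshold:
            pairs.append((i, j, dists[j]))
            devs.append(dists[j])
            hit_actual.add(j)
        else:
            unmatched_pred.append(i)
    fn = len(actual) - len(hit_actual)
    # cluster mutually-close unmatched predictions into single FPs
    fp = 0
    remaining = list(unmatched_pred)
    while remaining:
        seed = remaining.pop(0)
        fp += 1
        cluster = [seed]
        changed = True
        while changed:
            changed = False
            for k in list(remaining):
                if any(deviation(predicted[k], predicted[c]) < threshold
                       for c in cluster):
                    cluster.append(k)
                    remaining.remove(k)
                    changed = True
    return SiteMatchResult(pairs=pairs, tp=len(pairs), fp=fp, fn=fn,
                           deviations=devs)


@dataclass
class Metrics:
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    accuracy: Optional[float]


def classification_metrics(tp: int, fp: int, fn: int,
                           tn: Optional[int] = None) -> Metrics:
    """Precision, recall, F1 and (when TN is defined) accuracy.

    Undefined denominators yield ``None`` rather than 0.
    """
    if min(tp, fp, fn) < 0 or (tn is not None and tn < 0):
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    if tn is not None and (tp + tn + fp + fn) > 0:
        accuracy = (tp + tn) / (tp + tn + fp + fn)
    else:
        accuracy = None
    return Metrics(precision=precision, recall=recall, f1=f1, accuracy=accuracy)
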