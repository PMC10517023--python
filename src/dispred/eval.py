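"""Evaluation: AUC, ancestry-stratified reporting, the heterogeneity
sliding-window analysis, and linear probes for disentanglement.

The sliding-window analysis orders test individuals from genetically
homogeneous to admixed by the per-individual variance of their ancestry
proportions and reports each method's AUC in fixed-size windows along that
ordering, together with each window's mean ancestry composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EvalReport",
    "auc",
    "heterogeneity_order",
    "sliding_window_eval",
    "probe_disentanglement",
]


@dataclass
class EvalReport:
    """Per-method AUCs overall, per ancestry group, and along windows."""

    overall_auc: dict[str, float]
    group_auc: dict[str, dict[str, float]] = field(default_factory=dict)
    windows: list[dict] = field(default_factory=list)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random case outscores a random control.

    Mann–Whitney formulation: ties count one half.  Raises on single-class
    label vectors.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def heterogeneity_order(proportions: np.ndarray) -> np.ndarray:
    """Sort individuals from homogeneous to admixed.

    The per-individual statistic is the population variance (divide by K) of
    the K ancestry proportions — maximal for a single-ancestry row, zero for
    a perfectly even mixture; any positive rescaling gives the same order.
    Individuals are sorted by decreasing variance, stably, so ties keep
    their original relative order.
    """
    proportions = np.asarray(proportions, dtype=float)
    if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("proportion rows must sum to 1")
    variance = proportions.var(axis=1)
    return np.argsort(-variance, kind="stable")


def sliding_window_eval(
    ordering: np.ndarray,
    scores_by_method: dict[str, np.ndarray],
    labels: np.ndarray,
    proportions: np.ndarray,
    window: int = 750,
    stride: int = 50,
) -> list[dict]:
    """AUC per method in fixed windows along the heterogeneity ordering.

    Windows start at offsets 0, stride, 2*stride, ... while a full window
    fits; trailing individuals are dropped rather than scored in a short
    window.  A window containing a single phenotype class reports ``nan``
    for every method instead of raising, so long homogeneous stretches do
    not abort the analysis.
    """
    ordering = np.asarray(ordering)
    n = len(ordering)
    if window > n:
        raise ValueError(f"window {window} exceeds cohort size {n}")
    labels = np.asarray(labels)
    proportions = np.asarray(proportions, dtype=float)
    out: list[dict] = []
    for w_idx, start in enumerate(range(0, n - window + 1, stride)):
        idx = ordering[start : start + window]
        y_w = labels[idx]
        single_class = len(np.unique(y_w)) < 2
        entry = {
            "window": w_idx,
            "start": start,
            "mean_proportions": proportions[idx].mean(axis=0),
            "auc": {},
        }
        for name, scores in scores_by_method.items():
            entry["auc"][name] = (
                float("nan") if single_class else auc(np.asarray(scores)[idx], y_w)
            )
        out.append(entry)
    return out


def probe_disentanglement(
    z_matrix: np.ndarray, labels: np.ndarray, seed: int = 0
) -> float:
    """Cross-validated accuracy of a linear probe on a latent block.

    A logistic-regression classifier is fit in 5-fold stratified CV to
    predict the given labels from the latent coordinates; the mean held-out
    accuracy measures how much label information the block retains.  Ancestry
    should probe high from z_a and near chance from z_d when the latent
    space is well disentangled.
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(z_matrix).all():
        raise ValueError("latent matrix contains non-finite values")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("probe needs at least two classes")
    n_splits = 5
    if counts.min() < n_splits:
        n_splits = max(2, int(counts.min()))
        warnings.warn(
            f"smallest class has {counts.min()} members; using {n_splits} folds",
            stacklevel=2,
        )
    folds = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in folds.split(z_matrix, labels):
        clf = LogisticRegression(max_iter=2000)
        clf.fit(z_matrix[tr], labels[tr])
        accs.append(float(np.mean(clf.predict(z_matrix[te]) == labels[te])))
    return float(np.mean(accs))
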