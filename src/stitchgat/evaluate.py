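"""Evaluation harness: leave-one-institution-out splits, AUC summaries,
inter-rater agreement (PABAK) and calibration curves.

Models are trained on data from all institutions but one and scored on the
held-out institution; with five institutions this yields the five-fold
cross-validation whose per-sub-skill AUC mean ± standard deviation (population
convention, so printed values are directly recomputable) populates the
summary tables.  AUC is evaluated at stitch level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import Cohort, SUBSKILL_ORDER

__all__ = [
    "loio_splits",
    "compute_auc",
    "FoldResult",
    "summarize",
    "pabak",
    "calibration_curve",
]


def loio_splits(cohort: Cohort) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """One (train_idx, test_idx, held_out_institution) per institution."""
    insts = [r.institution_id for r in cohort.records]
    unique = list(dict.fromkeys(cohort.institutions))
    if len(unique) < 2:
        raise ValueError("leave-one-institution-out needs at least two institutions")
    splits = []
    arr = np.array(insts)
    for inst in unique:
        test = np.flatnonzero(arr == inst)
        train = np.flatnonzero(arr != inst)
        splits.append((train, test, inst))
    return splits


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve via midranks (Mann-Whitney).

    Equals P(score+ > score-) + 0.5 * P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class")
    ranks = rankdata(scores)  # midranks for ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class FoldResult:
    held_out_institution: str
    auc: dict[str, float]                 # sub-skill code -> AUC
    n_test: int
    attention: np.ndarray | None = None   # averaged 6x6 map


ARM_ORDER = ("independent", "joint", "no_attention", "no_kinematics")

ARM_LABELS = {
    "independent": "Independent",
    "joint": "Ours",
    "no_attention": "w/o Attention",
    "no_kinematics": "w/o Kinematics",
}


def summarize(fold_results: dict[str, list[FoldResult]]) -> pd.DataFrame:
    """Mean ± std AUC per sub-skill and arm, plus the six-skill MEAN row.

    Std uses the population (n-denominator) convention across folds.
    Rows: six sub-skill codes then "MEAN"; columns: a MultiIndex
    (arm, {mean, std}).
    """
    arms = list(fold_results)
    folds_per_arm = {a: sorted(f.held_out_institution for f in fold_results[a]) for a in arms}
    ref = folds_per_arm[arms[0]]
    for a in arms:
        if folds_per_arm[a] != ref:
            raise ValueError(f"arm {a!r} is missing folds: has {folds_per_arm[a]}, want {ref}")
    data = {}
    for a in arms:
        per_skill = {
            s.code: np.array([f.auc[s.code] for f in fold_results[a]])
            for s in SUBSKILL_ORDER
        }
        col_mean, col_std = {}, {}
        for code, vals in per_skill.items():
            col_mean[code] = vals.mean()
            col_std[code] = vals.std()  # population std
        # MEAN row: per-fold average over the six sub-skills, then mean/std
        # across folds (so its +/- can be far smaller than per-skill spreads)
        fold_means = np.array(
            [np.mean([f.auc[s.code] for s in SUBSKILL_ORDER]) for f in fold_results[a]]
        )
        col_mean["MEAN"] = fold_means.mean()
        col_std["MEAN"] = fold_means.std()
        data[(a, "mean")] = col_mean
        data[(a, "std")] = col_std
    index = [s.code for s in SUBSKILL_ORDER] + ["MEAN"]
    table = pd.DataFrame(data).loc[index]
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["arm", "stat"])
    return table


def pabak(ratings_a, ratings_b) -> float:
    """Prevalence-adjusted bias-adjusted kappa for binary ratings:
    ``2 * observed_agreement - 1``."""
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty 1-D vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("ratings must be binary")
    p_o = float((a == b).mean())
    return 2.0 * p_o - 1.0


def calibration_curve(probs, labels, n_bins: int = 10) -> list[tuple[float, float, int]]:
    """Reliability curve over equal-width probability bins.

    Returns (mean predicted probability, observed ideal rate, count) per
    non-empty bin; counts sum to n.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            out.append((float(probs[m].mean()), float(labels[m].mean()), int(m.sum())))
    return out
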