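"""Association between suturing skill scores and 3-month continence recovery.

Univariable logistic regressions give one effect ratio (exponentiated
coefficient — an odds ratio, reported under the tables' "rate ratio" label)
per skill domain with Wald 95% confidence intervals; a multivariable model
adds the four patient covariates (age, BMI, PSA, prostate volume) alongside
all six skill scores, and its per-case predicted probabilities feed the ROC
curve / AUC.

Case-level skill scores are the surgeon's mean predicted ideal-probability
per domain over their stitches (median available via ``aggregate``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from .datamodel import SUBSKILL_ORDER
from .evaluate import compute_auc

__all__ = [
    "AssociationRow",
    "fit_univariable",
    "fit_multivariable",
    "roc_from_predictions",
    "attach_case_scores",
    "COVARIATES",
]

COVARIATES = ("age", "bmi", "psa", "prostate_volume")


@dataclass
class AssociationRow:
    domain: str
    ratio: float            # exponentiated logistic coefficient
    ci_low: float
    ci_high: float
    p_value: float
    separation_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "domain": self.domain,
            "rate_ratio": self.ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "separation_flag": self.separation_flag,
        }


def _wald_row(domain: str, beta: float, se: float, p: float,
              flagged: bool = False) -> AssociationRow:
    return AssociationRow(
        domain=domain,
        ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p_value=float(p),
        separation_flag=flagged,
    )


def fit_univariable(scores, outcome, domain: str = "score") -> AssociationRow:
    """Maximum-likelihood logistic fit of the outcome on a single score."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if len(np.unique(outcome)) < 2:
        raise ValueError("outcome must contain both classes")
    if len(outcome) < 10:
        raise ValueError("need at least 10 cases")
    X = sm.add_constant(scores)
    flagged = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(outcome, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or res.bse[1] > 50:
            flagged = True
    except Exception:
        # complete separation: report a penalized refit, flagged
        flagged = True
        with np.errstate(all="ignore"):
            res = sm.Logit(outcome, X).fit_regularized(disp=0, alpha=1e-4, maxiter=500)
    beta = float(res.params[1])
    se = float(res.bse[1]) if hasattr(res, "bse") else np.nan
    p = float(res.pvalues[1]) if hasattr(res, "pvalues") else np.nan
    return _wald_row(domain, beta, se, p, flagged)


def fit_multivariable(
    table: pd.DataFrame,
    skill_columns: list[str] | None = None,
    outcome_column: str = "continence_3mo",
):
    """Joint logistic fit: six skill scores + four covariates + intercept.

    Returns (statsmodels result, predicted probabilities, association rows).
    Raises on rank-deficient design, naming the collinear columns.
    """
    skill_columns = skill_columns or [f"skill_{s.code}" for s in SUBSKILL_ORDER]
    cols = list(skill_columns) + list(COVARIATES)
    X = table[cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate values")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        bad = [c for c in cols if table[c].std() == 0]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1] + 1}); "
            f"zero-variance columns: {bad or 'collinear combination'}"
        )
    y = table[outcome_column].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    design = sm.add_constant(pd.DataFrame(X, columns=cols))
    with np.errstate(all="ignore"):
        res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    preds = np.asarray(res.predict(design), dtype=float)
    rows = [
        _wald_row(c, float(res.params[c]), float(res.bse[c]), float(res.pvalues[c]))
        for c in cols
    ]
    return res, preds, rows


def roc_from_predictions(predicted, outcome) -> tuple[pd.DataFrame, float]:
    """ROC curve points (monotone in both coordinates) and AUC."""
    predicted = np.asarray(predicted, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if len(np.unique(outcome)) < 2:
        raise ValueError("ROC is undefined with a single outcome class")
    fpr, tpr, thr = roc_curve(outcome, predicted)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, compute_auc(predicted, outcome)


def attach_case_scores(
    outcome_table: pd.DataFrame,
    stitch_scores: pd.DataFrame,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Attach per-domain case scores aggregated over each surgeon's stitches.

    ``stitch_scores`` needs a ``surgeon_id`` column plus one ``score_<code>``
    column per sub-skill (predicted ideal-probabilities).
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    score_cols = [f"score_{s.code}" for s in SUBSKILL_ORDER]
    agg = stitch_scores.groupby("surgeon_id")[score_cols].agg(aggregate)
    agg.columns = [f"skill_{s.code}" for s in SUBSKILL_ORDER]
    merged = outcome_table.drop(
        columns=[c for c in agg.columns if c in outcome_table.columns]
    ).merge(agg, left_on="surgeon_id", right_index=True, how="left")
    if merged[[f"skill_{s.code}" for s in SUBSKILL_ORDER]].isna().any().any():
        raise ValueError("some cases have no stitch scores for their surgeon")
    return merged
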