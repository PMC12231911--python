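"""Downstream evaluation statistics for signature scores.

Severity association (Spearman rho vs a SLEDAI-like score), Fisher
z-transformation of correlations and two-sample comparisons of z
distributions, responder vs non-responder t-tests, single-predictor logistic
regression with ROC/AUC, and covariance ranking of signatures against a
reference signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .sigscore import ScoreTable

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    signature: str
    statistic: float  # Spearman rho (or Pearson r)
    p: float
    n: int
    method: str = "spearman"


@dataclass
class ZComparison:
    group_a: str
    group_b: str
    z_a: np.ndarray
    z_b: np.ndarray
    d_mean: float
    p: float


@dataclass
class RocResult:
    signature: str
    auc: float
    n_responders: int
    n_nonresponders: int
    slope: float
    intercept: float


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def spearman_association(
    scores: pd.Series | np.ndarray,
    severity: pd.Series | np.ndarray,
    signature: str = "",
) -> AssociationResult:
    """Spearman rank correlation (average-rank ties) of score vs severity."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(severity, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input, correlation undefined")
        return AssociationResult(signature, float("nan"), float("nan"), len(x))
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(signature, float(rho), float(p), len(x))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher transformation z = atanh(r); requires |r| < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transformation")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def compare_z_distributions(
    z_a: np.ndarray | list[float],
    z_b: np.ndarray | list[float],
    label_a: str = "A",
    label_b: str = "B",
    equal_var: bool = True,
) -> ZComparison:
    """Two-sided two-sample t-test between two sets of Fisher z values.

    Classical pooled-variance Student test by default (Welch via
    ``equal_var=False``).  Two constant equal groups give p = 1 by
    convention.
    """
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    diff = float(a.mean() - b.mean())
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return ZComparison(group_a=label_a, group_b=label_b, z_a=a, z_b=b,
                       d_mean=diff, p=p)


# ---------------------------------------------------------------------------
# responder analyses
# ---------------------------------------------------------------------------

def responder_test(
    scores: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    equal_var: bool = True,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """t-test of mean signature score in responders (1) vs non-responders (0).

    Returns (d_mean, p) where d_mean = mean(responders) − mean(others).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both responder classes must be present")
    resp, nonresp = x[y == 1], x[y == 0]
    if len(resp) < 2 or len(nonresp) < 2:
        raise ValueError("each class needs at least 2 samples")
    res = stats.ttest_ind(resp, nonresp, equal_var=equal_var,
                          alternative=alternative)
    return float(resp.mean() - nonresp.mean()), float(res.pvalue)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware rank AUC (0.5 credit for ties)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = x[y == 1], x[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be nonempty")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def logistic_auc(
    scores: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    signature: str = "",
) -> RocResult:
    """Single-predictor logistic regression and AUC of predicted probabilities.

    The model is fitted by iteratively reweighted least squares; the AUC is
    the tie-aware trapezoidal ROC area of the predicted probabilities.  Since
    the logistic link is monotone, a positive fitted slope makes this equal
    to the rank AUC of the raw scores (asserted).  Under perfect separation
    the slope diverges; the AUC is then computed from the score ranks with a
    warning.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")

    design = sm.add_constant(x)
    slope = np.nan
    intercept = np.nan
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            intercept, slope = float(fit.params[0]), float(fit.params[1])
            if not np.all(np.isfinite(fit.params)):
                raise ValueError("non-finite coefficients")
            probs = np.asarray(fit.predict(design))
        auc = float(roc_auc_score(y, probs)) if np.ptp(probs) > 0 else 0.5
    except Exception:
        logger.warning(
            "logistic fit failed (perfect separation?); AUC from score ranks"
        )
        auc = mann_whitney_auc(x, y)
        slope = np.inf if auc >= 0.5 else -np.inf

    if np.isfinite(slope) and slope > 0:
        rank_auc = mann_whitney_auc(x, y)
        assert abs(auc - rank_auc) < 1e-9, "probability AUC != rank AUC"
    return RocResult(signature=signature, auc=auc, n_responders=n_pos,
                     n_nonresponders=n_neg, slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# signature similarity
# ---------------------------------------------------------------------------

def covariance_ranking(
    table: ScoreTable | pd.DataFrame,
    reference: str,
    k: int = 20,
) -> pd.Series:
    """Top-k signatures by sample covariance with a reference signature.

    Descending covariance, ties broken by name; returns all (with a note)
    when fewer than k other signatures exist.
    """
    scores = table.scores if isinstance(table, ScoreTable) else table
    if reference not in scores.columns:
        raise ValueError(f"reference signature {reference!r} not in table")
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    ref = scores[reference]
    others = scores.drop(columns=[reference])
    cov = others.apply(lambda col: col.cov(ref))
    if len(cov) < k:
        logger.info("only %d signatures available (k=%d)", len(cov), k)
    frame = cov.rename("covariance").reset_index().rename(columns={"index": "name"})
    frame = frame.sort_values(["covariance", "name"], ascending=[False, True])
    ranked = frame.set_index("name")["covariance"]
    return ranked.head(k)
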