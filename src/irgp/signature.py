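"""IRGPI risk scores, time-dependent ROC cutoff selection, risk groups.

The risk score of a sample is

    IRGPI(s) = sum_k  value_k(s) * coef_k,

where value_k(s) = 1 iff the first gene of pair k out-expresses the
second in sample s.  The score therefore lives on the attainable lattice
between the sum of negative and the sum of positive coefficients, and is
invariant to any strictly increasing per-sample transform of expression.

The high/low risk cutoff is chosen on a cumulative/dynamic time-dependent
ROC at a fixed horizon (default one year): cases are samples with an
event by the horizon, controls samples still under follow-up past it, and
censoring before the horizon enters through inverse-probability-of-
censoring weights (Kaplan-Meier estimate of the censoring distribution,
Uno-type).  The chosen cutoff is the candidate threshold closest, in
Euclidean distance, to the ideal corner (FPR 0, TPR 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix, FittedSignature

logger = logging.getLogger(__name__)

__all__ = [
    "TimeDependentROC",
    "score",
    "select_cutoff",
    "assign_groups",
    "horizon_in_units",
    "ipcw_roc",
]

_YEAR_LENGTH = {"days": 365.25, "months": 12.0, "years": 1.0}


def horizon_in_units(years: float, time_unit: str) -> float:
    """Convert a horizon in years into the clinical table's time unit."""
    try:
        return years * _YEAR_LENGTH[time_unit]
    except KeyError:
        raise ValueError(f"unsupported time unit {time_unit!r}") from None


@dataclass(frozen=True)
class TimeDependentROC:
    """IPCW ROC at a fixed horizon with the chosen corner-distance cutoff."""

    horizon: float
    thresholds: np.ndarray  # ascending; includes -inf and +inf
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_cutoff: float


def score(
    expr: ExpressionMatrix, sig: FittedSignature
) -> pd.Series:
    """IRGPI risk score per sample under a fitted signature.

    Uses the signature's own pair orientation (for the published signature,
    the printed one).  Every signature gene must be present in ``expr``.
    """
    if len(sig) == 0:
        raise ValueError("empty signature")
    missing = sorted(sig.genes - set(expr.data.index))
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    coefs = np.asarray(sig.coefficients)
    g1 = expr.data.loc[[p[0] for p in sig.pairs]].to_numpy(dtype=float)
    g2 = expr.data.loc[[p[1] for p in sig.pairs]].to_numpy(dtype=float)
    values = (g1 > g2).astype(float)  # pairs x samples, ties -> 0
    irgpi = values.T @ coefs
    return pd.Series(irgpi, index=expr.sample_ids, name="irgpi")


def _km_censoring(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Returns (times, G) as a right-continuous step function; censoring is
    the 'event' here, deaths are the censored observations.
    """
    order = np.argsort(time, kind="mergesort")
    t, cens = time[order], (1 - event[order])
    uniq = np.unique(t)
    n = len(t)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    d_cens = np.array([int(cens[t == u].sum()) for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(at_risk > 0, 1.0 - d_cens / at_risk, 1.0)
    return uniq, np.cumprod(factors)


def _step_eval(xs: np.ndarray, ys: np.ndarray, t: np.ndarray, left: bool) -> np.ndarray:
    """Evaluate a right-continuous step function (value 1 before the first x).

    ``left`` requests the left limit G(t-).
    """
    idx = np.searchsorted(xs, t, side="left" if left else "right") - 1
    out = np.ones(np.shape(t), dtype=float)
    valid = idx >= 0
    out[valid] = ys[idx[valid]]
    return out


def ipcw_roc(
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
) -> TimeDependentROC:
    """Cumulative/dynamic time-dependent ROC with IPCW at ``horizon``.

    Cases: event by the horizon, weighted 1/G(t_i-); controls: follow-up
    beyond the horizon, weighted 1/G(horizon).  Samples censored before
    the horizon contribute through the weights, not by exclusion.
    Candidate thresholds are midpoints between consecutive distinct scores
    plus +/- infinity; ties in corner distance resolve to the lower
    threshold (the larger high-risk group).
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    is_case = (time <= horizon) & (event == 1)
    is_control = time > horizon
    if not is_case.any():
        raise ValueError("no events before the horizon")
    if not is_control.any():
        raise ValueError("no samples at risk beyond the horizon")
    km_t, km_g = _km_censoring(time, event)
    w = np.zeros_like(scores)
    g_case = _step_eval(km_t, km_g, time[is_case], left=True)
    g_ctrl = float(_step_eval(km_t, km_g, np.array([horizon]), left=False)[0])
    if (g_case <= 0).any() or g_ctrl <= 0:
        raise ValueError("censoring distribution vanishes before the horizon")
    w[is_case] = 1.0 / g_case
    w[is_control] = 1.0 / g_ctrl

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    s_case, w_case = scores[is_case], w[is_case]
    s_ctrl, w_ctrl = scores[is_control], w[is_control]
    tot_case, tot_ctrl = w_case.sum(), w_ctrl.sum()
    tpr = np.array([w_case[s_case > c].sum() for c in thresholds]) / tot_case
    fpr = np.array([w_ctrl[s_ctrl > c].sum() for c in thresholds]) / tot_ctrl

    # weighted case/control concordance (ties at half weight)
    gt = (s_case[:, None] > s_ctrl[None, :]).astype(float)
    eq = (s_case[:, None] == s_ctrl[None, :]).astype(float)
    auc = float((w_case[:, None] * w_ctrl[None, :] * (gt + 0.5 * eq)).sum()
                / (tot_case * tot_ctrl))

    dist2 = fpr**2 + (1.0 - tpr) ** 2
    chosen = float(thresholds[int(np.argmin(dist2))])  # first = lowest threshold
    return TimeDependentROC(
        horizon=float(horizon), thresholds=thresholds, tpr=tpr, fpr=fpr,
        auc=auc, chosen_cutoff=chosen,
    )


def select_cutoff(
    scores: pd.Series,
    clinical: ClinicalTable,
    horizon_years: float = 1.0,
) -> TimeDependentROC:
    """Choose the risk cutoff by the time-dependent ROC corner rule.

    ``horizon_years`` is converted into the clinical table's declared
    time unit (1 year = 365.25 days or 12 months).
    """
    clin = clinical.subset(list(scores.index))
    horizon = horizon_in_units(horizon_years, clin.time_unit)
    roc = ipcw_roc(
        scores.to_numpy(), clin.time.to_numpy(), clin.event.to_numpy(), horizon
    )
    logger.info(
        "cutoff %.4g chosen at %.3g %s horizon (AUC %.3f)",
        roc.chosen_cutoff, horizon, clin.time_unit, roc.auc,
    )
    return roc


def assign_groups(scores: pd.Series, cutoff: float) -> pd.DataFrame:
    """Split samples into high (score > cutoff, strict) and low risk."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    group = np.where(scores.to_numpy() > cutoff, "high", "low")
    out = pd.DataFrame({"irgpi": scores, "group": group}, index=scores.index)
    out.index.name = "sample_id"
    n_high = int((group == "high").sum())
    logger.info("risk groups: %d high, %d low (cutoff %.4g)", n_high, len(group) - n_high, cutoff)
    return out
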