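"""Univariate survival screening of candidate gene pairs.

Each binary pair indicator is tested against overall survival twice: a
two-sample Mantel-Haenszel log-rank test and a univariate Cox
proportional-hazards fit (Efron ties).  Pairs passing the per-test alpha
feed the penalized model; no multiplicity correction is applied at this
stage because the lasso that follows performs its own selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .data_io import ClinicalTable
from .pair_transform import PairMatrix

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "CoxSeparationError", "logrank_test", "univariate_cox", "screen_pairs"]


class CoxSeparationError(RuntimeError):
    """Monotone likelihood / non-convergence in a univariate Cox fit."""


@dataclass(frozen=True)
class ScreenResult:
    """Per-pair screening statistics: log-rank and univariate Cox."""

    pair: tuple[str, str]
    chi_square: float
    logrank_p: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    cox_p: float
    p_value: float  # the p used for selection (cox by default)


def logrank_test(
    group: np.ndarray | pd.Series, clinical: ClinicalTable
) -> tuple[float, float]:
    """Two-sample Mantel-Haenszel log-rank test between group 1 and group 0.

    Returns (chi_square, p_value) with p from a 1-df chi-square.  Requires
    both groups non-empty; with zero events overall the test is undefined
    and (0, 1) is returned with a warning.
    """
    group = np.asarray(group)
    if group.shape[0] != len(clinical.data):
        raise ValueError("group vector and clinical table differ in length")
    if not np.isin(group, (0, 1)).all():
        raise ValueError("group vector must be binary")
    if group.min() == group.max():
        raise ValueError("both groups must be non-empty")
    time = clinical.time.to_numpy()
    event = clinical.event.to_numpy()
    if event.sum() == 0:
        warnings.warn("no events in either group; log-rank test undefined, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(
        time[group == 0], time[group == 1],
        event_observed_A=event[group == 0], event_observed_B=event[group == 1],
    )
    return float(res.test_statistic), float(res.p_value)


def univariate_cox(
    covariate: np.ndarray | pd.Series, clinical: ClinicalTable
) -> tuple[float, float, float, float]:
    """Univariate Cox fit of one covariate: (HR, ci_low, ci_high, p_value).

    Partial-likelihood estimate with Efron tie handling and Wald 95% CI.
    Raises :class:`CoxSeparationError` on monotone likelihood or
    non-convergence, ``ValueError`` for a constant covariate.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != len(clinical.data):
        raise ValueError("covariate and clinical table differ in length")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    df = pd.DataFrame(
        {"time": clinical.time.to_numpy(), "event": clinical.event.to_numpy(), "x": x}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, RuntimeWarning, Warning) as exc:
        raise CoxSeparationError(f"univariate Cox did not converge: {exc}") from exc
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 20:
        raise CoxSeparationError("monotone likelihood (perfect separation)")
    p = float(cph.summary.loc["x", "p"])
    return float(np.exp(coef)), float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se)), p


def screen_pairs(
    pm: PairMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    select_on: str = "cox",
) -> list[ScreenResult]:
    """Screen every pair against overall survival; keep raw p < ``alpha``.

    ``select_on`` chooses the selection p-value: "cox" (univariate Cox
    Wald p, the default) or "logrank".  Pairs with perfect separation or
    non-convergent fits are excluded.  Results are sorted by selection p.
    """
    if select_on not in ("cox", "logrank"):
        raise ValueError("select_on must be 'cox' or 'logrank'")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    clin = clinical.subset(pm.sample_ids)
    results: list[ScreenResult] = []
    n_flagged = 0
    for pair, (_, row) in zip(pm.pairs, pm.data.iterrows()):
        values = row.to_numpy()
        if values.min() == values.max():
            n_flagged += 1
            continue
        chi2, lr_p = logrank_test(values, clin)
        try:
            hr, lo, hi, cox_p = univariate_cox(values, clin)
        except CoxSeparationError:
            n_flagged += 1
            continue
        p_sel = cox_p if select_on == "cox" else lr_p
        results.append(
            ScreenResult(
                pair=pair, chi_square=chi2, logrank_p=lr_p,
                hazard_ratio=hr, hr_ci_low=lo, hr_ci_high=hi,
                cox_p=cox_p, p_value=p_sel,
            )
        )
    if n_flagged:
        logger.info("excluded %d pairs (constant or separation/non-convergence)", n_flagged)
    selected = sorted((r for r in results if r.p_value < alpha), key=lambda r: r.p_value)
    logger.info("screening kept %d of %d pairs at alpha=%g", len(selected), pm.n_pairs, alpha)
    return selected


def results_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabulate screening results for export."""
    return pd.DataFrame(
        {
            "pair": [f"{a}|{b}" for a, b in (r.pair for r in results)],
            "hazard_ratio": [r.hazard_ratio for r in results],
            "hr_ci_low": [r.hr_ci_low for r in results],
            "hr_ci_high": [r.hr_ci_high for r in results],
            "chi_square": [r.chi_square for r in results],
            "logrank_p": [r.logrank_p for r in results],
            "cox_p": [r.cox_p for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
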