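"""Validation of a risk stratification.

Kaplan-Meier curves with a log-rank comparison between risk groups,
time-dependent AUC at fixed horizons (same IPCW estimator as cutoff
selection), univariable and multivariable Cox models combining the
signature with clinical covariates, and plain diagnostic ROC between
sample classes (e.g. histological subtypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from sklearn.metrics import roc_auc_score

from .data_io import ClinicalTable
from .screening import logrank_test
from .signature import horizon_in_units, ipcw_roc

logger = logging.getLogger(__name__)

__all__ = ["KMCurve", "CoxFit", "km_logrank", "td_auc", "cox_with_covariates", "binary_roc"]

_STAGE_MAP = {
    "I": 1, "II": 2, "III": 3, "IV": 4,
    "STAGE I": 1, "STAGE II": 2, "STAGE III": 3, "STAGE IV": 4,
}


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group."""

    label: str
    times: np.ndarray  # sorted event/censoring times
    survival: np.ndarray  # step-function values, starts at 1
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing")


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate hazard ratios with Wald CIs from a Cox model."""

    table: pd.DataFrame  # index covariate; columns hazard_ratio, ci_low, ci_high, p_value
    covariates: tuple[str, ...]
    n: int
    n_events: int


def km_logrank(
    assign: pd.DataFrame, clinical: ClinicalTable
) -> tuple[dict[str, KMCurve], float, float]:
    """KM curves per risk group plus the two-sample log-rank test.

    ``assign`` is the output of :func:`irgp.signature.assign_groups`.
    """
    clin = clinical.subset(list(assign.index))
    groups = assign["group"].to_numpy()
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need both risk groups to compare survival")
    curves: dict[str, KMCurve] = {}
    for label in labels:
        mask = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(clin.time.to_numpy()[mask], clin.event.to_numpy()[mask], label=label)
        tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
        times = tbl.index.to_numpy(dtype=float)
        curves[label] = KMCurve(
            label=label,
            times=times,
            survival=kmf.survival_function_at_times(times).to_numpy(),
            at_risk=tbl["at_risk"].to_numpy(),
        )
    binary = (groups == labels[1]).astype(int)
    chi2, p = logrank_test(binary, clin)
    return curves, chi2, p


def td_auc(
    scores: pd.Series,
    clinical: ClinicalTable,
    horizons_years: list[float] = (1.0, 3.0, 5.0),
) -> dict[float, float]:
    """IPCW time-dependent AUC of a risk score at each horizon (in years)."""
    clin = clinical.subset(list(scores.index))
    out: dict[float, float] = {}
    for h in horizons_years:
        horizon = horizon_in_units(h, clin.time_unit)
        roc = ipcw_roc(
            scores.to_numpy(), clin.time.to_numpy(), clin.event.to_numpy(), horizon
        )
        out[float(h)] = roc.auc
    return out


def _encode_covariates(
    clinical: ClinicalTable,
    covariates: list[str],
    stage_as_ordinal: bool,
    reference_levels: dict[str, str] | None,
) -> pd.DataFrame:
    reference_levels = reference_levels or {}
    cols: dict[str, pd.Series] = {}
    for name in covariates:
        if name not in clinical.data.columns:
            raise KeyError(f"covariate {name!r} absent from clinical table")
        col = clinical.data[name]
        if name == "stage" and stage_as_ordinal:
            if col.dtype == object:
                mapped = col.astype(str).str.strip().str.upper().map(_STAGE_MAP)
                if mapped.isna().any():
                    raise ValueError("unrecognized stage labels; use I-IV or numbers")
                col = mapped
            cols[name] = col.astype(float)
        elif pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            ref = reference_levels.get(name, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed for {name!r}")
            for lev in levels:
                if lev != ref:
                    cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=clinical.data.index)


def _check_collinear(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank >= X.shape[1]:
        return
    # name columns exactly predictable from the preceding ones
    offending = []
    for j in range(1, X.shape[1]):
        prev, col = centered[:, :j], centered[:, j]
        beta, *_ = np.linalg.lstsq(prev, col, rcond=None)
        resid = col - prev @ beta
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(col)):
            offending.append(X.columns[j])
    raise ValueError(f"collinear covariates: {offending or list(X.columns)}")


def cox_with_covariates(
    assign_or_score: pd.DataFrame | pd.Series,
    clinical: ClinicalTable,
    covariates: list[str] = (),
    *,
    use_score: bool = False,
    stage_as_ordinal: bool = True,
    reference_levels: dict[str, str] | None = None,
) -> CoxFit:
    """Cox model of survival on the signature plus clinical covariates.

    The signature enters as the binary high-risk indicator by default; set
    ``use_score`` to use the continuous IRGPI instead (requires a score
    Series or an assignment frame with an ``irgpi`` column).  Stage is
    ordinal numeric (I-IV -> 1-4) unless ``stage_as_ordinal`` is false;
    other categorical covariates are one-hot encoded against a reference
    level (lowest sorted level unless declared).
    """
    if isinstance(assign_or_score, pd.Series):
        risk = assign_or_score.astype(float).rename("riskScore")
        if not use_score:
            raise ValueError("a bare score Series requires use_score=True")
    else:
        if use_score:
            risk = assign_or_score["irgpi"].astype(float).rename("riskScore")
        else:
            risk = (assign_or_score["group"] == "high").astype(float).rename("riskGroup")
    clin = clinical.subset(list(risk.index))
    X = _encode_covariates(clin, list(covariates), stage_as_ordinal, reference_levels)
    X.insert(0, risk.name, risk)
    _check_collinear(X)
    df = X.copy()
    df["time"] = clin.time
    df["event"] = clin.event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    table = pd.DataFrame(
        {
            "hazard_ratio": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef"] - 1.96 * summary["se(coef)"]),
            "ci_high": np.exp(summary["coef"] + 1.96 * summary["se(coef)"]),
            "p_value": summary["p"],
        },
        index=summary.index,
    )
    return CoxFit(
        table=table,
        covariates=tuple(X.columns),
        n=len(df),
        n_events=int(clin.event.sum()),
    )


def binary_roc(scores: pd.Series | np.ndarray, labels: np.ndarray) -> float:
    """Standard (non-survival) ROC AUC of a score against binary labels.

    Midrank tie handling; equals the Mann-Whitney U statistic divided by
    n1*n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be non-empty")
    return float(roc_auc_score(labels, scores))
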