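"""Clinical-relevance utilities: Kaplan-Meier / log-rank and Cox models.

Thin, validated wrappers around lifelines.  Group comparisons use the
k-group log-rank chi-square (k-1 degrees of freedom); hazard modeling uses
Cox proportional hazards with Efron tie handling, reported both univariate
and adjusted for a supplied covariate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


@dataclass
class SurvivalOutcome:
    group_summary: pd.DataFrame  # n, events, median survival per group
    logrank_stat: float | None = None
    logrank_p: float | None = None
    hazard_table: pd.DataFrame | None = None  # per covariate: HR, CI, p (uni + adjusted)
    km_fitters: dict = field(default_factory=dict)


def _check_inputs(times: np.ndarray, events: np.ndarray) -> None:
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")


def km_logrank(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
) -> SurvivalOutcome:
    """Per-group Kaplan-Meier estimates and the k-group log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    _check_inputs(times, events)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() == 0:
        raise ValueError("empty group")
    fitters = {}
    rows = []
    for g in labels:
        mask = groups == g
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(times[mask], events[mask])
        fitters[g] = kmf
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "events": int(events[mask].sum()),
                "median_survival": float(kmf.median_survival_time_),
            }
        )
    res = multivariate_logrank_test(times, groups, events)
    return SurvivalOutcome(
        group_summary=pd.DataFrame(rows).set_index("group"),
        logrank_stat=float(res.test_statistic),
        logrank_p=float(res.p_value),
        km_fitters=fitters,
    )


def cox_fit(
    times: pd.Series,
    events: pd.Series,
    covariates: pd.DataFrame,
    adjustment: pd.DataFrame | None = None,
    ties: str = "efron",
) -> SurvivalOutcome:
    """Univariate and (optionally) adjusted Cox proportional-hazards fits.

    Each column of ``covariates`` is fitted alone ("univariate" rows) and,
    when ``adjustment`` covariates are given, together with them
    ("adjusted" rows).  Complete cases only; dropped rows are logged.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    base = pd.DataFrame({"time": np.asarray(times, float), "event": np.asarray(events)})
    base.index = covariates.index
    _check_inputs(base["time"].to_numpy(), base["event"].to_numpy())
    frames = [base, covariates]
    if adjustment is not None:
        frames.append(adjustment)
    data = pd.concat(frames, axis=1)
    complete = data.dropna()
    if len(complete) < len(data):
        logger.info("cox_fit: dropped %d incomplete cases", len(data) - len(complete))

    rows = []
    for cov in covariates.columns:
        specs = [("univariate", [cov])]
        if adjustment is not None:
            specs.append(("adjusted", [cov] + list(adjustment.columns)))
        for kind, cols in specs:
            if ties == "efron":
                cph = CoxPHFitter()
                cph.fit(
                    complete[["time", "event"] + cols],
                    duration_col="time",
                    event_col="event",
                )
                s = cph.summary.loc[cov]
                coef, hr = float(s["coef"]), float(s["exp(coef)"])
                lo, hi = float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])
                p = float(s["p"])
            else:  # Breslow tie handling via statsmodels PHReg
                from statsmodels.duration.hazard_regression import PHReg

                model = PHReg(
                    complete["time"].to_numpy(),
                    complete[cols].to_numpy(dtype=float),
                    status=complete["event"].to_numpy(),
                    ties="breslow",
                )
                fit = model.fit()
                j = cols.index(cov)
                coef = float(fit.params[j])
                se = float(fit.bse[j])
                hr = float(np.exp(coef))
                lo, hi = float(np.exp(coef - 1.959964 * se)), float(np.exp(coef + 1.959964 * se))
                p = float(fit.pvalues[j])
            rows.append(
                {
                    "covariate": cov,
                    "model": kind,
                    "log_hr": coef,
                    "hr": hr,
                    "hr_ci_low": lo,
                    "hr_ci_high": hi,
                    "p": p,
                }
            )
    events_n = int(complete["event"].sum())
    summary = pd.DataFrame(
        [{"group": "all", "n": len(complete), "events": events_n, "median_survival": float("nan")}]
    ).set_index("group")
    return SurvivalOutcome(group_summary=summary, hazard_table=pd.DataFrame(rows))
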