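"""Association of the standardized GRS with disease risk and mortality.

Case-control outcomes are modelled with additive logistic regression
(log-odds per SD of the score, covariate-adjusted); survival outcomes with
the Cox proportional-hazards model (Efron ties).  Batches of outcomes share
one Benjamini-Hochberg FDR family and a minimum-case inclusion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from statsmodels.stats.multitest import multipletests

from .grs import GrsVector

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class FitError(RuntimeError):
    """Model fit failed or is untrustworthy (separation, non-convergence)."""


@dataclass
class CaseControlCohort:
    """Binary outcome plus covariates; y=1 marks a case."""

    y: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("y must be binary 0/1")
        if len(self.y) != len(self.covariates):
            raise ValueError("y and covariates have different lengths")

    def validate_for_fit(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise FitError("outcome contains a single class; logistic fit undefined")

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())


@dataclass
class SurvivalCohort:
    """Right-censored follow-up plus covariates; event=1 marks death/event."""

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.event = np.asarray(self.event)
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event must be binary 0/1")
        if not (len(self.time) == len(self.event) == len(self.covariates)):
            raise ValueError("time, event and covariates have different lengths")

    def validate_for_fit(self) -> None:
        if self.event.sum() == 0:
            raise FitError("no events observed; Cox fit undefined")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class AssociationResult:
    """One fitted coefficient on the exp scale with its Wald inference."""

    outcome: str
    term: str
    theta: float
    se: float
    effect_measure: str  # "OR" or "HR"
    estimate: float
    ci95: tuple[float, float]
    pvalue: float
    n: int
    n_cases_or_events: int
    fdr: float | None = None

    @classmethod
    def from_wald(
        cls,
        outcome: str,
        term: str,
        theta: float,
        se: float,
        effect_measure: str,
        n: int,
        n_cases_or_events: int,
        pvalue: float,
    ) -> "AssociationResult":
        return cls(
            outcome=outcome,
            term=term,
            theta=float(theta),
            se=float(se),
            effect_measure=effect_measure,
            estimate=float(np.exp(theta)),
            ci95=(float(np.exp(theta - Z_95 * se)), float(np.exp(theta + Z_95 * se))),
            pvalue=float(pvalue),
            n=int(n),
            n_cases_or_events=int(n_cases_or_events),
        )


def standardize_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Z-score continuous covariates; leave binary columns as 0/1."""
    out = covariates.copy()
    for col in out.columns:
        vals = out[col].to_numpy(float)
        uniq = np.unique(vals[~np.isnan(vals)])
        if len(uniq) <= 2:
            continue
        sd = vals.std(ddof=0)
        if sd > 0:
            out[col] = (vals - vals.mean()) / sd
    return out


def _design(grs: GrsVector | np.ndarray, covariates: pd.DataFrame) -> pd.DataFrame:
    score = grs.standardized if isinstance(grs, GrsVector) else np.asarray(grs, float)
    if len(score) != len(covariates):
        raise ValueError("GRS length does not match cohort size")
    X = pd.DataFrame({"grs": score}, index=covariates.index)
    X = pd.concat([X, standardize_covariates(covariates)], axis=1)
    return X


def fit_logistic_grs(
    cohort: CaseControlCohort, grs: GrsVector | np.ndarray, outcome: str = "outcome"
) -> AssociationResult:
    """Additive logistic regression of case status on the standardized GRS.

    Returns the odds ratio per SD of the score with Wald 95% CI and p-value.
    Raises :class:`FitError` on non-convergence or (quasi-)separation rather
    than returning a silent estimate.
    """
    cohort.validate_for_fit()
    X = sm.add_constant(_design(grs, cohort.covariates), has_constant="add")
    try:
        fit = sm.Logit(cohort.y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and numeric failures
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if not np.isfinite(fit.bse["grs"]) or fit.bse["grs"] > 1e3:
        raise FitError("logistic fit unstable (separation suspected)")
    return AssociationResult.from_wald(
        outcome=outcome,
        term="grs",
        theta=fit.params["grs"],
        se=fit.bse["grs"],
        effect_measure="OR",
        n=len(cohort.y),
        n_cases_or_events=cohort.n_cases,
        pvalue=fit.pvalues["grs"],
    )


def fit_cox_grs(
    cohort: SurvivalCohort, grs: GrsVector | np.ndarray, outcome: str = "outcome"
) -> AssociationResult:
    """Cox proportional-hazards fit of survival on the standardized GRS."""
    cohort.validate_for_fit()
    X = _design(grs, cohort.covariates)
    frame = X.copy()
    frame["time"] = cohort.time
    frame["event"] = cohort.event
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:
        raise FitError(f"Cox fit failed: {exc}") from exc
    theta = float(cph.params_["grs"])
    se = float(cph.standard_errors_["grs"])
    if not np.isfinite(se) or se > 1e3:
        raise FitError("Cox fit unstable")
    return AssociationResult.from_wald(
        outcome=outcome,
        term="grs",
        theta=theta,
        se=se,
        effect_measure="HR",
        n=len(cohort.time),
        n_cases_or_events=cohort.n_events,
        pvalue=float(cph.summary.loc["grs", "p"]),
    )


def test_interaction(
    cohort: CaseControlCohort | SurvivalCohort,
    grs: GrsVector | np.ndarray,
    covariate_name: str,
    outcome: str = "outcome",
) -> AssociationResult:
    """Wald test of the GRS x covariate product term in the refit model."""
    if covariate_name not in cohort.covariates.columns:
        raise ValueError(f"covariate {covariate_name!r} not in cohort design")
    cov = cohort.covariates[covariate_name].to_numpy(float)
    if len(np.unique(cov)) < 2:
        raise ValueError(f"covariate {covariate_name!r} is constant; interaction undefined")
    X = _design(grs, cohort.covariates)
    term = f"grs_x_{covariate_name}"
    X[term] = X["grs"] * X[covariate_name]
    if isinstance(cohort, CaseControlCohort):
        cohort.validate_for_fit()
        Xc = sm.add_constant(X, has_constant="add")
        fit = sm.Logit(cohort.y, Xc).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", False):
            raise FitError("interaction logistic fit did not converge")
        return AssociationResult.from_wald(
            outcome, term, fit.params[term], fit.bse[term], "OR",
            len(cohort.y), cohort.n_cases, fit.pvalues[term],
        )
    cohort.validate_for_fit()
    frame = X.copy()
    frame["time"] = cohort.time
    frame["event"] = cohort.event
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    return AssociationResult.from_wald(
        outcome, term, float(cph.params_[term]), float(cph.standard_errors_[term]),
        "HR", len(cohort.time), cohort.n_events, float(cph.summary.loc[term, "p"]),
    )


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_significance(p: float, fdr: float) -> str:
    """Study-wide decision rule: FDR<0.05 significant, else p<0.05 suggestive."""
    if fdr < 0.05:
        return "significant"
    if p < 0.05:
        return "suggestive"
    return "null"


def run_association_batch(
    outcomes: Sequence[tuple[str, CaseControlCohort | SurvivalCohort, GrsVector | np.ndarray]],
    min_cases: int = 60,
) -> pd.DataFrame:
    """Fit every outcome against its score and control the batch FDR.

    Case-control outcomes below ``min_cases`` cases are excluded (recorded in
    the result's ``attrs['excluded']``), mirroring the minimum-case inclusion
    rule used when many cancers share one control pool.  Returns one row per
    retained outcome with OR/HR, CI, p, FDR and classification.
    """
    if not outcomes:
        raise ValueError("no outcomes supplied")
    results: list[AssociationResult] = []
    excluded: list[tuple[str, str]] = []
    for name, cohort, grs in outcomes:
        if isinstance(cohort, CaseControlCohort) and cohort.n_cases < min_cases:
            excluded.append((name, f"cases {cohort.n_cases} < {min_cases}"))
            continue
        if isinstance(cohort, CaseControlCohort):
            results.append(fit_logistic_grs(cohort, grs, outcome=name))
        else:
            results.append(fit_cox_grs(cohort, grs, outcome=name))
    if not results:
        raise ValueError("no outcomes left after the minimum-case filter")
    fdrs = adjust_fdr([r.pvalue for r in results])
    rows = []
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
        rows.append(
            {
                "outcome": r.outcome,
                "effect_measure": r.effect_measure,
                "estimate": r.estimate,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "theta": r.theta,
                "se": r.se,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "classification": classify_significance(r.pvalue, r.fdr),
                "n": r.n,
                "n_cases_or_events": r.n_cases_or_events,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["excluded"] = excluded
    return table
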