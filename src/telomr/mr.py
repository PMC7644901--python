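"""Two-sample Mendelian randomization estimators and sensitivity battery.

All estimators consume a :class:`~telomr.instruments.HarmonizedSet` of per-SNP
exposure/outcome effect pairs (beta_x, se_x, beta_y, se_y) aligned to the
same effect allele.  The causal parameter theta is the log-odds of outcome
per unit of exposure (here, per SD of shorter telomere length).

Estimators
----------
wald_ratio        single-instrument ratio beta_y/beta_x
ivw               inverse-variance weighted slope (fixed or multiplicative
                  random effects), the primary estimator
weighted_median   median of the weighted ratio distribution; consistent when
                  under half the weight comes from invalid instruments
max_likelihood    joint-normal likelihood with per-SNP true exposure effects
                  profiled out
egger             weighted regression with a free intercept; the intercept
                  tests directional horizontal pleiotropy

Sensitivity
-----------
cochran_q         heterogeneity of per-SNP ratios about the pooled slope
leave_one_out     influence of each single instrument
mr_presso         simulation-based residual-sum-of-squares outlier test
run_mr_battery    the full suite plus a robustness decision rule
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .instruments import HarmonizedSet

Z_95 = 1.959963984540054


class MRError(ValueError):
    """Estimator preconditions violated (too few instruments, degenerate data)."""


@dataclass
class MREstimate:
    method: str
    theta: float
    se: float
    pvalue: float
    k: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.theta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.theta - Z_95 * self.se)),
            float(np.exp(self.theta + Z_95 * self.se)),
        )


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


@dataclass
class PressoResult:
    rss_observed: float
    global_p: float
    outlier_flags: np.ndarray
    outlier_p: np.ndarray
    rsids: list[str]
    n_sim: int
    seed: int | None

    @property
    def has_outlier(self) -> bool:
        return bool(self.outlier_flags.any())


def _wald_p(theta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(theta) / se))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-instrument causal ratio with first-order delta-method SE."""
    if beta_x == 0:
        raise MRError("wald ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return MREstimate("wald_ratio", float(theta), float(se), _wald_p(theta, se), k=1)


def ivw(hset: HarmonizedSet, model: Literal["fixed", "random"] = "fixed") -> MREstimate:
    """Inverse-variance weighted causal slope.

    Fixed effects: theta = sum(w*bx*by)/sum(w*bx^2) with w = 1/se_y^2 and
    var(theta) = 1/sum(w*bx^2).  Multiplicative random effects inflate the
    SE by max(1, sqrt(Q/(k-1))) to absorb excess heterogeneity.
    """
    bx, _, by, sy = hset.arrays()
    k = len(bx)
    if k < 1:
        raise MRError("no instruments")
    if model == "random" and k < 2:
        raise MRError("random-effects IVW needs at least 2 instruments")
    if np.all(bx == 0):
        raise MRError("all exposure effects are zero")
    if k == 1:
        # exact reduction to the single-instrument ratio
        est = wald_ratio(float(bx[0]), float(hset.table["se_x"].iloc[0]),
                         float(by[0]), float(sy[0]))
        return MREstimate("ivw_fixed", est.theta, est.se, est.pvalue, k=1)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * by * bx) / denom)
    se = float(np.sqrt(1.0 / denom))
    if model == "random":
        q = float(np.sum((bx**2 / sy**2) * (by / bx - theta) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return MREstimate(f"ivw_{model}", theta, se, _wald_p(theta, se), k=k)


def cochran_q(hset: HarmonizedSet, theta: float | None = None) -> HeterogeneityResult:
    """Cochran's Q heterogeneity of per-SNP ratio estimates about theta.

    Q = sum_j w_j (beta_yj/beta_xj - theta)^2, w_j = beta_xj^2/var(beta_yj);
    referred to chi-square with k-1 df.  Defaults theta to the fixed IVW.
    """
    bx, _, by, sy = hset.arrays()
    k = len(bx)
    if k < 2:
        raise MRError("Cochran's Q needs at least 2 instruments")
    if theta is None:
        theta = ivw(hset, "fixed").theta
    w = bx**2 / sy**2
    q = float(np.sum(w * (by / bx - theta) ** 2))
    p = float(stats.chi2.sf(q, k - 1))
    return HeterogeneityResult(Q=q, df=k - 1, pvalue=max(p, np.finfo(float).tiny))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted median of per-SNP ratios, bootstrap SE.

    Weights are the inverse first-order variances of the ratios,
    beta_x^2/se_y^2; the estimate interpolates the weighted empirical
    distribution at cumulative weight 1/2.  The SE comes from a parametric
    bootstrap resampling (beta_x, beta_y) from their reported normals.
    """
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    if k < 3:
        raise MRError("weighted median needs at least 3 instruments")
    ratios = by / bx
    weights = bx**2 / sy**2
    est = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(bys[b] / bxs[b], bxs[b] ** 2 / sy**2)
    se = float(boots.std(ddof=1))
    return MREstimate("weighted_median", est, se, _wald_p(est, se), k=k)


def _ml_profile_negll(theta: float, bx, sx, by, sy) -> float:
    # per-SNP true exposure effects profiled out analytically
    return float(0.5 * np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)
                              + np.log(sy**2 + theta**2 * sx**2)))


def max_likelihood(hset: HarmonizedSet) -> MREstimate:
    """Maximum-likelihood causal slope under joint normal measurement error.

    Model: beta_xj ~ N(mu_j, se_xj^2), beta_yj ~ N(theta*mu_j, se_yj^2) with
    the nuisance mu_j profiled out, leaving a 1-D profile likelihood in
    theta.  SE from the numerically observed information at the optimum.
    """
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    if k < 2:
        raise MRError("maximum likelihood needs at least 2 instruments")
    start = ivw(hset, "fixed").theta
    res = optimize.minimize_scalar(
        _ml_profile_negll,
        bracket=(start - 1.0, start, start + 1.0),
        args=(bx, sx, by, sy),
        method="brent",
    )
    if not res.success or not np.isfinite(res.x):
        raise MRError(f"likelihood optimizer failed: {res}")
    theta = float(res.x)
    h = max(1e-5, 1e-5 * abs(theta))
    d2 = (
        _ml_profile_negll(theta + h, bx, sx, by, sy)
        - 2.0 * _ml_profile_negll(theta, bx, sx, by, sy)
        + _ml_profile_negll(theta - h, bx, sx, by, sy)
    ) / h**2
    if d2 <= 0:
        raise MRError("likelihood not locally concave at the optimum")
    se = float(1.0 / np.sqrt(d2))
    return MREstimate("max_likelihood", theta, se, _wald_p(theta, se), k=k)


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Instruments are first oriented so every beta_x >= 0 (the intercept is
    only interpretable under that convention).  beta_y is regressed on
    beta_x with weights 1/se_y^2; the slope is the pleiotropy-adjusted
    causal estimate and the intercept's p-value is the directional
    pleiotropy test.  SEs use multiplicative-dispersion weighted least
    squares with the residual scale floored at 1 and a t reference on
    k-2 df.
    """
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    if k < 3:
        raise MRError("MR-Egger needs at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx = bx * sign
    by = by * sign
    if np.allclose(bx, bx[0]):
        raise MRError("all exposure effects equal; Egger slope unidentified")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    scale = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, scale)
    se_int, se_slope = np.sqrt(np.diag(cov))
    df = k - 2
    p_slope = float(2.0 * stats.t.sf(abs(coef[1]) / se_slope, df))
    p_int = float(2.0 * stats.t.sf(abs(coef[0]) / se_int, df))
    return MREstimate(
        "egger",
        float(coef[1]),
        float(se_slope),
        p_slope,
        k=k,
        intercept=float(coef[0]),
        intercept_se=float(se_int),
        intercept_p=p_int,
    )


def leave_one_out(
    hset: HarmonizedSet, estimator: Literal["ivw_fixed", "ivw_random"] = "ivw_fixed"
) -> pd.DataFrame:
    """Re-estimate omitting each instrument in turn.

    Returns one row per omitted rsid with the remaining-set estimate; at
    k=2 each row reduces to the other SNP's Wald ratio.
    """
    k = len(hset)
    if k < 2:
        raise MRError("leave-one-out needs at least 2 instruments")
    model = estimator.removeprefix("ivw_")
    rows = []
    for i in range(k):
        sub = HarmonizedSet(
            table=hset.table.drop(hset.table.index[i]).reset_index(drop=True)
        )
        est = (
            ivw(sub, model)  # type: ignore[arg-type]
            if len(sub) > 1 or model == "fixed"
            else ivw(sub, "fixed")
        )
        rows.append(
            {
                "omitted": hset.table.iloc[i]["rsid"],
                "theta": est.theta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or_": est.or_,
            }
        )
    return pd.DataFrame(rows)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, seed: int | None = None) -> PressoResult:
    """Simulation-based residual-sum-of-squares outlier test.

    The observed statistic is the weighted RSS of each SNP's outcome effect
    about its leave-one-out IVW prediction.  The null distribution is built
    by n_sim parametric draws of (beta_x, beta_y) from the reported
    variances around the leave-one-out fits; the global p is the rank-based
    tail probability with a +1 correction.  Per-SNP outliers are flagged
    when the simulated tail probability of their squared residual falls
    below 0.05 Bonferroni-corrected over k.
    """
    bx, sx, by, sy = hset.arrays()
    k = len(bx)
    if k < 4:
        raise MRError("MR-PRESSO needs at least 4 instruments")
    w = 1.0 / sy**2
    sw_num = np.sum(w * bx * by)
    sw_den = np.sum(w * bx**2)
    theta_loo = (sw_num - w * bx * by) / (sw_den - w * bx**2)
    resid2_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid2_obs.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    sw_num_s = np.sum(w * bx_s * by_s, axis=1, keepdims=True)
    sw_den_s = np.sum(w * bx_s**2, axis=1, keepdims=True)
    theta_loo_s = (sw_num_s - w * bx_s * by_s) / (sw_den_s - w * bx_s**2)
    resid2_s = w * (by_s - theta_loo_s * bx_s) ** 2
    rss_s = resid2_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(resid2_s >= resid2_obs[None, :], axis=0)) / (n_sim + 1)
    flags = outlier_p < 0.05 / k
    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        outlier_flags=flags,
        outlier_p=outlier_p,
        rsids=hset.table["rsid"].tolist(),
        n_sim=n_sim,
        seed=seed,
    )


@dataclass
class MRBatteryReport:
    """All estimators, heterogeneity, LOO, PRESSO, and the robustness call."""

    estimates: dict[str, MREstimate]
    heterogeneity: HeterogeneityResult
    loo: pd.DataFrame
    presso: PressoResult | None
    primary: MREstimate
    decision: str
    k: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            rows.append(
                {
                    "method": name,
                    "theta": est.theta,
                    "se": est.se,
                    "or": est.or_,
                    "ci_low": est.ci95[0],
                    "ci_high": est.ci95[1],
                    "pvalue": est.pvalue,
                    "k": est.k,
                    "intercept": est.intercept,
                    "intercept_p": est.intercept_p,
                }
            )
        return pd.DataFrame(rows)


def run_mr_battery(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MRBatteryReport:
    """Full estimation and sensitivity suite with the robustness decision.

    The primary estimator is fixed-effects IVW when Cochran's Q shows no
    heterogeneity (p > alpha), otherwise multiplicative random effects.
    The association is called "robust" when the IVW, weighted-median and
    maximum-likelihood p-values are all below alpha, the Egger intercept
    shows no directional pleiotropy (p > alpha) and PRESSO flags no
    outlier; "null" when the primary IVW is non-significant; otherwise
    "not_robust".
    """
    k = len(hset)
    het = cochran_q(hset)
    model = "fixed" if het.pvalue > alpha else "random"
    primary = ivw(hset, model)  # type: ignore[arg-type]
    estimates: dict[str, MREstimate] = {
        "ivw_fixed": ivw(hset, "fixed"),
        "ivw_random": ivw(hset, "random"),
        "weighted_median": weighted_median(hset, n_boot=n_boot, seed=seed),
        "max_likelihood": max_likelihood(hset),
        "egger": egger(hset),
    }
    loo = leave_one_out(hset)
    presso = mr_presso(hset, n_sim=n_sim, seed=seed) if k >= 4 else None
    if primary.pvalue >= alpha:
        decision = "null"
    else:
        robust = (
            estimates["weighted_median"].pvalue < alpha
            and estimates["max_likelihood"].pvalue < alpha
            and (estimates["egger"].intercept_p or 0.0) > alpha
            and (presso is None or not presso.has_outlier)
        )
        decision = "robust" if robust else "not_robust"
    return MRBatteryReport(
        estimates=estimates,
        heterogeneity=het,
        loo=loo,
        presso=presso,
        primary=primary,
        decision=decision,
        k=k,
    )
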