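"""Synthetic cohorts and summary statistics matching the study's assumptions.

Individual-level generators draw HWE genotypes at the panel's effect-allele
frequencies, build the standardized weighted score, add one Bernoulli(0.5)
and one standard-normal covariate (each with linear predictor effect 0.5),
and produce either a logistic case-control population with case/control
subsampling or Weibull survival times via the inverse-probability transform
with exact-count random censoring.

The summary-statistics generator fabricates paired exposure/outcome GWAS
effect estimates with a controllable causal slope, heterogeneity,
directional pleiotropy and a single injectable outlier, for exercising the
MR suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import CaseControlCohort, SurvivalCohort
from .grs import GenotypeMatrix, GrsVector
from .instruments import (
    HarmonizedSet,
    InstrumentPanel,
    InstrumentRecord,
    OutcomeSummary,
    load_packaged_panel,
)

COVARIATE_EFFECTS = (0.5, 0.5)  # binary X1, continuous X2


def _panel_mafs(panel: InstrumentPanel) -> np.ndarray:
    return np.array([r.eaf for r in panel])


@dataclass
class SimulationConfig:
    """Study conditions for the individual-level simulations.

    Defaults follow the published simulation design: 17 instruments at the
    panel EAFs, a 2,000,000-person source population for case-control
    sampling, Weibull(shape 1, scale 0.01) survival with 50% random
    censoring, 1,000 replicates, and a significance threshold of 1.67e-3
    (0.05 Bonferroni-corrected for 30 cancer types).
    """

    mafs: Sequence[float] = field(default_factory=lambda: _panel_mafs(load_packaged_panel()))
    weights: Sequence[float] | None = None  # defaults to panel betas (shorter scale)
    theta: float = 0.10
    cov_effects: tuple[float, float] = COVARIATE_EFFECTS
    population_n: int = 2_000_000
    n_cases: int = 50
    n_controls: int = 300_000
    weibull_shape: float = 1.0
    weibull_scale: float = 0.01
    censor_rate: float = 0.5
    n_reps: int = 1000
    alpha: float = 1.67e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        mafs = np.asarray(self.mafs, float)
        if ((mafs <= 0) | (mafs >= 1)).any():
            raise ValueError("all allele frequencies must lie in (0,1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0,1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.weights is None:
            panel = load_packaged_panel()
            self.weights = tuple(-r.beta for r in panel)  # shorter-LTL orientation

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SummarySimConfig:
    """Conditions for fabricated two-sample GWAS summary statistics."""

    k: int = 17
    causal_theta: float = 0.0
    exposure_n: int = 78_592
    outcome_n: int = 420_473
    heterogeneity_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    outlier_index: int | None = None
    outlier_displacement: float = 0.0  # in units of se_y
    se_x_scale: float = 0.006
    se_y_scale: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.exposure_n <= self.k or self.outcome_n <= self.k:
            raise ValueError("GWAS sample sizes must exceed the instrument count")


# ---------------------------------------------------------------------------
# Individual-level generators
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int, mafs: Sequence[float], seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Independent HWE genotypes: dosage_ij ~ Binomial(2, maf_j)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mafs = np.asarray(mafs, float)
    if ((mafs <= 0) | (mafs >= 1)).any():
        raise ValueError("maf outside (0,1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    return GenotypeMatrix(
        samples=[f"s{i + 1}" for i in range(n)],
        variants=[f"sim_snp{j + 1}" for j in range(len(mafs))],
        dosages=dosages,
    )


def simulate_covariates(
    n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One binary Bernoulli(0.5) and one standard-normal covariate."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "x1": rng.binomial(1, 0.5, size=n).astype(float),
            "x2": rng.normal(size=n),
        }
    )


def _standardized_score(gm: GenotypeMatrix, weights: Sequence[float]) -> GrsVector:
    raw = gm.dosages @ np.asarray(weights, float)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("simulated score has zero variance")
    return GrsVector(
        raw=raw, standardized=(raw - raw.mean()) / sd,
        n_snps_used=gm.n_variants, samples=list(gm.samples),
    )


def simulate_case_control(cfg: SimulationConfig) -> tuple[CaseControlCohort, GrsVector]:
    """Logistic population then exact case/control subsampling.

    Draws the population, forms eta = GRS_std*theta + 0.5*x1 + 0.5*x2,
    assigns case status with probability expit(eta), and samples exactly
    n_cases cases and n_controls controls without replacement.
    """
    rng = cfg.rng()
    gm = simulate_genotypes(cfg.population_n, cfg.mafs, rng=rng)
    grs = _standardized_score(gm, cfg.weights)
    cov = simulate_covariates(cfg.population_n, rng=rng)
    b1, b2 = cfg.cov_effects
    eta = grs.standardized * cfg.theta + b1 * cov["x1"].to_numpy() + b2 * cov["x2"].to_numpy()
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    case_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    if len(case_idx) < cfg.n_cases or len(control_idx) < cfg.n_controls:
        raise ValueError(
            f"population of {cfg.population_n} yielded {len(case_idx)} cases / "
            f"{len(control_idx)} controls; increase population_n"
        )
    chosen = np.concatenate(
        [
            rng.choice(case_idx, cfg.n_cases, replace=False),
            rng.choice(control_idx, cfg.n_controls, replace=False),
        ]
    )
    cohort = CaseControlCohort(
        y=y[chosen], covariates=cov.iloc[chosen].reset_index(drop=True)
    )
    sub = GrsVector(
        raw=grs.raw[chosen],
        standardized=grs.standardized[chosen],
        n_snps_used=grs.n_snps_used,
        samples=[gm.samples[i] for i in chosen],
    )
    return cohort, sub


def simulate_survival(
    cfg: SimulationConfig, n: int, rng: np.random.Generator | None = None
) -> tuple[SurvivalCohort, GrsVector]:
    """Weibull survival times by the inverse-probability transform.

    T = (-log(U) / (scale * exp(eta)))^(1/shape), i.e. a proportional-hazards
    Weibull with baseline hazard scale*shape*t^(shape-1).  Exactly
    round(censor_rate*n) individuals, chosen uniformly at random, are
    censored at a time drawn uniformly on (0, T_i); the rest are events.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rng is None:
        rng = cfg.rng()
    gm = simulate_genotypes(n, cfg.mafs, rng=rng)
    grs = _standardized_score(gm, cfg.weights)
    cov = simulate_covariates(n, rng=rng)
    b1, b2 = cfg.cov_effects
    eta = grs.standardized * cfg.theta + b1 * cov["x1"].to_numpy() + b2 * cov["x2"].to_numpy()
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (cfg.weibull_scale * np.exp(eta))) ** (1.0 / cfg.weibull_shape)
    n_censored = int(round(cfg.censor_rate * n))
    censored = rng.choice(n, n_censored, replace=False)
    event = np.ones(n, dtype=int)
    time = t_event.copy()
    event[censored] = 0
    time[censored] = rng.uniform(size=n_censored) * t_event[censored]
    cohort = SurvivalCohort(time=time, event=event, covariates=cov)
    return cohort, grs


# ---------------------------------------------------------------------------
# Two-sample summary statistics
# ---------------------------------------------------------------------------

def simulate_two_sample_summary(
    cfg: SummarySimConfig,
) -> tuple[InstrumentPanel, OutcomeSummary, HarmonizedSet]:
    """Fabricate a paired exposure panel and outcome summary table.

    True per-SNP exposure effects are drawn near the magnitudes of the
    packaged panel (|effect| ~ U(0.03, 0.09), random sign); observed
    effects add normal noise at the reported SEs.  Outcome effects are
    causal_theta * true effect plus optional heterogeneity (per-SNP slope
    noise), directional pleiotropy (intercept shift of pleiotropy_mean) and
    a single outlier displaced by outlier_displacement * se_y.  Returns the
    panel, the outcome table, and the already-aligned harmonized set for
    direct use by the MR suite.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    true_bx = rng.uniform(0.03, 0.09, size=k) * rng.choice([-1.0, 1.0], size=k)
    se_x = np.full(k, cfg.se_x_scale)
    se_y = np.full(k, cfg.se_y_scale)
    bx = rng.normal(true_bx, se_x)
    mean_by = cfg.causal_theta * true_bx
    if cfg.heterogeneity_sd > 0:
        mean_by = mean_by + rng.normal(0.0, cfg.heterogeneity_sd * np.abs(true_bx), size=k)
    if cfg.pleiotropy_mean != 0.0:
        # directional intercept on the Egger-oriented (beta_x >= 0) scale
        mean_by = mean_by + cfg.pleiotropy_mean * np.sign(true_bx)
    by = rng.normal(mean_by, se_y)
    if cfg.outlier_index is not None:
        by[cfg.outlier_index] += cfg.outlier_displacement * se_y[cfg.outlier_index]

    eafs = rng.uniform(0.05, 0.95, size=k)
    # non-palindromic allele pairs so harmonization is unambiguous
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    records = []
    pvals_x = 2.0 * _norm_sf(np.abs(bx) / se_x)
    for j in range(k):
        ea, oa = pairs[j % len(pairs)]
        records.append(
            InstrumentRecord(
                rsid=f"sim{j + 1}",
                chrom=str(j % 22 + 1),
                pos=1000 + j,
                gene=f"GENE{j + 1}",
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eafs[j]),
                beta=float(bx[j]),
                se=float(se_x[j]),
                pvalue=float(max(pvals_x[j], np.finfo(float).tiny)),
            )
        )
    panel = InstrumentPanel(records=tuple(records), orientation="shorter", gwas_n=cfg.exposure_n)
    pvals_y = 2.0 * _norm_sf(np.abs(by) / se_y)
    outcome = OutcomeSummary(
        table=pd.DataFrame(
            {
                "rsid": [r.rsid for r in records],
                "effect_allele": [r.effect_allele for r in records],
                "other_allele": [r.other_allele for r in records],
                "beta": by,
                "se": se_y,
                "pvalue": np.maximum(pvals_y, np.finfo(float).tiny),
                "eaf": eafs,
            }
        ),
        trait="simulated",
    )
    hset = HarmonizedSet.from_arrays(
        beta_x=bx, se_x=se_x, beta_y=by, se_y=se_y,
        rsids=[r.rsid for r in records],
        pvalue_y=np.maximum(pvals_y, np.finfo(float).tiny),
    )
    return panel, outcome, hset


def _norm_sf(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(z)
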