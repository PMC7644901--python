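"""End-to-end orchestration of the three analyses.

Ties the stages together the way the study ran them: genotype QC, score
construction and batch association for individual-level data; panel
orientation, harmonization, pleiotropy prescreen and the MR battery for
summary statistics; and the Monte-Carlo power grids.  File outputs carry a
provenance header (package version, config hash, seed) so identical runs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from . import __version__
from .association import (
    CaseControlCohort,
    SurvivalCohort,
    run_association_batch,
)
from .grs import compute_grs, qc_genotypes, read_dosages
from .instruments import (
    HarmonizedSet,
    flip_to_shorter,
    harmonize,
    load_instrument_panel,
    prescreen_pleiotropy,
    read_outcome_summary,
)
from .mr import MRBatteryReport, run_mr_battery
from .power import power_case_control, power_survival
from .simulate import SimulationConfig

log = logging.getLogger("telomr")


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path: str | Path, config: Mapping | None = None) -> None:
    """Write a TSV with a one-line provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = dict(config or {})
    header = (
        f"# telomr {__version__} config_hash={config_hash(cfg)} "
        f"seed={cfg.get('seed', 'NA')}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


def run_grs_association(
    dosage_path: str | Path,
    dosage_format: Literal["vcf", "tsv"],
    panel_path: str | Path,
    phenotype_path: str | Path,
    gwas_n: int,
    outcome_cols: Sequence[str],
    covariate_cols: Sequence[str],
    survival: bool = False,
    min_cases: int = 60,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
) -> pd.DataFrame:
    """QC -> GRS -> batch association -> FDR -> classification.

    The phenotype CSV must contain ``sample_id``, the outcome columns and
    the covariate columns.  For case-control runs each outcome column is
    binary and individuals negative for *every* outcome form the shared
    control pool.  For survival runs ``outcome_cols`` names event-indicator
    columns and a matching ``<outcome>_time`` column must exist.
    """
    panel = flip_to_shorter(load_instrument_panel(panel_path, gwas_n=gwas_n))
    gm = read_dosages(dosage_path, dosage_format, panel)
    log.info("loaded %d samples x %d variants", gm.n_samples, gm.n_variants)
    gm, qc_report = qc_genotypes(gm, call_rate_min, maf_min, hwe_p_min)
    log.info("QC removed %d variants", len(qc_report))
    grs = compute_grs(gm, panel)
    pheno = pd.read_csv(phenotype_path)
    missing = [c for c in list(outcome_cols) + list(covariate_cols) + ["sample_id"]
               if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype file missing column(s): {missing}")
    pheno = pheno.set_index("sample_id").loc[grs.samples]
    outcomes = []
    if survival:
        for col in outcome_cols:
            tcol = f"{col}_time"
            if tcol not in pheno.columns:
                raise ValueError(f"phenotype file missing column(s): ['{tcol}']")
            cohort = SurvivalCohort(
                time=pheno[tcol].to_numpy(float),
                event=pheno[col].to_numpy(int),
                covariates=pheno[list(covariate_cols)].reset_index(drop=True),
            )
            outcomes.append((col, cohort, grs.standardized))
    else:
        control_mask = (pheno[list(outcome_cols)] == 0).all(axis=1).to_numpy()
        for col in outcome_cols:
            case_mask = (pheno[col] == 1).to_numpy()
            sel = case_mask | control_mask
            cohort = CaseControlCohort(
                y=pheno.loc[sel, col].to_numpy(int),
                covariates=pheno.loc[sel, list(covariate_cols)].reset_index(drop=True),
            )
            outcomes.append((col, cohort, grs.standardized[sel]))
            log.info("%s: %d cases / %d shared controls", col, case_mask.sum(), control_mask.sum())
    return run_association_batch(outcomes, min_cases=min_cases)


def run_mr(
    panel_path: str | Path,
    gwas_n: int,
    outcome_path: str | Path,
    column_map: Mapping[str, str] | None = None,
    palindromic_policy: Literal["drop", "eaf_infer"] = "eaf_infer",
    prescreen_alpha: float = 0.05,
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int | None = None,
) -> tuple[MRBatteryReport, HarmonizedSet]:
    """Orient -> harmonize -> pleiotropy prescreen -> full MR battery."""
    panel = flip_to_shorter(load_instrument_panel(panel_path, gwas_n=gwas_n))
    outcome = read_outcome_summary(outcome_path, dict(column_map) if column_map else None)
    hset = harmonize(panel, outcome, palindromic_policy=palindromic_policy)
    if len(hset) == 0:
        raise ValueError("no instruments shared between panel and outcome")
    for rsid, reason in hset.dropped:
        log.info("dropped %s: %s", rsid, reason)
    hset = prescreen_pleiotropy(hset, alpha=prescreen_alpha)
    log.info("MR on k=%d instruments", len(hset))
    report = run_mr_battery(hset, n_boot=n_boot, n_sim=n_sim, seed=seed)
    return report, hset


def run_power(
    design: Literal["surv", "cc"],
    ns: Sequence[int],
    thetas: Sequence[float],
    n_reps: int = 1000,
    alpha: float = 1.67e-3,
    seed: int | None = None,
    population_n: int = 200_000,
    n_controls: int = 30_000,
) -> pd.DataFrame:
    """Power grid for either design (delegates to the power module)."""
    cfg = SimulationConfig(
        n_reps=n_reps, alpha=alpha, seed=seed,
        population_n=population_n, n_controls=n_controls,
    )
    if design == "surv":
        return power_survival(cfg, ns=ns, thetas=thetas)
    if design == "cc":
        return power_case_control(cfg, n_cases_grid=ns, thetas=thetas)
    raise ValueError(f"unknown design {design!r}")
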