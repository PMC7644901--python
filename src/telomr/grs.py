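"""Genotype QC and weighted genetic risk score construction.

The score for individual i is the weighted allele count
``raw_i = sum_j dosage_ij * beta_j`` over the instruments present in the
genotype data, with weights taken from the instrument panel oriented to
shorter telomere length.  The analysis uses the standardized score
(mean 0, variance 1 within the analysis sample), so the association
p-value does not depend on any rescaling of the raw score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .instruments import InstrumentPanel


class GenotypeError(ValueError):
    """Invalid genotype data or an operation that cannot proceed on it."""


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages, samples x variants, NaN = missing."""

    samples: list[str]
    variants: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.variants)) != len(self.variants):
            raise GenotypeError("variant rsids are not unique")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise GenotypeError("dosages outside [0, 2] found")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.variants)


@dataclass
class GrsVector:
    """Raw and standardized per-sample score."""

    raw: np.ndarray
    standardized: np.ndarray
    n_snps_used: int
    samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed minor-allele count, the probability of each
    possible heterozygote count is computed by the standard recurrence and
    the p-value is the summed probability of configurations no more likely
    than the observed one (no mid-p adjustment).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele copies
    # heterozygote count shares parity with the rare-allele count
    het_values = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    if len(het_values) == 0:
        return 1.0
    probs = np.zeros(len(het_values))
    # anchor the unnormalized recurrence at the distribution's mode so the
    # values only decay outward (no overflow at large n)
    mode = rare * (2 * n - rare) / (2.0 * n)
    mid = int(np.clip(np.searchsorted(het_values, mode), 0, len(het_values) - 1))
    probs[mid] = 1.0
    # unnormalized recurrence in both directions from the middle
    for i in range(mid, len(het_values) - 1):
        het = het_values[i]
        hom_r = (rare - het) // 2
        hom_c = (2 * n - rare - het) // 2
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
    for i in range(mid, 0, -1):
        het = het_values[i]
        hom_r = (rare - het) // 2
        hom_c = (2 * n - rare - het) // 2
        probs[i - 1] = probs[i] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(het_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_genotypes(
    gm: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants on call rate, minor allele frequency and HWE.

    The HWE exact test runs on hard calls (dosages rounded to 0/1/2 for the
    test only); MAF comes from the mean dosage of non-missing entries.
    Returns the filtered matrix plus a report of removed variants with the
    first filter each one failed and the offending value.
    """
    if gm.n_variants == 0:
        raise GenotypeError("empty genotype matrix")
    keep: list[int] = []
    report_rows: list[dict] = []
    for j, rsid in enumerate(gm.variants):
        col = gm.dosages[:, j]
        obs = col[~np.isnan(col)]
        call_rate = len(obs) / len(col)
        if call_rate < call_rate_min:
            report_rows.append({"rsid": rsid, "filter": "call_rate", "value": call_rate})
            continue
        if len(obs) == 0:
            report_rows.append({"rsid": rsid, "filter": "call_rate", "value": 0.0})
            continue
        af = obs.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf < maf_min:
            report_rows.append({"rsid": rsid, "filter": "maf", "value": maf})
            continue
        hard = np.rint(obs).astype(int)
        counts = np.bincount(hard, minlength=3)
        p_hwe = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))
        if p_hwe < hwe_p_min:
            report_rows.append({"rsid": rsid, "filter": "hwe", "value": p_hwe})
            continue
        keep.append(j)
    if not keep:
        raise GenotypeError("all variants removed by QC")
    report = pd.DataFrame(report_rows, columns=["rsid", "filter", "value"])
    filtered = GenotypeMatrix(
        samples=list(gm.samples),
        variants=[gm.variants[j] for j in keep],
        dosages=gm.dosages[:, keep],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Score computation
# ---------------------------------------------------------------------------


def compute_grs(
    gm: GenotypeMatrix,
    panel: InstrumentPanel,
    missing_policy: Literal["mean_impute", "drop_sample"] = "mean_impute",
) -> GrsVector:
    """Weighted allele score over the intersection of panel and genotypes.

    Requires the panel on the shorter-LTL orientation so the score increases
    with genetically shorter telomeres.  Missing dosages are mean-imputed at
    2*EAF from the panel, or the sample is dropped, per ``missing_policy``.
    """
    if panel.orientation != "shorter":
        raise ValueError("panel must be oriented to shorter telomere length")
    idx = [(j, panel.record(v)) for j, v in enumerate(gm.variants) if v in set(panel.rsids)]
    if not idx:
        raise GenotypeError("no panel SNPs present in the genotype matrix")
    cols = np.array([j for j, _ in idx])
    weights = np.array([rec.beta for _, rec in idx])
    expected = np.array([2.0 * rec.eaf for _, rec in idx])
    dos = gm.dosages[:, cols]
    samples = list(gm.samples)
    missing = np.isnan(dos)
    if missing.any():
        if missing_policy == "mean_impute":
            dos = np.where(missing, expected[None, :], dos)
        elif missing_policy == "drop_sample":
            keep = ~missing.any(axis=1)
            if not keep.any():
                raise GenotypeError("every sample has a missing dosage")
            dos = dos[keep]
            samples = [s for s, k in zip(samples, keep) if k]
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    raw = dos @ weights
    sd = raw.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise GenotypeError("raw score has zero variance; cannot standardize")
    standardized = (raw - raw.mean()) / sd
    return GrsVector(
        raw=raw, standardized=standardized, n_snps_used=len(idx), samples=samples
    )


# ---------------------------------------------------------------------------
# Dosage input
# ---------------------------------------------------------------------------


def read_dosages(
    path: str | Path,
    fmt: Literal["vcf", "tsv"],
    panel: InstrumentPanel,
) -> GenotypeMatrix:
    """Read effect-allele dosages from a VCF (GT or DS) or a TSV matrix.

    VCF records are matched to the panel by rsid; when the record's ALT is
    the panel's *other* allele (REF the effect allele), dosages are recoded
    as ``2 - dosage`` so they always count the panel effect allele.  Records
    at panel rsids whose alleles match neither orientation are excluded.
    TSV input (samples x rsid columns, first column sample id) is assumed
    already effect-allele coded.
    """
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        gm = GenotypeMatrix(
            samples=[str(s) for s in frame.index],
            variants=[str(v) for v in frame.columns],
            dosages=frame.to_numpy(float),
        )
        return gm
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")

    from cyvcf2 import VCF

    by_rsid = {rec.rsid: rec for rec in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        rsid = var.ID
        if rsid not in by_rsid:
            continue
        rec = by_rsid[rsid]
        ref = var.REF.upper()
        alt = var.ALT[0].upper() if var.ALT else ""
        fmts = var.FORMAT
        if "DS" in fmts:
            ds = np.asarray(var.format("DS"), float).reshape(-1)
        elif "GT" in fmts:
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        else:
            continue
        if (ref, alt) == (rec.other_allele, rec.effect_allele):
            col = ds
        elif (ref, alt) == (rec.effect_allele, rec.other_allele):
            col = 2.0 - ds
        else:
            import warnings

            warnings.warn(
                f"{rsid}: VCF alleles {ref}/{alt} match neither panel orientation; excluded"
            )
            continue
        variants.append(rsid)
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)
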