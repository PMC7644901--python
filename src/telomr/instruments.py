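"""Exposure instrument panel: loading, orientation, strength metrics, harmonization.

The exposure is leukocyte telomere length (LTL).  The instrument panel is a
set of independent index SNPs from a large LTL GWAS, each carrying its
per-allele effect on LTL (in SD units), standard error, effect-allele
frequency and association p-value.  Downstream analyses (GRS construction,
two-sample MR) consume the panel after it has been oriented so that positive
effects correspond to *shorter* telomeres, and — for MR — after per-SNP
alignment against outcome GWAS summary statistics.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: A1/A2 pairs that are their own strand-complement and therefore ambiguous.
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: EAF band inside which palindromic SNPs cannot be aligned by frequency.
EAF_AMBIGUITY_BAND = (0.42, 0.58)


class InstrumentError(ValueError):
    """Validation or orientation error in an instrument panel."""


@dataclass(frozen=True)
class InstrumentRecord:
    """One exposure SNP with its marginal effect on the exposure trait."""

    rsid: str
    chrom: str
    pos: int
    gene: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise InstrumentError(
                f"{self.rsid}: alleles must be single bases in A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise InstrumentError(f"{self.rsid}: effect and other allele are identical")
        if not (0.0 < self.eaf < 1.0):
            raise InstrumentError(f"{self.rsid}: eaf {self.eaf} outside (0,1)")
        if not self.se > 0:
            raise InstrumentError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            raise InstrumentError(f"{self.rsid}: pvalue {self.pvalue} outside (0,1]")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class InstrumentPanel:
    """Ordered instrument collection with a trait orientation.

    ``orientation`` records whether positive betas mean *longer* or *shorter*
    telomeres; the published table is on the longer-LTL scale and analyses
    run on the shorter-LTL scale after :func:`flip_to_shorter`.
    """

    records: tuple[InstrumentRecord, ...]
    orientation: Literal["longer", "shorter"]
    gwas_n: int

    def __post_init__(self) -> None:
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise InstrumentError(f"duplicate rsids in panel: {', '.join(dupes)}")
        if self.gwas_n <= len(self.records) + 1:
            raise InstrumentError(
                f"gwas_n={self.gwas_n} must exceed number of instruments + 1"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def record(self, rsid: str) -> InstrumentRecord:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(rsid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass(frozen=True)
class OutcomeSummary:
    """Outcome GWAS summary statistics for one trait, indexed by rsid."""

    table: pd.DataFrame  # columns: rsid, effect_allele, other_allele, beta, se, pvalue, [eaf]
    trait: str = "outcome"

    def __post_init__(self) -> None:
        required = {"rsid", "effect_allele", "other_allele", "beta", "se", "pvalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise InstrumentError(f"outcome table missing columns: {sorted(missing)}")
        if (self.table["se"] <= 0).any():
            bad = self.table.loc[self.table["se"] <= 0, "rsid"].tolist()
            raise InstrumentError(f"outcome se must be > 0; offending rsids: {bad}")

    def lookup(self, rsid: str) -> pd.Series | None:
        hit = self.table[self.table["rsid"] == rsid]
        if hit.empty:
            return None
        return hit.iloc[0]


@dataclass(frozen=True)
class HarmonizedSet:
    """Per-SNP exposure/outcome effect pairs aligned to the same effect allele."""

    table: pd.DataFrame  # columns: rsid, beta_x, se_x, beta_y, se_y, pvalue_y
    dropped: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        required = {"rsid", "beta_x", "se_x", "beta_y", "se_y"}
        missing = required - set(self.table.columns)
        if missing:
            raise InstrumentError(f"harmonized table missing columns: {sorted(missing)}")
        if len(self.table) and ((self.table["se_x"] <= 0) | (self.table["se_y"] <= 0)).any():
            raise InstrumentError("harmonized set contains non-positive standard errors")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def k(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = self.table
        return (
            t["beta_x"].to_numpy(float),
            t["se_x"].to_numpy(float),
            t["beta_y"].to_numpy(float),
            t["se_y"].to_numpy(float),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_x: Sequence[float],
        se_x: Sequence[float],
        beta_y: Sequence[float],
        se_y: Sequence[float],
        rsids: Sequence[str] | None = None,
        pvalue_y: Sequence[float] | None = None,
    ) -> "HarmonizedSet":
        k = len(beta_x)
        if rsids is None:
            rsids = [f"snp{i + 1}" for i in range(k)]
        frame = pd.DataFrame(
            {
                "rsid": list(rsids),
                "beta_x": np.asarray(beta_x, float),
                "se_x": np.asarray(se_x, float),
                "beta_y": np.asarray(beta_y, float),
                "se_y": np.asarray(se_y, float),
            }
        )
        if pvalue_y is not None:
            frame["pvalue_y"] = np.asarray(pvalue_y, float)
        return cls(table=frame)


# ---------------------------------------------------------------------------
# Loading and orientation
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = {
    "rsid": "rsid",
    "chr": "chrom",
    "pos": "pos",
    "gene": "gene",
    "a1": "effect_allele",
    "a2": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
}


def packaged_panel_path() -> Path:
    """Path of the packaged LTL instrument panel (17 index SNPs)."""
    return Path(importlib.resources.files("telomr") / "data" / "ltl_instrument_panel.tsv")


def load_instrument_panel(path: str | Path, gwas_n: int) -> InstrumentPanel:
    """Load a tab-separated instrument panel as published (longer-LTL betas).

    Parameters
    ----------
    path
        TSV with header columns rsid, chr, pos, gene, a1, a2, eaf, beta, se,
        pvalue.  a1 is the effect allele.
    gwas_n
        Sample size of the exposure GWAS the betas come from.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_PANEL_COLUMNS) - set(raw.columns)
    if missing:
        raise InstrumentError(f"panel file missing columns: {sorted(missing)}")
    records = []
    for i, row in raw.iterrows():
        try:
            rec = InstrumentRecord(
                rsid=row["rsid"],
                chrom=str(row["chr"]),
                pos=int(row["pos"]),
                gene=row["gene"],
                effect_allele=str(row["a1"]).upper(),
                other_allele=str(row["a2"]).upper(),
                eaf=float(row["eaf"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                pvalue=float(row["pvalue"]),
            )
        except InstrumentError:
            raise
        except (TypeError, ValueError) as exc:
            raise InstrumentError(
                f"malformed numeric field in row {i + 1} (rsid {row.get('rsid')!r}): {exc}"
            ) from exc
        records.append(rec)
    return InstrumentPanel(records=tuple(records), orientation="longer", gwas_n=gwas_n)


def load_packaged_panel(gwas_n: int = 78_592) -> InstrumentPanel:
    """The packaged 17-SNP LTL panel with its exposure GWAS sample size."""
    return load_instrument_panel(packaged_panel_path(), gwas_n=gwas_n)


def flip_to_shorter(panel: InstrumentPanel) -> InstrumentPanel:
    """Negate every beta so positive effects mean shorter telomeres.

    Alleles, EAF, SE and p-values are untouched; only the sign convention of
    the trait changes.  Refuses to flip a panel already on the shorter scale.
    """
    if panel.orientation != "longer":
        raise InstrumentError("panel already oriented to shorter telomere length")
    flipped = tuple(replace(r, beta=-r.beta) for r in panel.records)
    return InstrumentPanel(records=flipped, orientation="shorter", gwas_n=panel.gwas_n)


def flip_to_longer(panel: InstrumentPanel) -> InstrumentPanel:
    """Inverse of :func:`flip_to_shorter`."""
    if panel.orientation != "shorter":
        raise InstrumentError("panel already oriented to longer telomere length")
    flipped = tuple(replace(r, beta=-r.beta) for r in panel.records)
    return InstrumentPanel(records=flipped, orientation="longer", gwas_n=panel.gwas_n)


# ---------------------------------------------------------------------------
# Instrument strength
# ---------------------------------------------------------------------------


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, the squared Wald z: (beta/se)**2."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def proportion_variance_explained(f: float, gwas_n: int) -> float:
    """Fraction of exposure variance explained by one instrument.

    Uses PVE = F / (F + n - 2), the one-regressor identity linking the Wald F
    to the squared partial correlation in a GWAS of n individuals.
    """
    if gwas_n <= 2:
        raise ValueError(f"gwas_n must exceed 2, got {gwas_n}")
    if f < 0:
        raise ValueError("F statistic cannot be negative")
    return f / (f + gwas_n - 2)


WEAK_INSTRUMENT_F = 10.0


def summarize_instrument_strength(panel: InstrumentPanel) -> pd.DataFrame:
    """Per-SNP F and PVE plus panel-level summary attributes.

    Returns a DataFrame (rsid, gene, beta, se, F, pve, weak) whose ``attrs``
    carry total_pve, f_min, f_mean, f_max and the list of weak instruments
    (F below 10).
    """
    if len(panel) == 0:
        raise InstrumentError("cannot summarize an empty panel")
    rows = []
    for r in panel:
        f = f_statistic(r.beta, r.se)
        rows.append(
            {
                "rsid": r.rsid,
                "gene": r.gene,
                "beta": r.beta,
                "se": r.se,
                "F": f,
                "pve": proportion_variance_explained(f, panel.gwas_n),
                "weak": f < WEAK_INSTRUMENT_F,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total_pve"] = float(out["pve"].sum())
    out.attrs["f_min"] = float(out["F"].min())
    out.attrs["f_mean"] = float(out["F"].mean())
    out.attrs["f_max"] = float(out["F"].max())
    out.attrs["weak_instruments"] = out.loc[out["weak"], "rsid"].tolist()
    return out


# ---------------------------------------------------------------------------
# Harmonization against outcome summary statistics
# ---------------------------------------------------------------------------


def _alleles_match(ea_p: str, oa_p: str, ea_o: str, oa_o: str) -> str | None:
    """Classify how outcome alleles relate to panel alleles.

    Returns "same", "swapped", or None if irreconcilable.  Strand flips
    (complement pairs) are folded into the same two cases for
    non-palindromic SNPs.
    """
    if (ea_o, oa_o) == (ea_p, oa_p):
        return "same"
    if (ea_o, oa_o) == (oa_p, ea_p):
        return "swapped"
    comp = (COMPLEMENT[ea_o], COMPLEMENT[oa_o])
    if comp == (ea_p, oa_p):
        return "same"
    if comp == (oa_p, ea_p):
        return "swapped"
    return None


def harmonize(
    panel: InstrumentPanel,
    outcome: OutcomeSummary,
    palindromic_policy: Literal["drop", "eaf_infer"] = "eaf_infer",
) -> HarmonizedSet:
    """Align outcome effects to the panel's effect alleles SNP by SNP.

    SNPs absent from the outcome are dropped ("missing"); outcome records
    whose effect allele is the panel's other allele have beta_y negated;
    allele pairs that cannot be reconciled are dropped ("allele_mismatch").
    Palindromic SNPs (A/T, C/G) are ambiguous to strand: policy ``drop``
    removes them, ``eaf_infer`` keeps them when both EAFs sit outside the
    ambiguity band [0.42, 0.58] and aligns by frequency concordance, else
    drops ("palindromic_ambiguous").
    """
    rows: list[dict] = []
    dropped: list[tuple[str, str]] = []
    for rec in panel:
        hit = outcome.lookup(rec.rsid)
        if hit is None:
            dropped.append((rec.rsid, "missing"))
            continue
        ea_o = str(hit["effect_allele"]).upper()
        oa_o = str(hit["other_allele"]).upper()
        if ea_o not in VALID_BASES or oa_o not in VALID_BASES:
            dropped.append((rec.rsid, "allele_mismatch"))
            continue
        beta_y = float(hit["beta"])
        if rec.is_palindromic:
            if palindromic_policy == "drop":
                dropped.append((rec.rsid, "palindromic"))
                continue
            # frequency-based alignment: usable only when both EAFs are
            # decisively away from 0.5
            eaf_o = hit.get("eaf")
            if eaf_o is None or pd.isna(eaf_o):
                dropped.append((rec.rsid, "palindromic_ambiguous"))
                continue
            eaf_o = float(eaf_o)
            lo, hi = EAF_AMBIGUITY_BAND
            if lo <= rec.eaf <= hi or lo <= eaf_o <= hi:
                dropped.append((rec.rsid, "palindromic_ambiguous"))
                continue
            # concordant minor/major side -> same effect allele
            if (rec.eaf < 0.5) != (eaf_o < 0.5):
                beta_y = -beta_y
        else:
            rel = _alleles_match(rec.effect_allele, rec.other_allele, ea_o, oa_o)
            if rel is None:
                dropped.append((rec.rsid, "allele_mismatch"))
                continue
            if rel == "swapped":
                beta_y = -beta_y
        rows.append(
            {
                "rsid": rec.rsid,
                "beta_x": rec.beta,
                "se_x": rec.se,
                "beta_y": beta_y,
                "se_y": float(hit["se"]),
                "pvalue_y": float(hit["pvalue"]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["rsid", "beta_x", "se_x", "beta_y", "se_y", "pvalue_y"]
    )
    return HarmonizedSet(table=table, dropped=tuple(dropped))


def prescreen_pleiotropy(hset: HarmonizedSet, alpha: float = 0.05) -> HarmonizedSet:
    """Drop instruments Bonferroni-significant for the outcome itself.

    An instrument directly associated with the outcome (p below alpha/k,
    with k the current instrument count) is suspected of acting through a
    pathway other than the exposure and is removed before estimation.
    """
    if "pvalue_y" not in hset.table.columns or hset.table["pvalue_y"].isna().any():
        raise InstrumentError("prescreen requires an outcome p-value for every SNP")
    k = len(hset)
    threshold = alpha / k
    keep = hset.table["pvalue_y"] >= threshold
    removed = [
        (rsid, "pleiotropy_prescreen")
        for rsid in hset.table.loc[~keep, "rsid"]
    ]
    if not keep.any():
        raise InstrumentError("no instruments remain after pleiotropy prescreen")
    return HarmonizedSet(
        table=hset.table.loc[keep].reset_index(drop=True),
        dropped=hset.dropped + tuple(removed),
    )


def read_outcome_summary(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait: str = "outcome",
) -> OutcomeSummary:
    """Read outcome GWAS summary statistics from TSV with flexible headers.

    ``column_map`` maps canonical names (rsid, effect_allele, other_allele,
    beta, se, pvalue, eaf) to the file's column names, absorbing e.g.
    Pan-UKB-style headers.
    """
    raw = pd.read_csv(path, sep="\t")
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    keep = [
        c
        for c in ["rsid", "effect_allele", "other_allele", "beta", "se", "pvalue", "eaf"]
        if c in raw.columns
    ]
    return OutcomeSummary(table=raw[keep].copy(), trait=trait)
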