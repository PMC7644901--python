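import numpy as np
import pandas as pd
import pytest

from telomr import (
    HarmonizedSet,
    InstrumentPanel,
    InstrumentRecord,
    load_packaged_panel,
)

#: Printed per-SNP (F, PVE) reference values for the packaged 17-SNP panel,
#: at exposure GWAS n = 78,592.
PANEL_REFERENCE = {
    "rs3219104": (49.0, 6.23e-04),
    "rs55749605": (27.9, 3.55e-04),
    "rs10936600": (205.4, 2.61e-03),
    "rs13137667": (30.2, 3.85e-04),
    "rs4691895": (93.4, 1.19e-03),
    "rs7705526": (186.8, 2.37e-03),
    "rs34991172": (30.8, 3.91e-04),
    "rs2736176": (34.0, 4.33e-04),
    "rs59294613": (46.7, 5.94e-04),
    "rs9419958": (83.6, 1.06e-03),
    "rs228595": (33.6, 4.28e-04),
    "rs2302588": (36.0, 4.58e-04),
    "rs3785074": (34.0, 4.33e-04),
    "rs62053580": (31.0, 3.95e-04),
    "rs7194734": (38.0, 4.84e-04),
    "rs8105767": (60.8, 7.74e-04),
    "rs75691080": (55.4, 7.05e-04),
}


@pytest.fixture(scope="session")
def panel() -> InstrumentPanel:
    return load_packaged_panel()


@pytest.fixture()
def toy_hset() -> HarmonizedSet:
    """3-SNP set whose per-SNP ratios are all exactly 0.5."""
    return HarmonizedSet.from_arrays(
        beta_x=[0.10, 0.08, 0.05],
        se_x=[0.01, 0.01, 0.01],
        beta_y=[0.05, 0.04, 0.025],
        se_y=[0.02, 0.02, 0.04],
    )


@pytest.fixture()
def uneven_hset() -> HarmonizedSet:
    """4-SNP set with unequal ratios, for nontrivial heterogeneity."""
    return HarmonizedSet.from_arrays(
        beta_x=[0.10, 0.08, 0.05, 0.06],
        se_x=[0.01, 0.01, 0.01, 0.01],
        beta_y=[0.06, 0.03, 0.02, 0.035],
        se_y=[0.02, 0.02, 0.04, 0.03],
    )


def make_record(**overrides) -> InstrumentRecord:
    base = dict(
        rsid="rs1",
        chrom="1",
        pos=100,
        gene="GENE",
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.05,
        se=0.01,
        pvalue=1e-9,
    )
    base.update(overrides)
    return InstrumentRecord(**base)
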