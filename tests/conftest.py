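import numpy as np
import pandas as pd
import pytest

from dtmr.gwas_io import SummaryStatRecord
from dtmr.panel import GenotypePanel, VARIANT_COLUMNS


def make_record(**kw) -> SummaryStatRecord:
    """A valid summary-stat record with overridable fields."""
    base = dict(
        variant_id="rs1", chrom="1", pos=1000, effect_allele="A", other_allele="G",
        eaf=0.3, beta=0.1, se=0.02, p=1e-9, n=10_000,
    )
    base.update(kw)
    return SummaryStatRecord(**base)


def make_panel(dosages, mafs=None, pos=None, chrom="1") -> GenotypePanel:
    """Panel from a raw dosage array with auto-generated metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if mafs is None:
        with np.errstate(invalid="ignore"):
            mafs = np.nanmean(dosages, axis=0) / 2.0
    if pos is None:
        pos = [1 + 10_000 * j for j in range(m)]
    meta = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ea": "A",
            "oa": "G",
            "eaf": mafs,
        },
        columns=VARIANT_COLUMNS,
    )
    return GenotypePanel(dosages=dosages, sample_ids=[f"S{i + 1:04d}" for i in range(n)],
                        variants=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
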