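import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import COLUMNS, HarmonizedTable, SummaryTable


def make_table(records, trait_id="trait", trait_type="quantitative"):
    """Build a SummaryTable from per-record dicts (defaults filled in)."""
    rows = []
    for i, rec in enumerate(records):
        row = {
            "variant_id": f"rs{i + 1}", "chrom": "1", "pos": 1000 + i,
            "effect_allele": "A", "other_allele": "G",
            "eaf": 0.3, "beta": 0.1, "se": 0.01, "pval": 1e-9, "n": 10_000,
        }
        row.update(rec)
        rows.append(row)
    return SummaryTable(trait_id, trait_type, pd.DataFrame(rows)[COLUMNS])


def make_harmonized(beta_x, se_x, beta_y, se_y, **extra):
    """Build a HarmonizedTable directly from effect-pair arrays."""
    k = len(beta_x)
    df = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(k)],
        "beta_x": np.asarray(beta_x, float),
        "se_x": np.broadcast_to(np.asarray(se_x, float), k).copy(),
        "pval_x": 1e-9,
        "beta_y": np.asarray(beta_y, float),
        "se_y": np.broadcast_to(np.asarray(se_y, float), k).copy(),
        "pval_y": 0.5,
    })
    for key, val in extra.items():
        df[key] = val
    return HarmonizedTable("X", "Y", df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_pairs(rng):
    """A generic 10-SNP harmonized table with heterogeneous weights."""
    k = 10
    bx = rng.normal(0.1, 0.05, k)
    bx[np.abs(bx) < 0.02] = 0.05
    return make_harmonized(bx, rng.uniform(0.005, 0.02, k),
                           rng.normal(0.05, 0.03, k),
                           rng.uniform(0.01, 0.05, k))
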