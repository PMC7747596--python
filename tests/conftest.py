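import numpy as np
import pandas as pd
import pytest

from lipidheat import LipidDataset, Unit, percent_of_total, qc_filter
from lipidheat.simulate import SimConfig, simulate_study


def make_dataset(values: dict, meta: dict | None = None, unit: Unit = Unit.SIGNAL) -> LipidDataset:
    """Build a small dataset from {analyte: [per-sample values]}."""
    vals = pd.DataFrame(values)
    n = len(vals)
    vals.index = [f"s{i+1}" for i in range(n)]
    base = {
        "genotype": ["G1"] * n,
        "treatment": ["AT"] * n,
        "year": [2018] * n,
        "block": [1] * n,
        "replicate": list(range(1, n + 1)),
        "is_qc_pool": [False] * n,
    }
    if meta:
        base.update(meta)
    return LipidDataset(vals, pd.DataFrame(base, index=vals.index), unit)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (seed 0) with its ground truth."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_pct(default_study):
    """The default study after QC filtering and percent-of-total conversion."""
    ds, _ = default_study
    filtered, _ = qc_filter(ds)
    return percent_of_total(filtered)
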