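import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import perionet as pn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One full synthetic dataset shared by read-only tests."""
    cfg = pn.SyntheticConfig(rng_seed=11)
    regulon, truth = pn.generate_reference_regulon(cfg)
    counts = pn.generate_counts(regulon, truth, cfg)
    ppi = pn.generate_ppi(regulon, truth, cfg)
    norm = pn.normalize(counts)
    return {"config": cfg, "regulon": regulon, "truth": truth,
            "counts": counts, "ppi": ppi, "norm": norm}


@pytest.fixture()
def doubling_counts():
    """Two samples where sample2 = 2 x sample1, all entries positive."""
    rng = np.random.default_rng(3)
    col = rng.integers(10, 1000, size=40)
    counts = pd.DataFrame({"s1": col, "s2": 2 * col},
                          index=[f"g{i}" for i in range(40)])
    design = pd.DataFrame({"condition": ["a", "b"], "replicate": [1, 1]},
                          index=pd.Index(["s1", "s2"], name="sample"))
    return pn.CountMatrix(counts=counts, design=design)


def make_norm(values: pd.DataFrame, conditions: dict[str, str] | None = None):
    """Wrap a plain matrix as a NormalizedMatrix with unit factors."""
    design = pd.DataFrame(
        {"condition": [
            (conditions or {}).get(s, "a") for s in values.columns],
         "replicate": range(1, len(values.columns) + 1)},
        index=pd.Index(values.columns, name="sample"))
    return pn.NormalizedMatrix(
        values=values,
        size_factors=pd.Series(1.0, index=values.columns),
        design=design)
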