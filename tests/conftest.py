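import numpy as np
import pandas as pd
import pytest

from stemnet import simulate
from stemnet.data import CountMatrix, ExpressionMatrix, SampleTable


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 3 planted modules, 300 genes, 48 samples."""
    modules = (
        simulate.ModuleSpec("early", 40, "D1", cw_annotation_rate=0.05,
                            n_bait_tfs=1),
        simulate.ModuleSpec("scw", 50, "D3", cw_annotation_rate=0.8, n_bait_tfs=2),
        simulate.ModuleSpec("late", 35, "D5", cw_annotation_rate=0.0, n_bait_tfs=1),
    )
    design = simulate.FactorialDesign(
        years=("2013", "2014"),
        regimes=("WW", "WD"),
        internode_ranks=(12,),
        stages=("D1", "D2", "D3", "D4", "D5"),
        replicates=2,  # 2*2*1*5*2 = 40 samples... adjust below
    )
    return simulate.SimConfig(
        n_genes_total=300, module_specs=modules, design=design,
        n_background_baits=2, n_lowexpr_baits=1, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_expression(small_dataset):
    from stemnet.preprocess import filter_low_expression, normalize_counts

    filtered = filter_low_expression(small_dataset["counts"], 3, 10)
    return normalize_counts(filtered)


@pytest.fixture
def tiny_counts():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.integers(0, 50, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )
    return CountMatrix(df)


@pytest.fixture
def tiny_samples():
    rows = []
    for i, (year, stage) in enumerate(
        [("2013", "D1"), ("2013", "D2"), ("2014", "D1"), ("2014", "D2")]
    ):
        rows.append(
            {"sample_id": f"s{i}", "year": year, "block": "B1", "regime": "WW",
             "internode_rank": 12, "stage": stage, "replicate": 1}
        )
    return SampleTable(pd.DataFrame(rows), stage_order=("D1", "D2"))


def make_expression(values: np.ndarray, prefix: str = "g") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i:03d}" for i in range(values.shape[0])],
            columns=[f"s{j:03d}" for j in range(values.shape[1])],
        )
    )
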