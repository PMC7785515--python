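import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Compact two-class simulation shared by several test modules."""
    from costim.simulate import SimulationParams, simulate_experiment

    params = SimulationParams(
        class_counts={"cd28_linear": 40, "tcr_switch": 30, "null": 130}, seed=101)
    return simulate_experiment(params)


@pytest.fixture(scope="session")
def classified(small_sim):
    from costim.classify import run_classification

    return run_classification(small_sim.counts, small_sim.design,
                              small_sim.annotation)


@pytest.fixture()
def toy_annotation():
    ann = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(6)],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chrY"],
        "start": [100, 10_000, 300_000, 100, 50_000, 100],
        "end": [1_100, 12_000, 310_000, 2_100, 52_000, 600],
        "strand": ["+", "-", "+", "+", "-", "+"],
    })
    ann["length"] = ann["end"] - ann["start"]
    return ann.set_index("gene_id", drop=False)
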