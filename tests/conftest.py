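import numpy as np
import pandas as pd
import pytest

from corehybrid import (FeatureTable, ScenarioConfig, build_pedigree,
                        run_pipeline, simulate_scenario)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down scenario for fast unit tests."""
    return ScenarioConfig(n_parents_pop1=8, n_males_pop2=30, n_analytes=120,
                          n_latent=4, n_causal=20, module_size=5, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    parents, pedigree, phenotypes, truth = simulate_scenario(small_config)
    return {"config": small_config, "parents": parents, "pedigree": pedigree,
            "phenotypes": phenotypes, "truth": truth}


@pytest.fixture(scope="session")
def default_result():
    """Full study-scale pipeline run (18-parent diallel, 106 RIL hybrids,
    800 analytes, 60 causal), shared by the simulation-based acceptance
    tests."""
    return run_pipeline(ScenarioConfig(seed=42))


@pytest.fixture()
def toy_table():
    """Tiny hand-checkable feature table: 2 groups x 4 samples."""
    data = pd.DataFrame(
        {
            # nonzero in 3/4 of group A, 0/4 of group B
            "A1": [1.0, 2.0, 3.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            # all zero
            "A2": [0.0] * 8,
            # nonzero in exactly 2/4 of each group
            "A3": [1.0, 1.0, 0.0, 0.0, 2.0, 2.0, 0.0, 0.0],
            # nonzero everywhere
            "A4": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
        },
        index=[f"s{i}" for i in range(8)],
    )
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=data.index)
    return FeatureTable(data, groups=groups)


@pytest.fixture(scope="session")
def default_pedigree():
    return build_pedigree(ScenarioConfig())
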