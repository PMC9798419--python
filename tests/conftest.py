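import numpy as np
import pandas as pd
import pytest

import mirstab as ms


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    """Packaged reference-panel table: 7 windows + 7×11 log2FCs."""
    return ms.load_reference_panel_table()


@pytest.fixture()
def small_cm() -> ms.CountMatrix:
    df = pd.DataFrame(
        [[10, 20, 30], [5, 10, 15], [100, 200, 300], [8, 16, 24]],
        index=["miR-a", "miR-b", "miR-c", "miR-d"],
        columns=["s1", "s2", "s3"],
    )
    return ms.CountMatrix(df)


@pytest.fixture(scope="session")
def scenario() -> ms.Scenario:
    """One default synthetic study (200 miRNAs, 11 cancer datasets)."""
    return ms.generate_scenario(ms.PipelineConfig(rng_seed=1), seed=1)


@pytest.fixture(scope="session")
def healthy_normalized(scenario):
    """Normalized healthy time course restricted to expressed features."""
    cm, st = scenario.healthy
    nm = ms.normalize(cm)
    common = ms.common_features(nm, st, 20.0)
    kept = [f for f in nm.feature_ids if f in common]
    return ms.NormalizedMatrix(nm.values.loc[kept], nm.size_factors), st


def random_count_matrix(rng: np.random.Generator, n_feat=10, n_samp=8,
                        low=1, high=500) -> ms.CountMatrix:
    counts = rng.integers(low, high, size=(n_feat, n_samp))
    return ms.CountMatrix(pd.DataFrame(
        counts,
        index=[f"miR-{i}" for i in range(n_feat)],
        columns=[f"s{j}" for j in range(n_samp)],
    ))
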