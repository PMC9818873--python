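import numpy as np
import pandas as pd
import pytest

from icpair import (SimulationConfig, build_pairs, generate_cohort,
                    ssgsea_scores)

SMALL_CONFIG = SimulationConfig(n_samples=150, genes_per_set=12,
                                n_background_genes=60, seed=11)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic cohort shared by tests that only read it."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_scores(small_bundle):
    return ssgsea_scores(small_bundle.expression, small_bundle.gene_sets)


@pytest.fixture(scope="session")
def small_pairs(small_scores):
    return build_pairs(small_scores)


@pytest.fixture()
def toy_expression():
    """5 genes x 3 samples with distinct values per column."""
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(5, 3))
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(5)],
                        columns=["s0", "s1", "s2"])


def brute_force_cindex(scores, times, events) -> float:
    """Exhaustive double-loop Harrell's C (independent oracle)."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def make_survival(times, events, index=None, **extra) -> pd.DataFrame:
    idx = index if index is not None else [f"p{i}" for i in range(len(times))]
    df = pd.DataFrame({"time_months": times, "event": events}, index=idx)
    for k, v in extra.items():
        df[k] = v
    df.index.name = "sample_id"
    return df
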