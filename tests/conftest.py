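"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

import twinace as ta


@pytest.fixture(scope="session")
def cerebrum():
    return ta.cerebrum_paths()


@pytest.fixture(scope="session")
def small_cohort(cerebrum):
    """1,000 + 1,000 pairs under the cerebrum truth, prepared (5 classes)."""
    cfg = ta.SimulationConfig(n_mz_pairs=1000, n_dz_pairs=1000, seed=11)
    df = ta.simulate_pairs(cerebrum, cfg)
    df, spec, _ = ta.prepare(df)
    return df, spec


@pytest.fixture(scope="session")
def singleton_tetrachoric_data():
    """Independent individuals with a binary trait: the pair likelihood
    collapses to the classical individual-level tetrachoric likelihood.

    Prevalence is raised to 0.3 so the 2x2 table is well filled at n=2,000.
    """
    rng = np.random.default_rng(202)
    n = 2000
    r_true = -0.4
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, r_true], [r_true, 1.0]], size=n
    )
    prevalence = 0.3
    t_sz = ta.threshold_from_prevalence(prevalence)
    import pandas as pd
    df = pd.DataFrame({
        "pair_id": [f"s{i:05d}" for i in range(n)],
        # zygosity labels only satisfy the both-groups requirement; there
        # are no complete pairs, so no cross-member information exists
        "zygosity": ["MZ" if i % 2 == 0 else "DZ" for i in range(n)],
        "member": 1,
        "affected": (z[:, 0] > t_sz).astype(int),
        "bv": z[:, 1],
    })
    df["bv_cat"] = np.where(df["bv"] > np.median(df["bv"]), 2, 1)
    return df, prevalence, r_true
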