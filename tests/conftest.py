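import numpy as np
import pandas as pd
import pytest

from pqtlkit.datatypes import SimulationConfig, make_effect
from pqtlkit.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One planted cis and one planted trans effect in a compact cohort."""
    cfg = SimulationConfig(
        n_individuals=68,
        n_variants=600,
        n_traits=16,
        seed=11,
        effects=[
            make_effect("snp000100", "ab0002", 0.65, "cis"),
            make_effect("snp000450", "ab0005", 0.5, "trans"),
        ],
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_traits_68():
    """Pure-noise trait matrix for 68 individuals (no genetic effects)."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.standard_normal((68, 24)),
        index=pd.Index([f"NA{18500 + i:05d}" for i in range(68)], name="individual_id"),
        columns=pd.Index([f"ab{i:04d}" for i in range(24)], name="trait_id"),
    )
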