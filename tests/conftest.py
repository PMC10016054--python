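import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from duetsync import DesignSpec, DyadParams, simulate_dataset

CLEAN = dict(p_wrong_note=0.0, p_mistempo=0.0, p_outlier=0.0)


@pytest.fixture(scope="session")
def small_design() -> DesignSpec:
    return DesignSpec(n_pairs=2, trials_per_condition=8)


@pytest.fixture(scope="session")
def clean_params() -> DyadParams:
    return DyadParams(seed=42, **CLEAN)


@pytest.fixture(scope="session")
def noiseless_params() -> DyadParams:
    return DyadParams(
        seed=0,
        sigma_timekeeper=0.0,
        sigma_motor=0.0,
        sigma_fam=0.0,
        sigma_start=0.0,
        kappa=0.0,
        lambda_seg=0.0,
        **CLEAN,
    )


@pytest.fixture(scope="session")
def small_dataset(clean_params, small_design) -> tuple[pd.DataFrame, pd.DataFrame]:
    return simulate_dataset(clean_params, small_design)
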