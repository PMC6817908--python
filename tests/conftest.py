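import numpy as np
import pandas as pd
import pytest

from shorescan.config import SimulationConfig
from shorescan.methyl import BetaMatrix, CpGMap


@pytest.fixture
def small_config():
    """A small but structurally complete simulation."""
    return SimulationConfig(
        n_samples_tumor=40,
        n_samples_normal=40,
        n_genes=300,
        module_size=15,
        rng_seed=0,
    )


@pytest.fixture
def toy_map():
    frame = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(6) * 100,
            "region": ["north_shore"] * 2 + ["island"] * 2 + ["south_shore"] * 2,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(6)], name="probe_id"),
    )
    return CpGMap(frame)


def make_beta(values, groups, probe_ids=None):
    probe_ids = probe_ids or [f"cg{i:08d}" for i in range(len(values))]
    samples = list(groups.keys()) if isinstance(groups, dict) else [f"s{i}" for i in range(len(groups))]
    labels = list(groups.values()) if isinstance(groups, dict) else list(groups)
    df = pd.DataFrame(values, index=probe_ids, columns=samples, dtype=float)
    return BetaMatrix(df, pd.Series(labels, index=samples))
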