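import numpy as np
import pandas as pd
import pytest

from medipchip import (
    ArrayCondition,
    ArrayDesign,
    HitTable,
    SimulationConfig,
    generate_design,
    generate_truth,
    simulate_arrays,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=40, probes_per_promoter=20, effect_size=1.5, noise_sd=0.3, seed=202
    )


@pytest.fixture(scope="session")
def small_design(small_config):
    return generate_design(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_signals(small_design, small_truth, small_config):
    return simulate_arrays(small_design, small_truth, small_config)


@pytest.fixture
def toy_design() -> ArrayDesign:
    """Two promoters on one chromosome, 6 evenly spaced probes each."""
    promoters = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": "chr1",
            "tss": [1500, 6500],
            "strand": ["+", "+"],
            "region_start": [0, 5000],
            "region_end": [2300, 7300],
        }
    )
    starts = np.concatenate([np.arange(100, 2300, 380), 5000 + np.arange(100, 2300, 380)])
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(starts))],
            "chrom": "chr1",
            "start": starts,
            "length": 50,
            "gene_id": ["gA"] * 6 + ["gB"] * 6,
        }
    )
    return ArrayDesign(probes=probes, promoters=promoters)


def make_hit_table(hits: dict[str, list[int]], conditions) -> HitTable:
    """Build a HitTable from {gene_id: [0/1 per array]} and ArrayConditions."""
    frame = pd.DataFrame.from_dict(hits, orient="index").astype(bool)
    frame.columns = [c.array_id for c in conditions]
    per_array = [(c, frame[c.array_id]) for c in conditions]
    return HitTable.from_array_hits(per_array)
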