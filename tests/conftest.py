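import numpy as np
import pandas as pd
import pytest

from clonesucc import SimulationConfig, simulate_serial_experiment
from clonesucc.cli_io import annotation_from_design
from clonesucc.is_processing import run_filter_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(20170519)


def make_is_frame(rows):
    """rows: (chrom, pos, strand, tumor_id, enzyme, reads)"""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "tumor_id", "enzyme", "reads"]
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One deterministic succession experiment, reused across tests."""
    cfg = SimulationConfig(seed=42)
    return simulate_serial_experiment(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    rec = small_experiment
    matrix = run_filter_pipeline(
        rec.is_tables,
        rec.design["experiment"].to_dict(),
        tumor_order=list(rec.design["tumor_id"]),
    )
    return matrix, annotation_from_design(rec.design)
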