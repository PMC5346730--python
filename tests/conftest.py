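import numpy as np
import pandas as pd
import pytest

from resistnet.pipeline import PipelineConfig, run_pipeline
from resistnet.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def demo_config() -> SimulationConfig:
    """The packaged demo study: 600 genes, 6 modules, 120 samples."""
    return SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def demo_run(demo_config):
    """One full in-memory pipeline run on the demo simulation."""
    cfg = PipelineConfig(simulation=demo_config, outdir="unused")
    return run_pipeline(cfg, persist=False)


@pytest.fixture(scope="session")
def demo_data(demo_config):
    return simulate(demo_config)


@pytest.fixture
def toy_transcripts() -> pd.DataFrame:
    """Hand-written transcript table covering isoform and biotype cases."""
    rows = [
        # gene A: three isoforms, mean abundances {2, 5, 3} -> a2 wins
        ("a1", "GA", "protein_coding", 1000, 2.0, 2.0),
        ("a2", "GA", "protein_coding", 1500, 4.0, 6.0),
        ("a3", "GA", "protein_coding", 800, 3.0, 3.0),
        # gene B: single isoform
        ("b1", "GB", "protein_coding", 2000, 1.0, 4.0),
        # gene C: non-coding, must be dropped
        ("c1", "GC", "lincRNA", 900, 7.0, 7.0),
        # gene D: tied means -> lexicographically smaller transcript kept
        ("d2", "GD", "protein_coding", 700, 3.0, 3.0),
        ("d1", "GD", "protein_coding", 600, 2.0, 4.0),
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "biotype", "length_bp", "expr_a", "expr_b"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
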