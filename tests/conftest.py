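import numpy as np
import pandas as pd
import pytest

from methylpanel import Config, run_differential, run_preprocess
from methylpanel.simulate import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_sim():
    """A small panel with planted case effects, shared across tests."""
    cfg = SimConfig(n_genes=60, cytosines_per_gene=(5, 15), seed=11)
    return cfg, *simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_fits(small_sim):
    """Preprocessed + fitted version of the shared panel."""
    cfg, counts, sheet, annotation, truth = small_sim
    counts, B, sheet, report = run_preprocess(counts, sheet, annotation, Config())
    fits = run_differential(B, sheet, Config())["group"]
    return cfg, fits, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_counts(M, U, samples=None, start_pos=100):
    """Build a MethylCounts from plain arrays for hand-written fixtures."""
    from methylpanel import MethylCounts

    M = np.asarray(M, dtype=float)
    samples = samples or [f"S{j}" for j in range(M.shape[1])]
    keys = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(start_pos, start_pos + M.shape[0]),
        "strand": "+",
        "context": "CpG",
    })
    return MethylCounts(keys, samples, M, np.asarray(U, dtype=float))
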