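import numpy as np
import pandas as pd
import pytest

from taraclass import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=400, n_markers_per_chrom=200,
                            n_chromosomes=2, n_pairs=8, n_metastases=40,
                            seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default-scale cohort (15 pairs, 112 metastases, 5000 genes)."""
    return generate_cohort(SimulationConfig(seed=0))


def make_segments(rows):
    """Build a called segment table from (sample, chrom, cover_start,
    cover_end, mean_log2, state) tuples; marker fields are synthesized."""
    recs = []
    for sample, chrom, lo, hi, mean, state in rows:
        recs.append(dict(sample=sample, chrom=chrom, start=0, end=1,
                         n_markers=1, mean_log2=mean, state=state,
                         start_bp=int(lo) + 1, end_bp=int(hi),
                         cover_start=float(lo), cover_end=float(hi)))
    return pd.DataFrame(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
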