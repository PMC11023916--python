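import numpy as np
import pytest

from offcall import CnvSpec, SimConfig, simulate_bins, simulate_matrix


@pytest.fixture(scope="session")
def small_batch():
    """20-sample batch, 240 bins, three injected CNVs in S005."""
    cfg = SimConfig(
        n_samples=20, n_on_bins=180, n_off_bins=60, seed=3,
        cnv_spec=[CnvSpec("S005", 40, 8, 1),
                  CnvSpec("S005", 120, 3, 3),
                  CnvSpec("S005", 200, 1, 0)])
    bins = simulate_bins(cfg)
    matrix, truth = simulate_matrix(bins, cfg)
    return bins, matrix, truth, cfg


@pytest.fixture(scope="session")
def null_batch():
    """CNV-free batch for normalization statistics."""
    cfg = SimConfig(n_samples=12, n_on_bins=150, n_off_bins=50, seed=11)
    bins = simulate_bins(cfg)
    matrix, _ = simulate_matrix(bins, cfg)
    return bins, matrix, cfg


def make_ratio_batch(n_bins=1000, n_controls=10, rank=3, factor_sd=0.05,
                     noise_sd=0.02, seed=0):
    """Constructed control-ratio matrix with low-rank shared structure:
    ratio = 1 + loadings.factors + iid noise."""
    rng = np.random.default_rng(seed)
    factors = rng.normal(scale=factor_sd, size=(rank, n_bins))
    loadings = rng.normal(size=(n_controls, rank))
    controls = 1.0 + (loadings @ factors).T \
        + rng.normal(scale=noise_sd, size=(n_bins, n_controls))
    test = 1.0 + factors.T @ rng.normal(size=rank) \
        + rng.normal(scale=noise_sd, size=n_bins)
    return test, controls, rng
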