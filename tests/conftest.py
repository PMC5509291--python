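import numpy as np
import pytest

from methex.methylome import FilteredCpGMatrix, Group
from methex.simulate import SimConfig, simulate_genome, simulate_methylome


def make_matrix(first_levels, third_levels, positions=None, chrom="chr1"):
    """Build a FilteredCpGMatrix from per-site per-sample percent arrays.

    ``first_levels`` / ``third_levels`` are (n_sites, n_samples) arrays; NaN
    marks a sample below the depth cutoff at that site.
    """
    first = np.atleast_2d(np.asarray(first_levels, dtype=float))
    third = np.atleast_2d(np.asarray(third_levels, dtype=float))
    n_sites = first.shape[0]
    if positions is None:
        positions = [100 + 50 * i for i in range(n_sites)]
    sites = [(chrom, int(p)) for p in positions]
    levels = np.hstack([first, third])
    sample_ids = [f"F{i}" for i in range(first.shape[1])] + [f"T{i}" for i in range(third.shape[1])]
    groups = [Group.FIRST] * first.shape[1] + [Group.THIRD] * third.shape[1]
    return FilteredCpGMatrix(sites, levels, sample_ids, groups)


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated dataset shared across modules (30 genes, seed 11)."""
    cfg = SimConfig(seed=11, n_genes=30, frac_coupled=0.2, frac_dm_promoters=0.1, frac_de=0.1)
    genome = simulate_genome(cfg)
    callsets = simulate_methylome(cfg, genome)
    return cfg, genome, callsets
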