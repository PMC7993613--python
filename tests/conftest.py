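import numpy as np
import pandas as pd
import pytest

from bsakit import simcross, splicefx


def random_pool_table(rng: np.random.Generator, n_sites: int, n_chroms: int = 1) -> pd.DataFrame:
    """Random but well-formed PoolSite table, sorted by (chrom, pos)."""
    frames = []
    for c in range(n_chroms):
        n = n_sites if n_chroms == 1 else int(rng.integers(1, n_sites + 1))
        pos = np.sort(rng.choice(10_000_000, size=n, replace=False)) + 1
        depth_m = rng.poisson(40, n)
        depth_w = rng.poisson(40, n)
        alt_m = rng.binomial(depth_m, rng.uniform(0, 1, n))
        alt_w = rng.binomial(depth_w, rng.uniform(0, 1, n))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c + 1}",
                    "pos": pos,
                    "ref": "A",
                    "alt": "C",
                    "qual": 1000.0,
                    "mut_ref": depth_m - alt_m,
                    "mut_alt": alt_m,
                    "wt_ref": depth_w - alt_w,
                    "wt_alt": alt_w,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_gene():
    return splicefx.example_gene()


@pytest.fixture(scope="session")
def demo_isoforms(demo_gene):
    return splicefx.build_isoforms(demo_gene, 1, [8, 15, 221])


@pytest.fixture(scope="session")
def small_sim():
    """One seeded scaled-down cross simulation shared across tests."""
    design = simcross.paper_design(seed=3)
    founders = simcross.simulate_founders(design)
    cohort = simcross.simulate_f2_cross(founders, design)
    sites = simcross.pool_and_sequence(cohort, design, founders)
    return design, founders, cohort, sites
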