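"""Shared fixtures: small random matrices and a desk-scale test cohort.

The ``small_cohort`` fixture simulates a 3 Mb chromosome (600 bins at 5 kb)
with a handful of strong planted loops — large enough for the dot caller's
lambda chunking to populate several chunks, small enough for second-scale
unit tests.  The full-size preset cohorts are exercised by the acceptance
tests only.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from unionloops.contacts import ContactMatrix
from unionloops.dotcall import DotCallParams
from unionloops.model import BinnedChrom
from unionloops.simdata import LoopSpec, SimConfig, simulate_cohort

SMALL_CHROM_BINS = 600
SMALL_RES = 5000


def small_sim_config(**overrides) -> SimConfig:
    kw = dict(
        chrom_name="chrT",
        length_bp=SMALL_CHROM_BINS * SMALL_RES,
        resolution=SMALL_RES,
        n_samples=3,
        depth=9e5,  # same per-pixel intensity scale as the full presets
        alpha=1.0,
        bias_sigma=0.2,
        loop_spec=LoopSpec(
            n_loops=12,
            min_dist_bins=20,
            max_dist_bins=60,
            factor=6.0,
            sigma_bins=1.0,
            jitter_bins=1,
            min_separation_bins=20,
        ),
        seed=0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def small_dot_params(**overrides) -> DotCallParams:
    kw = dict(max_loci_separation=400_000, tile_size=1_000_000)
    kw.update(overrides)
    return DotCallParams(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_sim_config(), seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    m = small_cohort.matrices["S1"]["chrT"]
    m.prepare()
    return m


@pytest.fixture()
def random_matrix():
    """A dense-ish random 80-bin matrix with two masked bins."""
    rng = np.random.default_rng(7)
    n = 80
    chrom = BinnedChrom("c", n * SMALL_RES, SMALL_RES)
    dense = np.triu(rng.poisson(3.0, size=(n, n)))
    dense[13, :] = 0
    dense[:, 13] = 0
    m = ContactMatrix(chrom, sp.coo_matrix(dense))
    m.prepare()
    return m
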