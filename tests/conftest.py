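"""Shared fixtures: small handcrafted inputs plus session-scoped synthetic runs."""

import logging

import numpy as np
import pytest

import nomeprofile as npf
from nomeprofile.cli import RunConfig, run_match, run_profile, run_stratify

logging.getLogger("nomeprofile").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study conditions: 2 Mb, 200 promoters, seed 7."""
    return npf.simulate_dataset(npf.SimConfig())


@pytest.fixture(scope="session")
def default_match(default_dataset):
    res = default_dataset
    return run_match(res.genome, res.promoters, RunConfig())


@pytest.fixture(scope="session")
def default_strata(default_dataset, default_match):
    res = default_dataset
    matches = default_match[3]
    return run_stratify(res.genome, res.sites, res.promoters, matches, RunConfig())


@pytest.fixture(scope="session")
def recovery_dataset():
    """Parameter-recovery conditions: 300 promoters, coverage 20, seed 1."""
    cfg = npf.SimConfig(seed=1, n_promoters=300, mean_coverage=20)
    return npf.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_top_profiles(recovery_dataset):
    res = recovery_dataset
    top = npf.select_by_expression(res.promoters, 0.05, "top")
    raw, smoothed = run_profile(res.genome, res.sites, top, RunConfig())
    return top, raw, smoothed


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, tiny dataset for CLI and matcher unit tests."""
    cfg = npf.SimConfig(seed=5, length=150_000, n_promoters=10, mean_coverage=10)
    return npf.simulate_dataset(cfg)


def make_site_table(rows):
    """rows: iterable of (chrom, pos, context, meth, total)."""
    chrom, pos, ctx, meth, total = zip(*rows) if rows else ((), (), (), (), ())
    return npf.SiteTable.from_arrays(list(chrom), np.array(pos, dtype=np.int64),
                                     list(ctx), np.array(meth), np.array(total))


@pytest.fixture
def site_table_factory():
    return make_site_table
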