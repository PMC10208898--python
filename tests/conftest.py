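"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from hazelpop.variants import PopulationMap, VariantMatrix


def make_matrix(genotypes, pos=None, chrom="chr1", sample_prefix="s",
                ref="A", alt="T", site_depth=None):
    """Build a small VariantMatrix from a (samples x sites) list/array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    if pos is None:
        pos = np.arange(n_sites) * 100
    return VariantMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_samples)],
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array([ref] * n_sites, dtype=object),
        alt=np.array([alt] * n_sites, dtype=object),
        genotypes=g,
        site_depth=site_depth,
    )


@pytest.fixture(scope="session")
def neutral_panel_10():
    """One 10-diploid neutral coalescent panel reused across tests."""
    from hazelpop.simulate import neutral_panel

    return neutral_panel(n_diploid=10, L=1_000_000, theta_site=1e-3, seed=42)


@pytest.fixture(scope="session")
def toy_genome():
    from hazelpop.simulate import make_toy_genome

    return make_toy_genome(seed=7)


@pytest.fixture()
def two_pop_matrix():
    """4+4 diploid toy genotypes at 3 sites (hand-checkable)."""
    g = [
        [0, 1, 2],
        [0, 1, 1],
        [1, 2, 0],
        [0, 1, 2],
        [2, 0, 1],
        [2, 1, 1],
        [1, 0, 2],
        [2, 2, 0],
    ]
    vm = make_matrix(g)
    pops = PopulationMap({f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
    return vm, pops
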