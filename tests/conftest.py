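"""Shared fixtures: hand-built micro-panels and cached simulated panels."""

from __future__ import annotations

import numpy as np
import pytest

from ehhscan import HaplotypePanel, make_fixture


def build_panel(
    haps,
    positions=None,
    chrom="1",
    ancestral_is_ref=None,
    ref=None,
    alt=None,
):
    """HaplotypePanel from a plain 0/1 matrix (rows = haplotypes)."""
    haps = np.asarray(haps, dtype=np.uint8)
    n_hap, n_sites = haps.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if ancestral_is_ref is None:
        ancestral_is_ref = np.ones(n_sites, dtype=np.int8)
    return HaplotypePanel(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype=object),
        haplotypes=haps,
        sample_ids=[f"s{i}" for i in range(n_hap // 2)],
        ancestral_is_ref=np.asarray(ancestral_is_ref, dtype=np.int8),
    )


def random_panel(rng, n_hap=8, n_sites=10):
    """Random small panel; positions random strictly increasing."""
    haps = rng.integers(0, 2, size=(2 * ((n_hap + 1) // 2), n_sites)).astype(np.uint8)
    positions = np.sort(rng.choice(np.arange(1, 100_000), size=n_sites, replace=False))
    return build_panel(haps, positions=positions)


@pytest.fixture(scope="session")
def sweep_private_fix():
    return make_fixture("sweep_private", seed=1)


@pytest.fixture(scope="session")
def sweep_shared_fix():
    return make_fixture("sweep_shared", seed=1)


@pytest.fixture(scope="session")
def neutral_single_fix():
    return make_fixture("neutral_single", seed=0)


@pytest.fixture(scope="session")
def freqscan_fix():
    return make_fixture("freqscan_differentiated", seed=1)
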