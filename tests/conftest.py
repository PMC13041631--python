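"""Shared fixtures: small molecule corpora and batch builders.

Everything is generated programmatically (no stored data); the template pool
doubles as a source of valid, diverse SMILES.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_step  # noqa: E402

from divnav.synthetic_generator import _pooled  # noqa: E402


@pytest.fixture(scope="session")
def small_pool():
    """A 64-template pool: a cheap source of valid, mutually diverse SMILES."""
    return _pooled(64, 123)


@pytest.fixture(scope="session")
def filler_pool():
    """A 128-template pool used as mutually dissimilar filler molecules."""
    return _pooled(128, 7)


@pytest.fixture(scope="session")
def corpus(small_pool):
    """>= 100 valid canonical SMILES plus their raw spellings."""
    return list(zip(small_pool.raw_smiles, small_pool.canonical))


@pytest.fixture(scope="session")
def random_batches(small_pool):
    """20 random batches of <= 50 molecules drawn from the small pool."""
    rng = np.random.default_rng(42)
    batches = []
    for b in range(20):
        size = int(rng.integers(5, 51))
        idx = rng.choice(len(small_pool.raw_smiles), size=size, replace=True)
        batches.append(make_step([small_pool.raw_smiles[i] for i in idx], step=b))
    return batches
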