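"""Shared fixtures: a small designed library reused across test modules."""

import pytest

from mulsec import build_library, random_proteins, tile_library


@pytest.fixture(scope="session")
def small_proteins():
    return random_proteins(10, (120, 200), seed=11)


@pytest.fixture(scope="session")
def small_library(small_proteins):
    return build_library(small_proteins, seed=11)


@pytest.fixture(scope="session")
def small_oligo_sets(small_library):
    return tile_library(small_library.synthons)
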