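"""Shared fixtures: small synthetic corpora, generated once per session."""

from __future__ import annotations

import pytest

from pyruvoylsite.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A reduced corpus for fast unit tests (12 proteins, 1 site each)."""
    return SyntheticConfig(
        n_proteins=12, length_range=(60, 90), n_positive_sites=12, seed=7
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(small_config, tmp_path_factory):
    """The same small corpus written to disk."""
    out = tmp_path_factory.mktemp("fixtures")
    return generate(small_config, out_dir=out)


@pytest.fixture(scope="session")
def study_bundle():
    """Default study-shaped corpus: 46 proteins, one planted site each."""
    return generate(SyntheticConfig(seed=1))
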