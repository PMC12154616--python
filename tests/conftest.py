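"""Shared fixtures: one synthetic genome + alignments per test session."""

from __future__ import annotations

import pytest

from darkregions import ClassificationConfig, open_alignment
from darkregions.synthetic_data import (
    build_reference,
    default_spec,
    write_fixture,
)

FIXTURE_SEED = 1
DEPTH_TARGET = 10
READ_LEN = 500


@pytest.fixture(scope="session")
def synthetic_ref():
    return build_reference(default_spec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def fixture_paths(synthetic_ref, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(
        synthetic_ref, out, depth_target=DEPTH_TARGET, read_len=READ_LEN
    )


@pytest.fixture(scope="session")
def config():
    return ClassificationConfig()


@pytest.fixture()
def bamfile(fixture_paths):
    af = open_alignment(fixture_paths["bam"])
    yield af
    af.close()
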