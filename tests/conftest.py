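"""Shared fixtures: small and full-size synthetic cohorts."""

from __future__ import annotations

import pytest

from dsifunnel.synthetic import default_spec, generate


@pytest.fixture(scope="session")
def small_cohort():
    """30 patients per group — fast enough for CV-based tests."""
    return generate(default_spec(seed=5).with_group_sizes(30))


@pytest.fixture(scope="session")
def default_cohort():
    """The full 883-patient cohort at the published group sizes, seed 1."""
    return generate(default_spec(seed=1))
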