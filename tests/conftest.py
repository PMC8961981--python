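"""Shared fixtures: one small synthetic cohort and one reduced-length fit per
outcome, reused across unit-test modules to keep the suite fast."""

from __future__ import annotations

import pytest

from dmtrank import (
    BuildConfig,
    ModelSpec,
    SamplerSettings,
    build_switch_table,
    default_catalogue,
    default_generator_spec,
    generate_cohort,
    sample_switch_records,
)
from dmtrank.models import fit as fit_model


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_generator_spec(n_patients=250, seed=42))


@pytest.fixture(scope="session")
def small_table(small_cohort, catalogue):
    return build_switch_table(small_cohort, BuildConfig(catalogue=catalogue))


@pytest.fixture(scope="session")
def fast_settings():
    return SamplerSettings(steps=600, burn=500, thin=3, seed=7)


@pytest.fixture(scope="session")
def sampled_table(catalogue):
    """Flat 500-row switch table from the fast table-level sampler."""
    return sample_switch_records(default_generator_spec(seed=3), 500, seed=21)


@pytest.fixture(scope="session")
def relapse_fit(sampled_table, catalogue, fast_settings):
    spec = ModelSpec(outcome="relapse", catalogue=catalogue, sampler=fast_settings)
    return fit_model(sampled_table, spec)


@pytest.fixture(scope="session")
def cdp_fit(sampled_table, catalogue, fast_settings):
    spec = ModelSpec(outcome="cdp", catalogue=catalogue, sampler=fast_settings)
    return fit_model(sampled_table, spec)
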