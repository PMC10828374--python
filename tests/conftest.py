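"""Shared fixtures: one default simulated cohort per session.

The cohort is generated programmatically (no stored fixtures); seed 1 is
the suite's reference cohort.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

import metanoise as mn

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """(table, log, cytokines, truth) for the default config at seed 1."""
    return mn.simulate_cohort(mn.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_efficiency(default_cohort):
    _, log, _, _ = default_cohort
    return mn.efficiency_table(log)
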