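"""Shared fixtures.

The heavy cohort runs are session-scoped so that the policy-grid tests
and the statistical property tests share a single simulated arm set.
"""

from __future__ import annotations

import numpy as np
import pytest

from crcscreen import default_bundle, simulate_arms

MASTER_SEED = 20230917


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def arms_10k(bundle):
    """Per-arm per-person economics at n=10^4 over the follow-up grid,
    with fatal complications as configured (the study conditions)."""
    return simulate_arms(bundle, 10_000, MASTER_SEED,
                         followup_uplifts=(0, 5, 10, 15))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
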