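"""Shared fixtures: standard synthetic runs reused across test modules."""

import pytest

from sapfilm import PullingParams, simulate_pulling

STANDARD_SEED = 3


@pytest.fixture(scope="session")
def glycolipid_runs():
    """Full-length glycolipid pulling runs at the four standard tensions."""
    return {
        p: simulate_pulling(PullingParams(external_pressure=p, duration=25.0, seed=STANDARD_SEED))
        for p in (-0.5, -1.5, -2.5, -3.5)
    }


@pytest.fixture(scope="session")
def phospholipid_run():
    """Laterally stable phospholipid run at the most severe tension."""
    return simulate_pulling(
        PullingParams(
            external_pressure=-5.5,
            duration=22.5,
            mode="phospholipid",
            n_lipids=280,
            h_z=45.0,
            seed=STANDARD_SEED,
        )
    )
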