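"""Shared fixtures: simulated datasets are computed once per session.

Noise-free simulations are cached and noisy replicates derived from them
with ``add_noise``, which keeps the suite fast without changing any
result (noise is applied to the observed channels only).
"""

from __future__ import annotations

import numpy as np
import pytest

from oscferm import synthgen


@pytest.fixture(scope="session")
def osc_clean():
    """Noise-free oscillatory preset, 3 full post-transient cycles."""
    return synthgen.simulate_preset("oscillatory", noise_cv=0.0)


@pytest.fixture(scope="session")
def osc_clean_long():
    """Noise-free oscillatory preset, ~10 post-transient cycles."""
    return synthgen.simulate_preset("oscillatory", noise_cv=0.0, t_end=589.0)


@pytest.fixture(scope="session")
def steady_clean():
    return synthgen.simulate_preset("steady", noise_cv=0.0)


@pytest.fixture(scope="session")
def damped_clean():
    return synthgen.simulate_preset("damped", noise_cv=0.0)


@pytest.fixture(scope="session")
def preshift_clean():
    return synthgen.simulate_preset("preshift", noise_cv=0.0)


def post_transient(ts, period_h: float = 53.0, margin_h: float = 6.0):
    """Analysis window excluding the first simulated cycle (minus one
    sample margin so the first retained trough is interior)."""
    mask = ts.t >= period_h - margin_h
    return ts.t[mask], mask
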