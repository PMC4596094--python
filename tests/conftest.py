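"""Shared fixtures.

Long simulations are expensive, so every condition used by more than one
test is computed once per session through ``run_condition`` and cached.
"""

from __future__ import annotations

import pytest

from prebotc import MINUTE, SolverSettings, default_network, perturb, simulate
from prebotc.experiments import measure_rhythm

_CACHE: dict = {}


def run_condition(edits=None, duration_min=20.0, rel_tol=1e-8, abs_tol=1e-8,
                  initial=None, key=None):
    """Simulate a perturbed baseline config, memoized per session."""
    key = key or (repr(sorted((edits or {}).items())), duration_min, rel_tol, abs_tol)
    if key not in _CACHE:
        cfg = default_network()
        if edits:
            cfg = perturb(cfg, edits)
        settings = SolverSettings(duration=duration_min * MINUTE,
                                  rel_tol=rel_tol, abs_tol=abs_tol)
        _CACHE[key] = simulate(cfg, settings, initial=initial)
    return _CACHE[key]


@pytest.fixture(scope="session")
def baseline_trace():
    """Coupled model, shipped defaults, 20 min of model time."""
    return run_condition()


@pytest.fixture(scope="session")
def baseline_analysis(baseline_trace):
    return measure_rhythm(baseline_trace)


@pytest.fixture(scope="session")
def inhibition_block_trace():
    """Inhibitory synapse onto the sigh compartment removed."""
    return run_condition({"sigh.gsyn": 0.0})


@pytest.fixture(scope="session")
def inhibition_block_analysis(inhibition_block_trace):
    return measure_rhythm(inhibition_block_trace)
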