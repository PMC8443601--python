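"""Shared fixtures: small simulated experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from kinlock.synthetic_data import (
    ProbeGeometry,
    build_two_state_scheme,
    gillespie_path,
    path_phase_dwells,
    render_trace,
)


@pytest.fixture(scope="session")
def two_state_sim():
    """A 100-s two-state recording at the standard probe conditions.

    Returns (scheme, path, trace, truth) where truth is the
    (states, starts, durations) tuple of uncensored phase dwells.
    """
    scheme = build_two_state_scheme(k_f=100.0, k_u=100.0)
    path = gillespie_path(scheme, 100.0, seed=np.random.SeedSequence(101))
    trace = render_trace(path, ProbeGeometry(), seed=np.random.SeedSequence(102), scheme=scheme)
    truth = path_phase_dwells(path, scheme.phases())
    return scheme, path, trace, truth
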