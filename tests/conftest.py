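"""Shared fixtures: one production-shaped desk-scale run and tiny fast runs.

The desk-scale run (4 glutamine-rich chains of 50 residues, the full
stage schedule folded 1000x) is computed once per session and reused by
every test that needs realistic output; the mini runs (24 beads, folded
5000x, reduced target density so the wall zones do not dominate the tiny
box) exercise the identical code path in seconds for plumbing checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glutensim as g

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return g.ForceFieldConfig()


@pytest.fixture(scope="session")
def desk_system():
    specs = g.make_toy_sequences(4, 50, q_fraction=0.35, c_count=2, seed=7)
    return specs, g.build_topology(specs)


@pytest.fixture(scope="session")
def desk_run(desk_system):
    """Full protocol, shear mode, at the desk-scale study conditions."""
    _, topo = desk_system
    schedule = g.StageSchedule(scale=1000.0)
    return g.run_protocol(topo, schedule, mode="shear", seed=1)


@pytest.fixture(scope="session")
def mini_schedule():
    return g.StageSchedule(scale=5000.0, target_density=1.5)


@pytest.fixture(scope="session")
def mini_system():
    specs = g.make_toy_sequences(2, 12, q_fraction=0.3, c_count=1, seed=5)
    return g.build_topology(specs)


@pytest.fixture(scope="session")
def mini_runs(mini_system, mini_schedule):
    """Same seed, all three drive modes, on a tiny system."""
    return {mode: g.run_protocol(mini_system, mini_schedule, mode=mode, seed=3)
            for mode in ("none", "shear", "normal")}


def zigzag_chain(n: int, origin=(0.0, 0.0, 0.0), axis=0, zig=0.12,
                 spacing=0.36) -> np.ndarray:
    """A planar zigzag polyline with bond length ~0.38 and defined frames."""
    pts = np.zeros((n, 3))
    for k in range(n):
        pts[k, axis] = k * spacing
        pts[k, 2] = zig * (k % 2)
    return pts + np.asarray(origin, dtype=float)
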