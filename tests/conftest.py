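"""Shared fixtures: synthetic systems and scripted stub engines."""

from __future__ import annotations

import numpy as np
import pytest

from sumdcg.engine import SimState, TrajectorySegment
from sumdcg.toy_systems import (
    BeadSpec,
    Bond,
    ScenarioConfig,
    System,
    build_funnel_system,
)


@pytest.fixture(scope="session")
def funnel_system() -> System:
    """Default funnel scenario (neutral vestibule, no solvent)."""
    return build_funnel_system(ScenarioConfig())


@pytest.fixture()
def two_bead_system() -> System:
    """Minimal system for driving the supervisor with stub engines: one
    site bead at the origin, one ligand bead on the x axis."""
    beads = [
        BeadSpec(0, 0, "PKT", "receptor", 10.0, 0.0, 1.0, 0.0),
        BeadSpec(1, 1, "LIG", "ligand", 10.0, 0.0, 1.0, 0.0),
    ]
    coords = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
    return System(beads=beads, coords=coords, site_selection=frozenset([0]),
                  ligand_selection=frozenset([1]))


def make_random_system(n: int, seed: int, charged: bool = True,
                       with_bonds: bool = True, spread: float = 3.0) -> System:
    """Small random bead cluster for force/gradient checks.

    Beads are kept well inside the cutoff and away from each other so
    the truncated potentials are smooth at the sampled configuration.
    """
    rng = np.random.default_rng(seed)
    coords = np.empty((n, 3))
    placed = 0
    while placed < n:
        p = rng.uniform(-spread, spread, 3)
        if placed == 0 or np.linalg.norm(coords[:placed] - p, axis=1).min() > 1.6:
            coords[placed] = p
            placed += 1
    beads = [
        BeadSpec(i, i, "RND", "receptor", float(rng.uniform(10, 60)),
                 float(rng.uniform(-1, 1)) if charged else 0.0,
                 float(rng.uniform(1.2, 2.0)), float(rng.uniform(0.05, 0.6)))
        for i in range(n)
    ]
    bonds = []
    if with_bonds and n >= 2:
        for i in range(0, n - 1, 3):
            bonds.append(Bond(i, i + 1, float(rng.uniform(20, 80)),
                              float(np.linalg.norm(coords[i] - coords[i + 1]))))
    return System(beads=beads, coords=coords, bonds=bonds)


class ScriptedEngine:
    """Stub engine: moves the ligand bead of the two-bead system along x
    according to a prescribed distance function d(t_window_start, tau).

    ``distance_fn(start_time, tau)`` gives the site-ligand distance at
    offset tau (ps) into a window starting at ``start_time``.
    """

    def __init__(self, distance_fn):
        self.distance_fn = distance_fn
        self.calls = 0

    def __call__(self, system, state, duration, config):
        self.calls += 1
        n_frames = int(round(duration / config.save_interval))
        times = state.time + config.save_interval * np.arange(1, n_frames + 1)
        frames = np.repeat(state.coords[None, :, :], n_frames, axis=0)
        lig = system.ligand_bead_indices[0]
        for f, t in enumerate(times):
            d = self.distance_fn(state.time, t - state.time)
            frames[f, lig] = [d, 0.0, 0.0]
        zeros = np.zeros(n_frames)
        seg = TrajectorySegment(frames, times, zeros, zeros, zeros, zeros, zeros)
        end = SimState(frames[-1].copy(), state.velocities.copy(), float(times[-1]), state.rng)
        return seg, end


class RandomSeriesEngine(ScriptedEngine):
    """Stub engine emitting a fresh random distance series per window,
    drawn from the per-window engine RNG the supervisor provides."""

    def __init__(self, d0: float = 50.0, scale: float = 1.0):
        self.d0 = d0
        self.scale = scale
        self.calls = 0
        self.last_series: np.ndarray | None = None

    def __call__(self, system, state, duration, config):
        self.calls += 1
        n_frames = int(round(duration / config.save_interval))
        times = state.time + config.save_interval * np.arange(1, n_frames + 1)
        series = self.d0 + self.scale * state.rng.standard_normal(n_frames)
        frames = np.repeat(state.coords[None, :, :], n_frames, axis=0)
        lig = system.ligand_bead_indices[0]
        frames[:, lig, 0] = series
        frames[:, lig, 1:] = 0.0
        self.last_series = series
        zeros = np.zeros(n_frames)
        seg = TrajectorySegment(frames, times, zeros, zeros, zeros, zeros, zeros)
        end = SimState(frames[-1].copy(), state.velocities.copy(), float(times[-1]), state.rng)
        return seg, end
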