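"""The supervised-MD (SuMD) adaptive-sampling protocol.

The supervisor propagates dynamics in short time windows and monitors
the distance between the mass-weighted centroids of the ligand and of
the binding site.  A window is kept only if the ordinary-least-squares
slope of the distance-versus-time series is negative; otherwise it is
re-run from the same coordinates with freshly drawn Maxwell-Boltzmann
velocities (a tabu-like search with no biasing force).  After 30
consecutive rejected windows the run is abandoned.  Once the centroid
distance drops below 5 A the supervision is switched off and a series
of 30 short unsupervised windows probes the putative bound state,
re-engaging supervision whenever the distance climbs back above the
threshold; a run that survives all checks is extended by a final
unsupervised production run.

The supervisor is backend-agnostic: any callable with the signature
``engine(system, state, duration, engine_config) -> (segment, state)``
can drive it, which is how the test suite exercises the state machine
with scripted stub engines.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .engine import (
    EngineConfig,
    SimState,
    TrajectorySegment,
    initial_state,
    langevin_segment,
    maxwell_boltzmann_velocities,
)
from .toy_systems import System

__all__ = [
    "SupervisionConfig",
    "WindowRecord",
    "SuMDResult",
    "mass_weighted_centroid",
    "centroid_distance",
    "ols_slope",
    "supervised_window",
    "run_sumd",
    "binding_time_experiment",
    "compare_binding_times",
]


@dataclass(frozen=True)
class SupervisionConfig:
    """SuMD protocol parameters.

    window_length
        Supervised window duration in ps.  The atomistic protocol uses
        600 ps; the desk-scale default here is 10 ps.
    n_distance_samples_per_window
        Number of evenly spaced centroid-distance samples fitted per
        window (the slope criterion's data).
    max_consecutive_failures
        Consecutive rejected windows before the run is abandoned (30).
    bind_threshold
        Centroid distance (A) below which the ligand counts as bound (5).
    n_unsupervised_checks
        Number of short unsupervised windows probing the bound state (30).
    unsupervised_window_length
        Duration of each check window; defaults to ``window_length``.
    production_length
        Unsupervised extension after the checks succeed (25 ns in the
        atomistic protocol; desk-scale default 100 x window_length).
    bind_check
        "end" evaluates the 5 A criterion on the end-of-window distance
        (default); "any_frame" on every sampled distance.
    """

    window_length: float = 10.0
    n_distance_samples_per_window: int = 100
    max_consecutive_failures: int = 30
    bind_threshold: float = 5.0
    n_unsupervised_checks: int = 30
    unsupervised_window_length: float | None = None
    production_length: float | None = None
    bind_check: str = "end"
    geometric_centroids: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if self.bind_threshold <= 0:
            raise ValueError("bind_threshold must be > 0")
        for name in ("n_distance_samples_per_window", "max_consecutive_failures",
                     "n_unsupervised_checks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bind_check not in ("end", "any_frame"):
            raise ValueError("bind_check must be 'end' or 'any_frame'")

    @property
    def check_length(self) -> float:
        return self.unsupervised_window_length or self.window_length

    @property
    def production(self) -> float:
        return 100.0 * self.window_length if self.production_length is None else self.production_length


@dataclass
class WindowRecord:
    """Log entry for one protocol window."""

    index: int
    start_time: float  # ps, accepted-trajectory clock at window start
    duration: float  # ps
    distance_series: np.ndarray  # A
    slope: float  # A/ps (nan for unsupervised windows)
    decision: str  # "accepted" | "retried"
    consecutive_failures_after: int
    phase: str  # "supervised" | "unsupervised_check" | "production"
    end_distance: float  # A
    engine_seed: int


@dataclass
class SuMDResult:
    """Full outcome of one SuMD run."""

    status: str  # "bound" | "unbound_terminated" | "error"
    windows: list[WindowRecord]
    total_simulated_time: float  # ps, including retried windows
    first_binding_time: float | None  # ps, accepted-trajectory clock
    total_time_at_first_binding: float | None  # ps, incl. retried windows
    final_state: SimState | None
    trajectory: TrajectorySegment | None  # concatenated accepted frames
    error: str | None = None

    @property
    def n_accepted(self) -> int:
        return sum(1 for w in self.windows if w.decision == "accepted")

    def windows_log(self) -> pd.DataFrame:
        rows = [
            {
                "index": w.index,
                "start_time_ps": w.start_time,
                "duration_ps": w.duration,
                "slope_A_per_ps": w.slope,
                "decision": w.decision,
                "consecutive_failures_after": w.consecutive_failures_after,
                "phase": w.phase,
                "end_distance_A": w.end_distance,
                "engine_seed": w.engine_seed,
            }
            for w in self.windows
        ]
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def mass_weighted_centroid(coords: np.ndarray, selection: np.ndarray,
                           masses: np.ndarray) -> np.ndarray:
    """Centre of mass of the selected beads: sum(m_i x_i) / sum(m_i)."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    m = np.asarray(masses, dtype=float)[selection]
    return (m[:, None] * np.asarray(coords)[selection]).sum(axis=0) / m.sum()


def centroid_distance(system: System, coords: np.ndarray,
                      geometric: bool = False) -> float:
    """Distance between the ligand and binding-site centroids
    (minimum-image when the system has a box)."""
    masses = np.ones(system.n_beads) if geometric else system.masses
    c_lig = mass_weighted_centroid(coords, system.ligand_bead_indices, masses)
    c_site = mass_weighted_centroid(coords, system.site_bead_indices, masses)
    d = c_lig - c_site
    if system.box is not None:
        d -= system.box * np.round(d / system.box)
    return float(np.linalg.norm(d))


def ols_slope(times, distances) -> float:
    """Ordinary-least-squares slope cov(t, d) / var(t)."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(distances, dtype=float)
    if t.size < 2 or d.size != t.size:
        raise ValueError("need >= 2 (time, distance) pairs of equal length")
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        raise ValueError("times have zero variance")
    return float(tc @ (d - d.mean())) / denom


def _window_engine_config(engine_config: EngineConfig, window_length: float,
                          n_samples: int) -> EngineConfig:
    """Engine config whose save interval yields n evenly spaced distance
    samples per window."""
    interval = window_length / n_samples
    steps = interval / engine_config.dt
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError(
            f"window_length/n_samples = {interval} ps is not a multiple of dt={engine_config.dt}"
        )
    return dataclasses.replace(engine_config, save_interval=interval)


def _segment_distances(system: System, seg: TrajectorySegment, geometric: bool) -> np.ndarray:
    return np.array([centroid_distance(system, f, geometric) for f in seg.frames])


def supervised_window(system: System, state: SimState, engine_config: EngineConfig,
                      sup_config: SupervisionConfig, rng: np.random.Generator,
                      engine=langevin_segment, index: int = 0,
                      failures_before: int = 0):
    """Run one supervised window and apply the slope criterion.

    Returns ``(record, state, segment)``.  On acceptance (slope < 0,
    strictly) the end-of-window state is returned; on rejection the
    window-start coordinates are returned with freshly drawn
    Maxwell-Boltzmann velocities so the window can be re-simulated.
    """
    engine_seed = int(rng.integers(2**31))
    cfg = _window_engine_config(engine_config, sup_config.window_length,
                                sup_config.n_distance_samples_per_window)
    run_state = SimState(state.coords.copy(), state.velocities.copy(), state.time,
                         np.random.default_rng(engine_seed))
    seg, end_state = engine(system, run_state, sup_config.window_length, cfg)
    distances = _segment_distances(system, seg, sup_config.geometric_centroids)
    slope = ols_slope(seg.frame_times, distances)
    accepted = slope < 0.0
    if accepted:
        out_state = end_state
        failures_after = 0
    else:
        vel = maxwell_boltzmann_velocities(system.masses, engine_config.temperature,
                                           np.random.default_rng(int(rng.integers(2**31))))
        out_state = SimState(state.coords.copy(), vel, state.time,
                             np.random.default_rng(int(rng.integers(2**31))))
        failures_after = failures_before + 1
    record = WindowRecord(
        index=index,
        start_time=state.time,
        duration=sup_config.window_length,
        distance_series=distances,
        slope=slope,
        decision="accepted" if accepted else "retried",
        consecutive_failures_after=failures_after,
        phase="supervised",
        end_distance=float(distances[-1]),
        engine_seed=engine_seed,
    )
    return record, out_state, seg


def _unsupervised_window(system, state, engine_config, sup_config, rng, engine,
                         index, duration, phase):
    engine_seed = int(rng.integers(2**31))
    cfg = _window_engine_config(engine_config, duration,
                                max(1, int(round(duration / sup_config.window_length
                                                 * sup_config.n_distance_samples_per_window))))
    run_state = SimState(state.coords.copy(), state.velocities.copy(), state.time,
                         np.random.default_rng(engine_seed))
    seg, end_state = engine(system, run_state, duration, cfg)
    distances = _segment_distances(system, seg, sup_config.geometric_centroids)
    record = WindowRecord(
        index=index,
        start_time=state.time,
        duration=duration,
        distance_series=distances,
        slope=float("nan"),
        decision="accepted",
        consecutive_failures_after=0,
        phase=phase,
        end_distance=float(distances[-1]),
        engine_seed=engine_seed,
    )
    return record, end_state, seg


def run_sumd(system: System, initial_state: SimState, engine_config: EngineConfig,
             sup_config: SupervisionConfig, engine=langevin_segment,
             time_budget: float | None = None,
             collect_frames: bool = True) -> SuMDResult:
    """Execute the full three-phase SuMD protocol.

    Phase 1 keeps windows with a negative distance slope and abandons
    the run after ``max_consecutive_failures`` consecutive rejections.
    Phase 2 (entered when the centroid distance drops below
    ``bind_threshold``) runs ``n_unsupervised_checks`` unsupervised
    windows, returning to Phase 1 whenever a check window ends above the
    threshold.  Phase 3 appends one unsupervised production run.  An
    optional ``time_budget`` (ps of total simulated time, retries
    included) censors the run for experiment use.
    """
    rng = np.random.default_rng(sup_config.seed)
    d0 = centroid_distance(system, initial_state.coords, sup_config.geometric_centroids)
    if d0 < sup_config.bind_threshold:
        raise ValueError(
            f"ligand already within bind_threshold ({d0:.2f} < {sup_config.bind_threshold} A)"
        )

    windows: list[WindowRecord] = []
    segments: list[TrajectorySegment] = []
    state = initial_state
    total_time = 0.0
    failures = 0
    index = 0
    first_binding: float | None = None
    total_at_binding: float | None = None
    status = "unbound_terminated"

    def bound_in(record: WindowRecord) -> bool:
        if sup_config.bind_check == "any_frame":
            return bool((record.distance_series < sup_config.bind_threshold).any())
        return record.end_distance < sup_config.bind_threshold

    def note_binding(record: WindowRecord):
        nonlocal first_binding, total_at_binding
        if first_binding is None:
            first_binding = record.start_time + record.duration
            total_at_binding = total_time

    try:
        phase = 1
        while True:
            if phase == 1:
                if time_budget is not None and total_time >= time_budget:
                    status = "unbound_terminated"
                    break
                record, state, seg = supervised_window(
                    system, state, engine_config, sup_config, rng, engine, index, failures)
                windows.append(record)
                total_time += record.duration
                index += 1
                if record.decision == "accepted":
                    failures = 0
                    if collect_frames:
                        segments.append(seg)
                    if bound_in(record):
                        note_binding(record)
                        status = "bound"
                        phase = 2
                else:
                    failures = record.consecutive_failures_after
                    if failures >= sup_config.max_consecutive_failures:
                        status = "unbound_terminated" if first_binding is None else "bound"
                        break
            elif phase == 2:
                ok = True
                for _ in range(sup_config.n_unsupervised_checks):
                    if time_budget is not None and total_time >= time_budget:
                        break
                    record, state, seg = _unsupervised_window(
                        system, state, engine_config, sup_config, rng, engine,
                        index, sup_config.check_length, "unsupervised_check")
                    windows.append(record)
                    total_time += record.duration
                    index += 1
                    if collect_frames:
                        segments.append(seg)
                    if bound_in(record):
                        note_binding(record)
                    if record.end_distance > sup_config.bind_threshold:
                        ok = False
                        break
                if time_budget is not None and total_time >= time_budget:
                    break
                if ok:
                    phase = 3
                else:
                    failures = 0  # supervision re-engaged with a fresh counter
                    phase = 1
            else:  # phase 3: production
                if sup_config.production > 0:
                    record, state, seg = _unsupervised_window(
                        system, state, engine_config, sup_config, rng, engine,
                        index, sup_config.production, "production")
                    windows.append(record)
                    total_time += record.duration
                    index += 1
                    if collect_frames:
                        segments.append(seg)
                break
    except Exception as exc:  # engine failure mid-protocol: partial result
        return SuMDResult(
            status="error", windows=windows, total_simulated_time=total_time,
            first_binding_time=first_binding, total_time_at_first_binding=total_at_binding,
            final_state=state, trajectory=TrajectorySegment.concatenate(segments) if segments else None,
            error=f"window {index}: {exc}")

    trajectory = TrajectorySegment.concatenate(segments) if segments else None
    return SuMDResult(
        status=status, windows=windows, total_simulated_time=total_time,
        first_binding_time=first_binding, total_time_at_first_binding=total_at_binding,
        final_state=state, trajectory=trajectory)


# ----------------------------------------------------------------------
# binding-time experiments
# ----------------------------------------------------------------------

def _unsupervised_binding_run(system, state, engine_config, sup_config, rng, engine,
                              time_budget):
    """Plain (unsupervised) Langevin run, window-by-window, stopping at
    first binding or at the budget.  Matches the supervised runs'
    end-of-window binding criterion."""
    total = 0.0
    windows = 0
    while total < time_budget:
        record, state, _ = _unsupervised_window(
            system, state, engine_config, sup_config, rng, engine, windows,
            sup_config.window_length, "unsupervised_check")
        total += record.duration
        windows += 1
        if record.end_distance < sup_config.bind_threshold:
            return total, windows, True
    return total, windows, False


def binding_time_experiment(system: System, n_replicas: int, supervised: bool,
                            engine_config: EngineConfig, sup_config: SupervisionConfig,
                            time_budget: float, seeds=None,
                            engine=langevin_segment) -> pd.DataFrame:
    """Run independent binding replicas and tabulate time to first binding.

    Each replica gets seed ``sup_config.seed + replica_index`` (unless
    explicit seeds are given) for both its initial velocities and its
    supervisor stream.  Replicas that do not bind within ``time_budget``
    ps of total simulated time are censored at the budget.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if seeds is None:
        seeds = [sup_config.seed + i for i in range(n_replicas)]
    if len(seeds) != n_replicas:
        raise ValueError("seeds length must equal n_replicas")
    rows = []
    for rep, seed in enumerate(seeds):
        state = initial_state(system, engine_config.temperature, seed=seed)
        if supervised:
            cfg = replace(sup_config, seed=seed, production_length=0.0,
                          n_unsupervised_checks=1)
            res = run_sumd(system, state, engine_config, cfg, engine=engine,
                           time_budget=time_budget, collect_frames=False)
            bound = res.total_time_at_first_binding is not None
            t_bind = res.total_time_at_first_binding
            n_windows = len(res.windows)
            wins_to_bind = None
            if bound:
                wins_to_bind = next(
                    i + 1 for i, w in enumerate(res.windows)
                    if w.decision == "accepted"
                    and w.end_distance < cfg.bind_threshold)
        else:
            rng = np.random.default_rng(seed)
            total, n_windows, bound = _unsupervised_binding_run(
                system, state, engine_config, sup_config, rng, engine, time_budget)
            t_bind = total if bound else None
            wins_to_bind = n_windows if bound else None
        rows.append({
            "replica": rep,
            "seed": seed,
            "supervised": supervised,
            "bound": bound,
            "time_to_binding_ps": t_bind if bound else np.nan,
            "windows_to_binding": wins_to_bind if bound else np.nan,
            "total_windows": n_windows,
            "censored_time_ps": t_bind if bound else time_budget,
            "budget_ps": time_budget,
        })
    return pd.DataFrame(rows)


def compare_binding_times(df_supervised: pd.DataFrame,
                          df_unsupervised: pd.DataFrame) -> dict:
    """Medians of (censored) time to first binding and a one-sided
    Mann-Whitney U test that supervised times are smaller."""
    a = df_supervised["censored_time_ps"].to_numpy()
    b = df_unsupervised["censored_time_ps"].to_numpy()
    stat, p = mannwhitneyu(a, b, alternative="less")
    return {
        "median_supervised_ps": float(np.median(a)),
        "median_unsupervised_ps": float(np.median(b)),
        "n_bound_supervised": int(df_supervised["bound"].sum()),
        "n_bound_unsupervised": int(df_unsupervised["bound"].sum()),
        "mannwhitney_u": float(stat),
        "p_value": float(p),
    }
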