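"""Coarse-grained NVT Langevin dynamics engine.

Force field: harmonic bonds, 12-6 Lennard-Jones and Coulomb
electrostatics, both plainly truncated at a cutoff (default 9 A), plus
harmonic positional restraints.  Integration uses the BAOAB splitting
of Langevin dynamics at a target temperature (default 310 K, friction
1 ps^-1), with velocities initialised from Maxwell-Boltzmann.  When the
system has a cubic box the minimum-image convention applies to all
nonbonded pairs; coordinates are kept unwrapped.

Harmonic terms use the 1/2 k x^2 convention, so a restrained bead
equilibrates to per-axis positional variance k_B T / k.

The integrator runs inside numba-compiled kernels; Gaussian noise is
drawn in NumPy per saved-frame chunk from the seedable generator
carried in :class:`SimState`, which makes trajectories bit-for-bit
reproducible for a given state on one platform.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .toy_systems import System
from .units import KB, COULOMB, KCAL_TO_AMU_A2_PS2

__all__ = [
    "EngineConfig",
    "Restraint",
    "SimState",
    "TrajectorySegment",
    "Stage",
    "StageRecord",
    "OverlapError",
    "lj_energy",
    "coulomb_energy",
    "compute_forces",
    "maxwell_boltzmann_velocities",
    "initial_state",
    "instantaneous_temperature",
    "langevin_segment",
    "run_staged_equilibration",
    "minimize_steepest_descent",
    "restrain_all",
    "default_equilibration_schedule",
]

_HARD_FLOOR = 0.1  # A; nonbonded pairs closer than this abort the run


class OverlapError(RuntimeError):
    """Raised when two nonbonded beads come closer than the hard floor."""

    def __init__(self, i: int, j: int, time: float | None = None):
        self.pair = (i, j)
        at = f" at t={time:g} ps" if time is not None else ""
        super().__init__(f"beads {i} and {j} overlap (r < {_HARD_FLOOR} A){at}")


@dataclass(frozen=True)
class Restraint:
    """Harmonic positional restraint 1/2 k |x - ref|^2 on selected beads."""

    indices: np.ndarray
    k: float  # kcal/mol/A^2
    ref: np.ndarray  # (n, 3) A

    def __post_init__(self):
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "ref", np.asarray(self.ref, dtype=float))
        if self.ref.shape != (len(self.indices), 3):
            raise ValueError("restraint reference shape mismatch")


def restrain_all(system: System, k: float, indices=None) -> Restraint:
    """Restraint of the given beads (default: all) to the system's
    reference coordinates."""
    idx = np.arange(system.n_beads) if indices is None else np.asarray(indices, dtype=np.int64)
    return Restraint(idx, k, system.coords[idx])


@dataclass
class EngineConfig:
    """Integration and force-field evaluation parameters.

    dt (ps), temperature (K), friction (ps^-1) and cutoff (A) default to
    0.002 / 310 / 1.0 / 9.0; ``save_interval`` must be a multiple of dt.
    """

    dt: float = 0.002
    temperature: float = 310.0
    friction: float = 1.0
    cutoff: float = 9.0
    save_interval: float = 0.1
    restraints: list[Restraint] = field(default_factory=list)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        steps = self.save_interval / self.dt
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError("save_interval must be a positive multiple of dt")

    @property
    def steps_per_save(self) -> int:
        return int(round(self.save_interval / self.dt))


@dataclass
class SimState:
    """Instantaneous simulation state (coordinates, velocities, clock)
    plus the seedable RNG token driving the thermostat noise."""

    coords: np.ndarray  # (N, 3) A
    velocities: np.ndarray  # (N, 3) A/ps
    time: float = 0.0  # ps
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def copy(self) -> "SimState":
        return SimState(self.coords.copy(), self.velocities.copy(), self.time, copy.deepcopy(self.rng))


@dataclass
class TrajectorySegment:
    """Frames saved every ``save_interval`` with per-frame energy terms."""

    frames: np.ndarray  # (F, N, 3) A
    frame_times: np.ndarray  # (F,) ps
    e_bond: np.ndarray
    e_lj: np.ndarray
    e_coul: np.ndarray
    e_restraint: np.ndarray
    t_inst: np.ndarray  # K

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def e_total(self) -> np.ndarray:
        return self.e_bond + self.e_lj + self.e_coul + self.e_restraint

    @staticmethod
    def concatenate(segments: list["TrajectorySegment"]) -> "TrajectorySegment":
        return TrajectorySegment(
            np.concatenate([s.frames for s in segments]),
            np.concatenate([s.frame_times for s in segments]),
            np.concatenate([s.e_bond for s in segments]),
            np.concatenate([s.e_lj for s in segments]),
            np.concatenate([s.e_coul for s in segments]),
            np.concatenate([s.e_restraint for s in segments]),
            np.concatenate([s.t_inst for s in segments]),
        )


# ----------------------------------------------------------------------
# closed-form pair potentials
# ----------------------------------------------------------------------

def lj_energy(r: float, sigma: float, epsilon: float, cutoff: float) -> float:
    """12-6 Lennard-Jones energy 4 eps [(sigma/r)^12 - (sigma/r)^6],
    plainly truncated to zero at the cutoff."""
    if r <= 0:
        raise ValueError("r must be > 0")
    if r >= cutoff:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def coulomb_energy(r: float, q1: float, q2: float, cutoff: float) -> float:
    """Coulomb energy 332.0637 q1 q2 / r (kcal/mol), truncated at the cutoff."""
    if r <= 0:
        raise ValueError("r must be > 0")
    if r >= cutoff:
        return 0.0
    return COULOMB * q1 * q2 / r


# ----------------------------------------------------------------------
# packed parameter arrays + numba kernels
# ----------------------------------------------------------------------

class _Packed:
    """Flat pair/bond parameter arrays for the kernels, cached per System."""

    def __init__(self, system: System, cutoff: float):
        n = system.n_beads
        sig = system.sigmas
        if cutoff <= sig.max():
            raise ValueError(f"cutoff {cutoff} A must exceed the largest LJ sigma {sig.max()} A")
        eps = system.epsilons
        q = system.charges
        ii, jj = np.triu_indices(n, k=1)
        skip = {(b.i, b.j) if b.i < b.j else (b.j, b.i) for b in system.bonds}
        skip |= set(system.exclusions)
        if skip:
            mask = np.array([(a, b) not in skip for a, b in zip(ii, jj)])
            ii, jj = ii[mask], jj[mask]
        self.pi = ii.astype(np.int64)
        self.pj = jj.astype(np.int64)
        self.sig = 0.5 * (sig[ii] + sig[jj])
        self.eps = np.sqrt(eps[ii] * eps[jj])
        self.qq = COULOMB * q[ii] * q[jj]
        self.bi = np.array([b.i for b in system.bonds], dtype=np.int64)
        self.bj = np.array([b.j for b in system.bonds], dtype=np.int64)
        self.bk = np.array([b.k for b in system.bonds], dtype=float)
        self.br0 = np.array([b.r0 for b in system.bonds], dtype=float)
        self.masses = system.masses
        self.cutoff = float(cutoff)
        self.box = float(system.box) if system.box is not None else 0.0
        self.use_box = system.box is not None


def _packed(system: System, cutoff: float) -> _Packed:
    cache = getattr(system, "_packed_cache", None)
    if cache is None or cache.cutoff != cutoff or len(cache.masses) != system.n_beads:
        cache = _Packed(system, cutoff)
        system._packed_cache = cache
    return cache


def _restraint_arrays(n: int, restraints: list[Restraint]):
    rk = np.zeros(n)
    rref = np.zeros((n, 3))
    for r in restraints:
        rk[r.indices] = r.k
        rref[r.indices] = r.ref
    return rk, rref


@njit(cache=True)
def _forces_kernel(coords, pi, pj, sig, eps, qq, cutoff, box, use_box,
                   bi, bj, bk, br0, rk, rref, forces):
    n = coords.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    e_lj = 0.0
    e_coul = 0.0
    cutoff2 = cutoff * cutoff
    bad_i = -1
    bad_j = -1
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        if use_box:
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < _HARD_FLOOR * _HARD_FLOOR:
            bad_i = i
            bad_j = j
            return e_lj, e_coul, 0.0, 0.0, bad_i, bad_j
        if r2 < cutoff2:
            coef = 0.0
            if eps[p] > 0.0:
                sr2 = sig[p] * sig[p] / r2
                sr6 = sr2 * sr2 * sr2
                e_lj += 4.0 * eps[p] * (sr6 * sr6 - sr6)
                coef += 24.0 * eps[p] * (2.0 * sr6 * sr6 - sr6) / r2
            if qq[p] != 0.0:
                r = math.sqrt(r2)
                e_coul += qq[p] / r
                coef += qq[p] / (r2 * r)
            if coef != 0.0:
                fx = coef * dx
                fy = coef * dy
                fz = coef * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
    e_bond = 0.0
    for b in range(bi.shape[0]):
        i = bi[b]
        j = bj[b]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        if use_box:
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[b]
        e_bond += 0.5 * bk[b] * dr * dr
        coef = -bk[b] * dr / r
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    e_res = 0.0
    for i in range(n):
        if rk[i] > 0.0:
            dx = coords[i, 0] - rref[i, 0]
            dy = coords[i, 1] - rref[i, 1]
            dz = coords[i, 2] - rref[i, 2]
            e_res += 0.5 * rk[i] * (dx * dx + dy * dy + dz * dz)
            forces[i, 0] -= rk[i] * dx
            forces[i, 1] -= rk[i] * dy
            forces[i, 2] -= rk[i] * dz
    return e_lj, e_coul, e_bond, e_res, bad_i, bad_j


@njit(cache=True)
def _baoab_chunk(coords, vels, forces, nsteps, dt, c1, c2, sigv, acc_scale, noise,
                 pi, pj, sig, eps, qq, cutoff, box, use_box,
                 bi, bj, bk, br0, rk, rref):
    """nsteps of BAOAB; coords/vels/forces updated in place.  Returns the
    energy terms of the final force evaluation and the overlap flag."""
    n = coords.shape[0]
    e_lj = 0.0
    e_coul = 0.0
    e_bond = 0.0
    e_res = 0.0
    bad_i = -1
    bad_j = -1
    half = 0.5 * dt
    for s in range(nsteps):
        for i in range(n):
            for d in range(3):
                vels[i, d] += half * forces[i, d] * acc_scale[i]
                coords[i, d] += half * vels[i, d]
                vels[i, d] = c1 * vels[i, d] + c2 * sigv[i] * noise[s, i, d]
                coords[i, d] += half * vels[i, d]
        e_lj, e_coul, e_bond, e_res, bad_i, bad_j = _forces_kernel(
            coords, pi, pj, sig, eps, qq, cutoff, box, use_box,
            bi, bj, bk, br0, rk, rref, forces)
        if bad_i >= 0:
            return e_lj, e_coul, e_bond, e_res, bad_i, bad_j, s
        for i in range(n):
            for d in range(3):
                vels[i, d] += half * forces[i, d] * acc_scale[i]
    return e_lj, e_coul, e_bond, e_res, bad_i, bad_j, nsteps


def compute_forces(system: System, coords: np.ndarray,
                   restraints: list[Restraint] | None = None,
                   cutoff: float = 9.0):
    """Forces (kcal/mol/A) and energy terms for one configuration.

    Forces are the exact negative analytic gradient of the total
    potential (bonds + truncated LJ + truncated Coulomb + restraints),
    with minimum-image displacements when the system has a box.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_beads, 3):
        raise ValueError("coords shape does not match system")
    p = _packed(system, cutoff)
    rk, rref = _restraint_arrays(system.n_beads, restraints or [])
    forces = np.empty_like(coords)
    e_lj, e_coul, e_bond, e_res, bad_i, bad_j = _forces_kernel(
        coords, p.pi, p.pj, p.sig, p.eps, p.qq, p.cutoff, p.box, p.use_box,
        p.bi, p.bj, p.bk, p.br0, rk, rref, forces)
    if bad_i >= 0:
        raise OverlapError(int(bad_i), int(bad_j))
    terms = {"bond": e_bond, "lj": e_lj, "coulomb": e_coul, "restraint": e_res}
    terms["total"] = e_bond + e_lj + e_coul + e_res
    return forces, terms


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Velocities (A/ps) drawn from Maxwell-Boltzmann at ``temperature``."""
    masses = np.asarray(masses, dtype=float)
    sd = np.sqrt(KB * temperature * KCAL_TO_AMU_A2_PS2 / masses)
    return rng.standard_normal((len(masses), 3)) * sd[:, None]


def initial_state(system: System, temperature: float = 310.0, seed: int = 0) -> SimState:
    """Fresh state at the system's reference coordinates with
    Maxwell-Boltzmann velocities."""
    rng = np.random.default_rng(seed)
    v = maxwell_boltzmann_velocities(system.masses, temperature, rng)
    return SimState(system.coords.copy(), v, 0.0, rng)


def instantaneous_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """T = 2 KE / (3 N k_B) with KE = 1/2 sum m v^2 (unit-converted)."""
    velocities = np.asarray(velocities, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = len(masses)
    if n == 0:
        raise ValueError("no beads")
    if velocities.shape != (n, 3):
        raise ValueError("velocity/mass shape mismatch")
    ke = 0.5 * float((masses[:, None] * velocities**2).sum()) / KCAL_TO_AMU_A2_PS2
    return 2.0 * ke / (3.0 * n * KB)


def langevin_segment(system: System, state: SimState, duration: float,
                     config: EngineConfig) -> tuple[TrajectorySegment, SimState]:
    """Propagate ``duration`` ps of BAOAB Langevin dynamics, saving a
    frame (with energy terms) every ``config.save_interval``.

    The input state is not mutated; rerunning with an identical state
    reproduces the segment bit for bit.
    """
    n_frames_f = duration / config.save_interval
    n_frames = int(round(n_frames_f))
    if abs(n_frames_f - n_frames) > 1e-9 or n_frames < 1:
        raise ValueError("duration must be a positive multiple of save_interval")
    p = _packed(system, config.cutoff)
    rk, rref = _restraint_arrays(system.n_beads, config.restraints)

    st = state.copy()
    coords, vels, rng = st.coords, st.velocities, st.rng
    masses = p.masses
    acc_scale = KCAL_TO_AMU_A2_PS2 / masses
    c1 = math.exp(-config.friction * config.dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigv = np.sqrt(KB * config.temperature * KCAL_TO_AMU_A2_PS2 / masses)

    forces = np.empty_like(coords)
    out = _forces_kernel(coords, p.pi, p.pj, p.sig, p.eps, p.qq, p.cutoff, p.box,
                         p.use_box, p.bi, p.bj, p.bk, p.br0, rk, rref, forces)
    if out[4] >= 0:
        raise OverlapError(int(out[4]), int(out[5]), state.time)

    spf = config.steps_per_save
    frames = np.empty((n_frames, system.n_beads, 3))
    times = state.time + config.save_interval * np.arange(1, n_frames + 1)
    e_bond = np.empty(n_frames)
    e_lj = np.empty(n_frames)
    e_coul = np.empty(n_frames)
    e_res = np.empty(n_frames)
    t_inst = np.empty(n_frames)
    for f in range(n_frames):
        noise = rng.standard_normal((spf, system.n_beads, 3))
        elj, ecoul, ebond, eres, bad_i, bad_j, s_done = _baoab_chunk(
            coords, vels, forces, spf, config.dt, c1, c2, sigv, acc_scale, noise,
            p.pi, p.pj, p.sig, p.eps, p.qq, p.cutoff, p.box, p.use_box,
            p.bi, p.bj, p.bk, p.br0, rk, rref)
        t_now = state.time + (f * spf + s_done) * config.dt
        if bad_i >= 0:
            raise OverlapError(int(bad_i), int(bad_j), t_now)
        if not (np.isfinite(coords).all() and math.isfinite(elj + ecoul + ebond + eres)):
            raise RuntimeError(f"non-finite coordinates or energy at t={t_now:g} ps")
        frames[f] = coords
        e_bond[f] = ebond
        e_lj[f] = elj
        e_coul[f] = ecoul
        e_res[f] = eres
        t_inst[f] = instantaneous_temperature(vels, masses)

    seg = TrajectorySegment(frames, times, e_bond, e_lj, e_coul, e_res, t_inst)
    return seg, SimState(coords, vels, float(times[-1]), rng)


# ----------------------------------------------------------------------
# staged equilibration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Stage:
    duration: float  # ps
    restraints: list[Restraint]
    label: str = ""


@dataclass
class StageRecord:
    index: int
    label: str
    duration: float
    n_restrained: int
    mean_temperature: float  # K, nan for zero-duration stages
    rmsd_to_reference: float  # A, unfitted, vs stage-entry coordinates


def run_staged_equilibration(system: System, state: SimState, schedule: list[Stage],
                             config: EngineConfig) -> tuple[SimState, list[StageRecord]]:
    """Execute restraint-release stages in order, logging per-stage mean
    temperature and final RMSD to the pre-equilibration coordinates."""
    if not schedule:
        raise ValueError("schedule must be non-empty")
    for s in schedule:
        if s.duration < 0:
            raise ValueError("stage duration must be >= 0")
    ref = state.coords.copy()
    records: list[StageRecord] = []
    st = state
    for i, stage in enumerate(schedule):
        if stage.duration > 0:
            cfg = copy.copy(config)
            cfg.restraints = stage.restraints
            seg, st = langevin_segment(system, st, stage.duration, cfg)
            mean_t = float(seg.t_inst.mean())
        else:
            mean_t = float("nan")
        rmsd = float(np.sqrt(((st.coords - ref) ** 2).sum(axis=1).mean()))
        n_res = int(sum(len(r.indices) for r in stage.restraints))
        records.append(StageRecord(i, stage.label, stage.duration, n_res, mean_t, rmsd))
    return st, records


def default_equilibration_schedule(system: System, k: float = 1.0,
                                   durations=(5.0, 10.0, 5.0, 10.0)) -> list[Stage]:
    """Four-stage restraint release: everything -> receptor -> binding
    site -> free, with harmonic restraints of ``k`` kcal/mol/A^2."""
    rec = system.receptor_bead_indices
    site = system.site_bead_indices
    return [
        Stage(durations[0], [restrain_all(system, k)], "restrain-all"),
        Stage(durations[1], [restrain_all(system, k, rec)], "restrain-receptor"),
        Stage(durations[2], [restrain_all(system, k, site)], "restrain-site"),
        Stage(durations[3], [], "free"),
    ]


def toy_engine_config(system: System, dt: float = 0.004,
                      restraint_k: float = 10.0) -> EngineConfig:
    """Standard desk-scale engine settings for the synthetic scenarios:
    a slightly larger step than the atomistic default (safe for the soft
    coarse-grained potentials) and a stiff positional restraint on every
    receptor bead, making the scaffold effectively rigid so binding
    kinetics are ligand-dominated."""
    return EngineConfig(
        dt=dt,
        restraints=[restrain_all(system, restraint_k, system.receptor_bead_indices)])


def minimize_steepest_descent(system: System, coords: np.ndarray, n_steps: int = 200,
                              max_step: float = 0.1,
                              restraints: list[Restraint] | None = None,
                              cutoff: float = 9.0) -> np.ndarray:
    """Simple steepest-descent pre-relaxation with a capped step length."""
    x = np.asarray(coords, dtype=float).copy()
    step = max_step
    _, terms = compute_forces(system, x, restraints, cutoff)
    e_prev = terms["total"]
    for _ in range(n_steps):
        f, _ = compute_forces(system, x, restraints, cutoff)
        fmax = np.abs(f).max()
        if fmax < 1e-8:
            break
        trial = x + f * min(step / fmax, step / max(fmax, 1e-12))
        _, terms = compute_forces(system, trial, restraints, cutoff)
        if terms["total"] < e_prev:
            x = trial
            e_prev = terms["total"]
            step = min(step * 1.2, max_step)
        else:
            step *= 0.5
            if step < 1e-6:
                break
    return x
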