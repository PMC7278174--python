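"""Trajectory analytics for receptor--ligand binding simulations.

Covers the standard post-processing of an adaptive-sampling binding
run: the ligand-to-site centroid distance profile, a per-residue
decomposition of the ligand-receptor electrostatic and van der Waals
interaction energies, the interaction-energy-versus-distance landscape,
RMSD/RMSF stability metrics, grid-based pocket volumetry (grid points
inside an inclusion sphere not occluded by receptor beads) and
water-occupancy hotspot maps (fraction of frames in which each voxel
contains at least one solvent bead, with hotspots reported above a 10%
occupancy threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .engine import TrajectorySegment
from .supervision import centroid_distance
from .toy_systems import System
from .units import COULOMB

__all__ = [
    "EnergyTable",
    "LandscapeBin",
    "OccupancyGrid",
    "distance_profile",
    "per_residue_interaction_energy",
    "interaction_energy_landscape",
    "rmsd_series",
    "rmsf",
    "pocket_volume",
    "water_occupancy_map",
    "hotspots",
]


def _frames_times(trajectory):
    """Accept a TrajectorySegment or a bare (F, N, 3) array."""
    if isinstance(trajectory, TrajectorySegment):
        return trajectory.frames, trajectory.frame_times
    frames = np.asarray(trajectory, dtype=float)
    if frames.ndim != 3:
        raise ValueError("trajectory must be a TrajectorySegment or (F, N, 3) array")
    return frames, np.arange(frames.shape[0], dtype=float)


def distance_profile(trajectory, system: System) -> pd.DataFrame:
    """Ligand-to-binding-site mass-weighted centroid distance per frame."""
    frames, times = _frames_times(trajectory)
    if frames.shape[0] == 0:
        raise ValueError("empty trajectory")
    d = np.array([centroid_distance(system, f) for f in frames])
    return pd.DataFrame({"time_ps": times, "distance_A": d})


@dataclass
class EnergyTable:
    """Per-frame, per-receptor-residue ligand interaction energies.

    ``e_elec`` and ``e_vdw`` are (n_frames, n_residues) arrays in
    kcal/mol; summing both over residues reproduces the total
    ligand-receptor nonbonded energy of each frame.
    """

    frame_times: np.ndarray
    residue_ids: np.ndarray
    e_elec: np.ndarray
    e_vdw: np.ndarray

    def total_per_frame(self) -> np.ndarray:
        return self.e_elec.sum(axis=1) + self.e_vdw.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        f, r = np.meshgrid(np.arange(len(self.frame_times)), np.arange(len(self.residue_ids)),
                           indexing="ij")
        return pd.DataFrame({
            "time_ps": self.frame_times[f.ravel()],
            "residue_id": self.residue_ids[r.ravel()],
            "E_elec_kcal_mol": self.e_elec.ravel(),
            "E_vdw_kcal_mol": self.e_vdw.ravel(),
        })


def per_residue_interaction_energy(trajectory, system: System,
                                   cutoff: float = 9.0) -> EnergyTable:
    """Decompose the ligand-receptor nonbonded energy per receptor residue.

    For every frame and every receptor residue, sums the truncated
    Coulomb and 12-6 LJ pair energies over all (residue bead, ligand
    bead) pairs, with minimum-image distances when the system has a box.
    """
    frames, times = _frames_times(trajectory)
    lig = system.ligand_bead_indices
    rec = system.receptor_bead_indices
    if lig.size == 0 or rec.size == 0:
        raise ValueError("system must define ligand and receptor beads")
    for i in np.concatenate([lig, rec]):
        b = system.beads[i]
        if not (np.isfinite(b.lj_sigma) and np.isfinite(b.lj_epsilon) and np.isfinite(b.charge)):
            raise ValueError(f"bead {b.id} has missing nonbonded parameters")

    sig = system.sigmas
    eps = system.epsilons
    q = system.charges
    sig_p = 0.5 * (sig[lig][:, None] + sig[rec][None, :])
    eps_p = np.sqrt(eps[lig][:, None] * eps[rec][None, :])
    qq_p = COULOMB * q[lig][:, None] * q[rec][None, :]

    res_of_rec = np.array([system.beads[i].residue_id for i in rec])
    residue_ids = np.unique(res_of_rec)
    col = np.searchsorted(residue_ids, res_of_rec)

    nF = frames.shape[0]
    e_el = np.zeros((nF, len(residue_ids)))
    e_vdw = np.zeros((nF, len(residue_ids)))
    for f in range(nF):
        d = frames[f][lig][:, None, :] - frames[f][rec][None, :, :]
        if system.box is not None:
            d -= system.box * np.round(d / system.box)
        r = np.sqrt((d * d).sum(-1))
        inside = r < cutoff
        sr6 = np.where(inside, (sig_p / r) ** 6, 0.0)
        lj = 4.0 * eps_p * (sr6 * sr6 - sr6)
        el = np.where(inside, qq_p / r, 0.0)
        for a in range(lig.size):
            np.add.at(e_vdw[f], col, lj[a])
            np.add.at(e_el[f], col, el[a])
    return EnergyTable(times, residue_ids, e_el, e_vdw)


@dataclass(frozen=True)
class LandscapeBin:
    """One half-open distance bin [lo, hi) of the energy landscape."""

    distance_lo: float
    distance_hi: float
    mean_energy: float
    sd_energy: float
    n_frames: int


def interaction_energy_landscape(distances, energies, bin_width: float) -> list[LandscapeBin]:
    """Bin total interaction energy by centroid distance.

    Bins are the half-open intervals [k w, (k+1) w); empty bins are
    omitted; per-bin mean, population SD and frame count are reported.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = np.asarray(distances, dtype=float)
    e = np.asarray(energies, dtype=float)
    if d.shape != e.shape:
        raise ValueError("distance and energy series must have equal length")
    k = np.floor(d / bin_width).astype(int)
    out = []
    for kk in np.unique(k):
        sel = e[k == kk]
        out.append(LandscapeBin(kk * bin_width, (kk + 1) * bin_width,
                                float(sel.mean()), float(sel.std()), int(sel.size)))
    return out


def landscape_to_dataframe(bins: list[LandscapeBin]) -> pd.DataFrame:
    return pd.DataFrame([b.__dict__ for b in bins])


def _kabsch_rmsd(mov: np.ndarray, ref: np.ndarray) -> float:
    """RMSD after optimal rigid-body superposition (Kabsch).

    Computed from the fitted coordinates rather than scipy's reported
    residual, which loses precision near zero RMSD."""
    fitted = _kabsch_fit(mov, ref)
    return float(np.sqrt(((fitted - ref) ** 2).sum(1).mean()))


def _kabsch_fit(mov: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Superpose mov onto ref, returning the fitted coordinates."""
    mc = mov - mov.mean(0)
    rc = ref - ref.mean(0)
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + ref.mean(0)


def rmsd_series(trajectory, reference: np.ndarray, selection=None,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (A) to a reference structure, with optional Kabsch
    superposition of the selected beads."""
    frames, _ = _frames_times(trajectory)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(frames.shape[1]) if selection is None else np.asarray(selection, dtype=int)
    ref = reference[sel] if reference.shape[0] == frames.shape[1] else reference
    if ref.shape[0] != sel.size:
        raise ValueError("selection size does not match reference")
    out = np.empty(frames.shape[0])
    for f in range(frames.shape[0]):
        mov = frames[f][sel]
        if superpose:
            out[f] = _kabsch_rmsd(mov, ref)
        else:
            out[f] = np.sqrt(((mov - ref) ** 2).sum(1).mean())
    return out


def rmsf(trajectory, selection=None, superpose: bool = True) -> np.ndarray:
    """Per-bead root-mean-square fluctuation about the time-average
    position, after superposing every frame onto the mean structure.

    With ``superpose=False`` the frames are used as given, which is the
    right choice when the trajectory is already in a common receptor
    frame (e.g. a restrained scaffold) or when comparing against the
    closed-form fluctuation of individually moving beads (the fit
    itself redistributes motion among beads on small systems).
    """
    frames, _ = _frames_times(trajectory)
    if frames.shape[0] < 2:
        raise ValueError("rmsf requires >= 2 frames")
    sel = np.arange(frames.shape[1]) if selection is None else np.asarray(selection, dtype=int)
    sub = frames[:, sel]
    if superpose:
        sub = np.array([_kabsch_fit(fr, sub[0]) for fr in sub])
        mean = sub.mean(0)
        sub = np.array([_kabsch_fit(fr, mean) for fr in sub])
    mean = sub.mean(0)
    return np.sqrt(((sub - mean) ** 2).sum(-1).mean(0))


def pocket_volume(frame: np.ndarray, system: System, inclusion_center,
                  inclusion_radius: float, spacing: float = 0.5,
                  probe_radius: float = 1.4) -> float:
    """Grid-based pocket volume (A^3).

    Counts grid points inside the inclusion sphere that lie farther than
    ``probe_radius + sigma_i/2`` from every receptor bead centre; the
    volume is the count times spacing^3.  Receptor bead radii are taken
    as half their LJ sigma.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    center = np.asarray(inclusion_center, dtype=float)
    if system.box is not None:
        if np.any(center - inclusion_radius < 0) or np.any(center + inclusion_radius > system.box):
            raise ValueError("inclusion sphere extends outside the box")
    frame = np.asarray(frame, dtype=float)
    n = int(np.floor(inclusion_radius / spacing))
    ax = spacing * np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + center
    pts = pts[np.linalg.norm(pts - center, axis=1) <= inclusion_radius]
    rec = system.receptor_bead_indices
    if rec.size:
        radii = probe_radius + 0.5 * system.sigmas[rec]
        d = np.linalg.norm(pts[:, None, :] - frame[rec][None, :, :], axis=-1)
        free = (d > radii[None, :]).all(axis=1)
        pts = pts[free]
    return float(len(pts) * spacing**3)


@dataclass
class OccupancyGrid:
    """Voxelised fraction-of-frames solvent occupancy over a region."""

    origin: np.ndarray  # A
    spacing: float  # A
    dims: tuple[int, int, int]
    occupancy: np.ndarray  # dims-shaped, in [0, 1]
    n_frames: int

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + self.spacing * (np.asarray(idx, dtype=float) + 0.5)


def water_occupancy_map(trajectory, system: System, origin, dims,
                        spacing: float) -> OccupancyGrid:
    """Fraction of frames with >= 1 solvent-bead centre in each voxel.

    Voxel membership is half-open per axis: a point belongs to voxel i
    iff origin + i*spacing <= x < origin + (i+1)*spacing.  Frames are
    assumed already superposed onto a common receptor frame.
    """
    frames, _ = _frames_times(trajectory)
    sol = system.indices_by_role("solvent")
    if sol.size == 0:
        raise ValueError("system has no solvent beads")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    origin = np.asarray(origin, dtype=float)
    dims = tuple(int(d) for d in dims)
    counts = np.zeros(dims, dtype=np.int64)
    for f in range(frames.shape[0]):
        idx = np.floor((frames[f][sol] - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(dims)), axis=1)
        if ok.any():
            uniq = np.unique(idx[ok], axis=0)
            counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return OccupancyGrid(origin, float(spacing), dims, counts / frames.shape[0],
                         frames.shape[0])


def hotspots(grid: OccupancyGrid, threshold: float = 0.10) -> pd.DataFrame:
    """Voxels with occupancy strictly above ``threshold``, sorted by
    occupancy descending (ties broken by linear voxel index)."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    occ = grid.occupancy
    flat = occ.ravel()
    idx = np.nonzero(flat > threshold)[0]
    order = np.lexsort((idx, -flat[idx]))
    idx = idx[order]
    centers = np.array([grid.voxel_center(np.unravel_index(i, grid.dims)) for i in idx]) \
        if idx.size else np.empty((0, 3))
    return pd.DataFrame({
        "x": centers[:, 0] if idx.size else [],
        "y": centers[:, 1] if idx.size else [],
        "z": centers[:, 2] if idx.size else [],
        "occupancy": flat[idx],
        "voxel_index": idx,
    })
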