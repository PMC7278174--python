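"""Readers and writers for system topologies, trajectories and results.

A System is stored as a PDB file (beads as pseudo-atoms, one residue per
residue id, CRYST1 carrying the cubic box) plus a JSON parameter sidecar
for everything PDB cannot express (masses, charges, LJ parameters,
bonds, selections).  Trajectories are multi-frame XYZ (optionally DCD
when mdtraj is installed); tables are CSV; occupancy grids are OpenDX.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .analysis import OccupancyGrid
from .engine import EngineConfig, TrajectorySegment
from .supervision import SupervisionConfig, SuMDResult
from .toy_systems import BeadSpec, Bond, ScenarioConfig, System

__all__ = [
    "write_system",
    "read_system",
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "write_trajectory_dcd",
    "write_energies_csv",
    "write_occupancy_dx",
    "write_result_json",
    "RunConfig",
]

_ROLE_CHAIN = {"receptor": "A", "ligand": "B", "solvent": "C"}


def write_system(system: System, pdb_path, params_path) -> None:
    """Write topology as PDB + JSON parameter sidecar."""
    st = gemmi.Structure()
    st.name = "sumdcg system"
    if system.box is not None:
        st.cell = gemmi.UnitCell(system.box, system.box, system.box, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for bead, xyz in zip(system.beads, system.coords):
        cid = _ROLE_CHAIN[bead.role]
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        res = None
        chain = chains[cid]
        if len(chain) and chain[-1].seqid.num == bead.residue_id % 10000 \
                and chain[-1].name == bead.residue_name:
            res = chain[-1]
        if res is None:
            res = gemmi.Residue()
            res.name = bead.residue_name
            res.seqid = gemmi.SeqId(bead.residue_id % 10000, " ")
            res.het_flag = "H"
            chain.add_residue(res)
            res = chain[-1]
        atom = gemmi.Atom()
        atom.name = "C"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.serial = bead.id + 1
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(pdb_path))

    params = {
        "beads": [dataclasses.asdict(b) for b in system.beads],
        "bonds": [dataclasses.asdict(b) for b in system.bonds],
        "box": system.box,
        "site_selection": sorted(system.site_selection),
        "ligand_selection": sorted(system.ligand_selection),
        "exclusions": sorted(map(list, system.exclusions)),
        "meta": system.meta,
    }
    Path(params_path).write_text(json.dumps(params, indent=1))


def _validate_pdb_records(pdb_path) -> int:
    """Light syntactic check of coordinate records; returns atom count.
    Raises with the 1-based line number of the first malformed record."""
    n = 0
    with open(pdb_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise ValueError(f"{pdb_path}: malformed coordinate record at line {ln}")
                n += 1
    return n


def read_system(pdb_path, params_path) -> System:
    """Read a System back from PDB + JSON sidecar (round-trips
    write_system: parameters exactly, coordinates to PDB precision)."""
    n_atoms = _validate_pdb_records(pdb_path)
    if n_atoms == 0:
        raise ValueError(f"{pdb_path}: no atoms")
    params = json.loads(Path(params_path).read_text())
    beads = [BeadSpec(**b) for b in params["beads"]]
    if len(beads) != n_atoms:
        ids = [b.id for b in beads]
        raise ValueError(
            f"bead count mismatch: PDB has {n_atoms} atoms, params file lists "
            f"{len(beads)} beads (ids {min(ids)}..{max(ids)})")
    st = gemmi.read_structure(str(pdb_path))
    xyz = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break
    coords = np.array(xyz)
    if coords.shape[0] != len(beads):
        raise ValueError("bead count mismatch between PDB and params file")
    return System(
        beads=beads,
        coords=coords,
        bonds=[Bond(**b) for b in params["bonds"]],
        box=params["box"],
        site_selection=frozenset(params["site_selection"]),
        ligand_selection=frozenset(params["ligand_selection"]),
        exclusions=frozenset(tuple(p) for p in params.get("exclusions", [])),
        meta=params.get("meta", {}),
    )


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------

def write_trajectory_xyz(path, frames, times=None, element: str = "C") -> None:
    """Write a multi-frame XYZ file (one atom-count header per frame)."""
    frames = frames.frames if isinstance(frames, TrajectorySegment) else np.asarray(frames)
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    with open(path, "w") as fh:
        for f in range(frames.shape[0]):
            fh.write(f"{frames.shape[1]}\n")
            fh.write(f"t= {times[f]:.6f} ps\n")
            for x, y, z in frames[f]:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory_xyz(path):
    """Read a multi-frame XYZ file; returns (frames (F,N,3), times).

    Frames must share one atom count; a truncated final frame raises an
    error naming the frame index.
    """
    frames = []
    times = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    n_atoms = None
    frame_idx = 0
    while pos < len(lines):
        if lines[pos].strip() == "":
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {pos + 1}")
        if n_atoms is None:
            n_atoms = n
        elif n != n_atoms:
            raise ValueError(
                f"{path}: inconsistent atom count at frame {frame_idx} ({n} != {n_atoms})")
        if pos + 2 + n > len(lines):
            raise ValueError(f"{path}: truncated frame {frame_idx}")
        comment = lines[pos + 1]
        t = frame_idx
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        xyz = np.empty((n, 3))
        for a in range(n):
            lno = pos + 2 + a
            if lno >= len(lines):
                raise ValueError(f"{path}: truncated frame {frame_idx}")
            parts = lines[lno].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed atom line {lno + 1} in frame {frame_idx}")
            xyz[a] = [float(p) for p in parts[1:4]]
        frames.append(xyz)
        times.append(float(t))
        pos += 2 + n
        frame_idx += 1
    if not frames:
        raise ValueError(f"{path}: no frames")
    return np.array(frames), np.array(times)


def write_trajectory_dcd(path, frames, system: System) -> None:
    """Optional DCD export (requires mdtraj)."""
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover
        raise ImportError("DCD export requires the optional mdtraj package") from exc
    frames = frames.frames if isinstance(frames, TrajectorySegment) else np.asarray(frames)
    top = mdtraj.Topology()
    ch = top.add_chain()
    for bead in system.beads:
        res = top.add_residue(bead.residue_name, ch)
        top.add_atom("C", mdtraj.element.carbon, res)
    traj = mdtraj.Trajectory(frames / 10.0, top)  # A -> nm
    traj.save_dcd(str(path))


def write_energies_csv(path, segment: TrajectorySegment) -> None:
    pd.DataFrame({
        "time_ps": segment.frame_times,
        "E_bond": segment.e_bond,
        "E_lj": segment.e_lj,
        "E_coul": segment.e_coul,
        "E_restraint": segment.e_restraint,
        "T_inst": segment.t_inst,
    }).to_csv(path, index=False)


def write_occupancy_dx(path, grid: OccupancyGrid) -> None:
    """Export an occupancy grid as an OpenDX scalar field."""
    from gridData import Grid

    g = Grid(grid.occupancy, origin=np.asarray(grid.origin) + grid.spacing / 2.0,
             delta=grid.spacing)
    g.export(str(path), "DX")


def write_result_json(path, result: SuMDResult) -> None:
    payload = {
        "status": result.status,
        "total_simulated_time_ps": result.total_simulated_time,
        "first_binding_time_ps": result.first_binding_time,
        "total_time_at_first_binding_ps": result.total_time_at_first_binding,
        "n_windows": len(result.windows),
        "n_accepted": result.n_accepted,
        "error": result.error,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a full run (build -> equilibrate ->
    SuMD -> analysis), serialisable to/from YAML so every run directory
    carries a machine-readable record sufficient to reproduce it."""

    engine: EngineConfig = dataclasses.field(default_factory=EngineConfig)
    supervision: SupervisionConfig = dataclasses.field(default_factory=SupervisionConfig)
    scenario: ScenarioConfig = dataclasses.field(default_factory=ScenarioConfig)
    outdir: str = "sumd_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        eng = EngineConfig(**raw.get("engine", {}))
        sup = SupervisionConfig(**raw.get("supervision", {}))
        scn = ScenarioConfig(**raw.get("scenario", {}))
        return cls(engine=eng, supervision=sup, scenario=scn,
                   outdir=raw.get("outdir", "sumd_run"), seed=raw.get("seed", 0))

    def to_yaml(self, path) -> None:
        eng = dataclasses.asdict(self.engine)
        eng.pop("restraints", None)
        payload = {
            "engine": eng,
            "supervision": dataclasses.asdict(self.supervision),
            "scenario": dataclasses.asdict(self.scenario),
            "outdir": self.outdir,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
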