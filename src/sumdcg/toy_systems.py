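"""Synthetic coarse-grained receptor--ligand systems.

The generator builds desk-scale bead models of the binding scenarios a
supervised-MD protocol is meant to handle: a hollow receptor shell with a
single aperture (the extracellular vestibule) leading to a buried
attractive pocket (the orthosteric site), an optional positively charged
vestibule that electrostatically repels a charged ligand, optional
cryptic side sub-pockets carved into the shell, and optional explicit
solvent beads.  The ligand is a short three-bead chain placed, by
default, 35 A away from the receptor centre of mass along the aperture
axis, so a binding event requires diffusion toward and passage through
the vestibule.

All systems are pure functions of their :class:`ScenarioConfig` (and a
seed), so every downstream stage of the pipeline is reproducible without
any external input.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .units import COULOMB

__all__ = [
    "BeadSpec",
    "Bond",
    "System",
    "ScenarioConfig",
    "build_funnel_system",
    "make_vestibule_variant",
    "add_solvent",
]

# receptor architecture (A, kcal/mol, amu)
SHELL_RADIUS = 10.0
SHELL_SPACING = 3.6
SHELL_SIGMA = 4.2
SHELL_EPSILON = 0.1
#: vestibule rim beads are mildly attractive, emulating the transient
#: intermediate interactions ligands make at the extracellular vestibule
VESTIBULE_EPSILON = 0.35
SHELL_MASS = 50.0
APERTURE_HALF_ANGLE_DEG = 55.0
VESTIBULE_BAND_DEG = (55.0, 80.0)
POCKET_N_BEADS = 12
POCKET_SIGMA = 3.0
#: pocket cup centre offset toward the aperture (+x), A; pulls the
#: attraction zone's reach a little way into the entry channel
POCKET_OFFSET = 1.5
POCKET_MASS = 50.0
CRYPTIC_HOLE_HALF_ANGLE_DEG = 15.0
CRYPTIC_CAP_RADIUS = 13.5
CRYPTIC_SIGMA = 4.2
CRYPTIC_EPSILON = 0.3

# ligand: three-bead chain, optionally with one charged terminal bead
LIGAND_N_BEADS = 3
LIGAND_SIGMA = 2.0
LIGAND_EPSILON = 0.25
LIGAND_MASS = 60.0
LIGAND_BOND_K = 100.0
LIGAND_BOND_R0 = 1.5

SOLVENT_SIGMA = 2.8
SOLVENT_EPSILON = 0.15
SOLVENT_MASS = 18.0

#: cutoff used when calibrating the pocket well depth (matches the
#: engine's default nonbonded cutoff)
CALIBRATION_CUTOFF = 9.0

_ROLES = ("receptor", "ligand", "solvent")


@dataclass(frozen=True)
class BeadSpec:
    """Per-bead topology record: identity, residue, role and parameters."""

    id: int
    residue_id: int
    residue_name: str
    role: str
    mass: float
    charge: float
    lj_sigma: float
    lj_epsilon: float

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"bead {self.id}: role {self.role!r} not in {_ROLES}")
        if self.mass <= 0:
            raise ValueError(f"bead {self.id}: mass must be > 0")
        if self.lj_sigma <= 0:
            raise ValueError(f"bead {self.id}: lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise ValueError(f"bead {self.id}: lj_epsilon must be >= 0")


@dataclass(frozen=True)
class Bond:
    """Harmonic bond i-j with stiffness k (kcal/mol/A^2) and rest length r0 (A)."""

    i: int
    j: int
    k: float
    r0: float


@dataclass
class System:
    """Topology, parameters and reference coordinates of a bead system.

    ``site_selection`` holds the residue ids of the pocket-lining
    receptor beads used as the supervised binding site;
    ``ligand_selection`` the ligand residue ids.
    """

    beads: list[BeadSpec]
    coords: np.ndarray  # (N, 3) A, reference/initial coordinates
    bonds: list[Bond] = field(default_factory=list)
    box: float | None = None  # cubic edge length A, origin at corner
    site_selection: frozenset[int] = frozenset()
    ligand_selection: frozenset[int] = frozenset()
    #: bead-index pairs excluded from nonbonded interactions (beyond
    #: bonded pairs, which are always excluded).  The generators exclude
    #: all intra-receptor pairs: the scaffold is held by positional
    #: restraints, so internal nonbonded strain is unphysical here.
    exclusions: frozenset[tuple[int, int]] = frozenset()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.beads), 3):
            raise ValueError("coords shape does not match bead count")
        ids = [b.id for b in self.beads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate bead ids")
        n = len(self.beads)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references missing bead")
        self.exclusions = frozenset(
            (min(i, j), max(i, j)) for i, j in self.exclusions)
        roles = {bead.residue_id: bead.role for bead in self.beads}
        if self.site_selection:
            bad = [r for r in self.site_selection if roles.get(r) != "receptor"]
            if bad:
                raise ValueError(f"site_selection residues not receptor-role: {bad}")
        if self.ligand_selection:
            bad = [r for r in self.ligand_selection if roles.get(r) != "ligand"]
            if bad:
                raise ValueError(f"ligand_selection residues not ligand-role: {bad}")

    # ---- array views -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([b.lj_sigma for b in self.beads])

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([b.lj_epsilon for b in self.beads])

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.beads) if b.role == role], dtype=int)

    def indices_by_residues(self, residue_ids) -> np.ndarray:
        rid = set(residue_ids)
        return np.array([i for i, b in enumerate(self.beads) if b.residue_id in rid], dtype=int)

    @property
    def site_bead_indices(self) -> np.ndarray:
        return self.indices_by_residues(self.site_selection)

    @property
    def ligand_bead_indices(self) -> np.ndarray:
        return self.indices_by_residues(self.ligand_selection)

    @property
    def receptor_bead_indices(self) -> np.ndarray:
        return self.indices_by_role("receptor")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic binding scenario.

    pocket_depth
        Target minimum ligand-receptor interaction energy in the bound
        pose, kcal/mol (well depth; stored positive).
    pocket_radius
        Radius of the pocket-lining bead cup, A.
    vestibule_charge
        Total charge (e) spread over the aperture-flanking beads; 0
        gives the neutral scenario.
    ligand_charge
        Charge (e) on one terminal ligand bead (emulates a charged
        amine on the ligand).
    n_cryptic_pockets
        Number of cryptic side sub-pockets carved into the shell (0-4).
    n_solvent
        Number of explicit solvent beads added to the box.
    placement_distance
        Initial ligand-centroid to receptor-centroid distance, A.
    """

    pocket_depth: float = 10.0
    pocket_radius: float = 4.0
    vestibule_charge: float = 0.0
    ligand_charge: float = 0.0
    n_cryptic_pockets: int = 0
    n_solvent: int = 0
    placement_distance: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement_distance <= self.pocket_radius:
            raise ValueError("placement_distance must exceed pocket_radius")
        if self.n_cryptic_pockets < 0 or self.n_solvent < 0:
            raise ValueError("counts must be >= 0")
        if self.pocket_depth <= 0 or self.pocket_radius <= 0:
            raise ValueError("pocket_depth and pocket_radius must be > 0")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spaced unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_CRYPTIC_AXES = np.array(
    [[0.0, 1.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]
)


def _pair_lj(r: np.ndarray, sigma: np.ndarray, eps: np.ndarray, cutoff: float) -> np.ndarray:
    sr6 = (sigma / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    return np.where(r < cutoff, e, 0.0)


def _ligand_receptor_energy(
    lig_xyz: np.ndarray,
    rec_xyz: np.ndarray,
    sig_pair: np.ndarray,
    eps_pair: np.ndarray,
    qq_pair: np.ndarray,
    cutoff: float = CALIBRATION_CUTOFF,
) -> float:
    """Total nonbonded ligand-receptor energy for one configuration."""
    d = np.linalg.norm(lig_xyz[:, None, :] - rec_xyz[None, :, :], axis=-1)
    e = _pair_lj(d, sig_pair, eps_pair, cutoff)
    e = e + np.where(d < cutoff, qq_pair / d, 0.0)
    return float(e.sum())


def build_funnel_system(config: ScenarioConfig) -> System:
    """Build the funnel-pocket scenario.

    The receptor is a rigid spherical shell of excluded-volume beads
    with one aperture (a missing polar cap on the +x axis), enclosing a
    cup of attractive pocket-lining beads.  The pocket bead well depth
    is calibrated so that the minimum ligand-receptor interaction energy
    equals ``-pocket_depth`` (within a few percent).  The ligand chain
    is placed ``placement_distance`` from the receptor centre of mass
    along the aperture axis.
    """
    cfg = config
    if cfg.pocket_radius > SHELL_RADIUS - SHELL_SIGMA:
        raise ValueError(
            f"pocket_radius={cfg.pocket_radius} too large for shell radius "
            f"{SHELL_RADIUS} (must be <= {SHELL_RADIUS - SHELL_SIGMA})"
        )
    if cfg.n_cryptic_pockets > len(_CRYPTIC_AXES):
        raise ValueError(f"at most {len(_CRYPTIC_AXES)} cryptic pockets supported")

    cos_ap = math.cos(math.radians(APERTURE_HALF_ANGLE_DEG))
    band_lo = math.cos(math.radians(VESTIBULE_BAND_DEG[1]))
    band_hi = math.cos(math.radians(VESTIBULE_BAND_DEG[0]))

    n_shell = int(round(4.0 * math.pi * SHELL_RADIUS**2 / SHELL_SPACING**2))
    dirs = _fibonacci_sphere(n_shell)
    keep = dirs[:, 0] < cos_ap  # carve the aperture cap around +x

    # carve cryptic side holes
    axes = _CRYPTIC_AXES[: cfg.n_cryptic_pockets]
    cos_hole = math.cos(math.radians(CRYPTIC_HOLE_HALF_ANGLE_DEG))
    for ax in axes:
        keep &= dirs @ ax < cos_hole
    shell_dirs = dirs[keep]

    beads: list[BeadSpec] = []
    xyz: list[np.ndarray] = []
    bid = 0
    rid = 0
    for d in shell_dirs:
        name = "VST" if band_lo <= d[0] <= band_hi else "SHL"
        eps = VESTIBULE_EPSILON if name == "VST" else SHELL_EPSILON
        beads.append(
            BeadSpec(bid, rid, name, "receptor", SHELL_MASS, 0.0, SHELL_SIGMA, eps)
        )
        xyz.append(SHELL_RADIUS * d)
        bid += 1
        rid += 1

    # cryptic sub-pocket caps: small bead cups closing each side hole,
    # leaving a hydrophobic cavity between shell and cap
    for k, ax in enumerate(axes):
        perp = np.array([1.0, 0.0, 0.0])
        perp = perp - (perp @ ax) * ax
        perp /= np.linalg.norm(perp)
        perp2 = np.cross(ax, perp)
        cap_dirs = [ax]
        for a in np.linspace(0, 2 * math.pi, 5, endpoint=False):
            v = math.cos(math.radians(16)) * ax + math.sin(math.radians(16)) * (
                math.cos(a) * perp + math.sin(a) * perp2
            )
            cap_dirs.append(v / np.linalg.norm(v))
        for d in cap_dirs:
            beads.append(
                BeadSpec(bid, rid, "CRY", "receptor", SHELL_MASS, 0.0, CRYPTIC_SIGMA, CRYPTIC_EPSILON)
            )
            xyz.append(CRYPTIC_CAP_RADIUS * d)
            bid += 1
        rid += 1

    # pocket-lining cup: beads on rings about the -x axis at pocket_radius
    cup = [np.array([-1.0, 0.0, 0.0])]
    for theta_deg, n_ring, phase in ((40.0, 5, 0.0), (75.0, 6, 0.5)):
        th = math.radians(theta_deg)
        for a in (2 * math.pi / n_ring) * (np.arange(n_ring) + phase):
            cup.append(np.array([-math.cos(th),
                                 math.sin(th) * math.cos(a),
                                 math.sin(th) * math.sin(a)]))
    cup = np.array(cup)
    pocket_rids = []
    pocket_first_bead = bid
    for d in cup:
        beads.append(
            BeadSpec(bid, rid, "PKT", "receptor", POCKET_MASS, 0.0, POCKET_SIGMA, 1.0)
        )
        xyz.append(cfg.pocket_radius * d + np.array([POCKET_OFFSET, 0.0, 0.0]))
        pocket_rids.append(rid)
        bid += 1
        rid += 1

    rec_xyz = np.array(xyz)
    rec_masses = np.array([b.mass for b in beads])
    rec_centroid = (rec_masses[:, None] * rec_xyz).sum(0) / rec_masses.sum()

    # ligand chain along y, centroid on the aperture axis
    lig_rid = rid
    lig_offsets = np.array([[0.0, -LIGAND_BOND_R0, 0.0], [0.0, 0.0, 0.0], [0.0, LIGAND_BOND_R0, 0.0]])
    lig_charges = [0.0, 0.0, cfg.ligand_charge]
    lig_first_bead = bid
    for m in range(LIGAND_N_BEADS):
        beads.append(
            BeadSpec(
                bid, lig_rid, "LIG", "ligand", LIGAND_MASS, lig_charges[m], LIGAND_SIGMA, LIGAND_EPSILON
            )
        )
        bid += 1
    lig_start = rec_centroid + np.array([cfg.placement_distance, 0.0, 0.0]) + lig_offsets

    bonds = [
        Bond(lig_first_bead, lig_first_bead + 1, LIGAND_BOND_K, LIGAND_BOND_R0),
        Bond(lig_first_bead + 1, lig_first_bead + 2, LIGAND_BOND_K, LIGAND_BOND_R0),
    ]

    # calibrate the pocket epsilon so the bound-pose minimum interaction
    # energy equals -pocket_depth
    eps_pocket, pose, e_min = _calibrate_pocket(
        cfg, beads[:lig_first_bead], rec_xyz, pocket_first_bead, lig_offsets
    )
    for i in range(pocket_first_bead, pocket_first_bead + POCKET_N_BEADS):
        beads[i] = replace(beads[i], lj_epsilon=eps_pocket)

    box = 2.0 * (cfg.placement_distance + 12.0)
    shift = np.full(3, box / 2.0) - rec_centroid
    coords = np.vstack([rec_xyz, lig_start]) + shift
    exclusions = frozenset(
        (i, j) for i in range(lig_first_bead) for j in range(i + 1, lig_first_bead))

    system = System(
        beads=beads,
        coords=coords,
        bonds=bonds,
        box=box,
        exclusions=exclusions,
        site_selection=frozenset(pocket_rids),
        ligand_selection=frozenset([lig_rid]),
        meta={
            "scenario": "funnel",
            "config": cfg.__dict__.copy(),
            "aperture_axis": [1.0, 0.0, 0.0],
            "pocket_epsilon": eps_pocket,
            "pocket_min_energy": e_min,
            "pocket_min_pose": (pose + shift).tolist(),
            "vestibule_charge": 0.0,
        },
    )
    if cfg.n_solvent:
        system = add_solvent(system, cfg.n_solvent, cfg.seed)
    return system


def _calibrate_pocket(cfg, rec_beads, rec_xyz, pocket_first, lig_offsets):
    """Solve for the pocket-bead epsilon giving the requested well depth.

    With Lorentz-Berthelot mixing the ligand-pocket attraction scales as
    sqrt(eps_pocket), so at a fixed pose the calibration is a one-line
    solve; the pose itself shifts with eps, so solve and re-minimise a
    few times.
    """
    n_rec = len(rec_beads)
    sig_r = np.array([b.lj_sigma for b in rec_beads])
    eps_r = np.array([b.lj_epsilon for b in rec_beads])  # pocket rows = 1
    is_pocket = np.zeros(n_rec, dtype=bool)
    is_pocket[pocket_first : pocket_first + POCKET_N_BEADS] = True

    sig_pair = 0.5 * (LIGAND_SIGMA + sig_r)[None, :].repeat(LIGAND_N_BEADS, 0)
    qq_pair = np.zeros_like(sig_pair)

    def pair_eps(eps_pocket: float) -> np.ndarray:
        eps = np.where(is_pocket, eps_pocket, eps_r)
        return np.sqrt(LIGAND_EPSILON * eps)[None, :].repeat(LIGAND_N_BEADS, 0)

    def energy_split(center: np.ndarray, eps_pocket: float) -> tuple[float, float]:
        lig = center + lig_offsets
        e_all = _ligand_receptor_energy(lig, rec_xyz, sig_pair, pair_eps(eps_pocket), qq_pair)
        ep = pair_eps(eps_pocket).copy()
        ep[:, ~is_pocket] = 0.0
        e_cup = _ligand_receptor_energy(lig, rec_xyz, sig_pair, ep, qq_pair)
        return e_all - e_cup, e_cup  # wall, cup

    center = np.zeros(3)
    eps_pocket = 1.0
    for _ in range(4):
        res = minimize(
            lambda c: energy_split(c, eps_pocket)[0] + energy_split(c, eps_pocket)[1],
            center,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8},
        )
        center = res.x
        e_wall, e_cup = energy_split(center, eps_pocket)
        e_cup_unit = e_cup / math.sqrt(eps_pocket)
        if e_cup_unit >= 0:
            raise ValueError("pocket geometry is not attractive; cannot calibrate depth")
        s = (-cfg.pocket_depth - e_wall) / e_cup_unit
        if s <= 0:
            raise ValueError(
                f"pocket_depth={cfg.pocket_depth} unreachable: wall energy {e_wall:.3f}"
            )
        eps_pocket = s * s
    e_min = e_wall + math.sqrt(eps_pocket) * e_cup_unit
    return eps_pocket, center, e_min


def make_vestibule_variant(system: System, vestibule_charge: float) -> System:
    """Charge-only variant: spread ``vestibule_charge`` over the beads
    flanking the aperture (the ``VST`` residues).

    Emulates positively charged extracellular-loop residues repelling a
    charged ligand on its way into the pocket.  Coordinates and every
    other parameter are untouched.
    """
    idx = [i for i, b in enumerate(system.beads) if b.residue_name == "VST"]
    if not idx:
        raise ValueError("system has no aperture-flanking (VST) beads")
    per_bead = vestibule_charge / len(idx)
    beads = list(system.beads)
    for i in idx:
        beads[i] = replace(beads[i], charge=per_bead)
    out = System(
        beads=beads,
        coords=system.coords.copy(),
        bonds=list(system.bonds),
        box=system.box,
        exclusions=system.exclusions,
        site_selection=system.site_selection,
        ligand_selection=system.ligand_selection,
        meta={**copy.deepcopy(system.meta), "vestibule_charge": float(vestibule_charge)},
    )
    return out


def add_solvent(system: System, n_solvent: int, seed: int) -> System:
    """Add ``n_solvent`` solvent beads uniformly at random in the box,
    rejecting placements closer than 0.8 of the pair LJ sigma to any
    existing bead."""
    if n_solvent == 0:
        return system
    if system.box is None:
        raise ValueError("add_solvent requires a periodic box")
    rng = np.random.default_rng(seed)
    box = system.box
    existing = system.coords.copy()
    sig = system.sigmas.copy()
    placed: list[np.ndarray] = []
    max_tries = 200 * n_solvent
    tries = 0
    while len(placed) < n_solvent:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place solvent without overlap: placed {len(placed)} of {n_solvent}"
            )
        tries += 1
        p = rng.uniform(0.0, box, size=3)
        dmin = 0.8 * 0.5 * (sig + SOLVENT_SIGMA)
        d = np.linalg.norm(existing - p, axis=1)
        if np.any(d < dmin):
            continue
        placed.append(p)
        existing = np.vstack([existing, p])
        sig = np.append(sig, SOLVENT_SIGMA)

    beads = list(system.beads)
    bid = max(b.id for b in beads) + 1
    rid = max(b.residue_id for b in beads) + 1
    for _ in range(n_solvent):
        beads.append(
            BeadSpec(bid, rid, "SOL", "solvent", SOLVENT_MASS, 0.0, SOLVENT_SIGMA, SOLVENT_EPSILON)
        )
        bid += 1
        rid += 1
    coords = np.vstack([system.coords, np.array(placed)])
    return System(
        beads=beads,
        coords=coords,
        bonds=list(system.bonds),
        box=system.box,
        exclusions=system.exclusions,
        site_selection=system.site_selection,
        ligand_selection=system.ligand_selection,
        meta={**copy.deepcopy(system.meta), "n_solvent": n_solvent, "solvent_seed": seed},
    )
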