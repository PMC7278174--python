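# Methods

## The supervised-MD protocol

Supervised molecular dynamics (SuMD) is an adaptive-sampling scheme for
ligand-binding pathways that adds no biasing force.  Dynamics is
propagated in short time windows; during each window the distance
d(t) between the mass-weighted centroids of the ligand and of the
binding-site selection is sampled at `n_distance_samples_per_window`
evenly spaced times and fitted by ordinary least squares,

    m = cov(t, d) / var(t).

If m < 0 (strictly) the window is kept and the end-of-window coordinates
and velocities seed the next window; otherwise the window is re-simulated
from its starting coordinates with freshly drawn Maxwell-Boltzmann
velocities.  Thirty consecutive rejections abandon the run.  When the
centroid distance falls below the 5 Å binding threshold, supervision is
switched off and thirty short unsupervised windows probe the putative
bound state; any check window ending above the threshold re-engages
supervision (with a fresh failure counter).  A run surviving all checks
is extended by one unsupervised production run.  At atomistic scale the
window is 600 ps and the production run 25 ns; the desk-scale defaults
here are 10 ps windows and 100 windows of production.

Design points the protocol definition leaves open, resolved as follows
(all configurable):

- the slope is fitted to 100 samples per window;
- a slope of exactly zero counts as a failure (strict reading of
  "negative");
- the binding threshold is evaluated on the end-of-window distance
  (`bind_check="any_frame"` switches to any sampled frame);
- each post-binding check window defaults to one window length;
- velocity reassignment on retry is an explicit Maxwell-Boltzmann
  redraw, deterministic by seed, rather than an implicit property of
  the thermostat;
- centroids are mass-weighted (geometric available);
- all supervisor randomness flows from one seeded stream; replica i of
  an experiment uses seed + i;
- retried windows are logged but never contribute frames or time to the
  accepted trajectory.

## The coarse-grained engine

NVT Langevin dynamics with the BAOAB splitting; one force evaluation per
step; velocities initialised from Maxwell-Boltzmann at the target
temperature.  Units are Å, ps, amu, kcal/mol and elementary charges
(k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹; Coulomb constant 332.0637
kcal·Å·mol⁻¹·e⁻²; 1 kcal/mol = 418.4 amu·Å²·ps⁻²).

The force field is: harmonic bonds and harmonic positional restraints,
both in the ½k x² convention (so a restrained bead equilibrates to
per-axis positional variance k_B T/k); 12-6 Lennard-Jones with
Lorentz-Berthelot mixing; Coulomb electrostatics.  Both nonbonded terms
are plainly truncated at the cutoff (default 9 Å) — no Ewald summation:
at desk scale with a handful of point charges the truncation artefact
is acceptable and keeps the engine dependency-free.  Bonds are stiff
harmonics rather than constraints.  Minimum-image displacements apply
whenever the system declares a cubic box; coordinates are kept
unwrapped.  Defaults: dt = 0.002 ps, T = 310 K, friction 1 ps⁻¹
(interpreting the thermostat's "low damping of 1 ps⁻¹" as the Langevin
friction coefficient).  The synthetic scenarios are run at dt = 0.004
ps, which is comfortably stable for their soft potentials (stiffest
mode, the ligand bond, has a 0.18 ps period).

Nonbonded pairs on a topology's exclusion list are skipped, and the
generators exclude all intra-receptor pairs: the receptor scaffold is
held rigid by stiff positional restraints (k = 10 kcal/mol/Å² in the
standard setup), so internal scaffold strain is physically meaningless
there, and dropping it shrinks the pair list roughly fifteen-fold.

Staged equilibration mimics a four-step restraint-release protocol
(restrain everything → receptor only → binding site only → free), runs
under NVT throughout, and logs per-stage mean temperature and RMSD.  A
capped steepest-descent pre-relaxation is available in place of a full
conjugate-gradient minimiser.

Determinism: a trajectory is a pure function of (system, state, config);
noise is drawn from the generator stored in the state, and rerunning an
identical state reproduces the segment bit for bit on one platform.

## The synthetic scenarios

`build_funnel_system` emulates the statistical structure of a GPCR-like
binding event without any structural input:

- a rigid spherical shell of excluded-volume beads (radius 10 Å, LJ
  σ = 4.2 Å, lattice spacing 3.6 Å — impermeable to the ligand) with
  one missing polar cap of half-angle 55° forming the entry aperture;
- a mildly attractive rim band (ε = 0.35 vs 0.1 for plain shell beads)
  flanking the aperture, emulating the transient intermediate
  interactions ligands make with the extracellular vestibule, and
  carrying the optional vestibule charge (total charge spread evenly
  over the rim beads) that emulates positively charged extracellular
  lysines repelling a charged ligand;
- a cup of twelve pocket-lining beads on rings about the pocket axis at
  `pocket_radius` (default 4 Å), offset 1.5 Å toward the aperture so
  their attraction reaches into the entry channel.  Their LJ ε is
  calibrated (a one-dimensional solve, iterated with a rigid-ligand
  pose minimisation) so the minimum ligand-receptor interaction energy
  equals −`pocket_depth` (default 10 kcal/mol ≈ 16 k_BT at 310 K —
  deep enough that a bound ligand stays bound through production);
  these beads are the supervised binding-site selection;
- a three-bead harmonic ligand chain (bead mass 60 amu, σ = 2 Å,
  bond length 1.5 Å), optionally with one +1e terminal bead, placed
  `placement_distance` (default 35 Å) from the receptor centre of mass
  along the aperture axis;
- optional cryptic sub-pockets: small side holes in the shell closed by
  hydrophobic 6-bead caps, leaving wall cavities where resident solvent
  can be planted;
- optional solvent beads (σ = 2.8 Å, ε = 0.15, 18 amu) placed uniformly
  at random with overlap rejection (≥ 0.8 of the pair σ).

The cubic box edge is 2·(placement + 12) Å.  Everything is a pure
function of the scenario config and seed.

What the generator does *not* emulate: conformational selectivity, real
solvent structure and dielectric screening (charges interact in vacuum
with plain truncation, so the +3e vestibule is a much harder barrier
relative to k_BT than hydrated lysines would be), membrane, internal
receptor flexibility, and any chemically specific interaction
(hydrogen bonds, π-stacking).  Passing tests therefore demonstrate the
protocol's control flow and its generic kinetic consequences —
supervision accelerates first binding; a like-charged vestibule delays
it — not any quantitative property of real receptor–ligand systems.

## Experiments and their conditions

The binding-time experiment runs independent replicas (supervised runs
use the full protocol with production disabled and one check window,
since only the first binding matters; unsupervised runs are plain
Langevin windows with the same end-of-window binding criterion) and
records the total simulated time to first binding, *including* retried
windows, so the supervision overhead is charged fairly.  Standard
conditions, chosen once: 20 replicas per arm, a 1000 ps per-replica
budget (100 windows; the atomistic protocol samples binding within a
merged ~50 ns, i.e. ~83 of its 600 ps windows), dt = 0.004 ps, receptor
restraint k = 10 kcal/mol/Å².  Replicas that do not bind within the
budget are censored at the budget for medians and for the one-sided
Mann-Whitney comparison.  The selectivity analogue compares median
windows-to-binding between the neutral and the +3e-vestibule variant
with a +1e ligand; censored replicas contribute their total window
count.

## Trajectory analysis

- Per-residue decomposition: for each frame and receptor residue, the
  truncated Coulomb and LJ energies are summed over (residue bead,
  ligand bead) pairs; summing residues reproduces the total
  ligand-receptor nonbonded energy to ≲1e-6 kcal/mol (same formulas,
  different summation order).
- The interaction-energy landscape bins the per-frame ligand-receptor
  total (not the full system energy) by centroid distance in half-open
  bins [k·w, (k+1)·w); empty bins are omitted.
- RMSD uses Kabsch superposition (computed from the fitted coordinates,
  which stays accurate to ~1e-14 Å near zero, unlike the SVD residual).
  RMSF superposes frames onto the mean structure by default; the
  `superpose=False` path reproduces the closed-form fluctuation of
  individually moving beads exactly (a rigid-body fit on a finite
  scaffold necessarily absorbs part of a single bead's motion).
- Pocket volume is grid-based: points inside an inclusion sphere
  farther than probe_radius + σ/2 from every receptor bead, volume =
  count × spacing³.  At 0.5 Å spacing the empty 5 Å sphere is within
  5% of 4π/3·5³.
- Water-occupancy maps report, per voxel (half-open membership, ties to
  the lower voxel), the fraction of frames containing ≥ 1 solvent-bead
  centre; hotspots are voxels strictly above the 10% threshold, sorted
  by occupancy (ties by voxel index).  Frames must share a receptor
  frame before mapping (the restrained scaffold already does; merged
  apo replicas are concatenated after superposition).

## Numerical choices and limitations

- The slope criterion uses strict inequality; a perfectly flat window
  is a failure.
- Overlapping nonbonded beads (r < 0.1 Å) and non-finite energies abort
  a segment with a descriptive error rather than propagating NaNs.
- The binding-time experiment's supervised arm censors at the budget
  even when the run was abandoned earlier by the failure counter (it
  did not bind within the budget; nothing more is claimed).
- Desk-scale runs use ~90-bead systems and ps-scale windows; absolute
  times are not comparable to atomistic simulations — only the paired
  comparisons (supervised vs not, charged vs neutral) are meaningful.
- The Mann-Whitney test treats censored values as ties at the budget,
  which is conservative for the acceleration claim.
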