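# sumdcg — supervised molecular dynamics on coarse-grained toy systems

`sumdcg` is a desk-scale implementation of **supervised molecular
dynamics (SuMD)**, an adaptive-sampling protocol for ligand-binding
pathways, together with the trajectory-analysis suite that usually
accompanies it (per-residue interaction-energy decomposition,
interaction-energy landscapes, RMSD/RMSF, grid-based pocket volumetry
and water-occupancy hotspot maps).  It is aimed at people who want to
study, teach or extend the *protocol* — its acceptance rule, failure
handling, phase switching and kinetic consequences — without the cost
of atomistic MD: the engine is a coarse-grained NVT Langevin integrator
and the systems are synthetic receptor–ligand bead models whose
statistical structure emulates realistic binding scenarios (a buried
pocket behind a vestibule, a charged vestibule repelling a charged
ligand, cryptic sub-pockets, explicit solvent beads).

## The protocol

Dynamics is run in short windows of length Δt_w (600 ps at atomistic
scale; 10 ps here).  In each window the distance d(t) between the
mass-weighted centroids of the ligand and of the binding-site residues
is sampled n times and fitted by ordinary least squares,

    m = cov(t, d) / var(t).

The window is **kept** iff m < 0; otherwise it is re-run from the same
coordinates with resampled Maxwell–Boltzmann velocities.  No biasing
force is ever applied.  Thirty consecutive rejections abandon the run.
Once d < 5 Å, supervision is switched off and thirty short unsupervised
windows probe the bound state (supervision resumes if d drifts back
above 5 Å); a surviving run is extended by an unsupervised production
run.  The slope filter turns ligand diffusion into a tabu-like search
that samples binding events orders of magnitude faster than plain MD,
at unchanged equilibrium physics within each window.

## Worked example

Build the standard funnel scenario (a 91-bead receptor shell with a
calibrated −10 kcal/mol pocket, ligand placed 35 Å away) and run a
small supervised binding experiment:

```console
$ sumd build --out demo
wrote demo/system.pdb (91 beads, total charge +0.0 e)

$ sumd experiment --system demo/system.pdb --params demo/params.json \
      --replicas 5 --budget 1000 --seed 1 --out demo/exp.csv
5 replicas, 5 bound, median (censored) time to binding 390 ps -> demo/exp.csv
```

All five replicas bound within the 1000 ps budget; the median **total
simulated time to first binding — retried windows included — is
390 ps**.  (Plain unsupervised runs of the same system almost never
bind within this budget; see the acceptance results below.)  A full
single run writes the window log, accepted trajectory and result:

```console
$ sumd run --system demo/system.pdb --params demo/params.json \
      --seed 5 --out demo/run5
status=bound windows=129 accepted=76 total_simulated=2280 ps
```

The window log (`windows.csv`) shows the three phases; the run ends
with the ligand ~1.4 Å from the site centroid after 30 clean check
windows and 1000 ps of production:

```
index  start_time_ps  duration_ps  decision  phase               end_distance_A
126    730.0          10.0         accepted  unsupervised_check  2.58
127    740.0          10.0         accepted  unsupervised_check  2.07
128    750.0          1000.0       accepted  production          1.42
```

The same pipeline is available as a library (`sumdcg.toy_systems`,
`sumdcg.engine`, `sumdcg.supervision`, `sumdcg.analysis`, `sumdcg.io`),
and the supervisor accepts any engine callable with the segment
signature, which is how the test suite drives it with scripted stubs.

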