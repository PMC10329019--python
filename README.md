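# memsta

Desk-scale subtomogram averaging for membrane-attached cyclic (Cn)
channels, built around the bespoke analysis steps needed for in-cell
cryo-electron tomography of secretin-like complexes: a hollow, spool-shaped
C15 cylinder that sits on a membrane, looks almost identical from its top
and bottom, is only partially connected to the membrane on one side, and
swings by a few degrees about its membrane anchor.

Everything runs on synthetic data from a built-in generator, at box sizes a
laptop handles (default 48³ voxels, 5 Å/voxel), with full ground truth for
every planted parameter.

## What the package does

* **Synthetic data** (`memsta.simulate`) — an analytic spool phantom
  (flared hollow cylinder, sealed "gate" disc at the membrane end, Cn
  surface lobes, optional one-sided membrane-connector arc), a planar
  bilayer, the ±50°/5° single-axis missing wedge, planted 180° flips, swing
  tilts, symmetry-unit offsets and white noise — all seeded and
  byte-reproducible.
* **Refinement** (`memsta.refine`) — grid-search rigid alignment by
  wedge-constrained normalized cross-correlation, per-iteration exclusion
  of the worst-scoring fraction (default 20%), Cn-symmetrized averaging,
  gold-standard half-set FSC.  `SubtomogramRefiner` is a scikit-learn style
  estimator (`fit`, fitted attributes `map_`, `records_`, `resolution_`).
* **Membrane flip correction** (`memsta.flip`) — a cylindrical channel seen
  along its axis is nearly up/down symmetric, so refinements misalign a
  fraction of particles by 180°; `MembraneFlipCorrector` flips any particle
  whose axis does not face the centroid of its tomogram's picks (or the
  opposite side with `invert=True`).
* **Radius & symmetry diagnostics** (`memsta.radius`) — per-particle radius
  from the low-passed erected projection (argmax of the mean radial
  intensity × pixel size), radius histograms with peak detection, and an
  azimuthal Fourier spectrum that quantifies which cyclic order a map
  actually carries.
* **Symmetry relaxation** (`memsta.relax`) — after a Cn refinement every
  orientation is defined only up to a symmetry element, so one-sided
  features average out; `SymmetryRelaxer` finds each particle's best
  symmetry unit against a masked C1 reference (axis direction untouched),
  re-averages without symmetry, and `arc_occupancy` measures the recovered
  connector arc in degrees at a stated threshold.
* **Flexibility** (`memsta.flexibility`) — one iteration of focused
  alignment against a protein-only masked reference; the axis angle between
  the global and focused orientations is the per-particle swing tilt;
  tilts are sectioned into interval classes whose first/last populated
  members are the endpoint conformations.
* **Flip classification** (`memsta.classify`) — two-reference
  classification against a reference and its 180° flip separates mixed
  populations inserted in opposite directions.
* **Pipeline & CLI** (`memsta.pipeline`, `memsta` console script) — staged
  runs (`simulate → refine → flipfix → refine(local) → relax/flex/classify/
  radius`) with JSON manifests, content hashes and bit-identical reruns.

## Worked example

Recover a planted 2.86° two-endpoint swing from 300 noiseless particles
behind the ±50° missing wedge:

```python
import numpy as np
import memsta as M

ps = M.PhantomSpec()                     # C15 spool, wall radius 55 Å
ds = M.DatasetSpec(n_particles=300, tilt_model="two_endpoint",
                   tilt_amplitude=2.86, tilt_mixing=0.5, seed=11)
vols, records, truth = M.simulate_dataset(ps, ds)

cfg = M.RefinementConfig(n_sym=15, n_iterations=1, keep_fraction=1.0,
                         search_mode="local", angular_local=0.5,
                         local_range=1.0, inplane_local_range=0.5,
                         lowpass_final=40.0, wedge=M.AcquisitionGeometry())
_, refined, _, _ = M.refine_iterate(vols, records, cfg)

mask = M.cylinder_mask(48, 5.0, radius=85.0, z_min=-60.0, z_max=85.0)
focused = M.focused_refine(vols, refined, mask, M.build_phantom(ps),
                           wedge=M.AcquisitionGeometry())
tilts, classes, (ep_a, ep_b, sep) = M.tilt_trajectory(
    [r.orientation for r in refined], focused, n_intervals=5)
print(f"endpoint separation: {sep:.2f} deg")
print("class sizes:", [len(c.member_ids) for c in classes])
```

Output from this exact script:

```
endpoint separation: 3.03 deg
class sizes: [144, 9, 20, 96, 31]
```

The separation between the first and last populated tilt classes recovers
the planted 2.86° swing to within ~0.2°; the bimodal class populations
(144 in the near-0° class, 96 + 31 around 2.86°) mirror the planted 50/50
two-endpoint mixture, with the sparse middle bins collecting particles
whose tilt estimate fell between the modes.

The same workflows are available from the shell, e.g.
`memsta classify --out run1 --seed 7 --flip-fraction 0.2`.

## Acceptance benchmarks

`scripts/acceptance.py` re-runs three planted-recovery benchmarks from
scratch — two-reference flip classification of a 910-particle mixture with
187 planted flips, connector-arc occupancy after symmetry relaxation of a
planted 100° arc, and the dominant azimuthal order of a C5-constrained
average of C15-textured particles — and writes one JSON object with the
recovered numbers:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is a few minutes on one CPU.
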