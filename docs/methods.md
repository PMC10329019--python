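# Methods

## The problem and the model

Secretin-family channels are hollow, ~15-fold symmetric cylinders embedded
in or resting on bacterial membranes.  In-cell tomography of such particles
faces four coupled analysis problems that this package implements at desk
scale:

1. **Top/bottom ambiguity.**  Along its symmetry axis the cylinder has few
   low-resolution features, so early rounds of subtomogram alignment place
   a fraction of particles upside down, producing averages with a spurious
   mirror ("D-like") symmetry.  The cell geometry resolves the ambiguity:
   all picks from one (near-spherical) cell face a consistent side of the
   pick cloud's centroid.
2. **Symmetry averaging of one-sided features.**  A Cn refinement defines
   orientations only modulo the symmetry group; a membrane connector that
   covers a ~100° arc on one side is smeared into a faint ring.  Assigning
   each particle its azimuthal symmetry unit against a C1 reference and
   re-averaging without symmetry restores the arc.
3. **Small rigid flexibility.**  The particle swings by a few degrees about
   its membrane anchor.  A global alignment is dominated by the (flat,
   massive) membrane; a focused alignment against a protein-only masked
   reference follows the protein.  The per-particle axis angle between the
   two orientations is the swing tilt.
4. **Mixed insertion directions.**  Datasets can mix particles inserted in
   opposite directions; aligning each particle locally to a reference and
   to its 180° flip separates the populations.

## Synthetic world

`build_phantom` renders an analytic spool: a hollow cylinder of wall
mid-radius 55 Å flaring to 75 Å at both ends, height 160 Å, Gaussian wall
profile of 20 Å FWHM, a sealed gate disc at the low-z end, azimuthal
surface lobes `1 + a·cos(nφ)` (default a = 0.3, n = 15) giving exact Cn
texture, and an optional rim connector spanning a stated arc with linear
4° azimuthal edges whose half-maximum falls exactly on the arc boundary.
The default grid is 48³ voxels at 5 Å/voxel (240 Å extent), chosen so the
phantom, both bilayer leaflets (Gaussian sheets, 15 Å FWHM, 40 Å apart,
proximal leaflet 8 Å above the gate tip) and the connector all fit with
margin.  These proportions loosely follow secretin dimensions; they are
free parameters, not a claim about any deposited structure.

`simulate_dataset` places particles on a virtual spherical cell surface
(radius 400 voxels) pointing their +z axis at the cell center, then samples
per particle: a 180° flip (Bernoulli, or an exact planted count), a swing
tilt (`none`, `two_endpoint(amplitude, mixing)`, or `uniform(max)`; axis
uniform in the membrane plane or fixed), and a symmetry-unit offset
(uniform over the n units).  The volume is the rotated phantom plus the
analytic bilayer (rendered without interpolation), Fourier-masked by the
±50°, 5°-step single-axis wedge, plus white Gaussian noise added last.
"SNR 0.5" means var(noiseless composite)/var(noise) over the whole box.

Two flip semantics exist because two different experiments need them:
`misalignment` keeps the rendered pose consistent with the cell geometry
and corrupts the *record* by 180° (what flip correction must undo);
`population` composes the flip into the rendered pose and membrane (a
genuine mixture, what two-reference classification must separate).
`record_model="coarse"` initializes records at the placement rotation
only — the state a converged Cn refinement reports (no unit offset, no
swing tilt) — which is what the relaxation and flexibility stages consume.

What the generator does **not** emulate: CTF, tilt-series projection and
reconstruction artifacts beyond the wedge, membrane curvature, crowding,
or gold fiducials.  A green test therefore establishes the correctness of
the geometry and estimation machinery under the stated statistical model,
not robustness to real-tomogram systematics.

## Alignment scoring and its numerical hazards

Alignment maximizes normalized cross-correlation (NCC) over orientation
grids (quasi-uniform Fibonacci axis sampling × in-plane steps restricted to
one Cn fundamental domain; default coarse 12°, local 2°).  Translation
search is off by default: simulated particles are centered, and the swing
pivot is taken at the box center (a contact-point pivot would add a
sub-voxel shift at the ≤3° amplitudes modelled).

Three desk-scale biases were identified and are handled explicitly:

* **Wedge normalization.**  A particle spectrum lives inside its missing
  wedge.  In global mode each candidate (reference rotated to a grid
  orientation) is wedge-masked in Fourier space — exact constrained CC.
  In the fast local mode the particle is "erected" by its current
  orientation so one candidate stack serves all particles; there the
  denominator is corrected per particle by restricting candidate power to
  the analytically rotated wedge support (precomputed candidate power
  spectra × a boolean mask evaluated on rotated frequency coordinates).
  Without this correction local alignment drifts by degrees per iteration.
* **Interpolation-blur asymmetry.**  In an erected stack the identity
  candidate is the only un-resampled row; twice-interpolated probes then
  prefer its blurred neighbors (~one grid step outward bias).  The stack
  reference is pre-blurred with a net-zero pair of half-voxel trilinear
  shifts so all candidates share one resample's blur; the residual bias is
  "sticky at the start", which is the safe direction.
* **Exact rescoring.**  For fine recovery (noiseless planted tests, the
  swing readout) a final pass rescores a small neighborhood with
  per-particle rotated, wedge-filtered candidates against the raw volume —
  the same construction as the rendering path, so the score landscape has
  no interpolation bias at the truth.  This is `polish` in the refiner and
  `exact_polish` (default on) in `focused_refine`.

Characterized residual limits (all measured by the test suite's planted
datasets): a box-48 *data-average* focused reference (double-interpolated,
carrying an uncompensated missing cone) adds ~0.5° systematic tilt bias
versus the known phantom reference, so the swing benchmark seeds the
focused reference from the phantom; and the ±50° wedge makes symmetry-unit
assignment genuinely ambiguous for ~10% of particles even without noise
(the connector smears azimuthally in the erected frame), which leaves the
arc-occupancy readout intact because symmetric adjacent-unit confusion
preserves the arc's half-maximum edges.

## Refinement protocol

`refine_iterate` follows the standard gold-standard scheme: records are
split into half-sets A/B (alternating ids), each half is aligned against
its own average, the worst `1 − keep_fraction` of particles (default 20%)
are excluded each iteration (ties break toward the lower particle id;
previously excluded particles are re-eligible), and the halves are
re-averaged with Cn symmetrization (mean over the n rotations about z).
The alignment reference is low-passed on a schedule linear in spatial
frequency from `lowpass_start` (default 40 Å) to `lowpass_final` (default
2.5× pixel).  Holding the filter at 40 Å makes the alignment
membrane-dominated — exactly what the flexibility analysis wants from its
"global" stage.  A divergence guard aborts if the mean score drops by more
than 0.1 between iterations.  FSC between the final half-maps is read at
0.143 (configurable); resolution is the linear-interpolated first crossing,
or the Nyquist wavelength if the curve never crosses.

## Analysis conventions

* Orientations are canonical unit quaternions (w ≥ 0), serialized as four
  text columns at 9 significant digits so metadata round trips are
  byte-stable.  The 180° flip is fixed about the particle-frame x axis;
  for a Cn particle any in-plane axis is equivalent up to a symmetry
  element, fixing x just makes results deterministic.
* The facing test is `dot(v, axis) > 0` with `v` the unit vector from the
  particle to its tomogram's pick centroid (negated under `invert`).  Dot
  products within 1e-9 of zero are undecidable: the particle is left
  unflipped and counted in a warning budget rather than silently
  randomized.  The centroid can be overridden per tomogram for non-convex
  cells, where the heuristic can misassign vectors.
* Radius measurement excludes the on-axis bin from the argmax and breaks
  ties toward the smaller radius; the default measurement low-pass is
  40 Å.  Histogram peaks are local maxima above 10% of the modal count
  with ≥5% prominence — thresholds chosen here to make "one peak vs two"
  reproducible where the source workflow inspected the histogram visually.
* `arc_occupancy` thresholds the azimuthal rim-band profile at a stated
  fraction of its span above the profile minimum (the band unavoidably
  contains flare-wall and membrane baseline); near-uniform profiles (span
  < 5% of the maximum) count as fully occupied.  Occupancy is always
  reported together with its threshold, since the value is threshold
  dependent by construction.
* Symmetry relaxation scores exactly the n discrete unit offsets (no finer
  azimuthal search by default), keeps every axis direction mathematically
  unchanged, and re-averages at the assigned orientations without
  symmetrization.  The C1 reference can be seeded from focused
  classification (random half-splits scored by masked variance) or, in
  planted tests, from the generator phantom.
* Focused refinement runs exactly one iteration (no convergence loop).
  Trajectory intervals are equal-width over [0, max tilt] by default
  (equal-population quantile edges are available); endpoints are the first
  and last non-empty classes and the endpoint separation is the difference
  of their mean member tilts.  The unsigned axis metric is symmetry
  invariant by construction.
* Two-reference classification flips the reference about x (consistent
  with the flip convention), warns when the reference is self-similar
  under the flip (classes unidentifiable), and assigns exact ties to class
  0.

## Numerical choices

Trilinear interpolation throughout (adequate at 5 Å/voxel and keeps every
oracle comparison simple); volumes are float32 on disk (MRC2014, pixel size
in the header cella fields, creation label cleared for byte-identical
reruns) and float64 in computation; all Fourier operations use the
unshifted FFT layout with analytic frequency-domain masks.  Every source of
randomness flows from a single integer seed through `numpy`'s `SeedSequence`
machinery; identical configurations are bit-reproducible, which the
pipeline verifies by content-hashing every output into its manifests.

## Known limitations

Averaging does not wedge-compensate (no per-voxel Fourier weighting); at
the default near-top-view geometry a missing cone persists in averages and
slightly anisotropizes them.  The exclusion metric equals the alignment
score (NCC against the current reference), the simplest reading of
"similarity to the averaged structure".  Exclusion is applied per
iteration; whether the original pipeline excluded once or per iteration is
not documented, so the frequency is configurable.  Orientation recovery in the
refiner is grid-limited (no sub-grid interpolation, keeping the brute-force
oracle equivalence exact); the focused-refinement polish alone performs a
parabolic sub-grid refinement of the tilt magnitude, because 0.5°
quantization otherwise clusters the per-particle tilts and distorts the
extreme trajectory bins that define the endpoint conformations.
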