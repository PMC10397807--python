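# Methods

This note documents the models, algorithms, default parameters and design
choices behind densfit, and what its synthetic benchmarks do and do not
demonstrate.

## Overview of the protocol

densfit automates one round of flexible refinement of an atomic model
against a cryo-EM density map:

1. **Rigid-body pre-alignment** of the model to the map by maximizing the
   normalized cross-correlation between the forward-modeled density and the
   target.
2. **Density-guided dynamics**: overdamped Langevin dynamics on a
   structure-based restraint potential plus a density-bias energy
   `E_bias = −k·S`, where `S` is the normalized cross-correlation and `k`
   follows adaptive force scaling.
3. **Frame selection**: the best stereochemical frame within the plateau of
   the FSC-average time series.
4. **Restrained minimization** of the selected frame (steepest descent with
   heavy-atom positional restraints).
5. **Validation**: FSC curve and FSC-average, a windowed local-quality score
   when half-maps are available, and the stereochemical score.

A calibration mode repeats step 2–4 over a grid of header-relabeled pixel
sizes with several seed models and selects the pixel size with the best mean
stereochemical score; a per-axis radius-of-gyration diagnostic detects
anisotropic stretch or compression against a reference structure.

## Forward model

Atoms are spread as isotropic 3D Gaussians of width σ, weighted by a
per-atom amplitude (default: atomic number), normalized so the map integral
equals the summed in-grid amplitudes.  The width follows the map sampling:

    σ = 2 × pixel_size × 0.425

(e.g. 0.68 Å at 0.80 Å/pixel, 0.731 Å at 0.86 Å/pixel).  Kernels are
truncated axis-wise at `cutoff_sigmas·σ` (default 4σ; the neglected tail is
below e⁻⁸ ≈ 3×10⁻⁴ of the peak) and evaluated on per-atom local stencils,
making the cost O(n_atoms), independent of grid size.  The gradient of the
bias energy is propagated analytically through the spread; finite
differences appear only as test oracles.

Multi-Gaussian electron scattering factors and B-factor-dependent widths are
deliberately out of scope: for the similarity measure used here (Pearson
correlation, invariant to affine intensity transforms) a single Gaussian per
atom captures what matters — position and relative weight.

## Restraint potential

The engine does not carry a molecular-mechanics force field.  Instead a
structure-based (elastic-network-style) topology is derived from the
starting geometry: harmonic bonds between heavy atoms within a cutoff at
their observed lengths, harmonic angles between connected bond pairs at
their observed values, and a one-sided harmonic contact repulsion between
non-excluded pairs closer than the sum of their element radii minus 0.4 Å.
Defaults: bond cutoff 1.9 Å for all-atom models (covalent bonds, C–S
included), stiffness 1000 kJ/mol/Å² (bonds) and 100 kJ/mol/rad² (angles).
Pseudo-atom fixtures use an elastic-network cutoff of 5 Å with softer
constants (200/40 by default; see "Synthetic systems" below).

This stand-in preserves the property the protocol depends on — increasing
fitting forces degrade measurable stereochemistry (bond/angle strain,
clashes) — without the cost or parameterization burden of a full force
field.  It does not model electrostatics, secondary-structure specificity,
or solvent; conclusions about real proteins require a real force field.

## Dynamics and adaptive force scaling

Dynamics is overdamped Langevin (Euler–Maruyama):

    x ← x + μ F Δt + √(2 μ k_B T Δt) ξ

with mobility μ (default 0.05 Å²/(kJ·mol⁻¹·ps), a coarse-grained effective
value; the desk-scale benchmarks use 0.2, i.e. accelerated effective time as
is common for coarse-grained models), timestep 2 fs, and a per-step
displacement clamp of 0.25 Å per atom.  The clamp is a trust radius: when
the adaptive force constant saturates, forces can exceed what any fixed
timestep integrates stably, and clamping converts those episodes into
bounded gradient steps instead of blow-ups.  Runs at T = 0 with the bias
frozen at zero reduce to pure restraint relaxation.

Adaptive force scaling follows the similarity feedback rule: every feedback
interval Δt_fb, if the similarity did not increase, `k ← k·exp(Δt_fb/τ)`,
otherwise `k ← k·exp(−Δt_fb/τ)`, clamped to (0, k_cap].  Defaults: k starts
at 10 kJ/mol, τ = 4 ps, evaluation every 2 ps, 300 K, termination at 3 ns or
when k reaches 10⁶ kJ/mol.  (The starting value is printed ambiguously in
the protocol literature as "10e 1"; densfit reads it as 10 kJ/mol and makes
it configurable.)  The controller's behavior is worth understanding: it
equilibrates k near the smallest value that still makes progress against
thermal degradation, so k rises while the model lags the map and falls while
it catches up; runs end either at the time limit or because k has grown to
its cap ("excess adapted forces").

## Metrics

* **Similarity** — Pearson correlation of voxel values; unmasked by default
  (an optional mask restricts the statistics).
* **FSC** — per-shell normalized correlation of the 3D DFTs on unit-width
  integer-frequency shells; shell s has center frequency s/(N·p).  Shells
  where both maps have zero power report FSC = 1; where only one has power,
  FSC = 0.  The **FSC-average** is the arithmetic mean over shells up to the
  threshold frequency (default threshold 2.88 Å), the simplest faithful
  reading of an averaged-to-threshold FSC summary.
* **Local quality** — a clearly simplified analog of half-map-based local
  quality scores (FSC-Q-like): the grid is tiled with non-overlapping cubic
  windows (default 15 voxels, edge tiles re-anchored to stay cubic); each
  window's score is mean windowed FSC(model map, full map) minus mean
  windowed FSC(half1, half2).  The ±0.5 interpretation bands are preserved,
  but this is not the published FSC-Q algorithm and is not expected to
  reproduce deposited FSC-Q values.
* **Stereochemical score** — total = 10·bond_rms(Å) + 5·angle_rms(rad) +
  0.1·clash_per_1000, lower is better; weights chosen so typical well-
  refined fixtures score ≈ 0.5–1.5, configurable.  It plays the role of a
  knowledge-based model-quality potential in frame selection and pixel
  calibration; an external scorer (e.g. a GOAP executable) can be plugged in
  as a drop-in replacement, and its absence never breaks the default path.
* **Radius of gyration about an axis** — mass-weighted RMS perpendicular
  distance from the axis through the center of mass.  Ratios against a
  reference model are exactly s for a uniformly s-scaled copy, the founding
  property of the pixel-size diagnostic.

## Frame selection

The plateau is the superlevel set `fsc_avg ≥ (1 − ε)·max` (ε default 0.01);
within it, the frame with the lowest quality score wins, ties broken by
earliest time.  The superlevel-set definition admits non-contiguous
plateaus; it reduces to the intuitive late-trajectory plateau whenever the
FSC-average is monotone-then-flat.

## Pixel-size calibration

A mislabeled pixel size uniformly rescales every physical length the map
implies.  Relabeling is header-only (no resampling): voxel values are
untouched and extent and origin scale by new/old.  For each candidate pixel
size the spread width is recomputed from that pixel size, each seed model is
aligned and fitted, the plateau-best frame scored, and the per-pixel mean ±
standard error tabulated; the minimum of the mean selects the pixel size.
Seed models are snapshots of an unbiased (k = 0) dynamics run, spaced by a
configurable interval (default 4 ps).  Failed runs degrade to (n−1)
averaging rather than aborting the scan.

## Synthetic systems

The fixture generator builds pseudo-atom β-barrel-like models: one CA-like
bead per residue on a cylinder (default 4.7 Å strand separation, 3.8 Å bead
spacing, tilted strands), a self-avoiding random coil, or a two-chain barrel
dimer.  Beads carry residue-specific amplitudes (seeded, uniform ±70% around
the carbon value — real side chains span roughly glycine to tryptophan, a
~3.5× electron-count range); without this contrast the density is invariant
under bead permutation and fits can settle in register-shifted states that
real side-chain density forbids.  Target maps are forward-modeled densities
plus seeded Gaussian voxel noise; half-maps carry independent noise inflated
by √2 so that their average reproduces the full map's noise level in
expectation.  Model perturbations are spatially smooth random displacement
fields (sinusoidal modes, ~12 Å correlation length, net rigid-body component
projected out by superposition) rescaled to an exact RMSD: they emulate a
conformational offset between a starting model and a target state while
leaving local geometry intact, which is what separates a crystal-structure
start from a cryo-EM target.  All outputs are bit-reproducible from
(spec, seed).

What these fixtures emulate: the geometry-scale coupling that drives
pixel-size calibration, the similarity/stereochemistry trade-off that drives
frame selection, and half-map noise statistics.  What they do not emulate:
real scattering contrast, solvent/micelle density, CTF effects, anisotropic
resolution, or all-atom chemistry.  Passing benchmarks therefore validate
the mechanisms of the protocol, not its performance on real micrograph-
derived maps.

### Desk-scale benchmark conditions

The reference benchmarks (`densfit.benchmark`) use a 36-bead barrel in a
32³ box at 0.84 Å/voxel, and compress the time axis relative to the
full-scale protocol: runs of 30–200 ps with feedback constant τ = 0.5 ps
and feedback every 0.5 ps, keeping the pacing of adaptive scaling relative
to total run length comparable to τ = 4 ps within 3 ns.  Mobility is 0.2
Å²/(kJ·mol⁻¹·ps) (accelerated coarse-grained time).  Because the similarity
of a 36-bead system fluctuates far more than that of a 100k-atom system,
per-frame metric series are noisier than in full-scale runs; benchmark
readouts therefore average over the converged tail of a trajectory.

The pixel-size scan scores each run by the mean stereochemical quality over
its FSC-plateau frames rather than the single selected frame: at 36 beads
the selected-frame score is dominated by frame-to-frame fluctuation, and
min-over-noisy-frames selection adds its own noise.  Runs are paired across
pixel sizes by common random numbers so the per-pixel comparison is not
masked by run-to-run variance.

The radius-of-gyration scaling benchmark uses a geometrically balanced
barrel (radius comparable to half-height, so the density displacement of a
uniform scale change is comparable on every axis) and a deliberately soft
elastic network (bonds 10 kJ/mol/Å², angles 2 kJ/mol/rad²).  The reason: the
adaptive controller pins the bias stiffness near the smallest value that
still makes progress (effectively ~100–200 kJ/mol/Å² per atom at this system
size), so the converged scale response is a bias-vs-network competition with
response fraction k·c/(k·c + k_net); a soft network is what lets a 32-bead
model track few-percent scale changes at all.  Measured at these conditions,
the compression case (map relabeled 3% smaller) converges within 1% of the
scale factor on all axes, while the stretch case reaches ~60–75% response on
its slowest axis and can fall a few parts in ten thousand outside the 1%
band — softer networks close that gap for most seeds but begin to collapse
in others.  This asymmetric, partial response is an intrinsic property of
the marginal-progress controller at toy scale, not of the diagnostic: the
full-scale protocol, with three orders of magnitude more atoms and hence a
far stronger collective density signal, supports proportionally larger
adapted forces.

## Numerical choices and degenerate inputs

* Constant maps are rejected (normalization, similarity) with a dedicated
  degenerate-input error.
* Atoms whose truncated kernel misses the grid contribute nothing and feel
  no bias force; if the whole model leaves the grid the bias force is zero
  and a warning is issued.
* Angle forces near θ = π clamp sin θ at 10⁻⁸ to avoid the gradient
  singularity of the harmonic angle potential.
* Minimization is steepest descent with a backtracking line search,
  terminating at max per-atom force < 10⁻⁴ kJ/mol/Å (the protocol's printed
  threshold appears once per energy and once per energy/length; densfit uses
  force units) or on step-size underflow.
* FSC requires cubic grids; pad upstream if needed.  Shell 0 (the mean) is
  included in the average, consistent with "mean over shells up to the
  threshold".
* Selection ties break to the earliest frame; ε is exposed because the
  plateau was defined visually in the source protocol.

## Known limitations

* The restraint engine is not a force field; absolute stereochemical scores
  are comparable only within a topology.
* The adaptive controller holds the bias at marginal progress, so the
  instantaneous fit quality fluctuates around a k-dependent equilibrium;
  single-frame readouts of slowly-varying geometric quantities are noisy at
  toy scale.
* The local-quality score is a simplified windowed variant, not the
  published FSC-Q.
* Pixel-size relabeling never resamples; workflows that need a resampled
  map must do so in reconstruction software.
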