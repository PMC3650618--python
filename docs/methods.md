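# Methods

## Signal model and deconvolution

A voxel's diffusion-weighted signal is modelled as arising from an ensemble
of Gaussian diffusion compartments whose tensors follow a mixture of Wishart
distributions. The Laplace transform of a Wishart over symmetric
positive-definite matrices yields a closed-form attenuation per mixture
atom, so the measured signal becomes linear in the mixture weights:

    S(b, g) / S0 = Σ_j  w_j  (1 + b gᵀ (D_j / p) g)^(−p)

* **Dictionary.** 162 atoms; `D_j` has eigenvalues (1.5, 0.4, 0.4) µm²/ms —
  a typical single-fiber tensor — with its principal axis on the j-th vertex
  of the level-2 icosphere. The (1.5, 0.4, 0.4) tensors are the *expected*
  tensors of the Wishart (D̄ = pΣ), so the design matrix uses Σ_j = D_j/p;
  this keeps the stated eigenvalues interpretable as physical diffusivities.
* **Shape parameter.** `p = 2` by default (exposed in `build_basis`). As
  p → ∞ the atom attenuation tends to the pure Gaussian exp(−b gᵀD g);
  finite p fattens the tail, reflecting tensor dispersion within the voxel.
* **Normalization.** Signals are divided by the mean of the b = 0 volumes.
  Low-b (b = 100 s/mm²) volumes are not baseline: they enter the fit as
  ordinary rows with their own b.
* **Inversion.** Non-negative least squares (Lawson–Hanson active set, via
  `scipy.optimize.nnls`), which terminates at exact KKT conditions and
  returns sparse weights. Degenerate voxels (all-zero or non-finite signal)
  are flagged with w = 0 rather than raising; negative normalized samples
  (possible under noise) are clipped to zero and counted.

## Displacement profile and peak extraction

The orientation information is read off the water-displacement probability
evaluated at a fixed probe radius on the sphere:

    P(r u) = Σ_j w_j (4πt)^(−3/2) |D_j|^(−1/2) exp(−r² uᵀ D_j⁻¹ u / (4t))

evaluated at the 642 level-3 icosphere vertices with r = 12 µm and
t = Δ − δ/3. The gradient timings Δ, δ are acquisition metadata that bval
and bvec files do not carry, so t defaults to 20 ms (typical for a spin-echo
EPI at TE ≈ 55 ms) and is configurable. Peak *locations* are what tracking
consumes, and for resolvable fiber configurations (single fibers, or
populations separated by ≳ 75°) the extracted peak set is identical for
t ∈ [15, 40] ms (property-tested). Two caveats, both verified empirically:
lobes closer than the kernel width merge, and the merged summit can drift by
roughly one grid vertex as t changes; and longer t flattens angular contrast,
so the separation needed to resolve two populations grows with t. Both
reflect the physics of displacement profiles, not implementation choices.

Maxima are found exactly as a discrete multi-start ascent: from each of the
42 level-1 vertices (an index-prefix of the nested level-3 mesh), move to
the edge-neighbor with the greatest PDF value while it improves on the
current vertex (ties go to the lower vertex index, for determinism). Summits
are folded for antipodal symmetry (canonical hemisphere = last nonzero
coordinate positive), deduplicated at 15° — the level-3 grid spacing is
≈ 8°, so closer "distinct" maxima are unresolvable on this grid — sorted by
PDF value and truncated to K = 3 per voxel. A constant PDF yields an empty,
isotropic-flagged peak set. There is no minimum-probability threshold by
default; an optional max/mean contrast filter (`min_peak_ratio`, suggested
1.02) is available to flag near-isotropic voxels, and is used on phantoms
whose background is isotropic by construction.

## Tracking

* **Seeding.** Per brain voxel, a 4×4×4 lattice at fractional offsets
  (k + 0.5)/4 — 64 seeds/voxel forming a globally uniform field continuous
  across voxel boundaries. By default one bidirectional streamline is
  launched per seed-voxel peak (`seed_mode="per-peak"`), which populates
  branching systems; `"primary"` launches along the top peak only.
* **Propagation.** Euler steps of 0.25 mm. At each step the current voxel's
  peak with maximal |d·m| is chosen (most inline with travel direction d,
  sign-aligned); ties within 1e-9 go to the higher PDF value, then peak
  rank. Peaks are voxel-wise constant (nearest voxel); the raw data is
  interpolated to 1 mm beforehand instead of interpolating the
  multi-directional peak field, which has no consistent interpolant.
* **Stopping.** Turn > 50° per step (applied per step, the stricter reading),
  brain-mask exit, stop-mask entry (the entry point is kept, so pathways
  terminate *at* their subcortical target), voxels without peaks, and a
  2000-step cap (≈ 500 mm per direction) as a cycle guard. Fractional
  anisotropy is never computed: it is ambiguous in crossing-fiber voxels,
  which are precisely where multi-peak tracking must continue.
* **Coordinates.** All tracking is in world mm through the NIfTI affine;
  voxel lookup is nearest-voxel (round of the inverse-affine image). b-vectors
  are taken in the image frame (FSL dialect), with no gradient reorientation.

## Connectivity and volumes

A streamline belongs to a pathway if ≥ 1 point lies in every inclusion mask
and none in any exclusion mask. Track volume is the number of distinct
reference-grid voxels visited times the voxel volume — the simplest
definition consistent with integer-valued mm³ volumes on a 1 mm grid; it is
invariant to streamline order and duplication. Across-participant summaries
are the mean and sample (n−1) standard deviation per pathway, with
participants in whom a pathway could not be traced entering as zeros (only
with zeros do the published summary statistics reproduce from their own
table; one published mean, 778.2 mm³ for the opercularis–thalamus column, is
inconsistent with its own data, which yield 683.6 — the package reproduces
the table-derived value).

## Synthetic phantoms

`phantom.simulate_dwi` renders tubes of fibers (polyline centerline +
radius) on a voxel grid with the same Wishart forward model used in
reconstruction, volume fractions splitting equally among overlapping bundles
and an isotropic compartment (0.8 µm²/ms, grey-matter-like) filling the
background. The acquisition scheme mirrors a clinical HARDI protocol: 64
directions at b = 1000 s/mm² (level-2 icosphere axes), 6 at b = 100, 2 at
b = 0, on a 2 mm isotropic grid, interpolated to 1 mm before fitting as in
the processing pipeline. Noise is Rician — magnitude MR — with SNR defined
as S0/σ at b = 0; `default 30`, a realistic 3 T value, with ∞ available for
geometry-only studies. Per-voxel ground-truth directions are rasterized on
any requested grid to score angular recovery after resampling.

The named phantom set covers each tracking regime: STRAIGHT (one bundle,
ROIs at both ends), CROSS90 (orthogonal crossing), BRANCH (40° Y-fork),
CURVE (a 90° sweep of 10 mm radius — ~1.4° per 0.25 mm step, far below the
50° limit), and DISJOINT (two parallel, disconnected bundles: the
false-positive control, whose two-ROI filter must return zero streamlines).
The standard set is generated noiseless — these phantoms validate geometry
recovery, and noise robustness is a separate axis studied by overriding
`snr`.

What phantoms do **not** emulate: realistic brain geometry and partial-volume
tissue mixtures beyond tube boundaries, susceptibility/eddy/motion
artifacts, spatially varying noise from parallel imaging, or axon-scale
features (dispersion, radii). Passing phantom tests therefore demonstrates
that the estimator and tracker are correct for the model they assume, not
that in-vivo pathways inferred with them are anatomically certain.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| eigenvalues | (1.5, 0.4, 0.4) µm²/ms | single-fiber atom tensor |
| p | 2 | Wishart shape parameter |
| t | 20 ms | effective diffusion time Δ − δ/3 |
| r | 12 µm | displacement probe radius |
| dedup | 15° | peak merge tolerance (grid spacing ≈ 8°) |
| K | 3 | max peaks per voxel |
| step | 0.25 mm | Euler step |
| max_turn | 50° | per-step turn limit |
| seeds/voxel | 64 (4³) | uniform lattice |
| max_steps | 2000 | ≈ 500 mm cycle guard |
| b0 / low-b split | 50 / 500 s/mm² | gradient-table partition thresholds |

Resampling is trilinear with center-aligned grids (output voxel 0 coincides
with input voxel 0), which reproduces constant and linear intensity fields
exactly; masks are resampled nearest-neighbor. Icosphere subdivision keeps
every level an index-prefix of the next and every vertex set exactly closed
under negation, so antipodal folding is bitwise exact. Hill-climb ties,
peak-sort ties and seed ordering are all resolved by index, making every
stage deterministic: identical inputs and seeds give byte-identical
tractograms and CSVs.

## Problem sizes

Tests and the acceptance script run phantoms of 10×4×4 to 13×9×4 voxels at
2 mm (19×7×7 to 25×17×7 after 1 mm interpolation; roughly 1–4 k fitted
voxels each), 8 seeds per voxel, and ≥ 500 noisy voxels for the SNR-30
angular-error study — small enough to run in minutes on one core while
exercising every code path at the same voxel/step/angle scales as a
full-resolution study.

## Known limitations

* Peaks live on the 642-point grid; no continuous (off-grid) refinement, so
  angular error is bounded below by the ≈ 4–8° vertex spacing.
* Angular resolution degrades with diffusion time (see above); fiber
  populations closer than ~45–75° (depending on t) merge into one lobe.
* Tracking is deterministic; no uncertainty quantification or probabilistic
  variant, and no formal null distribution exists for tractography claims —
  the DISJOINT phantom provides an engineering false-positive control, not a
  statistical test.
* Eddy-current correction, skull stripping, registration and anatomical
  mask delineation are upstream of this package.
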