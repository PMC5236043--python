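# Methods

## Phantom model

The phantom emulates a wall-less multi-sphere contrast-sweep experiment.
Twelve spheres (diameters 10, 10, 6, 6, 12, 4, 10, 3, 8, 4, 4, 6 mm) of
uniform ¹⁸F concentration sit on a line ("string") inside a box of
¹¹C-loaded background medium; a separate box of sphere-strength ¹⁸F acts
as reference source. Two fixed measurement regions mirror the analysis
protocol: a nominal 6-mL box VOI inside the reference source and a nominal
15-mL box VOI inside the background. Half-lives are the physical constants
T½(¹⁸F) = 109.77 min and T½(¹¹C) = 20.36 min. Both media start at equal
concentration (1:1), and the true sphere-to-background ratio of frame k is
the ratio of frame-averaged concentrations

    c̄ = c₀ · 2^(−t₀/T½) · (1 − 2^(−Δt/T½)) · T½ / (Δt·ln 2),

which rises from 1.14 (frame 1 of a 1:1 start; the background decays
noticeably *within* the first 10-min frame) to ≈ 15 by frame 10. For
unit-contrast identity checks, `with_unit_frame_contrast` raises the
background start concentration by that 1.145 factor so the first frame's
frame-averaged ratio is exactly 1 (the instantaneous ratio crosses 1
mid-frame).

Geometry defaults: 2.0-mm isotropic voxels; sphere centers snapped to
voxel centers (deterministic VOIs; a configurable offset exists for
robustness studies), 24-mm center spacing along the grid's z axis;
background cross-section 48 × 48 mm; 18 mm (= 4 × system FWHM) of empty
margin around all active material. The grid is sized from the sphere
string rather than fixed, because a 12-sphere string at 24-mm spacing
needs ~290 mm of axial extent. Spheres are rasterized wall-less: each
voxel takes a volume-weighted mix of sphere and background concentration
from sub-voxel center counting. The experiment pipeline subdivides 8³
sub-voxels per voxel: center counting at 4³ misestimates the painted mass
of near-voxel-size spheres (+20% for 3 mm, +4% for 4 mm on a 2-mm grid),
while 8³ keeps every diameter within ~1.5% and 16³ within 1%.

Two phantom variants are built by the same constructor: the full
twelve-sphere set (`default_phantom`) and a reduced *study* phantom with
one sphere per unique diameter {3, 4, 6, 8, 10, 12} mm (`study_phantom`).
The experiments and the acceptance script use the study phantom: every
reported quantity is a per-diameter curve, the duplicate diameters of the
full set matter only for phantom-production error bars (replaced here by
seeded noise replicates), and the shorter string cuts the axial slice
count by ~40%.

## Acquisition model

The scanner's resolution is a single isotropic Gaussian of 4.5 mm FWHM
(between the two clinical systems' NEMA FBP resolutions of 4.4 and
4.7 mm), applied in image space; positron range, crystal effects and
acollinearity are not modeled separately. Data are emitted as
already-corrected, mean-preserving Poisson counts — attenuation, scatter
and randoms never enter. Projection is slice-wise 2D parallel-beam with
336 angles over 180° (336 = lcm(16, 21), so both clinical subset counts
partition the angle set exactly) and radial bins at the voxel pitch. The
projector is pixel-driven: each voxel splats onto the two radial bins
straddling its projected position with linear weights summing to one,
scaled by voxel area / bin width. Consequences: total counts are conserved
exactly at every angle, the EM sensitivity (backprojection of ones) is
exactly flat inside the field of view, and the sparse transpose is the
exact adjoint. Time-of-flight is out of scope.

Counts per frame default to 4×10⁸ per 48 axial slices (scaled to the
actual stack), with later frames receiving counts in proportion to their
decayed total activity. The level is a free parameter of the study — the
physical experiment reports no count statistics — and was calibrated to
the observed regime of the physical data: at unit contrast the max-based
metrics must recover 1 within a few percent in *both* reconstruction
modes (at 2×10⁶–10⁸ per 48 slices, noise biases A_max/A_50bg upward by
10–30%), while replicate scatter at high contrast stays measurable. At
the default level the replicate SD of RC_50bg is 0.3–2%, smaller than the
error bars of physical phantom repeats; the *comparative* dispersion claim
(PSF noisier than non-PSF) is unaffected, but absolute SD magnitudes
should not be read as calibrated to any particular scanner.

## Reconstruction

Standard OSEM, `x ← x/s_j · B_jᵀ(y_j / B_j x)` per subset j, subsets
interleaved over angles and visited in a fixed bit-reversed order; MLEM is
the subsets=1 case, for which the Poisson log-likelihood trace is
monotone. The initial image is the uniform constant satisfying
Σ s x₀ = Σ y. Resolution modeling is purely image-space: B = P∘G with G a
Gaussian of `psf_fwhm` (default matched to the 4.5-mm system blur) applied
before projection and, adjointly, after backprojection — the simplest
member of the resolution-modeling family, sufficient to reproduce its
artifact class; sinogram-domain kernels are not implemented. The Gaussian
post-filter is applied once after the final iteration (vendor conventions
are ambiguous; applying it between iterations would change convergence).
Division guards use ε = 10⁻¹² × max of the current expectation. Gaussian
blurs use a symmetric kernel truncated at 6σ with zero-padded boundaries,
making the operator self-adjoint to machine precision and the semigroup
property (a then b ≡ √(a²+b²)) hold to ~10⁻⁷ for σ ≳ 1 voxel.

## Quantification

Per-sphere VOIs contain the voxels whose centers lie strictly inside a
sphere of the physical diameter (nearest-voxel fallback when empty). On
the 2-mm grid the 3-mm VOI is a single voxel, and so is the 4-mm VOI —
its radius exactly equals the grid pitch, so the strict inequality
excludes the six face neighbors; this boundary tie is intentional and
documented rather than resolved by ≤. The isocontour metric uses the
background-corrected convention T = bg + 0.5·(A_max − bg) (the standard
EARL-style form; the experiment names the metric but not the formula),
with support restricted to the sphere VOI and the background taken from
the same frame's 15-mL VOI. The 6- and 15-mL "cube" VOIs are realized as
near-cubic integer-voxel boxes with exactly the nominal voxel count (750
and 1875 voxels at 2 mm). True concentration for RCs defaults to the
measured reference-VOI mean ("measured-truth", as a physical scan is
analyzed); an analytic "oracle-truth" mode is exposed for simulation-only
studies.

## Experiments and diagnostics

* **Contrast sweep** — ten 10-min frames from t = 0; per frame: simulate,
  reconstruct with each configured variant, measure all spheres.
* **Iteration sweep** — one frame (nearest a target ratio, default 8:1)
  simulated once; OSEM keeps per-iteration snapshots and every snapshot is
  post-filtered with each width, so one run covers the full grid.
* **Reproducibility** — N seeded noise realizations of one high-contrast
  frame (default nearest 13:1); reports per-sphere mean ± SD.
* **Diagnostics** — monotonicity of RC versus diameter uses non-strict
  ordering with a 0.02 RC tolerance band (configurable, reported) to
  absorb sampling jitter; the filter scan returns the smallest tested
  post-filter restoring monotonicity, optionally also requiring all
  RC ≤ 1.

Seeding: every frame × replicate gets a child seed derived from the
experiment seed via `numpy` SeedSequence, so identical configurations are
bit-identical and replicates are independent.

## Known limitations

* Only the ¹¹C-background arm is simulated; medium-dependent positron
  range (air vs silicone orderings) is not modeled.
* 2D slice-wise projection without oblique planes or TOF; the GE-arm
  findings are treated as qualitative replication of the same artifact
  class.
* With resolution modeling, RC_50bg of the 10–12 mm spheres shows a small
  early-iteration transient (the uniform initialization overshoots before
  the edge profile forms) instead of the strictly increasing
  iteration curves of the physical data; sub-centimeter spheres and all
  non-PSF curves do increase monotonically.
* In this simulator the post-filter restoring full monotonicity at 4
  iterations comes out at 4–6 mm depending on the noise realization,
  versus 3–4 mm on physical scanners — wider than 2 mm in both cases, but
  the exact width is kernel- and noise-specific.
* Synthetic-noise SD magnitudes are not scanner-calibrated (see
  Acquisition model); only comparative noise statements are meaningful.
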