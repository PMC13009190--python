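# Methods

This note documents the models, numerical choices, defaults, and known
limitations of the package.  It states no empirical result that the test
suite or acceptance script does not itself compute.

## Forward signal models

All signals are computed relative to S₀ = 1 in units of ms/µm² (b),
µm²/ms (diffusivities), µm (radii), and ms (pulse timings).

**Tensor.**  S = exp(−⟨B, D⟩_F) with B = b ggᵀ.  MD is the eigenvalue
mean; FA the normalized eigenvalue standard deviation
√(3/2)·‖λ−λ̄‖/‖λ‖, defined as 0 for an all-zero tensor; the principal
eigenvector is sign-canonicalized (first nonzero component positive).

**Dispersed stick.**  Three non-exchanging compartments: a
Watson-dispersed stick, an extracellular zeppelin, and free water.  The
Watson-stick integral is evaluated by Gauss–Legendre quadrature of order
64 in cos θ combined with a 48-point trapezoidal azimuth average; the
azimuthal factor is independent of the concentration κ and is cached per
voxel during fitting, reducing each objective evaluation to a small
weighted sum.  Quadrature error against a dense reference is below 1e-11
for κ ≤ 128 (the fitting bound is κ ≤ 64); above κ = 512 the coherent
stick limit exp(−b d_∥ (g·μ)²) is used, because the polar rule cannot
resolve the Watson peak there.  The zeppelin uses the standard
tortuosity constraint d_⊥ = d_∥ (1 − f_in) and is averaged over the
Watson distribution at the tensor level, with the second orientation
moment E[(n·μ)²] from the confluent hypergeometric expression (an
asymptotic branch beyond κ = 300 avoids overflow).  d_∥ = 1.7 and
d_iso = 3.0 µm²/ms are fixed.  ODI = (2/π) arctan(1/κ), with ODI(0) = 1
by the limit convention.

**Powder soma/neurite model.**  Fitted on per-shell direction averages
(the direction average of any oriented stick mixture is orientation-
distribution-independent, so the powder stick term
√(π/4bd)·erf(√(bd)) is exact).  The soma compartment is an impermeable
sphere under the Gaussian phase distribution (GPD): the Murday–Cotts /
Balinov series over the roots of j₁′(x) = 0, truncated at 20 roots by
default with a tail check that warns when the last term is non-
negligible.  Intrasoma diffusivity is fixed at 3.0 µm²/ms.

*GPD validity.*  Against a validated particle random-walk oracle
(100 000 walkers; the oracle reproduces the free-diffusion closed form
to sampling precision), the GPD series agrees within 1% for encoding
strengths with q·r_s of order one — e.g. (r_s, b) = (3 µm, 4.0),
(5 µm, 2.4), (7 µm, 1.2) at δ/Δ = 7/24 ms.  At stronger encoding the
Gaussian-phase assumption itself breaks down: the measured signal
overestimate is ≈18% at (8 µm, 4.0) and ≈23% at (10 µm, 6.0).  This is
a property of the approximation — which is also what SANDI-type fitting
uses as its estimand — not of the series implementation; apparent soma
radii at the largest radii/shells should be read accordingly.

**Pulse timings.**  δ = 7 ms and Δ = 24 ms by default (typical of
strong-gradient multishell protocols) and fully configurable; absolute
soma-radius values depend on this choice.

**Gradient directions.**  Per-shell direction sets are deterministic
Fibonacci lattices refined by electrostatic repulsion between antipodal
charge pairs.  The worst-case equal-weight powder error of the 60-point
set for a stick at b·d ≈ 10 is a few parts in a thousand to ~1%
depending on orientation; self-consistency fitting tests therefore
generate powder-consistent signals, while the end-to-end study absorbs
this (age-independent) discretization bias.

## Fitting

**Tensor**: weighted linear least squares on log-signals of the b ≤ 1.2
shells (weights = squared observed signals), batched over voxels;
non-positive signals are excluded per voxel, fewer than 7 usable volumes
fails the voxel, and negative eigenvalues are clamped to zero with a
flag.

**Dispersed stick**: bounded trust-region least squares over
(f_iso, f_in, κ) per voxel with the orientation fixed to the principal
tensor eigenvector (or supplied), 5 seeded Latin-hypercube starts, best
final cost wins.

**Powder soma/neurite**: the five free parameters
(f_ec, f_in, r_s, d_in, d_ec) are bounded to [0,1], [0,1], [1,12] µm,
[0.1,3] and [0.1,3] µm²/ms.  Multi-start proceeds by evaluating 256
seeded Latin-hypercube candidates vectorized across voxels, refining the
best 16 per voxel with a bounds-projected Levenberg–Marquardt (analytic
Jacobian, batched over voxel × start), and optionally polishing each
voxel's winner with a trust-region solve.  Ties break by first start
index.  Voxels failing any fit are flagged and excluded downstream.

*Why an optional prior.*  At the study noise level (snr = 50 on b = 0)
the powder model is sloppy: the box-scaled Jacobian at a gray-matter
operating point has two singular directions (an f_ec/f_in trade-off and
d_in) below the powder noise floor, and the Cramér–Rao bound for the
neurite fraction alone is ≈0.37.  The unregularized maximum-likelihood
estimator is then dominated by crosstalk: controlled known-truth
simulations show it retains essentially none of an injected neurite-
fraction age slope and leaks systematic age trends into the (truly
flat) soma fraction.  `fit_sandi` therefore accepts a Gaussian prior
over the parameter box (a maximum-a-posteriori estimate; zero weight —
the default — reproduces pure NLLS).  The pipeline profile uses
per-parameter weights (0.01, 0.01, 0.015, 0.03, 0.01) in box units,
calibrated on controlled simulations to minimize crosstalk into the
null soma component while retaining the injected slopes; this mirrors
the practice of machine-learning SANDI estimators, which are implicitly
regularized by their training prior.  The estimator uses a fixed
internal seed, so it is the same function of the data in every
replicate.

## Geometry

Conventions: 0-based voxel indices, native coordinates at voxel centres
((i + 0.5)·h mm), unfolded coordinates in [0,1]².

The Laplace fields are solved by red-black successive over-relaxation
(ω = 1.9) on the gray-matter mask with Dirichlet layers (0/1) on the
source/sink faces and no-flux behaviour on other walls (averaging over
in-mask neighbours only); iteration stops when the update max-norm falls
below 1e-6.  Gradients use central differences inside the mask and
one-sided stencils at walls, scaled by voxel size.

The midthickness surface places a regular n_AP × n_PD unfolded grid
(default 121 × 60 = 7260 vertices, the closest regular factorization to
the 7262-vertex convention of hippocampal unfolding tools) at the
solution of (ψ_AP, ψ_PD, ψ_IO) = (u, v, 0.5), found per grid point by a
nearest-voxel seed plus damped Newton iterations through the
trilinearly interpolated coordinate fields (the fields are extended one
voxel beyond the mask by nearest-neighbour fill).  This solves the same
equations as sliding along the inner–outer streamline while matching the
in-plane coordinates, and is exact on a rectangular slab; vertices whose
residual coordinate mismatch exceeds 0.02 are flagged invalid.  Subfield
labels are five equal proximal–distal bands (Sub, CA1, CA2, CA3,
DG/CA4) and long-axis labels five equal AP bands — configurable stand-
ins for atlas-propagated boundaries.

Thickness is the arc length of the inner–outer streamline through each
vertex (RK4 through the normalized ∇ψ_IO, step 0.25 voxel).
Gyrification is the native/unfolded vertex-area ratio with both areas
normalized by their surface totals, so an undistorted mapping gives
exactly 1.  Subfield volume counts gray-matter voxels per ψ_PD band
times the voxel volume and sums exactly to the total gray-matter
volume.  Surface sampling uses the enclosing voxel (no interpolation);
vertices outside the mask are missing values.

## Synthetic study

The generator is the study definition, not a tuning knob.  Defaults:
88 participants aged 8–19 years (uniform by default; a right-skewed
option emulates denser sampling of the younger range), 42/88 male, two
hemispheres each; six-shell protocol as above; Rician noise with
σ = S₀/snr, snr = 50; ages centred at 13.5 years so intercepts are
mid-cohort means.

Ground truth is parcel-wise linear in age with sex offsets, age-by-sex
interactions, and participant-level Gaussian residuals; values are
clipped to physical bounds with clipping counted.  The effect spec
drives the *derived* fractions: f_neurite and f_ec get mirrored slopes
(+0.006 and −0.006 per year, with mirrored ±0.002 age-by-sex terms), so
fsoma = 1 − f_ec − f_neurite has an exactly null age trend by
construction; the intracellular stick fraction is recovered as
f_in = f_neurite/(1 − f_ec).  The extracellular diffusivity declines
with age with a slope that steepens along the long axis
(−0.006 … −0.018 µm²/ms per year across the five AP bins), localizing
the diffusivity (MD) age effect to the AP axis; soma radius declines
slowly (−0.05 µm/yr); dispersion is age-flat (κ ≈ 1, ODI ≈ 0.5).
Mid-cohort means (f_neurite ≈ 0.23, f_ec ≈ 0.35, r_s ≈ 7 µm,
d_ec ≈ 1.0) sit in the ranges reported for hippocampal gray matter, and
residual SDs put parcel-level age correlations of the fitted metrics in
the |R| ≈ 0.5–0.8 range at n = 88 (the worked example in the README
shows one seed's values).  The stick orientation field is the analytic long-axis tangent
(a coherent field aligned with AP).

The domain is a curved gray-matter slab — topologically correct, with
labelled boundary faces and analytic coordinates retained for testing —
not realistic hippocampal anatomy (no SRLM, no atlas subfields, no
scanner artefacts beyond Rician noise).  The end-to-end study uses one
canonical anatomy (a fixed domain seed chosen for full surface validity
and balanced long-axis parcel coverage); replicates vary the cohort
draw and the noise.  Macrostructure (thickness, gyrification, volume)
is shared geometry scaled per subject by a seeded log-normal factor
(SD 0.05) with no age trend, emulating inter-individual anatomical
variability under the null that macrostructure is age-stable.

What passing tests therefore do and do not show: they demonstrate that
the measurement-and-analysis chain recovers known injected effects at
realistic noise, sample size, and geometry; they do not validate the
biophysical models against real tissue, tissue heterogeneity within
parcels, segmentation error, or registration error.

## Statistics

Hemisphere averaging precedes parcel statistics and is gated per metric
on a non-significant age-by-hemisphere interaction (configurable
override).  Age associations are two-sided Pearson correlations with
the asterisk ladder 0.01 / 0.005 / 0.0005 (0.01 being the Bonferroni
per-test alpha for the five-subfield family at family-wise 0.05); the
ladder is metadata — raw p-values are always emitted.  Interaction
tests compare a full and a reduced linear model (treatment coding,
alphabetical reference levels) by
F = ((SSE_red − SSE_full)/Δdf)/(SSE_full/df_full), with
Benjamini–Hochberg adjustment within each declared metric family;
degrees of freedom come from the fitted designs, and a numerically
perfect full fit yields infinite F with a warning.

Vertex-wise age contrasts fit DV ~ age + sex + age:sex per vertex by
OLS and report t = β̂_age/SE; missing participants are dropped per
vertex, zero-variance vertices are masked, exact fits flagged.
Positional gradients are the unfolded coordinates themselves; the
gradient summary reports |R| against each plus the mean |t|.  The spin
test builds its null from toroidal translations plus independent axis
flips of one map on the unfolded grid — rigid transforms that preserve
spatial autocorrelation — with the two-sided finite-sample p
(1 + #{|R_null| ≥ |R_obs|})/(n_perm + 1); 2500 permutations at full
scale, fewer in the reduced profile.  Reference maps ship as seeded
synthetic Gaussian random fields (white noise smoothed with a 4-grid-
unit kernel, standardized) standing in for published myelin/histology/
synaptic-density maps, which are not redistributed; any user-supplied
per-vertex map on the same grid can replace them.

## Problem sizes

The default test-suite and demonstration sizes are chosen to keep a
full run in minutes on one CPU while preserving the study structure:
the reduced pipeline profile uses 12 participants, a 20×14×10 grid, a
25×15 surface, and 200 spin permutations; the end-to-end sign-recovery
replicates use n = 88 participants with a 15×10 surface (~100 fitted
voxels per hemisphere) and batched fitting across all hemispheres;
recovery checks use 500 voxels, calibration checks 500–1000 null
simulations, and the spin-test calibration 500 replicates at 199
permutations.  The full-scale profile (88 participants, 2500
permutations, 121×60 surface) is a named preset.

## Known limitations

* The GPD sphere approximation overestimates the signal at strong
  encoding (measured above); apparent soma radii inherit this.
* Compartment T2 differences are ignored: all fractions are signal
  fractions, not volume fractions.
* The powder model at snr = 50 is intrinsically sloppy along two
  parameter directions; unregularized estimates of the fractions are
  extremely variable, and the MAP profile trades a small, calibrated
  shrinkage bias for stability.
* The spin-test transform family (toroidal shifts + flips) is a
  documented stand-in for published hippocampal spin-test mechanics,
  chosen because it preserves autocorrelation on a rectangular grid.
* No realistic anatomy, no scanner artefact simulation, no exchange
  between compartments, no nonlinear age models.
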