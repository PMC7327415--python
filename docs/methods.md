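# Methods

## Scope and model of the data

`slimspore` implements the computational pipeline for quantifying the
sporulation phosphatase SpoIIE in single live *Bacillus subtilis* cells
from two-channel Slimfield microscopy: channel 1 images SpoIIE-mYPet,
channel 2 the lipophilic membrane stain FM4-64, at 5 ms/frame and
80 nm/pixel with a ~250 nm FWHM point spread function (PSF) and a ~350 nm
depth of field. Because no raw microscopy is distributed, every estimator
is validated against a synthetic-data module that emulates the imaging
physics with known ground truth.

## Synthetic Slimfield generator

A cell is a hollow cylinder of width 0.9 µm capped by hemispherical
shells, with 1-pixel-thick walls; fluorophores are placed uniformly by
surface area (seeded) at a default density of 4000 µm⁻², which
approximates the deterministic integral of the PSF over the model surface
while keeping the Monte-Carlo texture below the segmentation thresholds.
Stage-specific spore features are added at the pole-side end:

| stage   | mYPet feature                                            | FM4-64 feature |
|---------|----------------------------------------------------------|----------------|
| I       | none                                                     | none (membrane only) |
| II_i    | cell-width disk septum                                   | same disk |
| II_ii   | released-SpoIIE envelope: polar hemispherical shell (r = 280 nm) closed by the septal disk, joined by the forespore's cylindrical flank | flat disk septum |
| II_iii  | hemispherical engulfment dome (r = 420 nm, apex toward the mother cell) | same dome |
| III     | spherical spore shell (r = 330 nm)                       | same shell |

The septum plane sits 300 nm from the pole-side cap base; body length is
drawn uniformly from 2.0–3.0 µm per cell. Septal and engulfment membrane
carries twice the FM4-64 density of the lateral wall (double leaflet),
which is what lets a 3-class Otsu separate the feature from the membrane
outline. The FM channel shows the *membrane* topology, so in stage II_ii
it renders the still-flat septum while the mYPet channel renders the
released envelope — exactly the combination the stage table keys on.

Rendering: each emitter contributes a 2D Gaussian of σ = FWHM/2.355
normalized to its photon count by the discrete kernel sum (photons are
conserved on the grid). Emitters within ±DOF/2 of the focal plane render
at nominal width; beyond that the width grows linearly with defocus
(slope 1 per DOF/2) and the amplitude renormalizes, producing the diffuse
out-of-focus haze seen over real cells. Noise is Poisson shot noise about
expectation + a constant camera offset, plus optional Gaussian read
noise; the presets `average` (offset 20, read σ 2) and `extreme`
(offset 80, read σ 10) are configuration-defined severities, not a
measured camera calibration. All stochastic operations are reproducible
given their seed.

What the generator does not emulate: EM-gain excess noise, chromatic
aberration or channel crosstalk, fluorophore blinking/maturation, cell
crowding or debris, and real biological variability of feature shapes.
Passing the validation therefore shows the *algorithms* are correct and
self-consistent at realistic SNR, not that classification of arbitrary
real micrographs reaches the same accuracy.

## Stage categorization

The classifier follows the 12-step procedure: coarse Otsu threshold on
the reference channel, largest component, rotation to the horizontal;
sausage (rectangle + two hemicircles) dimensions from the half-maximum
crossings of the membrane-ridge profiles, pulled in by the PSF half-width
(1.177 σ), with the transverse direction restricted to the central half of
the cell so the row profile ignores polar features — this recovers length
and width to within ~2 px on synthetic truth. A 3-class (double
threshold) Otsu on the 5-frame average defines candidate components above
the upper threshold inside the cell mask; acceptance requires centroid
within 40% of either cell end, within ±40% of the half-width of the
midline, area > 10 px, and (an addition, see below) mean intensity at
least twice the median in-cell intensity; the brightest survivor wins,
with one retry against the lower threshold excluding first-pass regions.
Absence of an mYPet feature means stage I. Features are ellipse-fitted;
aspect ratio > 1.2 ⇒ 'septa', else 'filled'.

Curvature of a 'septa' feature uses the dimensionless metric
κ = sagitta/(chord/4), which scores a flat septum ≈ 0 and a semicircular
midline exactly 2, straddling the decision threshold of 1. On rendered
images the steep ends of a curved septum are biased straight by
transverse PSF mixing, so the sagitta is estimated by circle-fitting the
intensity-weighted centerline of the bright arc over its central 70% and
evaluating the fitted circle across the full feature chord; a direct-bend
guard (< 0.5 px) short-circuits genuinely flat septa so the extrapolation
cannot amplify centerline noise. On ideal masks the metric reduces to its
anchors (straight → 0, semicircle → 2) and is rotation- and
translation-invariant.

Stage assignment: I if no mYPet feature; II_i if both features 'septa'
with κ < 1; II_ii if FM 'septa' and mYPet 'filled'; II_iii if both
'septa' with κ > 1; III if both 'filled'; anything else indeterminate.

The contrast gate (2× median) is needed because the synthetic stage-I
mYPet channel is *empty*: under a noise preset, Otsu thresholds computed
on pure noise otherwise produce speckle components that occasionally pass
the geometric rules. Any real septal or forespore structure exceeds the
gate by a wide margin (measured contrasts ≥ 3×).

Validation: 100 noise-free cells per stage classify 100% correctly, with
margins κ ≤ 0.3 (II_i) versus κ ≥ 1.3 (II_iii) and aspect ratios ≥ 1.9
('septa') versus ≤ 1.1 ('filled'). With the `average` preset accuracy
stays high (≥ ~96% per stage in spot checks) and degrades under
`extreme`. The eigenimage module (16×16 aligned, L2-normalized crops;
leading eigenvectors by Hotelling deflation — power iteration on the raw
second-moment matrix with eigenvalue deflation) matches a dense
eigendecomposition to 10⁻⁶ relative; it is a validation sidecar for the
rule-based classifier, not a classifier itself — the eigenvalue spectrum
of spore crops is dominated by the first component, which separates but
does not by itself categorize stages.

## Foci tracking

Candidates are local maxima of the high-pass residual (frame minus a
2×PSF Gaussian smooth) above 4 residual SDs; each is refined by iterative
Gaussian masking (centroid of image × Gaussian mask, σ = PSF, until the
shift < 0.1 px), giving ≤ 40 nm localization on bright spots (measured
~4 nm noise-free). Spot width is estimated from Gaussian-masked second
moments (mask σ = 2.5×PSF, inverted analytically), and spots outside
[0.5, 2]×PSF width are rejected. Intensity is the sum inside a 5-px
radius circle minus the circle area times the mean of the 17×17 square
outside the circle; SNR is the mean background-corrected circle intensity
over the background SD. Foci with SNR > 0.4 link greedily to the nearest
open track within 5 px, one focus per track per frame, no gap closing;
tracks shorter than 4 points are kept but flagged excluded. Over-tracking
freezes the last centroid and keeps measuring intensity to the end of the
stack for photobleach-step analysis.

## Stoichiometry

Intensity traces are Chung–Kennedy filtered: forward/backward window
means (windows 3 and 8) weighted by (window variance + squared deviation
of the window mean from the current point)⁻¹⁰ — the deviation term keeps
a noiseless step sharp where pure variance weighting would tie. The
characteristic single-fluorophore intensity I_single is the Gaussian-KDE
mode of terminal step sizes of over-tracked traces (plateau mode also
implemented); recovery on synthetic stacks is within ~3%. The bleach time
t_b is fitted once per dataset from all pooled foci intensities versus
time since illumination (single exponential, non-positive intensities
retained to avoid censoring bias; recovered within ~10% at ~70 traces).
Per-track stoichiometry is I₀/I_single with I₀ from a closed-form
least-squares fit of I₀·exp(−t/t_b) to the first 4 intensity points,
t_b held fixed; values are continuous, rounding is display-only.
Compartment copy number is (Σ in-mask pixel intensities − area ×
autofluorescence)/I_single, floored at 0; linearity on synthetic
titrations (50–800 molecules) has slope 1.0 ± 0.1. The membrane fraction
within the depth of field for a mid-plane focus on a cylindrical cell is
(2/π)·arcsin(DOF/W) ≈ 0.254 for W = 0.9 µm, DOF = 350 nm, giving the ×4
extrapolation from in-focus foci to whole-cell totals.

## Oligomer overlap model

Foci closer than the optical resolution merge, so an S-mer population
shows apparent stoichiometry peaks at multiples of S. Per cell,
λ = ρπr² (ρ = foci/feature-area, r = 250 nm resolution) is the mean
overlap count; P(x) is the zero-truncated-Poisson(λ) mixture over
k = 1..5 of Gaussians at k·S with sd σ√(kS), σ = 0.675 molecules, the
per-cell models averaged over the population, convolved with the same
0.7-molecule kernel as the data KDE (applied analytically in quadrature),
and renormalized to unit mass. Model selection uses Pearson's χ² on
1-molecule bins up to 30, discarding bins with no recorded focus,
dof = bins − 4 (λ, k, σ, S); the p-value is the conventional upper tail
by default with a CDF-based alternative exposed. On synthetic tetramer
populations (λ ∈ 0.05–0.5, n ≥ 200) the fit selects S = 4 against
{1, 2, 6, 8}.

## Mobility and membrane drag

MSD follows the N−1−n-term time average; D comes from a linear fit of
the first three MSD points constrained through 4σ² at τ = 0 with σ free
in [20, 60] nm (closed-form D per σ, bounded 1-D search over σ). Bias is
within 10% down to D ≈ 0.4 µm²/s per track; for slower D the intercept
dominates individual tracks and the D ≥ 0 floor biases per-track means
upward, so slow-mobility recovery (and the corresponding test) uses the
ensemble-mean MSD over 8 lags — the standard practice — which is unbiased
across 0.01–1 µm²/s. The D–S power law is a log–log regression with the
sign convention that decreasing D with S gives positive α.

Lateral drag on a membrane-spanning cylinder (radius a, height
h = 3 nm): γ = 4π(η₁+η₂)·a·C(ε), ε = 2aη_c/(hη_m), C(ε) ≈ 1/(ε ln(2/ε)),
η₁ = η₂ = η_c = 1 cP, η_m = 600 cP (vegetative) or 1000 cP (forespore),
D = k_BT/γ at 298 K. This reading reduces exactly to the
Saffman–Delbrück drag 4πη_m h/ln(2/ε) as ε → 0 and reproduces the
0.47 µm²/s ↔ ~40 nm correspondence (computed 40.4 nm). The forward map
is strictly decreasing; inversion is Brent root-finding on log a over
0.1–1000 nm (clipped to ε < 1), with round-trip error ≤ 10⁻⁶. The
close-packed helix bundle radius is (d/2)√n by area equivalence: 40
helices of 1.2 nm give 3.79 nm (≈ 4 nm).

## FRAP

Raw series are normalized to the prebleach mean with t = 0 at the first
post-bleach frame and fitted with
f(t) = f_plateau − (f_plateau − f_bleach)·exp(−t/t_r), free plateau,
t_r bounded below at 1.5 frame intervals (a faster "recovery" is
indistinguishable from one noisy point). Recovery is reported only when
the amplitude realized *inside the observation window* exceeds twice the
residual SD; with the amplitude taken from the extrapolated plateau the
false-positive rate on flat noisy curves measured 24%, versus 0–5% with
the windowed rule. 95% bounds on t_r come from a 200-resample seeded
parametric bootstrap. Noise-free curves refit exactly; at
amplitude/noise = 5 the median t_r is within 10%.

## Numerical conventions

Coordinates are 0-based (row, col); masks are boolean half-open; angles
measured from the image x-axis; the cell axis runs along image columns.
Degenerate inputs: blank frames raise a no-cell error; an empty feature
channel returns "no feature" (⇒ stage I); minor-axis-zero ellipses class
as 'septa'; skeletons under 3 px have κ = 0; negative fitted I₀ reports
stoichiometry 0, flagged. All randomness flows from explicit seeds; reruns
with the same configuration are byte-identical in CSV/JSON outputs.

## Problem sizes

The validation suite uses 100 cells per stage for the classifier
(~1 min), 500–1000 Brownian tracks per diffusion condition, ~70
photobleach traces for I_single/t_b recovery, 400–500 foci per oligomer
population, and 60–100 synthetic FRAP curves per decision-rule property —
sizes at which the sampling error of each check is several times smaller
than its tolerance.
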