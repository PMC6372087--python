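# Methods

`synaptiq` implements the quantitative analysis stages of a presynaptic
physiology workflow at a large glutamatergic terminal (the calyx of Held):
voltage-gated Ca²⁺ channel IV and tail-current fitting, readily-releasable
pool (RRP) estimation from high-frequency EPSC trains, miniature EPSC
analysis, immunogold point-pattern clustering on freeze-fracture replicas,
vesicle-to-active-zone geometry from thin-section EM, ratiometric Fura-2
calibration, and the group-comparison rules tying them together.  A seeded
synthetic-data module generates inputs with the statistical structure each
estimator assumes, together with ground truth, so the whole pipeline is
testable without raw recordings.

## Ca²⁺ current IV model

Peak current-voltage relationships are fitted with a Hodgkin-Huxley
activation model multiplying a Goldman-Hodgkin-Katz (GHK) open-channel
driving force:

    I(V) = Γ · V · (1 − e^{−(V−E_rev)/s}) / (1 − e^{−V/s}) · m∞(V)^n
    m∞(V) = 1 / (1 + e^{−(V−V_m)/k_m})

with s = 25 mV, n = 4 independent gates by default, E_rev the reversal
potential, V_m the per-gate half-activation voltage and k_m the activation
slope.  The driving-force factor is the exact algebraic form of the GHK
current equation in the limit of negligible internal Ca²⁺; it vanishes at
E_rev and is continuous at V = 0 through the series limit
V/(1 − e^{−V/s}) → s, which the implementation applies explicitly at V = 0
(elsewhere `expm1` keeps the quotient stable).  Γ is a conductance-scale
parameter (current per mV of GHK drive); its absolute units are not
physically meaningful without permeability calibration and it is treated as
a free scale.

Fitting is Levenberg-Marquardt least squares on (Γ, E_rev, V_m, log k_m);
the log parameterization enforces k_m > 0.  Default initialization: E_rev
from the interpolated zero crossing beyond the peak, V_m from the voltage of
half-maximal |I|, k_m = 8 mV, Γ from the peak current.  On non-convergence
the start point is perturbed by a deterministic ladder (≤5 restarts), so
fits are reproducible.  Tail currents (peak minus pre-step baseline after
repolarization) are fitted with a Boltzmann function
I_base + I_min/(1 + e^{−(V−V_1/2)/k}); the form is invariant under
(k, I_min, I_base) → (−k, −I_min, I_base + I_min), so a fit converging with
k < 0 is re-expressed with k > 0 and flagged.  The tail measurement window
(default 2 ms after repolarization) and the pre-step baseline window
(default 5 ms) are configuration parameters; the upstream protocol does not
pin them.

## RRP back-extrapolation and release probability

Per-stimulus EPSC amplitudes are peak minus local baseline.  At 300 Hz,
responses ride on the decaying tail of their predecessors, so the baseline
for stimulus i is a low-order polynomial trend fitted to the
0.3 ms preceding the stimulus and extrapolated under the response
(a quadratic captures the curvature of an exponentially decaying residual
to third order; on noiseless trains with 1.5 ms decay kernels the residual
bias is < 1%).  Enlarging the baseline window trades noise amplification
against residual-decay bias.

The remaining (uncompensated) series resistance is compensated offline to
0 MΩ by the steady-state voltage-error relation
I = I_meas·|ΔV|/(|ΔV| − I·R_s), solved in closed form as the stable root of
the equivalent quadratic (the limit of iterating the scale factor).  The
relation loses its solution when the corrected voltage error would exceed
half the driving force; that regime raises an error rather than returning
an extrapolated value.  Only the steady-state amplitude term is corrected —
no capacitive-filter correction — because amplitudes, not kinetics, feed
the downstream estimators.

The RRP is estimated by plotting cumulative EPSC amplitude against stimulus
number, fitting an ordinary least-squares line to the steady-state segment,
and back-extrapolating to time zero, where the first stimulus occurs
(x = stimulus index, 0-based).  The intercept estimates the RRP; the slope
is the replenishment rate, reported both raw (amplitude per stimulus) and
normalized (fraction of RRP per stimulus, the two conventions in circulation
for this number); the first EPSC divided by the RRP is the initial release
probability P_r, clipped to [0, 1] with an explicit flag when clipping
occurred.  The default steady-state window is the **last 5 of 30 stimuli**:
the cumulative curve approaches its asymptote geometrically, and on a
noiseless depletion train (N = 100, p = 0.2, 30 stimuli) the deterministic
extrapolation bias is 1.3% with the last-5 window versus 2.4% with a last-10
window.  RRP values stay in amplitude units (pA); divide by a mean quantal
amplitude to convert to quanta.

Known estimator bias: with vacancy-proportional replenishment during the
train, the time-zero intercept underestimates the true pool by approximately
p·(1 − N_ss/N₀)/(1 − λ) relative, λ = (1−p)(1−r), which at p = 0.2,
r = 0.016 is ≈ −13%, and P̂_r is correspondingly high by ≈ +0.02–0.03.  The
acceptance script reports this bias rather than hiding it.

The external-Ca²⁺ dose-response is fitted with the sigmoid
f(x) = max/(1 + e^{(x_half − x)/rate}); the standard concentration series is
0.2, 0.5, 0.75, 1.0, 1.5 mM.

## Miniature EPSC analysis

Detection is sliding scaled-template matching: a biexponential template
w(t) ∝ e^{−t/τ_decay} − e^{−t/τ_rise} (defaults 1.5/0.2 ms, unit negative
peak) is fitted at every lag as s·w + c by least squares, and the detection
criterion is s divided by the SD of the fit error (threshold 3.5).
Criterion maxima above threshold are thinned with a 2 ms refractory period,
ties resolved to the highest criterion; events below the minimum amplitude
(default 5 pA) are discarded.  The detector is deterministic for fixed
inputs and translation-equivariant.  All parameters are exposed because no
single published configuration is canonical; no figure-level event counts
from real recordings are asserted against this detector.

10–90% risetimes interpolate the crossing times of the 10% and 90% levels
of the baseline-to-peak excursion linearly between samples and return NaN
when noise prevents an ordered crossing pair.  Event frequency is a
centered 5 s moving average, truncated (not padded) at the trace edges.
Drug (Cd²⁺) comparisons drop the first 120 s after application as wash-in
and run the paired t test on frequencies from *disjoint* windows
(stride = window/step): overlapping moving-average windows are
autocorrelated and would inflate the type-I error of the paired test.

## Immunogold cluster analysis

Channel-class particles (12 nm gold) are clustered by circle dilation:
disks of radius r are extended from each particle and particles whose disks
intersect — center distance ≤ 2r, boundary-touching inclusive for
deterministic tie-breaking — join one connected component (KD-tree pair
search + sparse connected components; validated against O(n²) union-find).
Components with ≥2 particles at r = 30 nm are clusters; singletons are
counted separately and never as clusters.  The same construction at
r = 100 nm defines putative active-zone regions; because the radii are
nested, every 30 nm cluster lies in exactly one 100 nm region.
Reporter-class particles (6 nm, genotype marker) are excluded from
clustering.

Cluster and AZ areas are the union of member disks at the respective
radius, computed geometrically (buffered-point union at 256 segments per
circle, polygonal area error ~10⁻⁴ relative; the two-disk case agrees with
the lens closed form to 0.1% and random unions with a Monte-Carlo oracle to
1%).  Union-of-disks was chosen over convex hulls because the single-disk
areas (0.0028 μm² at 30 nm, 0.0314 μm² at 100 nm) sit consistently below
the field's reported mean cluster/AZ areas, as expected for few-disk
unions; a hull would degenerate for collinear or two-particle clusters.

The Thomas-process generator (Poisson parents, Poisson(μ) offspring with
isotropic Gaussian scatter σ) emulates clustered channel maps; defaults
(0.4 parents/μm², μ = 5, σ = 20 nm, 25 μm² faces) give ~5–6 particles per
cluster and cluster areas of ~0.008 μm², in the range reported for this
preparation.  It does not emulate face-boundary irregularity, particle-size
mislocalization, or labeling efficiency, so recovery tests validate the
geometry pipeline, not antibody performance.

## Vesicle geometry

Active-zone length is the polyline arc length.  Vesicle distances are exact
point-to-polyline Euclidean distances (perpendicular foot or nearest
vertex), measured from the vesicle center by default; edge mode subtracts
the vesicle radius, floored at 0.  A raster mode reproduces the
pixel-pipeline of image-analysis software (polyline marked on a grid with
quarter-pixel sampling, Euclidean distance transform, bilinear sampling at
the vesicle position) and agrees with the exact mode within 1 pixel at
1 nm/pixel — the residual half-pixel quantization of the mask.  Distances
are binned in half-open 5 nm bins over [0, 200) nm; vesicles at exactly
5 nm are *not* docked ("less than 5 nm" is strict, consistent with the
half-open bins); vesicles at or beyond 200 nm are excluded from the bins
and reported separately, so counts are conserved.

The profile generator draws a gently turning convex polyline and places
vesicles at sampled perpendicular distances on its outer side, which makes
the sampled distance exactly the nearest-polyline distance (ground truth by
construction).

## Fura-2 calibration

The background-subtracted F340/F380 ratio R converts to free calcium as
[Ca²⁺] = K_eff·(R − R_min)/(R_max − R), K_eff = 239.95 nM at 25 °C,
pH 7.2.  At the midpoint ratio (R_min + R_max)/2 the conversion returns
K_eff exactly — the analytic identity used as a self-test.  Ratios below
R_min map to 0 nM with a warning by default (noise near zero calcium);
strict mode raises instead; ratios at or above R_max raise a saturation
error.  Calibration fits the forward saturation form
R(c) = (R_min + R_max·c/K_eff)/(1 + c/K_eff) by least squares on
(concentration, ratio) standards — ten EGTA-buffered standards from
Ca²⁺-free to 1.4 μM in the default protocol — rather than a linearized
reciprocal transform, which would distort noise.

## Statistics dispatcher

Group comparisons follow a fixed selection procedure: Shapiro-Wilk per
group for normality and Bartlett for variance homogeneity; two normal
comparable-variance groups → unpaired two-tailed t; more than two → one-way
ANOVA with Dunnett's post hoc against the control; any non-normal group →
Mann-Whitney U (two groups; exact for combined n ≤ 20, tie-corrected
normal approximation otherwise) or Kruskal-Wallis with Dunn's rank-sum post
hoc (more).  Binned data use Fisher's exact test (2×2); paired designs the
paired t test, with identical samples returning the degenerate p = 1
convention under a warning.  Groups too small for Shapiro-Wilk (n < 3) fall
back to the nonparametric branch with a warning.  Normal groups failing
Bartlett use Welch's t (two groups) — a branch the source procedure leaves
unspecified.  Dunn's post hoc applies no multiplicity correction unless
configured.  α = 0.05 throughout.  Null calibration of the full dispatcher
(normality screen included) is ~4.5% rejections at nominal 5%.

## Numerical and testing choices

Problem sizes in the default test and acceptance runs — 30-stimulus trains,
16-voltage IV curves, 60 s mEPSC traces at 10 kHz, 25 μm² replica faces,
100-seed recovery ensembles — were chosen so each estimator's sampling error
is well below the tolerances being asserted while the whole suite stays
interactive.  All generators take explicit integer seeds
(`numpy.random.default_rng`); no hidden global RNG state.  Synthetic data
omit several features of real recordings: drifting baselines, stimulus
artifacts, electrode noise spectra, receptor saturation/desensitization
(handled pharmacologically in the source experiments), and facilitation
beyond the depletion model.  Passing recovery tests therefore demonstrate
correctness of the estimators under their stated models, not robustness to
every experimental artifact.
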