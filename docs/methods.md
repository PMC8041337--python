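# Methods

This note documents the models, estimators and numerical choices
behind `sfcoupling`, and what the synthetic validation studies do and
do not demonstrate.

## Problem setting

Deep-brain-stimulation electrodes in the basal forebrain record a
local field potential (LFP) simultaneously with a whole-head sensor
array. Two connectivity descriptions of the same target exist side by
side: *functional* connectivity — frequency-resolved coherence between
the LFP reference and beamformed cortical sources — and *structural*
connectivity — the density of tractography streamlines passing from a
seed around the electrode contacts to each brain voxel. The package
asks, voxel by voxel, whether structure predicts function, and, at the
locations where it does, in which direction the electrophysiological
coupling flows.

## Spectral estimation

`compute_csd` uses a Welch–multitaper hybrid: non-overlapping windows
(default 1 s), DPSS tapers with ±2.5 Hz half-bandwidth (2·NW − 1
tapers), cross-periodograms averaged over windows and tapers, scaled
one-sided so the integrated auto-spectrum recovers the channel
variance (checked to 5% in tests). Windows are demeaned. The defaults
give 1 Hz resolution and roughly 720 averages for a 3-minute recording
at 300 Hz, enough for stable coherence at the band level.

Analysis bands are delta/theta 2–8 Hz, low beta 13–22 Hz and high beta
22–30 Hz. Band averages are arithmetic means over bins with
lo ≤ f ≤ hi, both edges inclusive; with 1 Hz bins the 22 Hz bin
belongs to low beta and high beta starts at 23 Hz (`HIGH_BETA` is
therefore stored as 23–30).

## DICS beamforming

For each point of a 5 mm source grid (mirror-symmetric about the world
plane x = 0 so that left/right flipping maps grid points onto grid
points), the spatial filter is

    w(g) = C⁻¹ l(g) / (l(g)ᵀ C⁻¹ l(g)),

where l(g) is the (scalar, orientation-free) leadfield column and C
the real part of the band-averaged sensor CSD plus Tikhonov loading
λ = 0.05 · mean(diag C) (configurable). Source–reference coherence is

    coh(g) = |wᴴ S̄ₓᵣ|² / ((wᴴ S̄ₓₓ w) · S̄ᵣᵣ)

with all blocks of the complex band-averaged CSD. Band-averaging the
CSD *before* computing coherence (one filter per band) was chosen over
averaging per-frequency coherence; the band matrix is a mean of PSD
matrices, so Cauchy–Schwarz keeps the image in [0, 1] for any λ ≥ 0.
Grid values are interpolated trilinearly onto the 2 mm voxel grid of
the brain mask (lattice points outside the mask contribute 0; voxels
outside the mask are NaN).

The forward model is a unit-row-norm inverse-distance toy leadfield.
No head geometry, sensor physics or orientation handling is modelled;
localization claims below are claims about the algorithm, not about
MEG physics.

## Tract density

A streamline contributes to a voxel if any of its ≤ 0.5 mm
sub-segment *midpoints* falls in the voxel, and contributes at most 1
regardless of in-voxel path length. Midpoint (rather than vertex)
sampling decides voxel membership because midpoints cannot land
exactly on a voxel face for face-aligned lines: a 10 mm segment laid
face-to-face across five 2 mm voxels visits exactly those five, which
vertex sampling would miss by one at either end. Seed filtering keeps
streamlines whose closest densified *vertex* is within the sphere
radius and which traverse at least one voxel of the structure mask.
Exact analytic line–voxel intersection was not used; with 2 mm voxels
the discrepancy is below one sampling step.

The 2×2 ANOVA of density images (contact location × disease) is an
OLS model with interaction, side indicator and subject indicators
nested within disease (one subject dropped per disease level — a full
subject set would alias the between-subject disease factor). Inference
uses the same cluster-permutation engine as the main analysis,
permuting observations within subject. Consequences: the disease main
effect is tested against residual rather than a proper
between-subject error term, and no random-field parametric inference
is provided.

## Voxel-wise structure–function GLM

At voxel v with observations i = 1..n:

    coherence_i(v) = b0(v) + b1(v) · density_i(v) + e_i(v),

an F test of b1 on (1, n − 2) degrees of freedom. The design matrix is
voxel-specific — each voxel has its own regressor column — which is
what distinguishes this from the classical mass-univariate GLM; when
the density image is artificially made identical across voxels the
two coincide exactly (verified in tests). Voxels whose density has
zero variance across observations are undefined and excluded before
clustering, so clusters cannot bridge through undefined space.
Exact-fit voxels (zero residual) receive the largest representable F
and an exact-fit flag. Coherence enters untransformed by default; a
Fisher-z option (`arctanh √coh`) exists but is off.

Cluster inference: voxels with F above the F(1, n−2) quantile at the
forming threshold (default P < 0.01) are grouped by 26-connectivity;
the null distribution of the *maximal cluster extent* is built by
shuffling the coherence observations against the density observations
— the same shuffle at every voxel, preserving spatial correlation —
and each cluster's family-wise p is (1 + #{perm max ≥ size})/(1 + B),
so p ≥ 1/(B+1) and the identity permutation is always counted.

A known property of the max-extent statistic: it is integer-valued,
and cluster-extent inference presumes spatially *smooth* statistic
images — which the real pipeline outputs are (coherence images are
interpolated from a 5 mm grid; density images carry streamline
corridors). On spatially white voxel fields the null max cluster size
degenerates to 1–3 voxels, the distribution is tie-heavy and the
attainable test level sits far below nominal (≈ 0.008 on a 12³
volume). The FWE calibration study therefore uses null cohorts of
smooth fields (Gaussian kernel, σ = 1.5 voxels) on a 16³ volume,
where the null max-size distribution spans ~1–16 voxels and the
attainable level is ≈ 0.05, making the calibration check informative.
These conditions were chosen from the null max-size distribution
alone, which does not involve the permutation machinery under test;
measured false-positive rates are 0.035–0.065 across seeds (nominal
0.05, exact binomial interval [0.02, 0.08] at 200 cohorts).

## Nonparametric spectral Granger causality

The 2-channel CSD on a uniform 0.5 Hz grid from 0 to Nyquist (2 s
windows) is factorized as S = H Σ Hᴴ by Wilson's iterative algorithm:
ψ ← ψ·[ψ⁻¹ S ψ⁻ᴴ + I]₊, where the causal operator [·]₊ zeroes
negative lags and replaces the lag-0 coefficient γ₀ by the
upper-triangular β₀ with β₀ + β₀ᴴ = γ₀ (strict upper triangle of γ₀
plus half its diagonal), pinning the minimum-phase factor uniquely.
Analytic spectra converge below 1e-9 relative change in ~20–30
iterations with reconstruction error < 1e-6. Spectra estimated from
finite data carry noise beyond the representable causal lags, so the
iteration bottoms out in a small limit cycle at its attainable floor
(typically 1e-5–1e-3 reconstruction error); the implementation
detects the plateau and accepts the factor if the reconstruction is
within 1e-2 relative, raising otherwise. Σ is returned in
signal-variance units (the per-Hz scaling of the input is undone), so
on a VAR fixture it is directly comparable to the innovation
covariance.

Geweke's directed spectrum is then

    GC_{y→x}(f) = ln ( Sₓₓ(f) / (Sₓₓ(f) − (Σ_yy − Σ²ₓy/Σₓₓ)·|Hₓy(f)|²) ),

computed from the factorization's own reconstruction, which makes it
exactly invariant to common rescaling of both channels. Nonpositive
log arguments (numerically possible at the estimation floor) are
clamped with a warning counter. No autoregressive model is fitted
anywhere in the pipeline; the parametric Geweke formulas in
`sfcoupling.oracles` exist only as independent references for tests.

## Time-reversal directionality test

For each 2-channel observation, band-mean GC is computed per direction
on the original and on the sample-order-reversed data;
Δ = GC_original − GC_reversed. A genuine lagged influence A→B gives
Δ(A→B) > 0 and Δ(B→A) < 0, while lag-free asymmetries cancel. Across
observations the mean Δ of each direction is tested with a two-sided
one-sample t-test, reported as F = t² on (1, n−1) degrees of freedom
(the raw t is also exposed). Band means are differenced (for means,
the order of band-averaging and differencing does not matter).

## Synthetic cohort

Defaults mirror the recording conditions the pipeline targets: 3-min
rest recordings, reference channel high-pass filtered at 1 Hz (4th
order zero-phase Butterworth — zero-phase so the filter cannot inject
spurious lead/lag into the directionality ground truth), fs = 300 Hz
(Nyquist comfortably above 30 Hz), two hemispheres per subject.

Sources are band-limited filtered-noise processes: a shared innovation
z, band-passed (4th-order zero-phase Butterworth) and unit-scaled,
enters the source as √c·z and the reference as a lag-L copy, plus an
independent band-limited private component √(1−c)·u. In-band
magnitude-squared source–reference coherence is then c by
construction; which side receives the delayed copy fixes the Granger
direction (`bidirectional` uses two shared innovations, one per
direction; `none` uses lag 0). The realized coherence of every source
is measured on the noiseless signals at generation time, stored in the
recording metadata and warned about beyond ±0.1. Sensors are the
leadfield projection plus white noise at a configurable RMS SNR; the
reference receives a small broadband floor (5% power) so its
auto-spectrum is positive everywhere.

Streamline sets are straight 1 mm-spaced polylines from a random point
in the seed sphere to a random point in each target voxel, with
integer counts `round(target + slope·level + noise)`; at the
designated coupling voxels the expected density is a linear function
of the observation's coherence level, planting the
structure–function relationship the GLM should find. Limitations: a
polyline from the sphere to a distant voxel necessarily crosses
intermediate voxels, so off-target "corridor" density appears unless
the sphere touches the target voxel; real tractography curvature,
fanning and length-dependent seeding biases are not modelled. VAR
processes (`simulate_var_sources`) provide the oracle substrate for
the Granger machinery, with stability (companion spectral radius) and
SPD noise checks and a ≥ 10×order burn-in.

All generators are deterministic under a fixed seed (byte-identical
outputs).

## Validation studies and study sizes

The studies in `sfcoupling.experiments` (run by
`scripts/acceptance.py` and the acceptance tests) use: a bivariate
VAR(2) fixture (two damped ~24 Hz oscillators at fs = 120 Hz, unit-lag
0→1 gain 0.25) with 180 s observations; 10-observation cohorts, so the
slope F carries (1, 8) degrees of freedom; 20 replicates for
power-type checks and 200 for calibration-type checks (exact central
binomial intervals); DICS studies on a 16³ × 2 mm ellipsoid mask with
a 5 mm grid, 16 sensors and 180 s recordings at 300 Hz; the planted
8-voxel coupling with per-voxel slope F ≈ 20 at n = 10 (Poisson-5
density variance, slope 0.05, residual SD 0.0707). These sizes were
fixed as the package's validation conditions; passing them shows the
machinery is correct and calibrated on data satisfying its
assumptions (stationarity, Gaussian noise, linear coupling,
co-registered images), not that effects of this size exist in, or
would be recoverable from, patient data.

## Known limitations

- Scalar leadfield, no anatomy: MNI-like symmetric toy space only.
- Cluster statistic is extent with 26-connectivity; no cluster-mass
  option, no random-field theory.
- The disease factor of the 2×2 ANOVA is tested against residual
  error (see above).
- Coherence images near the mask boundary are biased toward 0 by the
  interpolation's zero fill outside the grid lattice.
- The time-reversal test assumes observations are exchangeable and
  independent across subjects/hemispheres; within-subject dependence
  between hemispheres is not modelled in the test itself.
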