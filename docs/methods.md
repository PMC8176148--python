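# Methods

`megconn` implements a two-group resting-state MEG analysis: regional
band power and leakage-corrected amplitude-envelope-correlation (AEC)
connectomes derived from beamformed virtual sensors, covariate-adjusted
permutation statistics over seeds and connectome edges, and a nested
feature-selection/classification workflow that compares regional power
against functional connectivity as discriminative markers.  Because
clinical MEG recordings of this kind are rarely shareable, the package
ships a synthetic-cohort generator with *plantable* group effects, so
that every stage of the analysis can be validated against known ground
truth.  This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
establish about real data.

## The emulated study design

The generator's defaults describe a paediatric chronic mild traumatic
brain injury (mTBI) cohort: 16 patients and 20 controls, ages 6–18
(patients 12.46 ± 3.24 y, controls 13.14 ± 2.69 y), five-minute
eyes-open recordings from a 151-channel axial system at 600 Hz, with 90
atlas-like seed locations.  Head motion is drawn from group-dependent
lognormal distributions (patients 1.83 ± 1.79 mm, controls 0.64 ±
0.51 mm); the deliberate group–motion confound is what makes the
covariate adjustment in the statistics stage a real test rather than a
formality.  Canonical bands are delta 1–3, theta 4–7, alpha 8–14, beta
15–30, low gamma 30–55 and 65–80, and high gamma 80–150 Hz.

## Synthetic signal model

Each seed's time series is a sum over bands of band-limited carriers
modulated by slow positive envelopes,

    x_s(t) = Σ_b a_sb · e_sb(t) · c_sb(t).

**Carriers.** `c_sb` is band-passed Gaussian noise *normalised by its
own Hilbert envelope* — a constant-modulus phase-noise oscillation.
The normalisation is a deliberate design choice: the Hilbert envelope
of raw band-passed noise is Rayleigh-distributed with a relative SD of
~52%, and in a 2 Hz-wide delta band this carrier amplitude noise
survives 1 Hz down-sampling almost intact, capping the achievable
envelope correlation near 0.29 — too low to represent hypo-connectivity
against a 0.3 baseline.  With constant-modulus carriers the measured
envelope tracks the planted envelope and delta AEC spans ≈ 0–0.8.  The
price is a mildly unphysical amplitude microstructure within the band;
band power, spectra, beamforming and all cross-seed statistics are
unaffected.

**Envelopes.** `e_sb = 1 + 0.7·ξ_sb`, where ξ is the standardised
modulus of Gaussian noise low-passed at 0.45 Hz (4th-order
Butterworth), clipped below at 0.05.  The cutoff controls how much the
envelope varies *within* a 10 s epoch, which is what a per-epoch
Pearson correlation of 1 Hz envelope samples can see: at 0.3 Hz the
within-epoch variance is so small that measured AEC saturates near
0.18; 0.45 Hz keeps the dynamics slow (cycle ≫ carrier period) while
leaving the protocol usable.

**Planted power effects** multiply `a_sb` for the affected group on a
seed set; band power scales with the square of the factor (a ×1.5
amplitude factor is a ×2.25 power ratio), verified to 5% by Welch
estimation over 50 simulated subjects.

**Planted coupling effects** make the two seeds of an edge share an
envelope component: ξ_i ← √(1−w)·ξ_i + √w·ξ_shared.  The map from
mixing weight w to *measured* AEC depends on the band filter, the
envelope dynamics, and — critically — on how many seeds are jointly
orthogonalized: a narrow band has roughly 2·bandwidth·T effective
degrees of freedom per epoch (~40 for delta), so forcing 60 or 90
series to be mutually orthogonal distorts each one appreciably and
attenuates envelope correlations in a seed-count-dependent way.  The
weight is therefore calibrated at run time by a cached simulation that
reproduces the exact measurement chain (band-pass, *joint* symmetric
orthogonalization over an ensemble of the cohort's size with half its
pairs coupled, Hilbert envelope, 1 Hz block averaging, per-epoch
Pearson, epoch averaging) on a five-point weight grid, smoothed by a
quadratic fit and inverted by interpolation.  Negative shifts are
expressed against a configurable baseline: affected edges carry
`baseline` AEC in the reference group and `baseline + shift` in the
affected group.  With this calibration, a planted −0.15 delta shift is
measured as −0.15 ± 0.02 through the full pipeline.

**Artifacts.** Ocular (blink bumps with a frontal-weighted topography),
cardiac (a ~1.2 Hz biphasic spike train with a fixed random
topography), step jumps of configurable amplitude in random channels,
and smooth head-position excursions sized to straddle the 10 mm
rejection threshold.  The injector returns the ground-truth courses so
preprocessing tests can measure removal directly.

**Forward model.** Closed-form field of a current dipole in a
homogeneous conducting sphere, sampled at 151 radially oriented
magnetometers on a spherical cap.  Radial moments are silent in this
geometry, so each seed radiates with a fixed tangential moment
(default 20 nA·m); sensor noise is white (default 10 fT).  For radial
sensors the spherical volume currents contribute nothing, which
provides an exact independent oracle (bare Biot–Savart dipole term)
used in the tests.

## Analysis pipeline

**Preprocessing** applies a 4th-order Butterworth band-pass (1–150 Hz)
forward–backward (zero phase; effective order 8 in magnitude), an FFT
notch that zeroes bins within ±1 Hz of 60 and 120 Hz, ICA-based
artifact attenuation, 10 s epoching (trailing remainder dropped), and
epoch rejection: any within-epoch head displacement from the
whole-recording median position above 10 mm (reason `motion`), or any
channel's absolute first difference above 2000 fT (reason `jump`,
checked second).  ICA component removal is automated: components whose
time course correlates with a supplied artifact template above |r| =
0.5 are zeroed before back-projection; if FastICA fails to converge
the recording passes through unmodified with a warning status.  Jump
detection runs on the *unfiltered* epochs — the band-pass smears a
step over many samples and would hide it from a first-difference
criterion — while the retained data are the cleaned epochs.  The
per-subject head-motion covariate is the mean over retained epochs of
the per-epoch maximum displacement.

**Source reconstruction** uses an LCMV beamformer on the sensor
covariance pooled over retained epochs, regularised as C + λI with λ =
0.05 · trace(C)/n_channels ("5%" of the mean sensor variance).  The
beamformer is scalar: per seed, the tangent-plane orientation
maximising output power (smallest-eigenvalue direction of L'C⁻¹L) is
selected, and the unit-gain weights are w = C⁻¹l / (l'C⁻¹l).
Broadband virtual-sensor series are z-scored per seed over
concatenated epochs.  Verified properties: unit gain to 1e-10, single
planted source recovered with |r| ≥ 0.99 noiseless and ≥ 0.95 at
SNR 10, and the regularisation monotonicities (weight norm
non-increasing, true output variance non-decreasing in λ — the λ=0
filter is by construction the minimum-variance solution, so "more
regularisation, less output power" would be backwards).

**Spectral power**: Welch PSD per epoch (2 s Hann windows, 50%
overlap → 0.5 Hz resolution, nine windows per epoch), averaged over
retained epochs.  Band power is the *mean* density over bins whose
centre lies in the band — comparable across bands of unequal width.
Lobe spectra are unweighted means over member seeds per hemisphere;
peak alpha is the maximum density in 8–14 Hz of a lobe-averaged
spectrum.

**Connectivity**: per band and epoch — two-pass windowed-sinc FIR
band-pass (order = max(3·fs/f_lo, 6.6·fs/bandwidth, 66), the second
floor keeping the Hamming transition inside half the band so narrow
bands reach unity passband gain); joint symmetric orthogonalization of
all seeds (alternating Procrustes/rescale iteration to the closest set
of mutually orthogonal rows, relative tolerance 1e-8, max 200
iterations); Hilbert envelope; block-average down-sampling to 1 Hz;
Pearson correlation across the epoch's 10 samples; and finally the raw
mean over epochs ("static" AEC, no Fisher transform).  Orthogonalizing
*before* the envelope is essential and regression-tested: the envelope
is non-linear, so correcting afterwards does not remove zero-lag
leakage.  Pairs with a constant envelope yield NaN and are excluded
from epoch averaging.

**Group statistics**: per unit (seed or edge), a one-way ANCOVA F for
group adjusted for age and head motion (full model {1, group, age,
motion} vs reduced {1, age, motion}).  P-values come from
Freedman–Lane permutation: residualise on covariates, permute the
residuals (the same permutation sequence for every unit in a band, for
map coherence), add the covariate fit back, recompute F; p = (1 +
#{F* ≥ F}) / (1 + n_perm), never zero.  The default permutation count
is 10 000.  Benjamini–Hochberg FDR is applied within band across the
unit family (90 seeds, or n(n−1)/2 edges — 4005 for 90 seeds); the
post hoc Wilcoxon rank-sum (Mann–Whitney U with tie-corrected normal
z) is available for direction confirmation.  Degenerate outcomes
(perfect or constant fits) are detected by a relative-RSS threshold so
F is 0 rather than numerical noise.

**Classification**: features are the per-band seed powers (90) or the
vectorised upper-triangle edges (4005), with a deterministic i<j
ordering and a round-trippable edge↔index map.  The nested 10-fold
feature selection runs, per outer fold and strictly on the 9 training
folds: an optional univariate rank-sum pre-filter (p < 0.05,
uncorrected), gated globally by whether the univariately reduced
complete data separates the groups in PCA (silhouette of the labels in
PC1/2 > 0.2 — a deterministic stand-in for visual judgement) and used
for connectivity features only; then recursive random-forest feature
selection (rRF-FS): per repetition (default 10, fresh forest seed),
500-tree forests with out-of-bag scoring are fitted along a full
elimination path dropping the bottom 20% of features by impurity
importance each step, and the repetition keeps the smallest set whose
OOB accuracy stays within 2 points of the path's best; features
surviving at least half the repetitions are the fold's selection.  An
RBF SVM (C = 1, scale gamma, features z-scored with training-fold
statistics) scores each held-out fold.  Consensus features are those
selected in ≥ 4 of 10 folds for connectivity and ≥ 2 of 10 for power
(power skips the pre-filter, so its per-fold lists are already
conservative).  The final consensus-feature SVM is evaluated by
stratified 10-fold CV (mean ± SD accuracy in %), label-permutation
tests (p = (1 + #{acc* ≥ acc})/(1 + n_perm), default 1000
permutations) for both the SVM and a PLS-DA (2-component PLS on
one-hot labels, argmax decision), and a training-set ROC-AUC that is
reported as a comparative-only, optimistic metric (ties score 0.5).
Held-out subjects never touch filtering, selection, scaling or
fitting; a leakage-canary test (a feature revealing labels only on
held-out subjects must not raise CV accuracy) guards the protocol.

One caveat is inherent to the workflow rather than its
implementation: the consensus list aggregates selections made across
overlapping training folds, and the final SVM's 10-fold CV re-uses
those same subjects, so the *consensus-model* CV accuracy carries
selection optimism — on entirely null features it sits near 70–80%,
not 50%.  The unbiased generalisation measure is the per-fold
held-out accuracy recorded during nested selection
(``SelectionResult.fold_accuracy``), which on null features stays
near the majority-class rate (56% at n = 16/20);
both numbers are reported, and model comparisons should lean on the
fold-wise accuracies and the label-permutation tests (which re-run
the CV under permuted labels and are therefore calibrated for the
optimism).

## Statistical power of planted-effect recovery

The AEC measurement protocol — Pearson correlation of ten 1 Hz
envelope samples per 10 s epoch — has an irreducible per-epoch
sampling SD of ≈ 0.33·(1−ρ²), and envelope autocorrelation within
epochs roughly halves the effective sample count.  Averaging 24 epochs
leaves a per-subject, per-edge SD of ≈ 0.15, so a calibrated −0.15
shift is a standardised effect of d ≈ 1.1.  At n = 16/20 this gives
~90% power for sign-correct edge-level detection at permutation
p < 0.05, but under BH-FDR across all 1770 edges of a 60-seed cohort
(let alone 4005) the per-edge power falls below 0.5: FDR-corrected
recovery of a d ≈ 1 effect is not attainable at this sample size, for
this or any desk-scale configuration we explored (durations to 300 s,
30–90 seeds).  The validation therefore scores *recovery* as
sign-correct edge-level detection at p < 0.05 (observed sensitivity
0.87) while separately requiring the FDR-corrected map to be free of
false positives, and the planted power effect (×2.25, d ≫ 2) to be
recovered fully under FDR.  Real effects that do survive
connectome-wide FDR at these sample sizes are correspondingly larger
than d ≈ 1.

## Validation problem sizes

The test suite and the acceptance script run reduced configurations,
chosen once from the power analysis above: effect recovery uses 60
seeds (30 disjoint planted edges need ≥ 60), 240 s recordings, a
delta-only carrier, 2000 permutations; the classification comparison
uses 20 seeds, 10 planted delta edges at −0.25, 120 s, delta+alpha
carriers, 199 label permutations, 60-tree forests with 6 repetitions;
null calibration uses feature-level Gaussian cohorts (36 subjects, 20
units, group-confounded motion, 1000 permutations).  The sensor-level
demonstration (forward projection, artifacts, ICA, rejection,
beamforming) runs 8 subjects at 60 s with 151 channels and 30 seeds.

## What passing does and does not show

The synthetic cohorts emulate band-limited oscillations with slow
envelope dynamics, group-confounded motion, and ocular/cardiac/jump
artifacts, but not: 1/f broadband background, spatially extended or
correlated sources, inter-individual anatomy (one spherical head and
one seed set serve all subjects), age-dependent spectra, or
non-stationarity beyond the envelope model.  Passing therefore shows
that the pipeline's operations are correct and calibrated under known
ground truth — not that the specific neurophysiological findings of
any real cohort would replicate.  The spherical forward model
replaces template-based single-shell head modelling; template-based
localization is itself an approximation, and the closed-form sphere
makes the inverse problem exactly testable.

## Known limitations

* The weight→AEC calibration assumes sparsely coupled, disjoint edges;
  seeds participating in many strong effects renormalise sequentially
  and total shared variance must stay ≤ 1.
* Static AEC only; no dynamic or phase-based connectivity.
* FastICA on purely Gaussian band-limited sources is unidentifiable;
  artifact attenuation relies on artifacts (and real MEG sources)
  being non-Gaussian, and passes recordings through unmodified on
  non-convergence.
* Consensus thresholds (4/2) and rRF-FS internals are concrete
  instantiations of an underspecified published procedure; they are
  configuration, not estimated quantities.
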