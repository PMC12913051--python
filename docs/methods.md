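# Methods

This note documents the models implemented in cyclovasc, the parameters
that matter, what the synthetic generators do and do not emulate, and the
numerical and design choices made where the published processing chain
leaves details open.

## ASL kinetic quantification

The perfusion-weighted signal is the single-compartment kinetic model of
a pseudo-continuous label (plug-flow bolus of duration τ delivered at
rate f, decaying with the T1 of blood; no exchange into the tissue
compartment, i.e. the apparent T1 equals blood T1). The model is
evaluated at t = PLD + τ from label onset — the time-origin convention
must be fixed somewhere, and label onset is the natural origin for a
bolus description. Perfusion is expressed in ml/100 g/min via the factor
6000 (s⁻¹ → per-minute per-100 g).

Defaults: T1 of blood 1.65 s and labelling efficiency α = 0.85, standard
3 T pCASL values, both config-exposed; blood–CSF partition coefficient
λ = 1.15, TE = 19 ms, T2\*(CSF) = 0.4 s, T2\*(blood) = 0.06 s for the
M0-blood calibration. The CSF T2\* is treated as seconds (consistent with
TE in seconds). The difference signal is computed as control − tag so
that it is positive in expectation.

Fitting exploits linearity in f: for fixed arrival time the least-squares
perfusion is a ratio of inner products, so the 2-D problem reduces to a
1-D search over arrival time — a 0.25 s grid over [0.25, 3.0] s followed
by bounded scalar minimisation (xatol 1e-6) around the best grid point,
ties broken towards lower SSres then smaller arrival time. Noiseless
signals are recovered to ~1e-7 relative. Voxels with any non-finite
sample, or all-zero signal, are flagged and excluded; the R² > 0.6 gate
is strict. Arrival times at or below the first PLD are structurally
unidentifiable (all samples fall after complete bolus passage, where the
arrival time cancels), so recovery guarantees start above the first PLD.

## TRUST oximetry

Blood T2 comes from unweighted nonlinear least squares of
s0·exp(−eTE/T2) over the effective echo times (0, 40, 80, 160 ms),
seeded log-linearly from the positive samples (long echoes can go
negative under noise). Flat series return T2 = ∞ with a warning;
non-decaying series warn and still return the fit.

The Yv calibration is the in-vitro bovine-blood quadratic
1/T2 = A + B(1−Yv) + C(1−Yv)² with haematocrit-dependent coefficients
(A = −13.5 + 80.2·Hct − 75.9·Hct², B = −0.5·Hct + 3.4·Hct²,
C = 247.4·Hct(1−Hct), rates in s⁻¹, 10 ms refocusing interval). B and C
are positive over physiological haematocrit, so the root in [0, 1] is
unique and found by bracketed root-finding; out-of-range T2 raises an
error reporting the attainable T2 interval. Haematocrit is Hb/34 (g/dL
basis), config-exposed. The Hb-from-T1 pathway is linear in 1/T1 with
default coefficients derived from the linear venous relaxometry
calibration 1/T1 = 0.52·Hct + 0.38; strict mode refuses to run without
explicit coefficients.

The CMRO2 arithmetic is implemented exactly as the protocol prints it:
the "CaO2" term folds OEF and the 39.34 µmol/ml conversion into one
factor and omits the dL→ml factor of 100, so the default ("printed")
units are 100× the conventional µmol/100 g/min; `convention="standard"`
applies the /100. This keeps the package's numbers comparable with the
protocol while documenting the conventional decomposition.

A simulated TRUST *session* averages several label/control repeats per
echo time before fitting (default in the validation chain: 3, the
conventional acquisition). This matters quantitatively: a single 4-point
curve at per-acquisition SNR 20 has a Cramér–Rao floor of roughly 7%
median T2 error, so session-level accuracy claims only make sense with
the protocol's averaging included.

## DIMAC pulsatility

The processing chain is: 4 × 4 voxel ROI mean → zero-phase second-order
Butterworth high-pass at 1/3 Hz (the cut-off is specified as a 3 s
period; zero-phase filtering preserves beat morphology) → Savitzky–Golay
smoothing (order 5, window 21 samples) → beat segmentation → per-beat OLS
Fourier model (intercept + five sine/cosine pairs at periods P/1…P/5) →
PI = range/mean per beat, averaged. Because a literal high-pass removes
the DC level that PI divides by, the pre-filter series mean is re-added
and retained.

Beat detection is not specified by the protocol and is implemented as:
systolic peaks by local-maximum search with prominence ≥ 0.5·SD on an
extra-smoothed detection trace (Savitzky–Golay window 31, order 3), with
minimum spacing max(0.33 s, 0.6·P̂) where P̂ is the dominant period from
the autocorrelation peak. A fixed 0.33 s spacing with raw-trace
prominence mis-segments long flat diastoles at realistic noise (splitting
~60 true beats into ~95), which is why the period-aware spacing and
detection smoothing are used; both are config-exposed. Beat boundaries
are the minima between successive peaks, so partial first/last beats are
discarded and an N-peak periodic record yields N − 2 complete beats.
Boundaries land wherever the diastole is lowest (typically at the
post-systolic undershoot or just before the upstroke), not at a fixed
phase. Beats shorter than 21 samples (11 coefficients) are skipped with a
log entry, as are beats with non-positive mean.

The synthetic waveform is a raised-cosine systolic peak (systole fraction
0.35 of the period) on a flat diastole, scaled so range/mean of the
noiseless waveform equals the requested PI exactly — the closed form is
what makes the generator an oracle. Default noise SD 3.3 on a mean level
of 100 gives per-beat fit R² ≈ 0.9 at PI 0.30. SNR for this modality is
defined as peak-to-peak pulsatile amplitude over noise SD: the
acquisition suppresses static signal, and PI estimation depends on
resolving the waveform, not the DC level. (The per-beat model's range is
noise-inflated — an 11-parameter fit at waveform SNR 20 biases PI upward
by well under 0.01; at mean-level-referenced SNR 20 the bias would be
~0.03 and intrinsic to the published method.)

## OCT-A vessel networks

Cleaning removes 8-connected clusters of fewer than 30 white pixels
(strict threshold). Skeletonisation uses the standard 2-D thinning of
scikit-image; the graph connects 8-neighbouring centreline pixels. The
per-node radius is the Euclidean distance transform at the centreline
pixel minus half a pixel: the EDT measures to the *centre* of the nearest
background pixel, half a pixel beyond the vessel boundary, so a width-9
bar correctly reads radius 4.5 px. Segments are maximal paths between
nodes of degree ≠ 2; length sums the 1/√2-pixel steps, radius is the mean
node radius, and paths under 3 nodes are discarded; isolated closed loops
are skipped with a log entry.

Resistance is R = 8ηl/(πr⁴) with η = 2.084e-3 Pa·s and l, r in µm
(R in Pa·s/µm³). Segment-to-sector assignment uses the segment's midpoint
node; sectors are the 1 mm-diameter foveal disc and the 3 mm parafoveal
ring split by ±45° diagonals, with temporal/nasal labels flipping with
eye laterality (right eye: temporal on image left). Per-sector resistance
is the unweighted mean over segments (a length-weighted alternative was
considered and rejected as the default because the segment is the
published unit of analysis). Vessel density is the vessel-pixel fraction
of the disc/ring.

Accuracy is quantisation-limited: the ±0.5 px radius discretisation
enters resistance through r⁴, so validation renders use a fine pitch
(0.25 µm/px) where rendered straight vessels of radius 5–25 µm measure
within 10% of the analytic value, with error shrinking as radius grows.
At instrument-like pitches (3 mm/320 px = 9.375 µm/px) radii below
~10 µm are at or below one pixel — the generator refuses sub-pixel radii
with a warning naming the segment.

The procedural tree generator grows straight segments by recursive
branching with per-generation radius tapering; every rendered segment's
true length, radius and analytic resistance are returned. It emulates
the geometry of a superficial vascular plexus, not its topology
(no anastomoses or capillary loops) and not OCT-A imaging artefacts
(projection, motion, segmentation error).

## Endocrine statistics

resProgesterone is the residual of an OLS regression of progesterone on
oestradiol (with intercept) pooled over sessions; residuals have exactly
zero sample covariance with oestradiol. Outcome models are
random-intercept linear mixed models fitted with statsmodels MixedLM
(optimizer cascade lbfgs → bfgs → powell → nm, predictors standardised
internally and estimates rescaled back exactly). Per-hormone inference:
χ²(1) likelihood-ratio tests between ML fits with and without the
hormone's slope; slopes and standard errors from the REML fit of the full
model; confidence intervals use t critical values at residual degrees of
freedom (small-sample practice). ROI enters as a categorical fixed effect
with the "global" rows as reference level, so interaction contrasts read
as deviation-from-global; laterality enters as a fixed effect when
present. The interaction follow-up is gated on a significant main effect
and reports the hormone × ROI LRT plus per-ROI Wald t contrasts at
residual df. Outlier handling drops rows with |standardised residual| >
k (default 2.5) and refits once, reporting the exclusion count. Missing
sessions are simply omitted (mixed models tolerate unbalanced panels);
no multiple-testing correction is applied by default across outcome
families.

A calibration caveat measured by the validation suite: at the study-like
design (21 participants, 52 sessions, intraclass correlation ≈ 0.8,
realistically skewed hormone distributions), the per-hormone tests are
anticonservative — null rejection at α = 0.05 is ≈ 6% for oestradiol and
≈ 8–9% for resProgesterone, whose leverage concentrates in the ~18
mid-luteal sessions. This is a property of mixed-model fixed-effect
tests at this sample size, not of the implementation (alternative
likelihood implementations reproduce the same statistics, and
Satterthwaite/Kenward–Roger-style corrections do not calibrate the
resProgesterone test either). p-values near 0.05 for high-leverage
hormone covariates in designs of this size should be read accordingly.

High/low state selection takes each participant's extreme phases with
ties resolved towards the earlier phase for the low state and the later
phase for the high state; single-phase participants are excluded. State
PCA z-scores columns (mean-imputing missing cells after z-scoring,
dropping all-missing variables), eigendecomposes the Pearson correlation
matrix, fixes component signs by making the largest-|loading| element
positive, and reports loadings (eigenvector × √eigenvalue), variance
fractions and cos² (squared coordinate over squared norm) per variable
and per observation. Cross-condition projection standardises the high
state with the low state's means/SDs and scores it on the low state's
eigenvectors; alignment change per component is the relative change in
mean per-observation cos². Per-observation cos² is one reading of "how
much each participant's data aligns with a component"; the absolute
score share is available from the returned scores if preferred.

Power: the smallest n whose two-sided one-sample t-test power (exact
noncentral-t tails, noncentrality dz·√n, df n−1) reaches the target; a
vectorised Monte-Carlo simulation serves as an independent oracle.

## Synthetic cohort

Phase-specific hormone distributions (pmol/L, nmol/L): oestradiol
150 ± 60 (EFP), 550 ± 250 (LFP; the peak is variably captured, hence the
large spread), 400 ± 150 (MLP); progesterone 1.5 ± 0.8, 3 ± 1.5, 30 ± 12,
truncated at physiological floors. These yield average within-participant
oestradiol excursions around 500 pmol/L and resProgesterone excursions
around 20 nmol/L. Outcomes are linear in oestradiol and resProgesterone
(defaults 0.0195 and 0.17 on a perfusion-like outcome, intercept 45,
participant intercept SD 5, residual SD 2.5) — with these conditions the
fitted χ² statistics fall in the range a strong hormone effect produces
at this cohort size. The default missing pattern thins 21 participants
to 17/17/18 sessions per phase; it is configurable, as are per-ROI slopes
for interaction studies.

All generators are seeded (`numpy.random.Generator`); identical seeds
give bit-identical outputs, and the pipeline fans a single seed into
per-stage substreams so adding a stage never perturbs another stage's
draws. All noise is additive Gaussian: at the simulated SNRs the Rician
floor of magnitude MRI is negligible, and Gaussian noise keeps the
generators analytically transparent. What passing tests show is that the
measurement chains invert their own forward models at realistic noise;
they do not certify robustness to motion, segmentation error, coil
inhomogeneity, physiological confounds or model misspecification, none
of which the generators emulate.

## Known limitations

- ASL: no motion correction, registration or GM segmentation (masks and
  parcellations are inputs); single-compartment model without dispersion.
- TRUST: sagittal-sinus (global) oximetry only; calibration coefficients
  are config values, not re-derived.
- DIMAC: beat detection is a heuristic (documented above); no velocity
  calibration of the signal.
- OCT-A: consumes already-binarised images; radius accuracy is
  quantisation-limited at instrument pitch; no artery/vein separation.
- Statistics: mixed-model hormone tests are anticonservative at small n
  (measured above); PCA conditions with few participants are exploratory.
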