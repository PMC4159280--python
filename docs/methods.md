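# Methods

This note documents the models, estimators and numerical choices behind
`peptidome`, what the synthetic cohorts do and do not emulate, and the
limits of what the test suite demonstrates.

## Synthetic cohorts

The generator emulates linear-mode MALDI-TOF profiles of bead-enriched
urine. Each cohort draws a set of "common peaks" shared by all subjects
(default 200, log-uniform positions on m/z 1,000–12,000, so the low-mass
region is crowded as in real peptide maps), always including the seven
realignment anchor peaks (m/z 1162 … 3373) at high abundance. Per-subject
peak areas are the group mean times a lognormal biological factor
(`subject_cv`, default σ = 0.4 — a 40–50% coefficient of variation, typical
of urinary peptide abundances); replicate spots add a smaller lognormal
technical factor (σ = 0.1). Case subjects' planted discriminant peaks are
scaled by the configured fold change (up or down); optional age-linked
peaks mix a standardized age covariate into the lognormal exponent at a
configurable rank-correlation strength.

A spectrum is the sum of Gaussian peaks with FWHM = m/z ∕ R (R = 800, the
instrument resolution used for data selection), an exponentially decaying
chemical baseline `B·exp(−(m/z−low)/τ)` (B = 30, τ = 2000 Da), additive
Gaussian detector noise, and a per-spectrum multiplicative m/z distortion
drawn as N(0, `calibration_error_ppm`) (default 150 ppm, comfortably inside
the 1000 ppm realignment tolerance). Intensities are clipped at zero. The
default grid step is 0.5 Da, resolving peaks of ≥ 1000 Da at desk-scale
array sizes.

Ages are truncated normals per group — controls/benign N(48.7, 12²) on
24–79 y, patients N(64.53, 10.97²) on 33–88 y, the clinical cohort
structure — and sex is Bernoulli(0.6 male). `simulate_feature_matrix`
bypasses spectrum rendering and returns replicate-averaged areas directly;
it is used for statistical calibration studies where the spectral layer
would only slow the loop without changing the question.

Not emulated: isotope fine structure and reflector-mode envelopes,
detector saturation, peak tailing/asymmetry, chemical (structured)
baseline noise, batch effects, and missingness mechanisms other than a
peak falling below the S/N threshold. Passing tests therefore show the
pipeline recovers truth under a well-behaved forward model; they do not
certify performance on real instrument quirks.

## Preprocessing

*Baseline.* "Convex hull with flatness f" has no published formula, so the
package defines it reproducibly: the intensity is first passed through a
running minimum whose window spans `(1 − f)` of the m/z range, then the
lower convex hull (Andrew monotone chain) of that floor is interpolated
back and subtracted, flooring at zero. `f = 1` is the pure hull — exact
for any convex background and idempotent (re-correcting changes nothing
beyond 1e−9 of the maximum); smaller `f` lets the baseline hug broader
curvature on spiky spectra. Default `f = 0.8`.

*Normalization.* Total-ion-current: intensities are rescaled so their sum
equals a target constant (1.0). Scale-invariant and idempotent.

*Recalibration.* Detected apexes are matched to the nearest reference
peak within its ppm tolerance (linear mode: 7 anchors at 1000 ppm;
reflector mode: 4 at 100/100/100/200 ppm). The warp interpolates the
matched ppm shifts piecewise-linearly across m/z, holding the shift
constant beyond the outermost anchor, so no point can move by more than
the largest matched shift (≤ the matching tolerance). Spectra matching
fewer than 4 (linear) / 2 (reflector) anchors are excluded as
non-recalibratable; the anchor minimums are our choice (enough points to
constrain a piecewise warp) where the source protocol is silent. A
planted global +500 ppm distortion is corrected to < 50 ppm residual at
the anchors.

*Averaging.* Replicates are linearly resampled to a common grid and
averaged pointwise into one mean spectrum per subject. The pipeline order
is fixed: baseline → normalize → recalibrate → average.

## Peak detection and areas

Peaks are picked on the total average spectrum (pointwise mean of subject
mean spectra). A candidate local maximum must clear S/N ≥ 3, where noise
is 1.4826 × MAD in a 100-point window around the apex (robust to
neighbouring peaks) and signal is the apex height above the window median
(the median absorbs the positive pedestal left by zero-clipped noise).
Candidates must also span at least 40% of the instrument peak width
(FWHM = m/z∕R) at half height — a resolution-800 profile cannot produce a
two-point spike, so this rejects residual noise bumps without touching
real peaks. Apexes closer than m/z∕R merge into the taller one.

Apex positions are refined by a least-squares parabola over the points
above 35% of apex height: symmetric sampling keeps the vertex unbiased
and averaging over the peak top localizes a 10×-noise peak to within half
a 0.5 Da grid step.

Peak bounds are the nearest flanking local minima ("zero-level",
valley-to-valley); per-subject areas are trapezoidal integrals over those
bounds, floored at zero, with absent peaks contributing area 0. Feature
labels are the nominal integer m/z (collisions keep one decimal).

## Statistics

*Age filter.* Ions whose areas rank-correlate with age (Spearman,
midrank ties, α = 0.05) are excluded before classification. When case and
control age distributions differ — as in the emulated cohort, where
patients average 16 years older — every genuine disease marker is
marginally age-correlated through the group difference alone, so the
orchestrator assesses the correlation **within the control group**; the
plain all-subject variant remains available. Constant ions (ρ undefined)
are retained with ρ recorded as 0.

*Group comparison.* Per ion, Shapiro–Wilk normality in each group and
median-centred Levene homogeneity (both at α = 0.05) gate the test: both
pass → pooled two-sample *t*; otherwise Mann–Whitney *U*. These are the
standard instantiations of the stated assumption gate; the source names
no specific tests. Direction is Up/Down by the case-vs-control median at
p < α, n.s. otherwise; p-values are also binned (<0.001, <0.05, >0.05).
No multiple-testing correction is applied by default, mirroring per-ion
reporting; Benjamini–Hochberg is available behind `fdr=True`. Under a
global null the fraction of ions at p < 0.05 calibrates to 0.05 ± 0.02.

## Classification

The split assigns round(n × 0.6) subjects per class to training
(deterministic given the seed); 153 + 137 subjects yield validation sets
of 61 and 55. Forward selection starts from the empty panel and, each
round, scores every remaining candidate by the k-fold (k = 10,
stratified) cross-validated accuracy of a linear SVM (C = 1, features
z-scored on the training folds) on the current panel plus the candidate.
Folds are drawn once per run so all candidates share them (variance
reduction; one cross-validation operator). The best candidate is added;
selection stops when no candidate *strictly* improves accuracy or at 20
features. Ties break toward the lower nominal m/z — deterministic and
reproducible. The kernel, C and z-scoring are our instantiation: the
discrimination burden is carried by the selection loop, and a linear
margin suits n ≪ p. A consequence of the strict-improvement stop is that
once a single planted ion saturates CV accuracy, a second genuine marker
is not added; this is the dominant failure mode in the panel-recovery
property (≥ 9/10 seeds recover both planted ions).

Training-phase performance is reported as pooled k-fold CV predictions on
the selected panel, in the same confusion-matrix layout as the
independent validation — both modes are emitted because published
whole-cohort CV tables and training-fraction captions can disagree about
which subjects they cover. ROC curves order subjects by decreasing
decision value, stepping ties diagonally in one move, which makes the
trapezoidal AUC equal the normalized Mann–Whitney statistic exactly.
Report percentages are rounded to 2 decimals.

## Mass identification

Masses are computed from residue elemental compositions: monoisotopic
masses from the principal isotopes, average masses from CODATA-2005
standard atomic weights (C 12.0107, H 1.00794, N 14.0067, O 15.9994,
S 32.065 — the table in long-standing use by vendor software; water
18.010565/18.01528, proton 1.007276, N-acetyl +C2H2O =
42.010565/42.0367). Cysteine is the free thiol: endogenous urinary
peptides are searched with no enzyme and no fixed modification, and the
published monoisotopic mass of the acetylated GP162 fragment is
reproduced only without carbamidomethylation. With these tables all eight
published monoisotopic [M+H]⁺ values are matched to ±0.001 Da and seven
of eight averages to ±0.005 Da; the printed average of the acetylated
GP162 fragment is internally inconsistent with its own printed
monoisotopic mass (no standard weight table brings them within 0.02 Da)
and is flagged in the test suite rather than matched.

ppm errors are signed, (observed − reference)/reference × 10⁶ — this
convention reproduces the published reflector-mode extremes (−53, +72).
Alignment goes linear-mode label → nearest reflector-mode peak within
1000 ppm (linear-mode labels are nominal integer masses recalibrated at
1000 ppm, so a tighter default would drop genuine matches) → all ESI
identifications whose theoretical monoisotopic [M+H]⁺ lies within
100 ppm of the reflector mass. Every candidate inside tolerance is kept;
more than one flags the signal as ambiguous (the m/z 2192 signal matches
both the GP162 and KPB1 fragments, 0.14 Da apart). Linear-mode ppm
comparisons use the average-mass table, since linear-mode signals
integrate the unresolved isotope envelope. The published linear-mode MME
range is not recomputable from rounded nominal labels and is reported but
not asserted.

## Problem sizes in tests and acceptance

The calibration properties run at stated reduced designs: panel recovery
uses 60 + 60 subjects with 2 planted fold-3 ions among ~100 uninformative
ones over 10 seeds; the null-cohort AUC runs the full spectral pipeline
at 50 + 50 subjects, 2 replicates, ~80 peaks on m/z 1,000–5,000 over 25
seeds and is asserted on the across-seed mean (a single 20 + 20
validation split has AUC standard error ≈ 0.1 under the null, so
per-seed bounds would test the sample size, not the pipeline); the
strong-effect check plants 12 fold-4 ions at low noise; the type-I rate
pools 100 null cohorts of 20 + 20 subjects × 50 ions via the
feature-level fast path. These sizes are the package's simulation
designs; scaling them up changes runtimes, not conclusions.

## Known limitations

- The baseline's flatness parameter is a declared reinterpretation of an
  undocumented vendor setting; absolute area values differ from vendor
  output, though group contrasts are preserved.
- The forward-selection stop rule can under-select correlated true
  markers once accuracy saturates (see above); the published workflow
  appears to share this property.
- Recalibration assumes a smooth, slowly varying m/z distortion;
  pathological warps between anchors are not detectable.
- Average-mass values depend on the atomic-weight vintage at the third
  decimal; the CODATA-2005 table is pinned for comparability with the
  published values.
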