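# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limits of the `strokebeta` pipeline.

## Signal model and spectral connectivity

Six ROI source time courses (ipsilesional/contralesional M1, S1, S2 —
labelled `c*`/`i*` because every subject is represented as
right-hemisphere-lesioned, mirroring the convention of flipping left
hemisphere lesions) are modelled as a stationary MVAR(p) process within
each analysis window:

    X_t = sum_{k=1..p} A_k X_{t-k} + eps(t),    Cov(eps) = C.

* **Estimation.** OLS on the lagged design pooled over epochs; lags never
  cross epoch boundaries. Default order p = 6 (fixed, with an override
  argument rather than an order-selection criterion). The residual
  covariance uses the 1/(T−1) denominator. Rank deficiency raises an
  error naming the deficient lag block; a fit whose companion matrix has
  an eigenvalue on or outside the unit circle is flagged (warning), since
  estimation noise can push a near-unit-root fit across the circle.
* **Spectra.** A(f) = Σ A_k e^{−i2πfk/fs}; Ā = I − A; H = Ā⁻¹;
  S = H C Hᴴ. The Hermitian-transpose factorization is the only one that
  makes S Hermitian positive-semidefinite with real nonnegative power on
  the diagonal. PSD = diag(S)/fs (two-sided density convention — the
  oracle test compares against `scipy.signal.welch(...,
  return_onesided=False)`). MSC is clipped into [0, 1] against rounding.
  PDC uses the source-column normalization (Σ over targets of PDC² = 1 at
  every frequency, enforced to 1e−10 in tests); entry (i, j) is the
  influence of source j on target i. Frequency grid: 1–45 Hz in 0.5 Hz
  steps.
* **Time resolution.** Sliding windows (0.2 s length, 0.05 s step), each
  fitted by pooling that window's samples across all epochs. Band/window
  summaries are arithmetic means over frequency bins in 13–30 Hz and
  window centers inside the rebound window. A whole-epoch single fit is
  the degenerate case (step larger than the epoch).
* **Rebound window.** The beta envelope (band-pass 13–30 Hz, squared
  analytic signal, epoch-averaged, expressed relative to the −0.5–0 s
  baseline) is tested against zero at every post-stimulus time point with
  a sign-flip permutation test; the window is the longest contiguous
  significant positive run. If none exists the canonical 0.6–1.2 s window
  is used with a warning. On generated cohorts the derived window is
  typically ≈ 0.63–1.28 s: the lower edge lags the planted 0.6 s onset by
  the envelope's rise time and the upper edge overshoots 1.2 s by the
  filter/Hilbert smoothing, giving Jaccard ≈ 0.8 against the planted
  interval.

## Permutation statistics

One-sample deviations from zero use sign-flip resampling of a textbook
one-sample t; group differences use row-shuffle resampling of a
pooled-variance two-sample t. Decisions are two-sided on |t| against the
95th/99th percentiles of the null, with the add-one p-value
(1 + #{|t*| ≥ |t|})/(n_perm + 1) so p is never zero; the percentile
decision is additionally guarded by the p-value so a degenerate null
massed at zero cannot produce spurious significance. Default 5000
resamples. Zero-variance inputs: p = 1 when the mean is zero, exact
enumeration of all 2ⁿ sign patterns otherwise (n ≤ 20). Families can be
summarized per-test (default, matching per-connection reporting) or with
a max-statistic threshold for family-wise control; max-stat assumes the
family shares one permutation seed.

Connection *strength* ("MSC different from zero") is tested by default on
MSC minus a subject-specific surrogate baseline (20 phase-scrambled
surrogates per subject; phases randomized independently per epoch and
channel, which preserves each amplitude spectrum while destroying
cross-channel dependence), because raw MSC is positively biased and never
zero. The surrogate MSC is computed from one pooled fit over the analysis
window — re-estimating the full sliding grid per surrogate would multiply
cost ~40× without changing the estimated bias. A raw-MSC mode exists
behind a flag. Directionality uses the asymmetry PDC_ij − PDC_ji averaged
over band and window, sign-flip tested against zero.

## Lesion metrics

Binary masks on a voxel grid, 0-based indices, volumes from the
voxel-size product; no world-affine math (fixtures are grid-native, and
NIfTI I/O maps voxels directly). Streamline–lesion intersection is "any
shared voxel". ROI damage = 100·|lesion ∩ ROI|/|ROI|. Tract disconnection
= percent of the tract's streamlines intersecting the lesion; the
projection mean averages CST/CS/CT/FPT/PPT and the commissural mean the
three callosal segments (exact arithmetic means, tested). The voxel-wise
disconnection map divides, per voxel, lesioned through-streamlines by all
through-streamlines. SSPL is a BFS hop count on the parcel graph (edge =
≥ 1 streamline with endpoints in both parcels); the lesioned graph keeps
an edge if at least `min_intact` (default 1) supporting streamlines avoid
the lesion. A pair disconnected by the lesion gets an explicit `inf`
sentinel; group statistics drop non-finite values (with the subject count
implicit in the per-feature n) rather than imputing a large number. All
metrics are monotone under lesion growth (property-tested).

## Synthetic study conditions

The generator is first-class code and defines the conditions every test
runs under:

* **Cohort structure.** Default n = 36: low/high initial function planted
  20:16 and improvers within the low group 8:20 (the analysis' group
  sizes); labels drawn first, severity conditional on label (low: U(0.85,
  1), high: U(0.05, 0.7)), so the NHPT map reproduces the split by
  construction. NHPT_T0 = 20 + 100·severity + N(0, 5²) s, clipped into
  the label's side of the 100 s cutoff and capped at 120 s (severity 1 =
  did not finish). Improvers lose 10–40 s at T1; non-improvers repeat T0
  exactly.
* **Dynamics.** Per ROI an AR(2) pole pair at 20 Hz with radius 0.95
  inside the order-6 stack; all time-varying behavior is gain modulation
  of the innovations (baseline gain 1, suppression ≈ 0.4 over 0.2–0.5 s,
  subject-specific rebound gain over 0.6–1.2 s with short linear
  transitions), which preserves stability by construction. Ipsilesional
  rebound gain: 1.5 (high function), 1.2 (low, improver), 0.9 (low,
  non-improver), jitter SD 0.05; contralesional gain 1.4 throughout.
* **Couplings.** At a shared resonance a directed coupling c transfers
  roughly c²|H(f₀)|² ≈ 400 c² of the source power into the target, so
  couplings must stay well below 0.05 or they swamp the planted gain
  effects in raw band power. Chosen once: intra-hemispheric S2→S1, S2→M1,
  S1→M1 couplings of 0.01 (low) vs 0.04 (high function); an
  inter-hemispheric M1→M1 and S1→S1 drive of 0.015 planted only within
  the low-function group, ipsilesional→contralesional for improvers and
  the reverse for non-improvers, with zero reverse coupling. PDC reads
  the coefficients directly (and the Ā diagonal is small at resonance),
  so these small terms are reliably detectable while their power transfer
  stays second-order. Every emitted stack passes the companion-eigenvalue
  check (max modulus 0.95).
* **Stimulation.** 60–80 stimuli at an interstimulus interval of 1.5 s
  (default) or 3.005 s; epochs −0.5 to 1.5 s or −0.5 to 3 s accordingly.
  With the 1.5 s interval the previous trial's rebound tail overlaps the
  next baseline, exactly as in a real fast protocol; this damps the
  apparent relative rebound but leaves all group orderings intact. An
  optional dropout fraction thins triggers, standing in for trial loss
  whose true rate is unknown.
* **Lesions.** A 24³ grid at 2 mm with cortical ROI blobs, subcortical
  parcels, descending projection tracts funneling through an
  internal-capsule corridor (per-streamline waypoint jitter so partial
  disconnection varies continuously), three callosal segments above the
  corridor, and association streamlines M1–S1 and S1–S2 (no direct M1–S2
  streamline, so that pair's intact SSPL is 2). Lesions are ellipsoids in
  the corridor with radius increasing in severity and an extra
  enlargement for non-improvers. The atlas stands in for population
  parcellation/tractography resources with the same interfaces
  (`make_atlas_fixture` — synthetic by construction).
* **What the generator does not emulate:** sensor-space physics, 1/f
  background spectra, ocular/cardiac artifacts, spatial leakage between
  ROIs, registration error, or lesion shapes beyond smooth ellipsoids.
  Passing tests therefore demonstrate that the *analysis chain* recovers
  planted effects of realistic size and direction — not that it would
  survive every pathology of real MEG/MRI data.

With every planted effect set to zero the generator produces exchangeable
groups, and the permutation batteries reject at the nominal ~5% rate
(calibration tested at 500 replicates).

## Prediction

Outcome coding: improved = 0, didn't improve = 1 (the positive class for
sensitivity/PPV; the flipped orientation is always reported alongside).
Candidates default to the seven features the group analyses motivate:
ipsilesional M1 and S1 rebound power, intra- and inter-hemispheric S1–M1
MSC, lesion volume, projection mean, commissural mean. Pipeline per fit:
z-scoring (n−1 denominator), VIF screening (threshold 2.5; columns above
it are grouped by pairwise |r| ≥ 0.7 and each group replaced by the mean
of its z-scores), forward stepwise logistic regression on Wald p-values
(enter < 0.15, remove ≥ 0.15; a visited-state guard terminates
enter/remove cycles, which the equal thresholds otherwise permit), with a
backward variant for stability checks. Logistic fits are IRLS to 1e−8;
separation (divergent coefficients or singular information) is flagged
and refit with a small ridge (1e−4) so 20-subject cohorts never crash.

LOOCV is honest: merging, selection, and fitting are re-run on every
training fold, and the held-out probability never sees its own row
(property-tested by mutating the held-out label). A full-sample stepwise
fit is reported separately for coefficient interpretation. Brier score =
mean squared probability error; AUC by the Mann–Whitney/midrank
formulation; confusion counts at probability 0.5; proportions carry exact
Clopper–Pearson 95% CIs. Under the null, honest CV with in-fold selection
is pessimistic — AUC at or slightly below 0.5 — which is the expected
behavior, not a defect; planted-effect cohorts clear 0.8.

## Problem sizes and orchestration

The default demo (`run_all`): 36 subjects, 60 stimuli, 5000 permutations,
20 surrogates — about 20–30 s on one CPU and bit-reproducible under a
fixed seed (artifact SHA-256 manifest compared across reruns). The
acceptance script's heavier recomputations (500-replicate calibration,
50-seed recovery checks, 20-cohort rebound recovery, 100-fixture oracle
sweeps, double end-to-end run) total a few minutes. Oracle checks at
larger n (e.g. 2¹⁶-sample spectra) are sized so their statistical noise
is far below the tolerances they enforce.

## Known limitations

* The MVAR is fitted per window under a local-stationarity assumption;
  rapidly time-varying coupling within a 0.2 s window is averaged out.
* PDC magnitudes depend on the source-column normalization convention;
  comparisons across conventions (e.g. generalized/row-normalized PDC)
  are not meaningful.
* The surrogate MSC baseline corrects the dominant positive bias but not
  epoch-count-dependent variance differences between subjects with very
  different trial counts.
* SSPL uses unweighted hop counts on a binary parcel graph; streamline
  counts beyond the `min_intact` threshold carry no weight.
* The stepwise/LOOCV machinery targets the small-cohort regime (n ≈ 20);
  for large feature sets penalized alternatives would be preferable and
  are out of scope.
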