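# Methods

`podeeg` implements an intraoperative-EEG risk model for postoperative
delirium (POD): four frontal channels (Fp1, Fp2, F7, F8) recorded during
general anesthesia, plus the handful of clinical covariates available in
any operating room, are turned into three classifier probabilities that
are fused into one risk number per patient. This note documents the
model, its assumptions, the tunable parameters, and what the synthetic
cohorts used for validation do and do not establish.

## Processing model

**Cleaning.** Raw EEG is cleaned in a fixed order: (1) an amplitude
artifact mask from the patient's pooled 99 % quantile of absolute
amplitudes (one threshold per patient because amplitude scales differ
between recordings; flagged samples are dilated by 0.1 s to cover spike
neighborhoods); (2) common average reference; (3) zero-phase Butterworth
band-pass 0.3–50 Hz; (4) segmentation into maximal artifact-free runs,
shrunk by a 1 s edge pad at every boundary (filter edge effects) and
discarding runs under 1 s; (5) per-patient z-scoring over the pooled
segments. Patients with less than 20 min of clean EEG are excluded (the
20-minute boundary counts as included). The band-pass order is 5: a
zero-phase order-4 filter attenuates a 60 Hz tone at 256 Hz sampling by
only 88 % (18.7 dB), short of the ≥ 20 dB stop-band requirement the
pipeline is specified to meet; order 5 gives ≈ 23 dB with an unchanged
passband.

**Burst suppression.** A channel-averaged sliding-RMS envelope (0.25 s
window) on the z-scored segments marks a sample suppressed when the
envelope stays below 0.2 z-units for at least 0.5 s. Because the signal
is z-scored, the threshold must be relative; 0.2 z corresponds to an
~86 % amplitude drop in a signal that is suppressed ~25 % of the time.
From the timeline follow the burst suppression ratio (BSR = suppressed
time / artifact-reduced recording time) and the longest suppression
phase (LSP), with runs never bridging artifact gaps — unobserved time is
not claimed suppressed. The suppressed set is monotone in the threshold.

**Spectral frames.** Each segment gets a Welch PSD (1 s periodic Hann
windows, 50 % overlap, FFT zero-padded ×2 for a 0.5 Hz grid, channels
averaged, grid 0.5–50 Hz). Segments are grouped into 2-minute frames of
*clean* time — the concatenated artifact-free axis, so every frame holds
a comparable amount of data — by their midpoints, and frames average
their segments' PSDs. Classifiers consume log10 power. The Welch
estimator is computed by a vectorized routine verified in the tests to
be numerically identical (≤ 1e-12) to `scipy.signal.welch`; the
indirection exists because the pipeline computes tens of thousands of
small spectra per cohort.

**Covariance frames.** The z-scored segments are band-filtered into
delta (0.3–4), theta (4–8), lower alpha (8–12), higher alpha (12–15),
lower beta (15–20) and higher beta (20–30 Hz); the 6×4 filtered rows are
stacked with the suppression timeline into a 25-row multiband signal.
Per-segment covariance uses the exact closed-form oracle-approximating
shrinkage (OAS) of Chen, Wiesel, Eldar & Hero (2010), including the 2/p
terms (scikit-learn's `oas` intentionally drops them, which matters at
the segment lengths seen here; the package codes the published formula
and keeps scikit-learn as a large-n cross-check). OAS output is always
symmetric positive definite, so every frame is a point on the SPD
manifold. Frame covariance is the arithmetic mean of its segment
covariances (SPD, cheap; whether the original frame mean is Euclidean
or Riemannian is unknowable — an explicitly open choice). An adaptive
Riemannian potato rejects outlier frames: each frame's affine-invariant
distance to a running geometric mean is z-scored against the last 50
inlier distances (mean/SD) and flagged above z = 2.5; the mean moves a
geodesic step of 0.1 toward inliers only; the first 10 frames seed the
statistics and are then scored like any other. Flagged frames are
removed from the covariance *and* spectral streams so both classifiers
see the same frames. Because the metric is affine invariant, the mask is
unchanged under common rescaling of all frames.

## Classifiers

**patient / patient+burstsupp.** A balanced random forest (500 trees,
√d features per split, unlimited depth): each tree grows on a bootstrap
of the minority class plus an equal-size draw from the majority, making
the per-tree class ratio 1:1 regardless of the ~19 % POD prevalence.
Features: age, ASA score, operation length (exact duration), a
benzodiazepine premedication flag, one-hot induction
(Propofol/Thiopental/Etomidate) and maintenance
(Propofol/Desflurane/Sevoflurane/Isoflurane) agents; unseen levels map
to "Other" so a frozen model never crashes on a new cohort. The
patient+burstsupp variant appends BSR and LSP.

**spec / cov.** Frames are classified by a bagged ensemble of
class-weighted linear SVMs with two-level undersampling: (1) keep all
minority patients, subsample the majority to max(minority, ⌈majority/3⌉);
(2) sample up to 10 frames per patient (20 per minority patient for the
covariance stream, which diversifies the minority side of the reference
point). Each candidate SVM is accepted only if its AUC over *all* frames
of the full training set reaches a threshold starting at 0.70; after 5
consecutive rejections the threshold decays by 2.5 % (multiplicative),
so training terminates with exactly R = 25 saved estimators. A patient's
probability is the mean ratio of frames classified POD over estimators
and frames — p = (1/(R·T)) Σ_r Σ_t c_{r,t} — with a zero SVM decision
value counted as non-POD. Covariance frames are first projected to the
tangent space at a class-balanced Riemannian reference point (the
Karcher mean of the two class Karcher means, computed from one balanced
sampling draw at ensemble start and shared by all R estimators); tangent
vectors use the upper-triangle vectorization with √2 off-diagonal
scaling, so the vector norm equals the manifold distance to the
reference. The reference is serialized with the model and reused on new
cohorts without refitting. The linear SVMs run with `dual=False`,
`tol=1e-3`: on these noisy overlapping frame clouds a tighter tolerance
multiplies cost several-fold without changing AUC.

**Fusion.** p_comb = max(p_patient+burst, min(p_spec, p_cov)) — a
deliberately false-negative-averse rule: a low-risk call needs the
clinical classifier *and* at least one EEG classifier to agree. Because
the three probabilities are different kinds of averages, each
classifier's g-mean-optimal training threshold (g = √(TPR·(1−FPR)),
candidates at midpoints of distinct sorted probabilities, ties toward
the smaller threshold, 0.5 for degenerate inputs) is shifted to 0.5; the
subset of classifiers actually shifted (all three, or each two-of-three)
is the one maximizing the training AUC of p_comb, with ties resolved in
a fixed preference order. Shifted probabilities are clipped to [0, 1].
To keep small probabilities informative, p_comb is replaced by the plain
mean p_m of the classifiers with training AUC ≥ 0.55 whenever
p_m < 0.25. Binary calls use the fixed 0.5 threshold, chosen to keep the
negative predictive value high. Threshold and shift selection uses
out-of-bag probabilities for the forests — in-sample balanced-RF
probabilities are nearly separated and carry no threshold information —
and in-sample frame-ratio probabilities for the ensembles, whose bagging
already leaves most frames out of each base learner's draw.

**Grouping and transfer.** Because maintenance agents shape the EEG,
one full stack is trained per agent group (Propofol, Desflurane,
Sevoflurane) with ≥ 20 patients and both classes, plus an
all-medications stack that also serves patients on other or mixed
agents. Transfer to a new cohort refits nothing: saved reference points,
forests, ensembles and shifts are applied as-is.

## Evaluation protocol

Repeated stratified cross-validation at the patient level (all frames of
a patient stay in one fold; folds stratified by POD label for validity
at ~20 % prevalence; default 10×10, the synthetic benchmark uses 2×5).
All training-derived state is fit on training folds only; each fold
records its training patient ids and a SHA-256 hash of ids+labels so
leakage is auditable. AUC-ROC is the performance measure (Mann-Whitney
normalization, ties ½), NPV = TN/(TN+FN) at the 0.5 call threshold
(reported missing when there is no negative call). Exclusions (< 20 min
clean EEG, missing clinical data) are applied before CV.

## Synthetic cohorts

No public dataset has this structure, so validation uses a generative
model whose defaults encode the study conditions: ~19 % POD prevalence;
agent mix ≈ 28/37/34/1 % Propofol/Desflurane/Sevoflurane/other; age
69.2 ± 6.1 y (+2.7 y for POD), ASA 2.41 ± 0.59 (+0.24), operation length
2.61 ± 1.53 h (+1.27 h), benzodiazepine rate 5.8 % (+1.1 pp); recordings
of 25–45 min at 128 Hz (the benchmark tests use 24–34 min to bound
runtime — stated here as the package's problem-size choice).

Signals are built from components with exact planted ground truth:

* 1/f ("pink") background, 8 µV RMS per channel, plus a mild common-mode
  baseline wander;
* a narrow-band alpha oscillator (Gaussian spectral bump, σ 0.75 Hz)
  with agent-dependent gain and peak (Propofol strongest/fastest),
  per-patient lognormal amplitude (σ = 0.2), *independent across
  channels* so the common average reference does not cancel it; POD
  multiplies alpha power by `alpha_power_ratio_pod` (default 0.6);
* suppression episodes from an alternating-renewal process (exponential
  episode/gap durations, amplitude ×0.05), expected fraction
  0.15 ± 0.07 plus `bsr_shift_pod` (default +0.10) for POD; a
  constructive variant plants an exact total fraction and an exact
  longest run for detector validation;
* flat-topped common-mode "electrode pop" transients (2–5 s, plateau at
  5 EEG SDs, ≥ 2 % of recording time) — they give the amplitude
  distribution the clustered heavy tail real artifacts have, which the
  pooled-quantile mask implicitly relies on; being common-mode they are
  removed exactly by re-referencing; and
* isolated spikes of 10× the patient's 99 % amplitude quantile
  (0.1–0.5 s) at 0.5/min, guaranteed above the mask threshold.

Pops and spikes are planted ≥ 1.5 s clear of suppression episodes so
that artifact removal cannot truncate the planted longest run; the cost
is a small upward BSR bias (≈ +0.01 at the default artifact load, since
removed time is never suppressed time), which the recovery tests bound.

**What the synthetic cohorts do not emulate:** pharmacodynamics and
dosage, cross-channel alpha coherence, eye/EMG artifacts, non-stationary
anesthetic depth, or any realistic coupling between clinical covariates
and the EEG (classes differ in EEG and clinical features independently).
Passing benchmarks therefore demonstrates that the pipeline recovers
planted effects of realistic size through the full preprocessing and
fusion chain and that the fusion adds value exactly when an EEG effect
exists — not that these AUC levels would be attained on clinical data.

## Numerical choices

Symmetric eigendecompositions with a 1e-12 eigenvalue floor back all
matrix functions. The Karcher mean iterates
M ← M^{1/2} exp(s·Σ w_i log(M^{−1/2}C_iM^{−1/2})) M^{1/2} from the
log-Euclidean mean (tolerance 1e-9 on the tangent-mean norm, ≤ 100
iterations, convergence failure raises with diagnostics); the step s
starts at 1 and halves whenever the tangent norm stops contracting, a
standard safeguard for spread-out matrix sets. The potato's burn-in seed
mean uses a relaxed 1e-4 tolerance — it only initializes the adaptive
reference, and frames whose suppression-timeline row is nearly constant
sit far apart on the manifold, where the fixed point converges slowly. Degenerate
inputs raise typed errors: zero-variance channels, empty segment series,
all frames potato-flagged, single-class training sets. Random state
flows from a single integer seed split deterministically per stage; the
same seed reproduces cohorts, threshold histories and predictions
bit-exactly.

## Known limitations

The suppression detector's parameters (envelope window, z-threshold,
minimum duration) are conventional choices, configurable rather than
asserted as canonical. Whether 2-minute frames should follow wall-clock
or clean time is ambiguous; clean time was chosen so frames carry
comparable data. The potato "variation" is one reasonable adaptive
design among several. Headline clinical results (AUC ≈ 0.77 overall,
NPV ≈ 0.91 on real cohorts) cannot be reproduced here because the
underlying data are not shareable; the synthetic benchmarks above are
the substitute evidence.
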