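# Methods

`swemg` analyses 64-channel high-density surface EMG (HD-sEMG) recorded
over the submental and infrahyoid muscle groups during swallowing, and
classifies dysphagia severity into four levels (none / mild / moderate /
severe). This note documents the models, the numerical choices, and what
the synthetic data generator does and does not emulate.

## Electrode grid

The array has 64 channels in three patches:

* infrahyoid left (channels 1–24) and right (41–64): mirrored 6-row ×
  4-column patches, 11 mm row and column pitch;
* submental (channels 25–40): one 2-row × 8-column patch straddling the
  midline, 5.5 mm row pitch and 11 mm column pitch.

Coordinates are planar millimetres: origin on the body midline at hyoid
level, `x` positive toward the subject's left, `y` positive superior.
Channel numbering within a patch is row-major (columns by increasing `x`,
rows superior→inferior); this assignment is a documented convention — the
symmetry and barycenter indicators depend only on the mirror pairing and
the coordinates, never on which physical electrode carries which number.
Mirror pairing about `x = 0` gives 8 pairs inside the submental patch and
24 pairs across the infrahyoid patches.

## Preprocessing

Signals (µV, 1000 Hz) pass a zero-phase 4th-order Butterworth band-pass of
20–500 Hz followed by Q = 30 IIR notches at the powerline fundamental and
its odd harmonics (50, 150, 250, 350, 450 Hz). Three deliberate choices:

* **Upper band edge.** At 1000 Hz sampling the 500 Hz edge coincides with
  Nyquist; the design edge is clipped to 0.998 × Nyquist to keep the
  band-pass topology rather than silently dropping the low-pass half.
* **Odd-harmonic notches.** Powerline interference harmonics are
  predominantly odd (symmetric nonlinear loads suppress even ones), and
  restricting the notch set keeps 100 Hz and neighbouring EMG content
  untouched. An arbitrary set of notch centers can be passed explicitly.
* **Coherent line regression.** Stationary sinusoids at the notch
  frequencies are removed first by least squares (amplitude + phase per
  channel), in the spirit of regression-based line removal used in
  EEG/EMG (e.g. CleanLine). Zero-phase filtering of a recording that
  still contains a strong line component makes the high-Q notches ring
  for ~0.2 s at the recording edges; with the coherent component
  regressed out they have nothing to ring on.

All filtering is forward–backward (zero phase) so envelope timing, and
hence the detected onset, carries no group delay. The envelope is a
moving-RMS of the signal over a 100 ms window, with the window shrinking
at the boundaries (a constant input maps to a constant envelope).

Amplitude metrics: RMS = √mean(x²), MAV = mean |x|, and
SNR = 20 log₁₀(RMS_active / RMS_rest) dB. The active/rest-ratio SNR
definition is an assumption (no closed form is standard); the generator's
burst "SNR" targets use the same definition so the two agree.

## Swallow capture

Detection operates on the mean envelope of the 16 submental channels
(swallow initiation is expressed submentally first). The threshold is the
mean of a 1500 ms reference span of that envelope plus 3 × its population
standard deviation. In *healthy* mode the reference is a resting span
(default: the first 1500 ms of the trial); in *dysphagia* mode the hyoid
muscles assist bolus holding early, so the reference is that early
contraction span — the arithmetic is identical and the mode is an explicit
flag, never auto-detected.

`T_c` is the first envelope sample at or above the threshold; the analysis
window is `T_s = T_c − 500 ms` to `T_e = T_c + 1500 ms` (2000 ms).
Additional swallows are found by re-arming detection after each `T_e`.

Two robustness choices in the default pipeline wiring
(`capture_swallow`), both optional at the operation level:

* **Detection envelope without notches.** The Q = 30 notches ring ~0.2 s;
  applied zero-phase they smear burst energy *backwards*, which tripped
  the (deliberately tight) 3 SD threshold 100–300 ms before the true
  onset in simulation. The detection envelope is therefore computed from
  the band-passed, line-regressed signal; features and indicators use the
  fully notched chain.
* **Settle margin and dwell.** The first 200 ms of a trial lie in the
  zero-phase filters' edge-settle region (reflective padding inflates
  noise power there) and are excluded from the search, and a crossing
  must persist for 100 ms to count: a genuine burst exceeds the threshold
  for hundreds of milliseconds, while resting-noise grazes of a 3 SD
  threshold last a few tens. `detect_swallow`'s defaults keep the literal
  first-sample-crossing semantics.

With these defaults, onset recovery on the synthetic "none" phenotype is
within ±100 ms in 100/100 seeded trials (typical error ≈ −20 ms from the
centred envelope window).

## The three indicators

**Intensity maps.** A 3000 ms capture from `T_s` is split into six 500 ms
frames; per-frame, per-channel RMS is min–max normalised over all 6 × 64
values (an all-equal window maps to 0 by convention). Each frame is
spatially expanded per region by biharmonic-spline interpolation: the
interpolant is a weighted sum of 2-D biharmonic Green's functions
g(d) = d²(ln d − 1) with weights solving the exact interpolation system; a
1e-10 diagonal regulariser keeps the solve well conditioned without
visible smoothing (electrode values are reproduced to < 1e-6).

**Degree of symmetry (DOS).** A 1500 ms capture from `T_c` is split into
15 equal segments; for each mirrored pair the segment RMS ratio
left/right is formed, and DOS is the mean of the 15 × 8 (submental) or
15 × 24 (infrahyoid) ratios. Ratios are oriented literally left/right, so
right-dominant activity yields DOS < 1 (clinical summaries often fold
this to ≥ 1; the raw orientation is kept so the statistic remains a mean
of ratios). A right-side segment RMS below 1e-9 µV raises an error;
clamping to the floor is available but off by default.

**Barycenter and confidence ellipse.** Per segment of the same 15-segment
window, the activity barycenter is the RMS-weighted centroid of the
region's electrode coordinates (n = 16 submental, 48 infrahyoid); it
always lies in the electrode convex hull. The scatter of barycenters is
summarised by an ellipse centred at the sample mean, axes along the
covariance eigenvectors, semi-axis lengths √(q·λᵢ) with q the χ²
quantile at the confidence level with 2 degrees of freedom
(q ≈ 5.991 at 95%). Orientation ties are broken toward +x.

## Features and classifier

Each trial contributes 7 features × 64 channels = 448 features, computed
on the 2000 ms `[T_s, T_e]` window: non-excess kurtosis (Gaussian → 3;
excess selectable), envelope full-width at half maximum (ms; half-max
crossings located by linear interpolation, window edge as fallback),
sample entropy (m = 2, r = 0.2 × SD — the literature defaults; computed by
an O(n²) compiled template count, invariant to affine scaling because r
tracks the SD), and four Welch-PSD features (256-sample Hann windows, 50%
overlap): peak frequency, peak frequency / Nyquist, total power
(≈ variance by Parseval), and spectral centroid. FWHM is taken on the
envelope rather than on the PSD peak; the PSD-peak alternative sits
behind the same interface.

The classifier is a two-stage design presented as a model/results pair:

1. **Standardisation + augmentation.** Features are z-scored with
   statistics of the training split only. The training pool is balanced
   and enlarged by Gaussian jitter: synthetic samples are randomly chosen
   originals plus N(0, (0.05 × per-feature SD)²) noise with inherited
   labels, up to 2124 × 0.7 ≈ 1486 training rows by default. Augmenting
   before the 70/30 split is available behind a flag but leaks test
   information and is off by default.
2. **Scatter-matrix LDA.** The generalised eigenproblem
   S_b v = λ S_w v is solved with S_w shrunk toward a scaled identity
   (ridge 1e-3) so the problem stays well posed when samples are scarce;
   with four classes the projection is 3-dimensional (the rank bound
   C − 1).
3. **Random forest** on the 3-D projection. Default hyperparameters are
   the reference optimum (500 trees, depth 15, split 2, leaf 2). A
   genetic algorithm can re-tune them: discrete search space
   (trees 10–500 step 10; depth 5–50 or unlimited; split 2–10; leaf
   1–10), 40 generations × 50 individuals by default, tournament
   selection (size 3), uniform crossover (p = 0.7), per-gene mutation
   (p = 0.1), one elite, fitness = mean stratified-CV accuracy. With deap
   unavailable here the GA is a compact in-package implementation.

Splitting is stratified 70/30 so every class appears in both splits.
Evaluation reports accuracy, the confusion matrix, per-class recall,
per-sample probabilities, and one-vs-rest ROC/PR curves. New-subject
assessment averages the per-trial class probabilities over a subject's
repeated swallow-test trials (typically nine).

## Synthetic data generator

Each channel is baseline Gaussian tone (default 2 µV RMS) plus bursts —
unit-RMS Gaussian noise band-passed to 20–250 Hz (where surface-EMG
spectral mass concentrates), amplitude-modulated by a raised-cosine
(Tukey) envelope — plus an optional common-mode 50 Hz sinusoid (5 µV).
Bilateral asymmetry scales every left-side channel by the target RMS
ratio `r`; the generated pairwise ratio then equals `r` up to
baseline-noise dilution. All randomness flows from one integer seed, with
per-recording sub-seeds spawned deterministically.

Severity presets encode four phenotypes: *none* — one strong symmetric
sequential swallow (submental onset 2000 ms leading infrahyoid, ~30 µV,
r = 1); *mild* — the same sequence, weaker (16 µV) with a prolonged
relaxation tail; *moderate* — low-level submental pre-activation before
the main burst, prolonged infrahyoid activity, r = 1.15; *severe* —
simultaneous submental + infrahyoid recruitment, r = 2, and a repeat
swallow. Amplitudes per severity are free parameters (no quantitative
per-severity amplitudes exist to copy); they are validated only through
the recovery properties (onset within ±100 ms, DOS within 10% of the
imposed ratio at burst SNR ≥ 10 dB). Cohort generation jitters onsets
(±100 ms), durations (±10%), amplitudes (±15%) and asymmetry (±3%)
within class.

What the generator does **not** emulate: motor-unit physiology and volume
conduction, electrode–skin impedance and motion artifacts, intra- and
inter-subject anatomical variability, task (volume/viscosity) effects on
burst shape, and non-stationary or drifting powerline interference. Task
labels are metadata only. Consequently, passing tests show that the
*analysis chain* recovers known structure under realistic noise — they do
not certify clinical performance on human recordings, and the end-to-end
classification accuracy on this synthetic cohort (≥ 0.90 required by the
test suite; 1.0 observed at the default conditions) is a property of the
preset separability, not a clinical claim.

## Problem sizes and tolerances

The reference synthetic cohort is 40 trials per class (160 recordings of
6 s × 64 channels), a desk-scale stand-in chosen so the whole pipeline —
simulation, filtering, detection, 448-feature extraction, augmentation to
~1486 training rows, LDA + RF — runs end to end in a few minutes on one
core. Stochastic recovery checks average ≥ 20 seeds (DOS) or 100 seeded
trials (onset). Monte-Carlo ellipse containment uses 10⁴ points with a
±0.01 band. Interpolation exactness is asserted at 1e-6; the spline
regulariser (1e-10) sits four orders below that. Degenerate inputs
(constant segments, all-zero RMS, singular covariance, empty windows)
raise typed errors rather than returning NaNs.

## Known limitations

* DOS left/right orientation means values < 1 for right-dominant
  subjects; consumers expecting folded (≥ 1) symmetry must fold
  explicitly.
* The FWHM feature falls back to the window edge when the envelope never
  drops below half-max inside the window, truncating the true width.
* Sample entropy returns ln(n) as a finite ceiling when no template pair
  persists at m + 1 (the statistic is undefined there); constant series
  return 0.
* The GA fitness caches hyperparameter evaluations within one run but
  performs no early stopping; full-scale tuning (40 × 50 individuals with
  cross-validated forests) is minutes-to-hours of compute and is off by
  default.
* The file format stores one recording per CSV + JSON sidecar;
  multi-recording containers (e.g. HDF5) are not implemented.
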