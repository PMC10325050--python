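# Methods

This note records the models, conventions, parameters and deliberate design
choices behind `eegtriage`, in the order data flows through the pipeline.

## Signal model of the synthetic generator

Each synthetic recording is a sum of band-limited Gaussian processes — one
per frequency band (delta 1–4, theta 4–8, alpha 8–12, mu 12–16, beta 16–20,
gamma 25–40 Hz), each 4th-order-Butterworth-filtered white noise normalized
to unit variance and scaled so its power is proportional to the profile's
band weight — plus a broadband white-noise floor (default 0.15 of the
signal scale), all multiplied to a 30 µV amplitude scale. Coherence is
injected by mixing one shared latent band-limited source into every channel
with weight √c in the profile's coherence band, so the magnitude-squared
coherence between channels approaches c. Hemispheric asymmetry multiplies
the eight left-hemisphere channels (FP1, F3, C3, P3, O1, F7, T7, P7) by
(1 + a).

Default class profiles encode the standard electrophysiology of brain
injury: the Normal profile is alpha-dominant
(0.25/0.15/0.35/0.08/0.12/0.05 over the six bands); the TBI profile shows
diffuse slowing (0.45/0.25/0.12/0.06/0.08/0.04); the Stroke profile shows
slowing plus a 0.35 left-right amplitude asymmetry. Cohort demographics are
truncated-normal ages (mean 42, sd 13, truncated to the study's 18–65
range) with a 0.65 male fraction. All randomness flows through one
`numpy.random.Generator` per call; identical seeds give bitwise-identical
output.

What the generator does **not** emulate: eye-blink/EMG artifacts, line
noise, sleep architecture, non-stationarity, volume-conduction topography
beyond the hemisphere split, or pediatric EEG. Tests passing on this
generator therefore certify the pipeline's mechanics (spectral estimation,
selection, training, matching), not clinical performance on real EEG.

## Preprocessing

Standardization keeps exactly the 19 canonical 10–20 channels in fixed
order (legacy names T3/T4/T5/T6 are mapped to T7/T8/P7/P8; common clinical
prefixes/suffixes such as `EEG `/`-REF` are stripped) and resamples
polyphase at the exact rational ratio. The 1–100 Hz bandpass is a 4th-order
Butterworth applied forward–backward (zero phase, so attribution overlays
stay time-aligned); filtering precedes any downsampling so the 100 Hz edge
is never aliased. Re-referencing subtracts the instantaneous cross-channel
mean; it is idempotent and leaves a per-sample channel mean of zero to
numerical precision. Artifact removal is a hook: given an external
component labeling (brain / muscle / eye / heart / line noise / channel
noise / other, with mutually inverse mixing transforms), the signal is
reconstructed from brain components only; with no labeling the stage is a
logged pass-through. Sessions are concatenated first, the initial 60 s is
discarded once, and floor((T−60)/180) full 3-minute segments are cut with
1-based indices (segment #1 spans minutes 1–4); EDF+D (discontinuous) files
are rejected because concatenation assumes continuity.

EDF is read through `mne`; the writer is a minimal plain-EDF encoder
(16-bit, 1-s records, symmetric physical range per channel) sufficient for
round-tripping cohorts through files, with demographics and the class label
carried in the patient/recording identification fields.

## Feature engine

All spectral estimates use Welch's method: 2-s Hann windows, 50% overlap,
per-window mean detrend. Band powers integrate the one-sided density over
half-open band bins (so adjacent bands share no bin); the relative-power
and entropy denominators run over the 1–100 Hz support of the bandpass —
note the band set intentionally leaves 20–25 Hz and 40–100 Hz uncovered, so
relative powers do not sum to 1. Spectral entropy is the Shannon entropy of
the normalized 1–100 Hz spectrum divided by log(bin count), giving [0, 1].
Coherence computes the windowed FFTs once per channel and forms all 171
pair cross-spectra from them (identical math to per-pair Welch coherence,
verified against it to machine precision, at 1/20 the cost). Phase–
amplitude coupling is the mean-vector-length modulation index
|Σ A·e^{iφ}| / Σ A for three couplings (delta, theta, alpha phase → gamma
amplitude), with phases and envelopes from analytic signals of the
band-filtered trace; the three-coupling choice is configurable rather than
canonical. A channel with zero 1–100 Hz power raises a degenerate-input
error rather than emitting NaN.

The registry is a fixed total order of 1406 names
(`abs.<band>.<ch>`, `rel.<band>.<ch>`, `se.<ch>`, `coh.<band>.<a>-<b>`,
`pac.<low>_gamma.<ch>`, `stat.<stat>.<ch>`), band-major within family,
pairs lexicographic by canonical index: 114 + 114 + 19 + 1026 + 57 + 76.

## Cohort construction

Similarity exclusion embeds the feature matrix with t-SNE to three
dimensions (perplexity 30, capped at (n−1)/3 for small n; PCA
initialization; learning rate "auto"; seeded) and scores each segment by
the summed Euclidean distance to its k = min(n−1, 50) nearest embedded
neighbours; k = n−1 reproduces a literal all-points reading. The lowest
floor(0.5·n) scores are kept, ties broken by segment id. We run 3000
gradient steps rather than the optimizer's customary 1000: at 1000 the
3-D embedding is measurably unconverged (KL divergence still falling) and
planted far outliers are not yet peripheral; at 3000 they are excluded at
≥ 95% across seeds. Exclusion runs per class by default. Because t-SNE
compresses global distances, the *ranking* of extreme outliers is not
guaranteed — the supported contract is membership in the excluded half.

Matching takes each TBI recording and selects, per pool, the same-sex
candidate with minimal |Δage| ≤ 5 years; equal minima are resolved
uniformly at random under the given seed. Candidates may serve several
anchors (the default), with a without-replacement flag; recordings lacking
age or sex are skipped with a logged count.

## Feature selection

The regularized discriminant uses the pooled within-class covariance
blended toward its diagonal, Σ_γ = (1−γ)Σ + γ·diag(Σ), and per-pair
coefficient vectors β = Σ_γ⁻¹(μ_i − μ_j) with |β| ≤ δ zeroed. (δ, γ) are
chosen by seeded random search within a ≤ 30-evaluation budget (any
sequential optimizer satisfies the interface; the budget is the binding
constraint), minimizing 5-fold cross-validated misclassification of a
pairwise-vote classifier; δ is parameterized as a quantile of the
coefficient magnitudes so the search space is scale-free. The per-feature
score is the max |β| over class pairs — the multi-class reduction is our
choice — and features above mean + 1 sample sd are selected. Constant
columns are dropped with a warning; a singular covariance at γ = 0 raises
an error advising γ > 0.

ReliefF uses every instance, k = 10 neighbours, Manhattan distance on
range-normalized features, penalizing difference to nearest same-class hits
and rewarding prior-weighted difference to each other class's nearest
misses; weights lie in [−1, 1] and a brute-force exhaustive-neighbour
implementation agrees to 1e−12 in tests. The top 100 by weight are kept,
registry order breaking ties.

## Network engine and architectures

With no deep-learning framework among the dependencies, the package ships a
compact numpy engine: architectures are declarative DAGs of layer specs;
output shapes and parameter counts are pure functions of the spec (so the
audits need no instantiation); instantiated models support batched forward,
full backpropagation (including through-time for the LSTM, verified by
finite differences layer-by-layer), Adam, inverse-frequency class
weighting, stratified holdout with early stopping, and gradient extraction
at any node for attribution.

Conventions chosen once and applied package-wide: convolutions and pools
use 'same' padding; pools default to stride 1 when none is stated; "leaky
ReLU scale 0.01" is a negative slope of 0.01; batch-norm affine terms count
as trainable; the LSTM emits its last hidden state. The STFT stage uses a
128-point periodic Hann window, hop 32, 256-point FFT — for an 18000-sample
input that yields 129 one-sided bins × 559 frames, and with real+imaginary
parts of 19 channels stacked, the published 38-channel tensor and the
8320-channel concatenation (32·129 + 32·129 + 64) follow exactly. The
audited trainable totals are 1,148,691 for the STFT Network and 7,880,963
for the Sensor Fusion Network; layer totals depend on drawing conventions
and are logged, not asserted. Featureless networks take segments
downsampled to 100 Hz (19 × 18000); feature-based training standardizes
per-feature using training-split statistics only, with a 10% holdout
(20% for featureless).

Topographic maps interpolate per-band relative power from 19 schematic
scalp positions (azimuthal layout, unit head disc) onto a 134 × 134 grid by
thin-plate-spline interpolation — exact at the electrodes, zero outside the
disc. Coincident electrode positions are rejected.

## Attribution and evaluation

Temporal Grad-CAM: the gradient of the (pre-softmax) class score w.r.t. the
topologically last convolutional map — the target layer is configurable by
node name — is averaged into per-filter weights; the weighted, rectified
combination is collapsed over residual non-time axes by mean, linearly
upsampled to the input grid, and smoothed by a centred 1-s moving average
with shrinking edge windows (length-preserving, nonnegative, mean-
conserving up to edges). Traces are exported unnormalized with an optional
max-normalization. Architectures without convolutions are rejected — a
contract the pipeline's explain stage surfaces as a recorded notice rather
than a failure.

ROC curves come from a threshold sweep with equal scores grouped (via
scikit-learn's curve construction) and trapezoidal AUC, each class in turn
positive against the other two; the micro-average pools all 3n
(score, indicator) pairs into one sweep and is the headline number.

## Score triage

w_p(s) = (4p + r)/5 on a grid of the observed scores plus {0, 1}. p is the
precision among records scoring ≥ s; r is the retained share of all true
positives (a flag switches to the retained-records reading, which equals
p). Ties in w_p resolve toward the higher threshold; thresholds retaining
nothing are skipped with a log entry. In the degenerate all-positive case
the rule retains everything, with s* at the minimum observed score.

## Problem sizes

The test and demonstration runs use desk-scale sizes chosen to exercise
every code path: cohorts of 10 recordings per class at 600 s each (three
segments per recording), 60-point embeddings with 5 planted outliers,
600 × 1406 training matrices for the Feature Network, and ≤ 30-evaluation
selector searches on 50–60 features. The pipeline scales linearly in
segments; nothing in the implementation assumes these sizes.

## Known limitations

Training the two largest convolutional networks (STFT Network, SFN) end to
end in the numpy engine is functional but slow at realistic cohort sizes;
the engine targets auditability and the desk-scale experiments here, not
GPU-class throughput. ICA decomposition itself is out of scope (the
cleaning stage consumes an external labeling). The printed layer-count
conventions of the source figures are ambiguous, so layer totals are
informational. The synthetic generator's limitations (above) bound what
green tests imply about clinical data.
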