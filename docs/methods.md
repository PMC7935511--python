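# Methods

## Problem and scope

The package classifies speakers as early-stage Parkinson's disease (PD) or
healthy control (HC) from short voice recordings. PD speech shows
hypokinetic dysarthria — reduced prosodic variation, breathier phonation,
less precise articulation — which moves the spectral envelope statistics
that MFCCs summarize. Two pipelines share one frontend: a generative
MFCC-GMM baseline and a discriminative x-vector/TDNN branch with cosine,
LDA + cosine, or PLDA back-ends. Both are wrapped in a repeated random
subsampling ensemble with EER/DET evaluation. Since the clinical
recordings the design targets cannot be shipped, every experiment here
runs on a parametric source-filter voice synthesizer with a controllable
class effect.

## Synthetic cohort

Each subject is a set of source-filter parameters drawn from
gender-specific distributions: fundamental frequency (M 120 Hz / F 210 Hz
log-normal), four formant center frequencies around a gender template,
aspiration-noise level, and a slow pitch-modulation depth. A recording is
an impulse train at the (slowly modulated) fundamental plus aspiration
noise, shaped by a one-pole glottal slope, passed through a cascade of
second-order formant resonators, amplitude-modulated, and arranged into
0.5–1.2 s speech bursts separated by 0.15–0.35 s pauses. Sessions apply a
random channel gain and spectral tilt and add a stationary colored noise
floor; each session also emits a 5 s calibration recording of that noise
floor alone. The telephone condition band-limits to 300–3400 Hz and
resamples to 8 kHz; the high-quality condition is 16 kHz (96 kHz
supported, downsampled to 16 kHz before the embedding branch).

The PD class is a deterministic shift of the subject-level parameters, in
units of the subject-level SD (`subject_sd`, default 0.08 on log scale):
formant dispersion compressed by `effect_size · subject_sd`, aspiration
noise raised by twice that, pitch-modulation depth reduced by it. This is
a proxy for hypokinetic dysarthria's envelope effects, not a clinically
validated simulation; no quantitative clinical effect magnitude exists to
calibrate against, so `effect_size` is a free simulation knob. At
`effect_size = 0` the label is exchangeable by construction. Defaults:
`session_sd = 0.05`, `frame_sd = 0.1` (slow amplitude modulation), one
10 s task per session.

What the generator does **not** emulate: phonetic content (no text, no
task-specific articulation), age/comorbidity covariates, codec artifacts,
or realistic room acoustics. Passing tests therefore demonstrate that the
pipeline machinery is correct and sensitive to envelope-level class
structure — not that it detects clinical PD.

## Frontend

* Log-energy computed on the raw frame at 16-bit full scale (so the
  conventional energy-VAD floor of 5.0 natural-log units applies to
  [−1, 1] float audio); 19/23/30 MFCCs from 23/24/31 triangular Mel
  filters depending on branch and channel, orthonormal DCT-II with
  coefficient 0 excluded (log-energy carries the level information).
  Pre-emphasis 0.97, Hamming window, 20 ms/10 ms framing for the
  baseline and 25 ms/10 ms for the embedding branch.
* Energy VAD: keep a frame iff logE > 5.0 + 0.5 · mean(logE).
* Sliding-window cepstral mean subtraction over 300 ms, centered,
  shrinking at edges, applied to static features before Δ/ΔΔ (the
  ordering is a design choice; deltas of mean-subtracted cepstra keep the
  channel-cancellation property).
* Spectral subtraction (high-quality channel only): 32 ms Hann frames,
  50 % overlap; noise magnitude spectrum = mean short-time magnitude of
  the session calibration silence; over-subtraction factor 2.0 (the
  Berouti-typical range; 1.0 leaves ~9 dB of a matched stationary noise,
  2.0 about 24 dB), spectral floor 0.02 × noise magnitude, phase kept.
* Segmenting: 1–5 s non-overlapping tiles; a final remainder shorter than
  1 s merges into the previous tile when the merge stays ≤ 5 s, is kept
  alone if ≥ 25 ms, and is dropped otherwise. The mismatched mode keeps
  any duration in [25 ms, 100 s] and splits longer files into equal
  fragments that share a parent id, whose x-vectors are averaged.

## GMM baseline

Diagonal-covariance mixtures (20 components high-quality / 50 telephone
in the full design; 8 in the desk battery, since mixture size should
follow the quantity of training speech) fit by EM from k-means
initialization. EM is driven one iteration at a time through
scikit-learn so the mean log-likelihood can be recorded and checked
non-decreasing; a per-dimension variance floor at 10⁻³ of each
dimension's global variance guards component collapse (cepstral
dimensions span orders of magnitude, so a scalar floor either distorts
the quiet dimensions or protects nothing). Tolerance 10⁻⁴ on the mean
log-likelihood; float-level wobbles at convergence terminate the loop,
decreases beyond 10⁻⁴ are an error. The subject score is the sigmoid of
the frame-averaged log-likelihood ratio; the sigmoid scale (default 1.0)
is a calibration knob the EER is invariant to.

## TDNN and x-vectors

The frame-level layers splice contexts {−2..2}, {−2,0,2}, {−3,0,3}, {0},
{0} (receptive field 15 frames); statistics pooling takes the biased
(population) per-dimension mean and SD; the x-vector is the pre-ReLU
affine output of the first segment-level layer. The full-size layer
widths (512/512/512/512/1500 → 3000 → 512) are kept as the dimension
contract; training and experiments use a width-divided desk profile
(default 48/48/48/48/96 → 192 → 48) because the implementation is plain
numpy with manual backpropagation — adequate for the small nets trained
here, with gradients verified against finite differences. Training is
per-chunk Adam (lr 2·10⁻³) on 2–4 s crops, cross-entropy over speaker
(or two-class) targets, seeded and single-threaded, hence reproducible.
The embedding extractor used in experiments is trained on a disjoint
synthetic background cohort of 8 speakers, mirroring the use of an
external speaker corpus; its class labels are never used.

## Back-ends

* Class references: arithmetic mean of the training x-vectors per class;
  near-zero references are flagged degenerate for cosine scoring.
* LDA: generalized eigenproblem of between- vs within-class scatter with
  ridge 10⁻⁶·trace/d on the within-class scatter; top-2 directions for
  the discriminant-space cosine (with two classes the second direction
  comes from the within-class whitening); a separate LDA stage reduces to
  16 dimensions (capped by sample count) before PLDA.
* PLDA: exact EM for x = μ + Fh + Gw + ε with class latent h shared
  within a class and per-vector w. The E-step computes the joint
  posterior moments in closed form (h by Woodbury per class; w
  conditionally independent given h); the M-step updates [F G] and
  diagonal Σ jointly; a minimum-divergence step folds the posterior
  latent covariances back into F and G each iteration — without it EM
  crawls along a near-flat ridge in the scale of F. The marginal
  likelihood (matrix-determinant-lemma form) is recorded and must not
  decrease. Scoring uses the two-covariance log-likelihood ratio
  (across-class FFᵀ, within-class GGᵀ + Σ) of the same-h vs
  independent-h hypotheses against the class-mean references; ranks
  default to rank_F = 1 (two classes), rank_G = dim − 1.

## Augmentation

Four corruption kinds per training segment — RIR convolution
(peak-preserving), noise bursts re-drawn every 1 s at one per-copy SNR in
[0, 15] dB, one continuous music excerpt at [5, 15] dB, and a 3–7-voice
babble sum at [5, 15] dB — from a synthetic bank (colored noise bursts,
harmonic tone mixtures, source-filter babble voices, exponentially
decaying RIRs). Two of the four copies are kept uniformly at random,
tripling the set. Only training subjects are ever augmented; references
use the clean vectors, the LDA/PLDA fits additionally see the copies.

## Ensemble evaluation

Balanced training groups drawn without replacement per run (default 40
runs; the desk battery uses 24), test = everyone else; per-subject final
score = mean over out-of-bag runs. EER uses the achievable operating
points only (thresholds between distinct score values — important with
tied scores) with linear interpolation at the FPR/FNR crossing, verified
against an exhaustive-counting oracle. DET curves are averaged pointwise
in the probit domain on a fixed FPR grid; the EER of the averaged curve
is the single-model estimate.

## Desk-scale study conditions

The standard battery runs both branches on 16 PD + 16 HC male
high-quality cohorts (one 8 s free-speech task, 24 runs of 10 + 10
balanced training, so each subject is tested about nine times) at effect
sizes 0, 1 and 3, over three seeded cohorts. These sizes keep the full
battery to a few CPU-minutes while leaving the null-calibration
Monte-Carlo error within about ±0.07 EER. Observed behavior: both
branches sit at chance (mean aggregated EER ≈ 0.5) at effect 0 and
decrease monotonically to ≈ 0.1 at effect 3.

## Known limitations

* The synthetic PD effect is an envelope-parameter proxy; results do not
  transfer to clinical claims.
* At 32-subject scale the ensemble's out-of-bag aggregate is not reliably
  better than the mean per-run EER for the GMM branch: one subject is
  worth 3–6 EER points, and the aggregate always includes the cohort's
  stably-atypical subjects while small per-run test groups often omit
  them. The improvement from aggregation is a large-cohort property; the
  x-vector branch does show it at this scale.
* The numpy TDNN is not meant for large nets or corpora; the full-width
  architecture is exercised only as a forward-pass contract.
* PLDA rank and pre-reduction dimension defaults are heuristics for
  two-class problems with tens of training vectors, not tuned settings.
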