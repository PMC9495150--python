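# Methods

This note documents the models, algorithms and design choices behind
`birdcall`, in the order the pipeline runs them.

## Problem setting

Automated species identification from bird-call recordings: given a mono
16 kHz clip containing one vocalising species, predict the species from a
fixed label set. The pipeline standardises heterogeneous field recordings
into fixed-size spectral feature matrices and classifies them with a
recurrent network that attends over both the frequency and time axes.

## Synthetic corpus generator

Real bird-call corpora are large and unevenly licensed, so the package
ships a generator that emulates the signal structure the preprocessing
and the classifier rely on:

- **Species voice**: each species owns a fundamental-frequency band
  (centres spaced ≥ 200 Hz apart between 500 and 6500 Hz, bandwidth
  80–180 Hz), a harmonic count (1–3, capped so every partial stays below
  7.9 kHz), a syllable-duration range inside 50–500 ms, an
  inter-syllable-gap range, a chirp slope (±1500 Hz/s) and an amplitude
  jitter.
- **Syllables** are Hann-enveloped harmonic stacks of a linear chirp —
  the simplest signal with controllable duration, bandwidth and rhythm.
- **Clips** alternate syllables and silent gaps for a duration drawn from
  6–14 s, so the 10 s standardiser must exercise both its padding and its
  cropping path, then add white Gaussian noise. `noise_db` states the
  *noise peak* (≈ 4σ) relative to the syllable peak; −25 dB is the corpus
  default, leaving the noise-frame RMS near −37 dBFS.
- Everything is driven by `numpy.random.default_rng(seed)`: a fixed seed
  reproduces a corpus bit-for-bit, including the written WAV files.

Because species bands are disjoint, a trivial band-energy classifier
already separates a noise-free corpus (tested at ≥ 95%). Passing training
tests on this corpus therefore demonstrates that the pipeline can recover
a signal that is genuinely present; it says nothing about robustness to
overlapping vocalisers, reverberation, or the long-tailed class balance
of field data, none of which the generator models.

## Preprocessing chain

1. **High-pass**: order-10 Butterworth at 150 Hz, applied
   forward-backward (`sosfiltfilt`, 0.25 s reflect padding) — zero phase,
   so syllable boundaries do not shift; the doubled order gives > 40 dB
   rejection at 100 Hz. A clip whose filtered residue stays below
   −50 dBFS (e.g. pure mains hum) is rejected as silent rather than
   renormalised noise.
2. **Noise gate**: 25 ms frames, 50% overlap; frames whose RMS falls
   below the clip peak by more than the threshold (default −40 dB,
   configurable) are zeroed, others pass untouched. The gate must sit
   *above* the noise floor of the material: desk configs on the −25 dB
   synthetic corpus use −30 dB.
3. **Syllable detection**: runs of non-silent frames, merged across gaps
   < 20 ms, reported as half-open `[start, end)` spans at frame
   resolution. A clip is **valid** iff at least one span lasts
   50–500 ms.
4. **Silence trimming**: syllable spans are kept together with their
   preceding gap capped at 1 s — rhythmic inter-syllable intervals
   survive verbatim, long silences shrink.
5. **Standardisation**: exactly 10 s at 16 kHz (160,000 samples), peak
   scaled to exactly 1.0 (0 dBFS). Shorter clips are tiled then
   truncated (preserving the species' rhythm); longer clips are
   centre-cropped.

## Features

- **STFT**: Hann window of 400 samples, hop 200, centred framing — a
  10 s clip yields 801 frames × 201 frequency bins of magnitudes.
- **Mel-spectrogram**: 128 triangular filters uniform on the Mel scale
  (`f_mel = 2595 log10(1 + f/700)`) over 0–8000 Hz, area-normalised,
  applied to the power spectrogram; converted to decibels as
  `10 log10(P/P_max)` floored at −80 dB. At a 400-point FFT the
  narrowest low-frequency triangles straddle no bin and stay zero; this
  is inherent to a 128-band analysis of a 201-bin spectrum.
- **MFCCs**: first 20 orthonormal type-II DCT coefficients (orders 0–19)
  of each dB-scaled Mel column.
- **Fusion**: Mel rows stacked on MFCC rows → 148 × 801. With
  normalisation on (default), each block is standardised independently
  over *all* its elements — `(x − mean(x))/std(x)` with the population
  standard deviation — before stacking, so both blocks enter the model
  at comparable scale.
- **Waveform baseline**: the standardised signal cut into 800
  non-overlapping 200-sample frames (200 × 800), letting the same
  sequence model consume raw audio for feature-type comparisons.

## Classifier

The fused matrix is a one-channel map (H = 148 feature rows, W = 801
time frames).

**Coordinate attention.** The map is average-pooled along each spatial
axis; the two pooled maps are concatenated (length H+W), mixed by a
shared 1×1 transform to a small intermediate width (default 8 — the
usual reduction-ratio rule is undefined at one channel), normalised over
the concatenated map (learnable scale/shift), passed through SiLU, split
back into the two directions, restored to the channel count by
per-direction 1×1 transforms, and squashed by sigmoids. The resulting
row gate g^h ∈ (0,1)^H and column gate g^w ∈ (0,1)^W re-weight the map
elementwise: `y[c,i,j] = x[c,i,j] · g^h[i] · g^w[j]`. Setting both gates
to 1 reproduces the attention-free network exactly (tested), which is
what the CA ablation toggles.

**Sequence model.** Columns become an 801-step sequence of 148-vectors
feeding a 2-layer LSTM (hidden 512 at full scale) with the standard
cell: forget/input/output sigmoid gates over `[h_{t−1}, x_t]`, tanh
candidate state, additive cell update, `h_t = o_t ⊙ tanh(C_t)`. Dropout
0.3 acts between layers and after the first head layer, during training
only. A bidirectional variant (per-layer forward+backward passes,
concatenated) exists for ablations; unidirectional is the default. The
classification head reads the **last** timestep's top hidden state:
FC(→hidden) + SiLU → dropout → FC(→n_species) → softmax.

Parameters initialise uniformly in ±1/√fan_in from a seeded generator.
The network and its gradients run on an in-repo reverse-mode autodiff
engine over numpy arrays (`birdcall.autodiff`), finite-difference-checked
in the test suite.

## Training

- **Split**: stratified 4:1 — per class, a seeded shuffle then a cut at
  ⌊0.8·n⌋.
- **Objective** (default `paper_bce`): the summed binary cross-entropy
  over all class outputs of the softmax posterior,
  `−Σ_n [y_n log p_n + (1−y_n) log(1−p_n)]`, probabilities clamped at
  1e−12, batch-averaged. The canonical multiclass form `−log p_true` is
  available as `loss="softmax_ce"`. The summed-BCE form differs from
  canonical cross-entropy by the Σ(1−y)log(1−p) term; both are kept
  because the choice measurably changes optimisation behaviour.
- **Optimiser**: AdamW (decoupled weight decay, default 0.01),
  step-decayed learning rate (factor 0.1). Full-scale defaults: 70
  epochs, batch 256, lr 1e−4, decay every 10 epochs.
- **Gradient clipping**: global L2 norm capped at 1.0. Without it,
  desk-scale LSTM runs diverge on a substantial fraction of seeds; with
  it they converge reliably. Set `grad_clip=0` to disable.
- Training is deterministic for a fixed seed under single-threaded
  execution (one RNG drives batch order, dropout masks and
  initialisation).

### Desk-scale configuration

CPU-only runs shrink the problem, not the method:

| knob | full scale | desk default | why |
|---|---|---|---|
| corpus | 72k clips / 264 species | 8 species × 25 clips | minutes, not days |
| hidden units | 512 | 64 | capacity matched to task |
| epochs | 70 | 15–30 | converges on the easy corpus |
| batch | 256 | 16–32 | small training sets |
| lr / decay | 1e−4 / per 10 | 3e−3 / per 15 | small batches need larger steps; decay after the run has learned |
| `time_pool` | 1 | 8–16 | average-pools the 801-frame axis before the LSTM (100/50 steps), cutting BPTT cost ~an order of magnitude |

`time_pool` is a training-side data reduction; the feature contract
(148 × 801) and the full-length forward pass are unchanged and tested at
full size. On one CPU the 8-species desk run (features → 30-epoch
training → evaluation) takes ~1 minute.

At desk scale both the CA-on and CA-off models usually saturate
(mAP = 1.0) on the synthetic corpus, so ablation comparisons mostly
register ties; comparisons are made only between models trained to
convergence, since half-trained CA models transiently lag their plain
counterparts.

## Evaluation

All metrics are one-vs-rest over the softmax score matrix: accuracy
(correct/all), per-class precision/recall/F1 (0/0 → 0 with a warning;
aggregates are unweighted class means), pairwise-indicator AUC (ties
credited 0.5 by default — the strict `I[f(t0)<f(t1)]` indicator is a
flag — macro and pooled-micro variants), top-5 accuracy (ties at the
fifth rank broken by ascending class index), and average precision as
the precision-weighted recall staircase, with mAP the unweighted mean of
per-class APs. ROC curves threshold at every distinct score and always
span (0,0)–(1,1); their trapezoidal area equals the pairwise AUC
(tested to 1e−10). The 2-component PCA embedding delegates to
scikit-learn and is cross-checked against an eigendecomposition oracle.
Degenerate classes (no positives) are skipped with warnings rather than
poisoning aggregates.

## Numerical choices

- dB conversion floored at −80 dB; normalisation uses the population
  standard deviation; constant matrices are an error, not a silent 0/0.
- Softmax subtracts the (non-differentiated) row maximum — exact, since
  softmax is shift-invariant.
- Probabilities are clamped to [1e−12, 1−1e−12] before logarithms; the
  clamp passes no gradient outside its interval.
- Segment times are seconds from clip start, half-open intervals; gate
  framing is 400/200 samples.
- WAV output quantises to int16 with round-half-away and ±1 clipping.

## Known limitations

- The generator does not model overlapping vocalisers, reverberation,
  non-stationary noise, or class imbalance; accuracy numbers on it are
  a functional check of the pipeline, not a field-performance estimate.
- The numpy engine is single-threaded and eager; full-scale training
  (512 hidden units, 801 steps, 264 classes) is out of its intended
  range by orders of magnitude.
- AUC on easy synthetic tasks is near 1 for every model, echoing its
  known weakness as a discriminator between strong multi-class models.
- The printed-form BCE loss treats the softmax outputs as independent
  binary problems; its gradients differ from canonical cross-entropy,
  and desk-scale experience shows it converges at least as reliably.
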