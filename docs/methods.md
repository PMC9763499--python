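# Methods

This note documents the models and procedures implemented in `callfinder`,
the parameters that matter, the synthetic data the tests rely on, and the
design decisions taken where the underlying method left room.

## Preprocessing pipeline

A raw recording becomes a network input through eight steps, in order:

1. **Mono + resampling.** Channels are averaged; rate conversion uses
   polyphase band-limited interpolation (`scipy.signal.resample_poly`).
2. **STFT power spectrogram.** Hann window of `fft_window_length` samples,
   hop `fft_hop`, magnitude squared. Frames are only taken where the full
   window fits (no boundary padding), giving F = window/2 + 1 rows and
   T = 1 + ⌊(n − window)/hop⌋ columns.
3. **Random augmentation** (training only). One uniform draw each from
   `intensity_interval` (dB; multiplies power by 10^(g/10)),
   `pitch_interval` and `time_interval` (axis-scaling factors applied by
   nearest-neighbor row/column remapping on the power spectrogram). Output
   column j reads input column ⌊j/t⌋; output row i reads input row ⌊i/p⌋,
   rows without a source become zero.
4. **Frequency compression.** `n_freq_bins` (default 256) target
   frequencies linearly spaced on [f_min, f_max]; each output row copies
   the nearest in-band input row. Rows outside the band never contribute;
   a band without any spectrogram row is an error.
5. **Noise mixing** (training only, when a noise pool is provided). A noise
   spectrogram — itself pitch/time-augmented and frequency-compressed — is
   tiled or randomly cropped to the clip's width and scaled by α such that
   10·log10(meanPower(signal)/(α·meanPower(noise))) equals an SNR drawn
   uniformly from `snr_interval`. An all-zero noise spectrogram is
   rejected (the scaling would be undefined).
6. **dB conversion.** 10·log10(max(power, 1e−10)); the floor is far below
   any signal of interest and avoids −∞.
7. **Normalization.** `minmax`: (x − min)/(max − min), with a constant
   matrix mapping to all zeros; `db`: clip((x − min_db)/(ref_db − min_db))
   to [0, 1]. `minmax` is level-invariant; `db` preserves absolute level
   information, which is useful when the recording chain is calibrated and
   consistent.
8. **Length fitting.** The matrix is cropped or zero-padded to
   T_net = round(sequence_length · sample_rate / hop) columns. Training
   uses a uniformly random offset; validation, test and prediction are
   centered.

All randomness flows through one explicit numpy `Generator`, so a seed
reproduces every augmented clip bit for bit.

## Network

An 18-layer residual CNN on the (1, n_freq_bins, T_net) input: a 7×7
stride-2 stem convolution with batch norm and ReLU (the conventional stem
max-pooling layer is removed to keep early time-frequency resolution), four
stages of two basic blocks (two 3×3 convolutions each, identity shortcuts,
1×1 projection where shape changes) with widths 64/128/256/512, stages 2–4
entering with stride 2. Total downsampling is 16× in both axes. The final
feature maps are globally average-pooled — adaptive to any F′×T′, so the
sequence length is a free parameter — into a 512-vector mapped linearly to
n classes. Convolutions use Kaiming (fan-out) initialization; batch norm
starts at γ = 1, β = 0.

The layers, backpropagation, and the Adam optimizer are implemented in
numpy inside the package (`callfinder.nn`): convolution is im2col plus a
BLAS matmul, arithmetic is float32. Gradient correctness is verified by
finite-difference tests in float64. `NetworkSpec.widths`/`blocks` are
configurable, which the desk-scale demonstrations use (below).

## Training

Cross-entropy loss; Adam with batch size 8, β₁ = 0.5, β₂ = 0.999, default
initial learning rate 1e−5. "Improvement" means a strict increase of
validation accuracy over the best seen; ties are stale. After
`lr_patience_epochs` (default 4) stale epochs the learning rate halves and
the decay counter resets; after `early_stop_patience_epochs` stale epochs
training stops. The weights of the best validation epoch are restored.
Training clips are re-preprocessed each epoch with augmentation and random
cropping; validation and test clips are preprocessed once, centered and
unaugmented. Class imbalance is not reweighted.

Splitting is recording-exclusive: per class, recordings are shuffled with
the seed and assigned greedily to the partition with the largest clip-count
deficit against the 70/15/15 targets (ties in train/validation/test order);
a recording assigned for one class keeps its partition for all others. One
guard supplements the greedy rule: when the remaining unassigned recordings
are only just enough for the partitions still empty, those are filled
first, so no partition ends up empty (at least three distinct recordings
are therefore required). With R equal recordings the achieved fractions
deviate from the targets by at most one recording's share.

## Detection and evaluation

Sliding windows of length ε start at 0, κ, 2κ, … while start + ε fits the
tape; if audio remains uncovered, one final short window ending exactly at
the tape end is appended and zero-padded for scoring (a tape shorter than ε
is one padded window). Frames with target probability strictly above δ are
positive; maximal runs of positive frames merge into annotations spanning
first start to last end, with confidence the run's maximum probability.

Smoothing fills gaps: a negative frame becomes positive when it has
overlapping neighbor frames and all of them are positive, evaluated in one
pass over the original flags (no cascades); with κ = ε windows do not
overlap, the neighbor set is empty, and smoothing never fires. The same
rule serves two entry points: `smooth_frames` relabels argmax-labeled
frames, and `extract_annotations(smooth=True)` applies it to the
δ-thresholded flags before run merging — thresholding first keeps the
extraction monotone in δ (raising δ never increases annotated time) and
means a δ of 1.0 yields no annotations regardless of content.

Time-wise scoring first merges ground-truth intervals whose gap is at most
ξ (default ε/2): a window straddling such a gap still contains mostly
vocalization. Precision is the fraction of predicted time inside the
merged ground truth extended by λ (default ε/2) at each border — clipped to
the recording bounds — and recall is the fraction of *unextended* merged
ground-truth time covered by predictions. Both are duration-weighted, so
they are invariant to splitting a prediction into abutting pieces. Empty
predictions make precision undefined (reported as `None`), empty ground
truth makes recall undefined.

For frame-wise ROC/AUC each frame is labeled positive when at least half of
it overlaps the merged ground truth; the ROC sweeps every distinct score as
a threshold and the trapezoid AUC then equals the Mann–Whitney rank
statistic with tie averaging (cross-checked against scikit-learn). UAR is
the unweighted mean of per-class recalls; classes without any true sample
are excluded with a warning.

## Multi-stage classification

Because the upstream detector has a low false-positive rate, a *noise*
argmax on a detected excerpt is only accepted above a confidence threshold
(default 0.85, strict); otherwise the runner-up class takes the frame. A
clip shorter than ε is scored as a single window equal to the clip; longer
clips are scored at starts 0, κ, 2κ, … keeping full windows only, so
truncated border content cannot produce spurious frames. Each frame adds
its voted class's probability — not the full probability vector, which is
the one reading of cumulative voting that makes a single frame's decision
coincide with the frame vote — to that class's mass; the largest mass wins,
ties breaking by class name for determinism. The noise override applies
uniformly, including the single-window case.

## Synthetic data

The generator emulates the structure of an annotation campaign, not the
acoustics of real animals. Classes are pure tones, linear chirps,
amplitude-gated pulse trains (10 Hz gate, 50% duty), or white noise; clips
mix the class signal with white noise at a uniformly drawn mean-power SNR
and are peak-normalized. Defaults: 8 kHz sampling, 100 clips per class
over 20 recordings, durations 0.3–0.8 s, SNR 0–10 dB. Tapes are continuous
white noise (amplitude 0.05) with events planted uniformly at random,
non-overlapping with a 0.1 s guard, at `call_density` events/minute
(default 10/min over 60 s, i.e. 10 events), each scaled to a drawn SNR
against the background; the ground truth lists the exact intervals.
Everything is reproducible from the seed alone.

What passing tests on this corpus do **not** show: robustness to colored or
non-stationary noise, overlapping calls, within-class variability, reverb,
or recording-chain differences — real corpora need their own validation on
held-out annotated tapes.

## Desk-scale study conditions

The end-to-end demonstrations (tests and the worked example) run on one CPU
in about a minute each, using: 64 frequency bins over 500–4000 Hz, 0.5 s
sequence length (T_net = 31), a narrow (16, 32, 64, 128) network, min-max
normalization (training clips are peak-normalized but tape windows are not,
so level-invariant normalization is the appropriate mode), Adam at 1e−3 for
at most 20 epochs with patience 6, ε = 0.5 s, κ = 0.25 s, δ = 0.5. The
1e−5 default learning rate is kept for real corpora, where many epochs over
thousands of clips are the norm; the demonstrations use the larger rate
because they see only a few hundred gradient steps. The full-width
(64, 128, 256, 512) × 256-bin network is what the architecture tests
exercise; it is also trainable with this package, just not in seconds.

## Numerical choices and edge cases

- dB floor 1e−10 before log; min-max of a constant matrix → all zeros.
- Nearest-neighbor ties in frequency compression resolve to the lower row.
- Window arithmetic uses a 1e−9 s tolerance against float drift.
- T_net rounds to the nearest frame and is at least 1.
- Noise clips shorter than the signal are tiled, longer ones randomly
  cropped, before SNR scaling.
- Annotation confidence is the maximum frame probability in the run (a
  single reported confidence is needed; the maximum is threshold-consistent:
  the run survives exactly the δ below it).
- Checkpoints store weights, batch-norm statistics, the architecture spec,
  the preprocessing config and the class-name order, so prediction is
  self-describing.

## Limitations

- No mel/perceptual frequency scale, no denoising, no streaming inference.
- The numpy engine is single-threaded apart from BLAS; it is sized for the
  small models used here, not for large-scale training.
- Probabilities are uncalibrated; the noise-override threshold and δ are
  operating points to be chosen per use case.
- Cross-validation folds and database-backed corpora are out of scope;
  corpora are directories of WAV clips named
  `LABEL_ID_RECORDING_STARTms_ENDms.wav` (a class subdirectory overrides
  the label).
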