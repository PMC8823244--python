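# Methods

`usvdetect` detects, segments and denoises mouse ultrasonic vocalizations
(USVs) in high-sample-rate audio with a hybrid convolutional–recurrent frame
classifier. This note records the model, the numerical choices behind the
implementation, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Signal representation

Audio is mono, nominally sampled at 250 kHz (anything at or above 250 kHz is
accepted; lower rates are resampled up on read, though they cannot add
spectral content). The working image is a log-Mel spectrogram:

- **124 triangular Mel bands** spanning 1–125 kHz on the HTK Mel scale
  (`mel = 2595 log10(1 + f/700)`). Band *i* spans edge frequencies
  `edges[i] .. edges[i+2]` with its peak at `edges[i+1]`.
- **~332 frames/s**: the hop is `round(rate / 332)` samples (753 at 250 kHz,
  ~3 ms per frame). The analysis window is 1024 samples (Hann), longer than
  the hop; the FFT is zero-padded to 4096 points so the narrow low-frequency
  Mel bands (≈60 Hz triangle flanks near 1 kHz) retain spectral support —
  with a 1024-point FFT (244 Hz bins) the bottom bands would be empty.
- **Log compression** is `log(E + 1e-10)`; silence maps exactly to
  `log(1e-10)`, which is also the padding value wherever a context extends
  past the recording ("no signal before the recording").
- **Frame time spans** are the non-overlapping half-open intervals
  `[t·hop, (t+1)·hop)/rate`. A frame is labeled 1 when its span intersects
  any USV annotation. Using hop-width spans (rather than window-width ones)
  makes label→interval round trips exact to within one frame period per
  edge; the longer analysis window only affects the energies, not the
  temporal bookkeeping.

No amplitude normalization is applied to the raw audio. Short segments
cannot be normalized stably, and the Mel transform is nonlinear, so scale
robustness is instead trained in through value jitter (below).

## Model

Every frame is classified from its 124 × 51 context patch (the frame plus 25
neighbors per side) in two stages.

**CNN frequency-masking stage.** Two branches see each patch:

- a *1-D branch* convolving along the frequency axis of the patch's mid
  column (default: two layers, kernel 7, channels 16 → 1), accentuating
  candidate USV frequencies in the frame itself;
- a *2-D branch* convolving the whole patch (default: three 5 × 5 layers,
  channels 8 → 16 → 1, 'same' along frequency, 'valid' along time) followed
  by mean pooling over the remaining 39 time columns, suppressing structured
  noise visible in the context.

The branch outputs are multiplied elementwise and squashed with a sigmoid
into a **frequency mask column**: 124 independent per-band probabilities in
[0, 1]. Multiplying the input patch by its mask column yields the filtered
patch; the mask drives both denoising and frequency-boundary estimation.
Because the time axis is never padded inside the convolution stack (the map
is padded once at its outer edges with the silence floor), the mask column of
frame *t* depends on exactly the 51-frame context — the full-map pass and the
per-window definition coincide bit-for-bit, and inference can run the CNN
over an arbitrarily long map in one pass.

**BiLSTM frame classifier.** The mask columns form a sequence read by one
bidirectional LSTM layer (64 hidden units per direction) followed by a fully
connected layer to two classes and a softmax, giving per-frame
P(USV)/P(background). Inference feeds the BiLSTM in 332-frame (1 s) segments,
matching the training regime; the CNN mask is segment-independent.

The layer sizes above are deliberately the smallest that preserve the
two-branch + recurrent topology and train in minutes on one CPU core; all of
them are config-exposed.

**Loss.** Class-weighted softmax cross-entropy over frames,
`-mean_t w(y_t) log p_t(y_t)`, with `(w_USV, w_bg)` normalized to sum to 1.
By default the weights are the inverse class prevalence of the assembled
training frames — a 25 % USV / 75 % background mix yields weights
(0.75, 0.25).

**Implementation.** The network and its gradients are implemented directly
over NumPy arrays; convolutions are direct-form Numba kernels
(channels-first, time innermost) and the LSTM is a batched recurrence with
manual backpropagation through time. Parameters are float32; the complete
analytic gradient is verified against central finite differences in float64
in the test suite. The optimizer is Adam (lr 1e-3, batch 32 segments,
global-norm gradient clip 5). With a fixed seed, initialization, shuffling
and the loss trajectory are reproducible.

## Training-set engineering

Vocal activity is rare in long recordings, so training clips are *condensed*:
USVs separated by less than `max_gap` = 1 s are chained, each chain becomes
one clip of 1–20 s (chains over the limit are split recursively at their
largest internal gap), padded by 0.1 s of context per side, and clamped at
inter-chain gap midpoints so clips never overlap and every USV lies in
exactly one clip. Background-only noise clips (1 s) are then added so the
model also sees silence and interference; a noise clip carrying USV labels is
rejected. The train/validation split (80/20) is made at the clip level so
overlapping frames cannot leak across the split. The best-validation-F1
epoch's weights are kept. Fine-tuning restarts from a checkpoint with an
architecture-compatibility check.

**Augmentation** (training-time, on the log-Mel maps):

- *frequency shift*: ±15 bands by default, vacated bands filled with the
  silence floor — generalizes to vocal ranges absent from the training data;
- *value jitter*: `out = map · exp(s/6) + o` with `s ∈ [−3, +3]` a.u. and
  `o ∈ [−50, +10]` a.u. — tolerance to acquisition gain and offset. The two
  a.u. ranges are exposed as independent knobs (offset and gain) since
  either reading of "scale" is representable;
- *line injection*: random full-width horizontal lines (continuous humming)
  and full-height vertical lines (broadband impulses), 1–4 of each at
  uniform intensity 1–8 a.u.

Gaussian and salt-and-pepper noise are implemented but off by default; they
were not found useful in this regime.

## Post-processing

Frames with P(USV) ≥ 0.5 form maximal runs; runs closer than `merge_gap` =
10 ms are merged and runs shorter than `min_dur` = 5 ms are dropped (both
sit below typical USV durations, whose median is ~50 ms; both are
config-exposed, and raising the threshold never increases total detected
duration). A detection's frequency bounds are the lowest/highest band whose
mean mask over the detection reaches 0.5, reported as the band's lower/upper
edge frequency — conservative, since Mel resolution is coarse at high
frequencies. Denoising is exactly `spectrogram ⊙ mask ⊙ track` (the track
broadcast across bands), nothing else.

## Evaluation

Detections are matched to (merged, non-AC) truth intervals greedily in
chronological order; any positive temporal overlap counts by default
(`min_iou` raises the bar if desired). The first detection on a truth is a
true positive (`USV`); re-tags of already-found truths are `Partial`
(neither tp nor fp by default, a flag counts them as fp); one detection
spanning several truths is `Multi` and counts exactly once, consuming the
truths it covers. Recall = tp/(tp+fn), precision = tp/(tp+fp), F1 their
harmonic mean, with 0 reported (and flagged) for undefined ratios.

Segment **magnitude** is the mean of squared samples. **Local SNR** of USV
*i* is `R_i = (M_sig+bg,i − M_bg,i)/M_bg,i`, with `M_bg,i` the mean magnitude
of the flanking non-USV gaps; `R_i` is zero when a call is no louder than
its surroundings, undefined (flagged) over silent background, and invariant
to global amplitude scaling. **Global SNR** pools all USV samples against
all non-USV samples.

## Synthetic data

The generator produces the statistical structure the detector assumes, not
acoustically realistic mouse calls:

- syllables are frequency-modulated sinusoids confined to 30–110 kHz,
  10–150 ms, with raised-cosine onset/offset ramps; shapes are up/down
  sweeps, arcs, and one-jump syllables — no harmonics, no room acoustics,
  no microphone response;
- a default clip is 1 s with one call of 2–4 syllables and 30–100 ms
  within-call gaps, i.e. the condensed USV-dense regime (roughly a quarter
  of frames vocal), so the assembled default corpus lands near the 25/75
  class mix;
- background is Gaussian noise (σ = 0.01 a.u.) plus fixed humming tones at
  5/20/45 kHz and Poisson broadband clicks (2/s, 1 ms) — the two noise
  archetypes the augmentations mimic;
- syllable amplitude is calibrated iteratively against the package's own
  local-SNR measurement until the median `R_i` hits the requested target
  (default 2.0, within a few percent), closing the loop between generator
  and evaluator;
- everything is driven by one seed; identical seeds give bitwise-identical
  audio and truth tables.

Because the generator and the detector share assumptions (band-limited FM
sweeps over stationary noise), passing the synthetic end-to-end check shows
the pipeline is self-consistent and trainable — it does *not* certify
performance on real recordings, which contain call types, nonstationary
noise and reverberation the simulator omits.

## Problem sizes used in the checks

The end-to-end check trains the default model on 400 one-second synthetic
clips plus 100 noise clips (seed 0, target local SNR 2), for 6 epochs, and
evaluates on 100 held-out clips, then sweeps 30 clips at each target SNR in
{2.0, 1.0, 0.5, 0.1} with the same trained model. These sizes train in a few
minutes on a single CPU core while leaving the detection task non-trivial.

## Known limitations

- Frequency bounds inherit Mel-scale coarseness above ~70 kHz; upper bounds
  are conservative band edges, not Hz-accurate contours.
- The package detects and segments USVs; it does not classify syllable
  types or analyze call syntax.
- Training at realistic corpus scale (hundreds of hours) is out of scope;
  the training loop is engineered for condensed clips.
- Integer-PCM WAV input is scaled to [−1, 1); float WAV is used as stored.
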