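# Methods

## Signal model of the simulator

Each synthetic channel is

```
x(t) = b(t) + Σ_k  e_k(t − t_k) · [ A_k sin(2π f_k (t − t_k) + φ_k) + c_k ]
```

where `b(t)` is 1/f^β background noise (white Gaussian noise whose Fourier
magnitudes are shaped by `f^(−β/2)`, DC removed, rescaled to a target RMS)
and each spindle event `k` is a sinusoid under a tapering envelope `e_k`
(Hann by default; Gaussian and squared-sine selectable). Event times `t_k`
follow a Poisson process thinned by rejection so that consecutive events on
a channel are separated by at least `min_gap_s`; per-event frequency,
duration, peak amplitude and phase are drawn uniformly from the regime's
ranges. Channels are generated independently — a simplification: real C3/C4
spindles co-occur frequently.

Two regimes describe the two populations:

| parameter | normal | insomnia-like |
|---|---|---|
| frequency `f_k` | U(11, 16) Hz | U(11, 16) Hz |
| duration | U(0.8, 1.5) s | U(0.4, 0.8) s |
| envelope peak `A_k` | U(20, 30) μV | U(25, 50) μV |
| baseline offset `c_k` | 0 | U(0, 10) μV |

The normal regime yields symmetric ±30 μV excursions with ~1 s bursts; the
insomnia-like regime yields shorter bursts whose excursions span an
asymmetric range (about −10 to +40 μV) and, being shorter, a smaller
sigma-band energy footprint. The defaults the simulator fixes itself
(nothing in the domain pins them): sampling rate 1024 Hz, channels C3 and
C4, 5 events/min, `min_gap_s` = 2 s, β = 1.

**Background RMS.** The default `noise_scale_uv = 40` was calibrated so
that held-out classification accuracy on a simulated healthy cohort lands
in the low-90s — the difficulty regime typical of real spindle
classification — and so that the regime shift measurably degrades an
unadapted model. At 15 μV ("high SNR") the task is near ceiling; that
setting is used where a separability check, not difficulty, is the point.
Between ~20 and ~45 μV the task moves from trivial to hard; the transition
is steep because the only discriminative signal is the band-limited burst.

What passing tests on this simulator do **not** show: robustness to
artifacts (EMG, eye movements, mains hum), K-complexes and other transient
look-alikes, stage-dependent background changes, or electrode variability.
They do show that the pipeline's geometry, training mechanics, metrics and
transfer contracts are correct, and that relative effects (domain-shift
degradation, finetuning recovery, transfer-mode ordering) behave sensibly.

## Preprocessing

Order: polyphase resample to 100 Hz → zero-phase FIR band-pass → z-score.

* **Resampling** uses the exact rational factor (1024 → 100 Hz is 25/256)
  with the polyphase resampler's built-in anti-alias filter. Annotations
  are stored in seconds and survive unchanged.
* **Band-pass**: cascade of a Hamming windowed-sinc high-pass at 0.3 Hz and
  low-pass at 30 Hz. The high-pass is built by spectral inversion of a
  unit-DC-gain low-pass, so DC is rejected exactly. Kernel lengths follow
  the Hamming rule (transition ≈ 3.3/N cycles/sample) for transition widths
  of 0.3 Hz (low side) and 0.25 × 30 = 7.5 Hz (high side), inflated by a
  one-third margin so in-band ripple near 28 Hz stays well inside ±1 dB;
  −6 dB points sit at the band edges, stopband attenuation exceeds 50 dB.
  Applied zero-phase (one forward pass on a reflection-padded signal, group
  delay trimmed) so spindle midpoints stay aligned for window extraction.
  Recordings shorter than three filter lengths (~46 s at 100 Hz) are
  rejected rather than padded.
* **z-score** is per channel over the whole recording by default. Whether
  normalization should instead be per extracted window is genuinely open;
  both are implemented (`zscore_scope`), and per-recording is the default
  because it preserves relative amplitude between events and background
  within a subject.

## Windowing

Positives are centred on the annotation midpoint (half-open 300-sample
interval; centre within one sample of the midpoint by construction).
Windows that would cross a recording boundary are dropped and counted, not
padded — padding would fabricate signal. Negatives are drawn uniformly
without replacement from start positions at least `guard_s = 0.5` s away
from every annotated event (spindle tails just outside the annotation must
not leak into the negative class) and may not overlap one another, so no
training sample is duplicated. Per-(subject, channel) seeds are derived by
stable hashes from the one windowing seed, making the window multiset
independent of cohort ordering. Greedy non-overlapping placement fills at
most ~75 % of free signal (random parking), so requesting negatives close
to that bound fails with the achieved count.

## Architecture and training

Five Conv → BatchNorm → ReLU blocks — channels (16, 16, 32, 32, 64),
kernels (7, 7, 5, 5, 3), stride 1, "same" padding — with 2× average
pooling after blocks 2 and 4 (temporal grid 300 → 150 → 75), then
flatten → FC(64) → ReLU → FC(2) → softmax. The spindle-class probability
is the ROC score. Width and kernel choices are sized to train on one CPU
core in minutes at ~10⁴ windows; they are config-exposed and recorded in
model provenance. No dropout. He initialization; Conv→BN→ReLU ordering;
BatchNorm ε = 1e-5, momentum 0.1, unbiased running variance.

The engine (`spindlecnn.nn`) is pure numpy: im2col convolution lowered to
a single sgemm per layer (channels-last layout to avoid transposition
copies), explicit backward passes validated against central finite
differences, and AdamW with decoupled weight decay (0.01, applied to
matrix/tensor weights only). Everything is float32 with float64 optimizer
state; given identical seeds and data, training is bit-reproducible, which
is what makes "frozen layer" a bitwise-testable property.

Training: cross-entropy on softmax outputs (canonical pairing for a
probability head), batch 128, AdamW with lr schedule
`lr(e) = lr0 · 0.75^floor(e/3)`, lr0 = 0.1, 100 epochs by default. lr0 of
0.1 is aggressive for AdamW: it converges reliably in the high-SNR
condition but can fail to leave the initialization basin on hard-noise
data, so the trainer aborts with a diagnostic on a non-finite loss and
0.001 is the documented safe alternative — the domain-shift reference
experiment trains its source model at 0.001 for exactly this reason.
Reference experiments use reduced epochs (12 for the high-SNR check, 20
for the shift experiments) because the synthetic task converges within a
few epochs; these sizes are recorded in `spindlecnn.experiments`.

Cross-validation is subject-grouped by default: folds partition subjects,
never windows, so evaluation is always cross-subject. Window-level folds
remain available (`fold_grouping="by_window"`). Reported summary is mean ±
standard deviation over fold metrics.

## Metrics

Confusion counts at the argmax (0.5) threshold give accuracy, recall,
precision (spindle class; precision defined as 0 when nothing is predicted
positive, F1 as 0 when precision + recall is 0; recall raises when no
positives exist — that is a caller error, not a value). AUC is the
Mann–Whitney rank statistic on the spindle probability: average ranks make
tied scores count one half. An evaluation set with a single class raises.

## Transfer learning

`all_conv` copies all five conv blocks; `first_four` copies blocks 1–4 and
re-initializes block 5. "Layer k" means the whole block — convolution plus
its BatchNorm, running statistics included. The head is always
re-initialized (both modes retrain it from scratch). Transferred blocks are
frozen by default: excluded from the optimizer and their BatchNorm
statistics pinned, so the transferred part is bitwise invariant through any
amount of finetuning; `freeze_transferred=False` finetunes everything from
the transferred initialization instead. The trainable set of `all_conv`
(head only) is a strict subset of `first_four`'s (block 5 + head).

Finetuning uses the source schedule with `finetune_lr0 = 0.01` replacing
lr0: retraining a re-initialized block on a small target cohort at 0.1
collapsed intermittently in development (accuracy falling to chance in a
minority of seeds), while 0.01 is stable and preserves the qualitative
ordering of the modes. Setting `finetune_lr0 = train.lr0` restores full
inheritance.

On the default-noise shift experiment, the expected picture is: the
unadapted source model loses several accuracy points on the insomnia-like
regime; both finetuned modes recover part of the gap; `first_four`
typically recovers more than `all_conv`, consistent with early blocks
encoding population-independent sigma features and the last block
population-specific ones.

## Numerical and degenerate-input choices

* EDF is written with a ±200 μV physical range (16-bit step ≈ 0.006 μV);
  values outside are clipped. Reading goes through an independent EDF
  implementation, so round-trip tests also validate the writer's format.
* Constant (zero-variance) channels cannot be z-scored and raise, naming
  the channel; constant windows are finite through BatchNorm via ε.
* Convolution kernels must be odd so "same" padding is symmetric.
* Annotation tables are half-open intervals `[onset, onset+duration)` in
  seconds from recording start; rows with non-positive duration are dropped
  with a warning on read.
* Upsampling is rejected (only downsampling occurs in this design);
  resampling to the current rate is the identity.

## Known limitations

Single-channel windows only (no C3+C4 fusion); no artifact model; no
whole-night sliding-window inference; the simulator's event statistics
(density, inter-event intervals, SNR) are package choices exposed as
config, not population-derived values.
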