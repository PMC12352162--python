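# Methods

This note documents the models and procedures implemented in `burstdecode`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation studies do and do not
show about real recordings.

## Synthetic sessions

The generator (`burstdecode.simulate`) emulates one delayed verbal
free-recall experiment:

* **Task schedule.** Lists of 12 words, each shown 1.6 s, separated by a
  blank inter-stimulus interval drawn uniformly from 0.75–1.0 s; a 20 s
  arithmetic distractor immediately follows word 12, then a 30 s free
  recall window.  Each word is recalled independently with probability
  `recall_p` (default 0.25, a typical free-recall hit rate).
* **Background.** Each channel is independent Gaussian noise spectrally
  shaped to a 1/f² power law (slope configurable), rescaled to 20 µV RMS,
  plus a 60 Hz line sinusoid (default 2 µV).  Channels are generated from
  independent child seeds.  Supported sampling rates are the clinical ones
  (500, 512, 1000, 1024, 2000 Hz); the default is 500 Hz and other rates
  are resampled to 500 Hz after filtering.  The montage is generated as
  already bipolar-referenced, which keeps the ground-truth bookkeeping
  exact; the bipolar re-referencing operator is exercised separately.
* **Bursts.** Discrete oscillatory events are Hann-windowed sinusoids.
  High-gamma bursts default to 120 ± 30 Hz, 150 ± 40 ms, rate 1.0 /s per
  channel; beta bursts to 25 ± 8 Hz, 200 ± 50 ms, rate 0.8 /s.  Default
  amplitude is 8× the background SD — a clearly detectable regime, i.e. a
  recording that passes the low-voltage quality screen.  Burst *centers*
  are Poisson-placed uniformly within trial windows, and tails may spill
  across window boundaries.  (An earlier design that re-drew bursts to fit
  entirely inside their window created a burst-mass dip phase-locked to
  word onsets; a memory-state decoder could exploit that dip even with no
  configured difference between conditions, breaking the package's null
  calibration, so spill-over placement was adopted.  Per-window burst
  counts remain exactly Poisson.)
* **Class structure.** The session is partitioned into non-overlapping
  windows — word+ISI spans, distractor/gap background, recall windows.
  Word windows of recalled items receive configurable (rate, amplitude)
  multipliers per band; background carries the baseline regime; recall
  windows carry their own regime (default: high-gamma 2.0 /s, beta
  0.3 /s).  With all multipliers at 1 and recall regime equal to baseline,
  burst statistics are stationary over the whole recording — the basis of
  the null-calibration studies.  The recall-period regime is a modeling
  choice (task literature specifies only the timing); it exists to make
  the memory-state contrast learnable and its exact values are not claims
  about recall-epoch physiology.
* **Not simulated** (by default): interictal discharges, muscle/speech
  artifact, electrode geometry, volume conduction, cross-channel
  correlation.  A per-channel gain lets tests create low-voltage channels
  for the quality screen.

## Preprocessing

Bipolar montage (adjacent-contact differences per strip/grid/depth probe;
n contacts → n−1 channels), 60 Hz notch (fourth-order Butterworth
band-stop, 59–61 Hz), per-recording standardization of each contact to
zero mean and unit variance, polyphase resampling to the 500 Hz analysis
rate.  All filters are applied forward–backward (zero phase) so burst
timing is preserved for detection; the task literature is silent on phase
handling and zero-phase is the choice that protects the downstream
estimates.  The low-voltage screen band-passes the *physical* (µV) signal
to 80–200 Hz and 15–40 Hz with zero-phase FIR filters, takes the maximum
RMS over 200 ms windows (100 ms hop), and flags channels below 5 µV
(high gamma) or 10 µV (beta); thresholds are applied to the bipolar
montage.

## Burst detection and the convolved representation

The wavelet transform uses complex Morlet wavelets with σ_t =
n_cycles/(2πf); 7 cycles on a 4 Hz grid over [50, 250] Hz for high gamma,
5 cycles on a 1 Hz grid over [5, 50] Hz for beta (grids deliberately
over-cover the strict bands so contours are not clipped at band edges; at
500 Hz the top grid frequency is capped below Nyquist).  The transform is
evaluated in the frequency domain — one FFT of the signal, then a
unit-energy Gaussian spectral window per analysis frequency — which is
algebraically the standard wavelet convolution and keeps hour-scale
recordings cheap.  The power map is block-averaged in time (5 samples for
the high-gamma grid, 10 for beta) before detection; the resulting 10–20 ms
resolution is well under the wavelets' own temporal smearing.

Detection z-scores each frequency row across time, finds connected
supra-threshold regions (default z ≥ 2), expands each region's z-maximum
to its half-maximum contour by flood fill, and takes the contour's
temporal extent as onset/offset.  **Peak frequency is assigned from the
raw-power maximum within the region, not the z-map maximum**: per-row
z-scoring divides by the 1/f background variance, which is tiny at high
rows, so the z-argmax of a burst's region is systematically dragged to the
top of the detection grid; raw power is what "spectral content" means
physically.  Events whose peak frequency falls outside the strict band
(80–200 or 15–40 Hz) are discarded; temporally overlapping same-band
events are merged (union of extents, frequency of the strongest seed,
summed power).  At z = 2 the detector also yields a steady trickle of
small noise events (≈9.4 /s high-gamma, ≈2.5 /s beta on pure 1/f noise —
frozen as a regression fixture); these carry near-median power and hence
near-unit kernel amplitudes, while genuine bursts stand out through the
power scaling.

Each burst becomes a Gaussian kernel A·exp(−(t−p)²/2w²) with A = burst
power normalized by the median detected-burst power of that
channel/band/session, p the onset/offset midpoint, and w the burst
duration (a width multiplier is exposed).  Kernels are evaluated to where
the tail falls below 1e−13·A, so the sampled series matches the analytic
sum to better than 1e−9.  Summation yields one non-negative series per
contact and band; rows are stacked contact-major, high-gamma before beta.

## Burst SNR

Per contact and band: band-pass with a symmetric FIR filter (order 500 for
80–200 Hz, order 100 for 15–40 Hz), zero-phase; noise = RMS of the
filtered trace; candidate peaks = local maxima of the absolute filtered
trace at least 2× the RMS; signal = 95th percentile of those peak
amplitudes; SNR = signal/noise.  When no peak clears the threshold (a
burst-free narrowband signal — e.g. a pure tone, whose peaks sit at √2
times the RMS) all local maxima are used; this fallback is what makes the
analytic pure-tone value SNR = √2 hold.  Experiment-level SNRs are the
arithmetic means across contacts.  These SNRs feed only the explanatory
GLM, never the decoders.

## Decoders

One architecture for all four problems: three Conv1D layers of 64, 128, 64
filters (kernel 3, 'same' padding, ReLU), each followed by batch
normalization, then global average pooling over time and a single sigmoid
unit; Adam at its default step size (1e−3); binary cross-entropy.
Epochs/batch size: 100/128 (`cnn1`), 150/128 (`cnn2a`, `cnn2b`), 100/32
(`cnn3`).  The network is implemented in NumPy (float32, fully seeded, so
training is bit-reproducible on a given BLAS); batch-norm uses ε = 1e−3
and a running-statistics momentum of 0.9 — a numerical choice that lets
the inference-time statistics warm up within the epoch counts used here.

Cross-validation is stratified k-fold (k = 5; k = 2 for `cnn3`, whose
trials are whole sessions), with the model retrained from scratch each
fold and test-fold probabilities pooled into one ROC per experiment.
Stratification is a deliberate choice for small, imbalanced datasets.  For
the **memory-state** problem the folds additionally hold out whole lists
(grouped stratification): the random 3-s recall segments drawn from one
30-s recall window can overlap each other, and ungrouped folds would let a
test segment share samples with a training segment — the decoder then
recognizes recall *content* rather than recall *state*, inflating AUROC
under a true null.  Encoding-epoch problems keep plain stratified folds
(adjacent-trial overlap exists but labels are independent across
neighbors, so it cannot inflate the null).  `train_test_distinct` trains
once on one experiment and scores another, quantifying cross-validation
optimism.  No early stopping, no validation split, no class rebalancing
(inverse-frequency loss weights exist but default off).

The memory-state dataset pools the stimulus-locked encoding tensors
(label 1) with the random recall segments (label 0) as one shuffled set —
"paired then randomly concatenated" read as a pooled shuffled set.  The
3-s encoding window starts at word onset (covering the 1.6 s word, the
ISI, and the margin to the next onset).  Good/poor recall sessions are
labeled by recall count strictly exceeding the mode of the session's
counts, ties in the mode broken toward the smaller value.

## Metrics

AUROC via rank statistics (ties count one half), verified against an
O(n²) pairwise oracle and trapezoidal integration.  The operating point
maximizes Youden's J = sensitivity + specificity − 1; ties in J are broken
toward higher sensitivity (an ulp-tolerant tie set guards against
floating-point noise splitting exact ties).  PPV and F1 are reported as 0
when no positive predictions are made.  AUROC groups are compared with
two-sided t-tests (paired or unpaired); a zero-variance paired difference
reports t = 0 with an undefined (NaN) p.

## Explanatory GLM

Normal family, identity link, fixed intercept, no random effects — i.e.
ordinary least squares — of experiment AUROC on electrode type (depth 0 /
subdural 1), contact count, mean high-gamma and beta burst SNRs, recall
probability and word-trial count.  The default design is the curated set
of 41 interaction terms used in the published analysis of this problem
(headline term: the four-way contact-count × HG-SNR × beta-SNR ×
recall-probability interaction); a full 63-term factorial sits behind a
flag.  Covariates enter raw (unstandardized).  Rank-deficient designs
raise a singularity error naming the collinear terms.

## LIME for burst tensors

Each tensor row is tiled into 10 equal segments (the last absorbs the
remainder).  Perturbed copies zero an independent Bernoulli(0.5) subset of
(row, segment) cells — zero being the "no burst" baseline of the
non-negative convolved series — and a plain least-squares surrogate is
fitted to the model's probabilities (no kernel weighting, no adaptive
segmentation).  The default sample count is 4× the number of cells, with
a hard floor of 2× for identifiability.  The top 20% of cells by
|coefficient| are flagged influential; flags are counted across trials
into a frequency map (exportable as TSV and heat map).

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run the pipeline end to end at
demonstration scale, chosen so the full suite completes on a single CPU:
sessions of 6–10 lists (72–120 word trials) with two bipolar contacts,
decoder input tensors sampled at 20 Hz (the Gaussian burst kernels have
sub-hertz bandwidth, so nothing is lost below the 500 Hz analysis rate),
and 30–50 training epochs for the subsequent-memory decoders; the
memory-state decoder's signal arm uses its full 100 epochs, while its null
arm (where training length cannot create class information) uses 30.
Null-calibration bands are ±0.05 around chance for means over ≥5 seeded
runs and ±0.08 for the 3-seed ablation study (the per-run SD of a pooled
null AUROC at these trial counts is ≈0.05).

What passing shows: the detector recovers planted bursts with quantified
timing/frequency accuracy; the decoders extract exactly the class
information the generator plants (null runs stay at chance, the
signal-recovery curve is monotone in effect size, ablating beta removes
beta-borne information); the metrics, GLM and surrogate explainer agree
with independent closed-form oracles; and the whole pipeline is
byte-deterministic under a fixed configuration.  What passing does not
show: performance on real iEEG — real bursts are not Hann-windowed
sinusoids, artifact and epileptiform activity are absent, channel counts
and noise structure are idealized, and the recall-period regime is an
assumption.

## Known limitations

* Burst detection at z = 2 is liberal; downstream robustness relies on
  power-scaled kernel amplitudes rather than a clean event list.
* The half-maximum contour slightly under-covers Hann-shaped bursts
  (onset/offset sit ≈0.3 duration inside the true extent; ≈40 ms at the
  default durations), a bias inherent to half-maximum timing.
* The printed form of the Gaussian kernel in the source literature is
  typographically garbled; the standard negative exponent is assumed, and
  w is read literally as the burst duration (configurable multiplier).
* CNN training, while deterministic, is float32; bit-reproducibility holds
  within one BLAS build, not across platforms.
* No cross-regional analyses, electrode localization, or artifact
  detection beyond the low-voltage screen.
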