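# Methods

This note documents the models, parameter choices, and numerical
conventions behind `pathasv`, and what the synthetic-data results do and
do not establish about real clinical speech.

## Verification model

**Front-end.** Utterances are 16 kHz, 16-bit mono PCM. Conditioning runs
in three passes:

1. *Low-energy pruning.* Frames (10 ms, non-overlapping) whose RMS level is
   more than 30 dB below the utterance's own loudest frame are removed and
   the remainder concatenated. The dB reference is the utterance peak:
   absolute sound-pressure level is unrecoverable from digital samples, so
   a relative criterion is the only well-defined reading of a fixed-dB cut.
2. *Voice activity detection.* A per-sample mean-square envelope over a
   30 ms window, smoothed by an 8 ms moving average, is thresholded 30 dB
   below its peak (with an absolute floor of 1e-6 so pure silence yields no
   activity); active gaps shorter than 6 ms are bridged. This is an
   energy VAD honoring the three stated constants (window, maximum bridged
   silence, smoothing); it is behavior-compatible with dedicated VAD tools,
   not bit-compatible with any particular one.
3. *Partial utterances.* Contiguous voiced stretches ≥ 1825 ms
   (29 200 samples) survive; shorter stretches are discarded.

Features are 40 log-mel filterbank energies per frame: 25 ms Hann window,
10 ms hop, 512-point FFT, no padding (so T = 1 + ⌊(samples − 400)/160⌋),
Slaney-style mel scale from 0 Hz to the 8 kHz Nyquist, and a 1e-10 floor on
band energies before the log so features are always finite. The mel
dialect and band edges are recorded in `FrontendConfig` and can be changed.

**Encoder.** A stack of LSTM layers followed by one linear projection; the
d-vector is the L2-normalized projection of the top layer's final-frame
output. The full-scale configuration is 3 × 768 with 256-dim embeddings;
every dimension is overridable, and the desk-scale presets use 2 × 64 × 32
(`reduced`) and 1 × 32 × 16 (`tiny`). Weights are Xavier-normal, all
biases zero (including LSTM gate biases — no forget-gate offset). The
encoder, its backward pass, and the Adam optimizer are implemented on
numpy via a small reverse-mode tape (`pathasv._autodiff`); finite-difference
tests pin the gradients to 1e-4 or better.

**GE2E loss.** Batches hold N speakers × M partials (full scale N=16,
M=4), each randomly cropped to a common length drawn per batch from
`[crop_frames_min, crop_frames_max]` (default [140, 180] frames, inside
the 181-frame minimum partial; the desk presets use shorter crops to cut
sequence length). Similarities are w·cos + b with leave-one-out centroids
on the true-speaker block; the loss is the softmax form. Conventions:

* initial (w, b) = (10, −5), the conventional starting point of the
  adopted method;
* w is clamped to ≥ 1e-6 after each update so similarity remains an
  increasing function of cosine;
* the log-sum-exp is computed against a detached row maximum;
* embedding rows are re-normalized inside the loss graph, making the loss
  well-defined (and its gradient finite-difference-consistent) for
  arbitrary inputs — a no-op for the encoder's already-unit outputs;
* gradients are globally L2-clipped at 3; the optimizer is Adam.
* Useful closed form: a constant similarity matrix gives L_G = ln N.

Training is always from scratch. The learning rate is a per-experiment
choice; the full-scale default is 5e-5 (inside the 1e-5…1e-4 band used at
scale), while the desk presets use 2e-3/3e-3 — small recurrent networks on
small corpora need larger steps to converge within their step budgets.
Optional early stopping monitors a held-out GE2E loss with a patience
counter; the presets use fixed step budgets instead.

**Evaluation.** Partials of a test utterance are concatenated *before*
framing; windows of 160 frames at 50 % overlap are encoded and the window
d-vectors averaged element-wise, then re-normalized (the adopted method's
convention; recorded in `EvalConfig`). Shorter inputs are encoded as one
window. With eval_M = 2 each test speaker contributes one enrollment
utterance and one probe (chosen by a seeded draw per repetition); each
probe is scored against every enrollment centroid — the all-vs-all policy
that gives verification EER its full impostor denominator.

**EER.** Accept iff score ≥ threshold; FAR(t) is the impostor fraction
accepted, FRR(t) the genuine fraction rejected. FAR − FRR is swept over
the observed scores (plus an all-reject sentinel) and the crossing located
by linear interpolation in the (FAR, FRR) values; interpolation weights
depend only on the rate values, so the EER is invariant under strictly
increasing score transforms, and ties resolve to the lower threshold.
Degenerate single-valued score sets fall back to the midpoint convention
(identical genuine/impostor multisets give exactly 50 %).

## Synthetic corpus

The generator's purpose is structural: every downstream stage must be
exercisable and the study's qualitative findings reproducible without any
clinical data. It is a classic source–filter synthesizer, not a TTS
system — speaker-discriminative structure, not intelligible speech, is the
requirement.

* **Identity.** Each speaker has a base f0 (adult males 85–155 Hz, adult
  females 165–255 Hz, children 210–330 Hz) and four formant resonances
  drawn around a vocal-tract-scaled template (±12 % per formant), fixed
  for life. Between-speaker spacing comfortably exceeds within-speaker
  variation (per-syllable ±6 % formant excursions), which the identity-
  separability test verifies in log-mel space.
* **Source.** An impulse train with per-cycle jitter (f0 perturbation) and
  shimmer (amplitude perturbation), spectrally tilted by two one-pole
  lowpasses (≈ −12 dB/oct), plus aspiration noise mixed at the source in
  proportion to the breathiness parameter.
* **Pathology mapping.** dysphonia → jitter 1.5–4 %, shimmer 6–14 %,
  breathiness 0.25–0.55; CLP → nasality 0.35–0.75 (an added 280 Hz nasal
  resonance and a 750 Hz antiresonance notch); dysarthria → articulation
  slowdown ×1.3–1.9 with f0/formant modulation depths reduced to 40 %;
  dysglossia → displaced F2 (×0.78–1.25) and F3 targets; controls carry
  small baseline values. The mapping mirrors the clinical phonetic
  character of each group at the level an ASV front-end can see.
* **Channels.** Each microphone label applies a fixed 65-tap FIR
  coloration (treble-tilted "dnt", band-tilted "plant", bass-tilted
  "logi") and a label-specific noise floor (−55/−50/−52 dB re peak). The
  real microphones' responses are unpublished; these filters are
  arbitrary-but-fixed, distinguishable confounds.
* **Metadata.** Ages and WRR are drawn per group from normal distributions
  matching the clinical dataset's summary statistics (e.g. children
  patients ≈ 9.6 ± 3.7 years, WRR ≈ 50 ± 17 %), clipped to valid ranges.
  WRR is drawn independently of the acoustic identity parameters, so the
  EER–WRR correlation is ≈ 0 *by construction* — matching the structure,
  not the magnitude, of the empirical finding.
* **Timing.** Utterances default to 2.8–4.2 s: lead/tail silences
  (80–200 ms / 50–150 ms), one long voiced phrase, and a 250–500 ms
  mid-utterance pause when both halves can stay ≥ 2 s. This guarantees at
  least one training-grade partial per utterance while still exercising
  the VAD.
* **Seeds.** Hierarchical (`master_seed` → per-speaker `SeedSequence`
  children → per-utterance seeds); corpora are byte-reproducible.

What passing tests on this corpus **do not** show: real pathological
speech has phonetic content, prosody, disfluencies, room acoustics, and
within-speaker variability (health, recording date) that the generator
does not model; absolute EERs here say nothing about absolute clinical
re-identification risk. The pipeline's *mechanics* — filtering rules,
feature geometry, loss behavior, trial construction, statistics — are what
the tests establish.

## Experiments and statistics

* Cohorts are sampled per repetition; the 80/20 split rounds the test
  share (85 → 68/17, 124 → 99/25, 50 → 40/10) with a floor of two test
  speakers. Train/test speaker sets are disjoint by construction.
* Age matching is best-of-k resampling (default 50 tries) toward a target
  mean with a tolerance band — adequate at these cohort sizes.
* Per-repetition EER is pooled over that repetition's full trial set;
  experiment summaries are mean ± std over repetitions. WRR is paired with
  EER as the test set's mean WRR per repetition.
* Group comparison: Shapiro–Wilk per group, then the pooled-variance
  Student's t (the textbook unpaired test) with a Welch switch;
  significance at P ≤ 0.05; no multiple-testing correction is applied
  across comparisons (deliberately, matching the study design).
  Both groups constant and equal → (t, p) = (0, 1).
* Training-size fits are OLS of EER on ln(count); R² = 1 − SS_res/SS_tot.

## Desk-scale problem sizes

The package's own study configurations are sized for a single CPU: the
`reduced` preset (2 × 64 × 32 encoder, N=10 × M=4 batches, 80–100-frame
crops, 200 steps, lr 2e-3) trains in well under a minute per repetition;
the `tiny` preset (1 × 32 × 16, N=8 × M=2, 50–70-frame crops, ≤ 40 steps)
supports many-repetition statistical studies such as the 10-seed × 20-
repetition EER–WRR decoupling run. The desk-scale training-size sweep
trains on {10, 40, 80} speakers from a 100-speaker pooled corpus with a
*fixed* 16-speaker held-out cohort: at full scale the 80/20 design is fine
because even the smallest test set yields stable EER estimates, but a
cohort of 10 would leave two test speakers and an EER quantized to a
handful of values, confounding the trend with measurement granularity.
Holding the test cohort fixed isolates the training-set-size effect — the
qualitative logarithmic improvement the sweep is meant to exhibit. (The
80/20 whole-cohort sweep remains the default behavior of
`training_size_sweep`.)

## Known limitations

* The VAD and the 30 dB prune share an energy criterion; after pruning,
  most inter-phrase silence is already gone, so VAD mainly polishes
  boundaries. The ordering (prune first) follows the documented pipeline.
* The LSTM runs in float64 on numpy; it is fast enough for the desk-scale
  presets but not intended for the full 3 × 768 configuration on large
  corpora.
* `eval_m > 2` is supported by the same code path (enrollment centroid of
  eval_m − 1 utterances) but is not part of the default study surface.
* Synthetic WRR is pure metadata; the generator does not attempt to make
  low-WRR speech acoustically less intelligible.
* The EER of very small test cohorts (two speakers → two genuine, two
  impostor trials) is heavily quantized; the harness enforces only a
  two-speaker floor, so interpret small-cohort EERs accordingly.
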