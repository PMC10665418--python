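# pathasv

**Speaker-verification re-identification risk for pathological speech.**

Speech recorded in clinical settings — from people with voice disorders
(dysphonia), neuromotor speech disorders (dysarthria), structurally caused
articulation disorders (dysglossia), or cleft lip and palate (CLP) — is
increasingly shared for research. A privacy question follows directly: how
easily can a speaker be *re-identified* from such recordings by an automatic
speaker-verification (ASV) system, and does the pathology itself change that
risk? `pathasv` implements a complete, tested pipeline for studying this
question: a text-independent d-vector verification system trained with the
generalized end-to-end (GE2E) loss, an experiment harness with repeated
train/test resampling, the associated statistical analyses, and — because
clinical speech corpora cannot be redistributed — a synthetic
pathological-speech corpus generator that reproduces the *structure* of such
data (stable per-speaker vocal identities, group-specific perturbations,
microphone channels, age/intelligibility metadata).

It is aimed at speech-privacy and voice-biomarker researchers who need a
reproducible ASV risk-measurement pipeline that runs on a single CPU.

## The model

Each utterance is reduced to 40-dimensional log-mel filterbank energies
(25 ms windows, 10 ms hop, 512-point FFT) after low-energy pruning (30 dB
below the utterance peak), energy-based voice activity detection (30 ms
window, 6 ms maximum bridged silence, 8 ms smoothing), and extraction of
contiguous voiced *partial utterances* of at least 1825 ms. An LSTM stack
with a linear projection maps a feature sequence to a unit-norm embedding
(d-vector) **e**_ji for speaker *j*, utterance *i*. For a training batch of
*N* speakers × *M* partials, with centroids **c**_k (leave-one-out
**c**_j^(−i) for the true speaker), the similarity matrix is

    S_ji,k = w · cos(e_ji, c_j^(−i)) + b   if k = j
             w · cos(e_ji, c_k) + b        otherwise

with trainable scale *w* > 0 and offset *b*, and the GE2E loss is

    L_G = (1 / MN) Σ_ji [ −S_ji,j + log Σ_k exp(S_ji,k) ].

At evaluation, each test utterance's partials are concatenated, encoded
through a 160-frame sliding window with 50 % overlap, and the window
d-vectors averaged and re-normalized. With `eval_m = 2`, one utterance per
speaker enrolls (the probe is never part of its own enrollment) and one
probes; every probe is scored against every enrollment centroid by cosine
similarity, and performance is summarized by the **equal error rate** (EER):
the operating point where the false acceptance rate equals the false
rejection rate. *Lower EER = higher re-identification risk.*

The harness repeats each experiment over resampled 80/20 speaker splits,
compares group EER distributions (Shapiro–Wilk, then a two-tailed unpaired
t-test at P ≤ 0.05), correlates EER with the word recognition rate (WRR, an
intelligibility proxy carried as metadata), and fits the training-size
relationship EER = a + b·ln(n) by ordinary least squares.

## Worked example

```python
import numpy as np
from pathasv.synthetic_data import SynthConfig, synth_corpus
from pathasv.experiments_stats import (
    ExperimentSpec, FeatureStore, reduced_configs, run_experiment,
    correlate_eer_wrr,
)

cfg = SynthConfig.demo(n_per_group=3, utterances_per_speaker=8, master_seed=11)
manifest = synth_corpus(cfg, "scratch/demo_corpus")   # 21 speakers, 168 WAVs

enc_cfg, tr_cfg, ev_cfg, fe_cfg = reduced_configs(steps=150, seed=3)
spec = ExperimentSpec(name="demo", n_speakers=21, train_fraction=0.7,
                      repetitions=2, seed=3)
result = run_experiment(manifest, spec, enc_cfg, tr_cfg, ev_cfg, fe_cfg,
                        feature_store=FeatureStore(fe_cfg))
print(f"EER {result.mean_eer:.2f} +/- {result.std_eer:.2f} %")
```

On one CPU this trains a reduced encoder (2 LSTM layers × 64 units, 32-dim
embeddings) from scratch twice (~30 s per repetition) and prints:

```
EER 0.00 +/- 0.00 %
```

— the six held-out speakers are re-identified *perfectly*, far below the
50 % chance level, because the synthetic speakers carry genuinely distinct
vocal identities and this cohort is small. Larger test cohorts and weaker
training budgets give non-zero EERs (the training-size sweep below lands
around 6–15 %). During training the GE2E loss falls from ≈ 1.5 to ≈ 0.1
(for reference, a totally uninformative constant similarity matrix gives
L_G = ln N, about 2.3 for the preset's N = 10 speakers per batch).

The same machinery is exposed on the command line:

```bash
pathasv synth scratch/corpus --n-per-group 3 --seed 11
pathasv experiment run scratch/corpus/manifest.csv --n-speakers 21 \
    --repetitions 2 --preset reduced --seed 3
pathasv experiment sweep scratch/corpus/manifest.csv --sizes 10,20 --preset tiny
```

## Layout

| module | contents |
| --- | --- |
| `pathasv.corpus_io` | manifest data model, exclusion filters, WAV/CSV I/O |
| `pathasv.synthetic_data` | source–filter synthesizer, group perturbations, corpus writer |
| `pathasv.frontend` | pruning, VAD, partial extraction, log-mel, batch assembly |
| `pathasv.ge2e` | encoder, similarity matrix, GE2E loss, Adam training loop |
| `pathasv.evaluation` | sliding-window d-vectors, trials, EER |
| `pathasv.experiments_stats` | experiment harness, t-tests, correlation, log regression |
| `pathasv.cli` | `pathasv synth / train / eval / experiment / stats` |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
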