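"""Study harness and statistical analyses.

An experiment samples a speaker cohort (optionally age-matched), splits it
80/20 into disjoint train/test speaker sets, trains the verification
system from scratch, and measures the test-set EER; the whole cycle is
repeated (20 times in the full design) and summarized as mean +/- std.
Group EER distributions are compared with Shapiro–Wilk normality checks
and a two-tailed unpaired t-test at the P <= 0.05 level; the influence of
intelligibility is probed as the Pearson correlation between per-repetition
EER and mean test-set word recognition rate; and the training-size effect
is summarized by a logarithmic least-squares regression y = a + b*ln(x)
of EER on speaker count.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .corpus_io import CorpusManifest, Group, Microphone, SpeakerRecord, read_wav
from .evaluation import EvalConfig, build_trials, compute_eer, utterance_dvector
from .frontend import FeatureMatrix, FrontendConfig, concatenated_features, waveform_to_partial_features
from .ge2e import EncoderConfig, TrainConfig, train


@dataclass(frozen=True)
class AgeMatching:
    target_mean: float
    target_std: float
    tolerance: float = 1.0  # acceptable |sample mean - target mean|, years
    max_tries: int = 50


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    n_speakers: int
    group_filter: tuple[tuple[Group, Microphone], ...] | None = None
    train_fraction: float = 0.8
    repetitions: int = 20
    age_matching: AgeMatching | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_speakers < 5:
            raise ValueError("n_speakers must be >= 5")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ExperimentResult:
    spec: ExperimentSpec
    eers: tuple[float, ...]          # percent, one per repetition
    wrrs: tuple[float, ...]          # mean test-set WRR per repetition
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.eers) != self.spec.repetitions:
            raise ValueError("need one EER per repetition")

    @property
    def mean_eer(self) -> float:
        return float(np.mean(self.eers))

    @property
    def std_eer(self) -> float:
        return float(np.std(self.eers, ddof=1)) if len(self.eers) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "experiment": self.spec.name,
            "n_speakers": self.spec.n_speakers,
            "repetitions": self.spec.repetitions,
            "eer_pct": list(self.eers),
            "wrr_pct": list(self.wrrs),
            "mean_eer": self.mean_eer,
            "std_eer": self.std_eer,
        }


@dataclass(frozen=True)
class RegressionFit:
    intercept_a: float
    slope_b: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, x) -> np.ndarray:
        return self.intercept_a + self.slope_b * np.log(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p: float
    significant: bool                # at P <= 0.05
    shapiro_a: tuple[float, float]   # (W, p)
    shapiro_b: tuple[float, float]


# ---------------------------------------------------------------------------
# Feature preparation


class FeatureStore:
    """Per-utterance feature cache shared across repetitions and experiments.

    Keys are utterance ids; values hold the training-side partial features
    and the evaluation-side concatenated features of that utterance.
    """

    def __init__(self, frontend_cfg: FrontendConfig = FrontendConfig()):
        self.cfg = frontend_cfg
        self._partials: dict[str, list[FeatureMatrix]] = {}
        self._concat: dict[str, FeatureMatrix | None] = {}

    def _load(self, utt) -> None:
        wave, _ = read_wav(utt.wav_path)
        self._partials[utt.utterance_id] = waveform_to_partial_features(
            wave, self.cfg, utterance_id=utt.utterance_id
        )
        self._concat[utt.utterance_id] = concatenated_features(
            wave, self.cfg, utterance_id=utt.utterance_id
        )

    def partials(self, utt) -> list[FeatureMatrix]:
        if utt.utterance_id not in self._partials:
            self._load(utt)
        return self._partials[utt.utterance_id]

    def concatenated(self, utt) -> FeatureMatrix | None:
        if utt.utterance_id not in self._concat:
            self._load(utt)
        return self._concat[utt.utterance_id]

    def speaker_partials(self, speaker: SpeakerRecord) -> list[FeatureMatrix]:
        out: list[FeatureMatrix] = []
        for utt in speaker.utterances:
            out.extend(self.partials(utt))
        return out


def _matches(speaker: SpeakerRecord, spec: ExperimentSpec) -> bool:
    if spec.group_filter is None:
        return True
    return any(
        speaker.group is g and speaker.microphone is m for g, m in spec.group_filter
    )


def _sample_cohort(
    speakers: list[SpeakerRecord], spec: ExperimentSpec, rng: np.random.Generator
) -> list[SpeakerRecord]:
    pool = np.arange(len(speakers))
    if spec.age_matching is None:
        picks = rng.choice(pool, size=spec.n_speakers, replace=False)
        return [speakers[i] for i in picks]
    am = spec.age_matching
    best, best_err = None, np.inf
    for _ in range(am.max_tries):
        picks = rng.choice(pool, size=spec.n_speakers, replace=False)
        ages = [speakers[i].age for i in picks]
        err = abs(float(np.mean(ages)) - am.target_mean)
        if err < best_err:
            best, best_err = picks, err
        if err <= am.tolerance:
            break
    return [speakers[i] for i in best]


# ---------------------------------------------------------------------------
# The experiment loop


def run_experiment(
    manifest: CorpusManifest,
    spec: ExperimentSpec,
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    eval_cfg: EvalConfig = EvalConfig(),
    frontend_cfg: FrontendConfig = FrontendConfig(),
    feature_store: FeatureStore | None = None,
) -> ExperimentResult:
    """Sample -> split 80/20 -> train from scratch -> EER, repeated.

    Train and test speaker sets are disjoint in every repetition; no test
    speaker's audio reaches training.  The per-batch speaker count is
    capped at the training-cohort size.  Fully deterministic given
    `spec.seed` (and the configs).
    """
    candidates = [s for s in manifest.speakers if _matches(s, spec)]
    if len(candidates) < spec.n_speakers:
        raise ValueError(
            f"experiment {spec.name}: needs {spec.n_speakers} matching speakers, "
            f"manifest has {len(candidates)}"
        )
    store = feature_store or FeatureStore(frontend_cfg)
    eers, wrrs, thresholds = [], [], []
    for rep in range(spec.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, rep)))
        cohort = _sample_cohort(candidates, spec, rng)
        n_test = int(round((1.0 - spec.train_fraction) * len(cohort)))
        n_test = max(2, n_test)
        order = rng.permutation(len(cohort))
        test = [cohort[i] for i in order[:n_test]]
        train_set = [cohort[i] for i in order[n_test:]]

        train_features = {
            s.speaker_id: store.speaker_partials(s) for s in train_set
        }
        train_features = {
            k: v for k, v in train_features.items() if len(v) >= train_cfg.m_utterances
        }
        rep_train_cfg = replace(
            train_cfg,
            n_speakers=min(train_cfg.n_speakers, len(train_features)),
            seed=int(rng.integers(2**31)),
        )
        fitted = train(train_features, encoder_cfg, rep_train_cfg, frontend_cfg)

        speaker_dvectors = {}
        for s in test:
            usable = [
                u for u in s.utterances if store.concatenated(u) is not None
            ]
            if len(usable) < eval_cfg.eval_m:
                continue
            picks = rng.choice(len(usable), size=eval_cfg.eval_m, replace=False)
            speaker_dvectors[s.speaker_id] = [
                utterance_dvector(
                    fitted.encoder,
                    store.concatenated(usable[int(i)]),
                    eval_cfg,
                    speaker_id=s.speaker_id,
                    utterance_id=usable[int(i)].utterance_id,
                )
                for i in picks
            ]
        scores = build_trials(speaker_dvectors, eval_cfg, rng)
        eer, thr = compute_eer(scores)
        eers.append(eer)
        thresholds.append(thr)
        wrrs.append(float(np.mean([s.wrr for s in test if s.wrr is not None])))
    return ExperimentResult(
        spec=spec, eers=tuple(eers), wrrs=tuple(wrrs), thresholds=tuple(thresholds)
    )


def training_size_sweep(
    manifest: CorpusManifest,
    sizes: list[int],
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    eval_cfg: EvalConfig = EvalConfig(),
    frontend_cfg: FrontendConfig = FrontendConfig(),
    repetitions: int = 20,
    seed: int = 0,
    feature_store: FeatureStore | None = None,
    n_test: int | None = None,
) -> list[ExperimentResult]:
    """One experiment per cohort size, drawn from the pooled manifest.

    By default each size is a whole cohort split 80/20, mirroring the
    full-scale design.  With `n_test` set, the sizes are interpreted as
    *training*-set sizes and every experiment holds out the same number of
    test speakers — at desk scale this keeps the trial-set granularity
    constant across sizes, so EER differences reflect training-set size
    rather than test-cohort quantization.
    """
    store = feature_store or FeatureStore(frontend_cfg)
    results = []
    for size in sizes:
        if n_test is None:
            spec = ExperimentSpec(
                name=f"all-spk-{size}",
                n_speakers=size,
                repetitions=repetitions,
                seed=seed,
            )
        else:
            total = size + n_test
            spec = ExperimentSpec(
                name=f"all-spk-{size}",
                n_speakers=total,
                train_fraction=size / total,
                repetitions=repetitions,
                seed=seed,
            )
        results.append(
            run_experiment(
                manifest, spec, encoder_cfg, train_cfg, eval_cfg, frontend_cfg, store
            )
        )
    return results


# ---------------------------------------------------------------------------
# Statistics


def compare_groups(
    a: list[float], b: list[float], welch: bool = False
) -> GroupComparison:
    """Shapiro–Wilk normality per group, then a two-tailed unpaired t-test.

    The default is the pooled-variance Student's t; set `welch=True` for
    the unequal-variance variant.  Significance is declared at P <= 0.05.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    wa = sps.shapiro(a)
    wb = sps.shapiro(b)
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        t=float(t),
        p=float(p),
        significant=bool(p <= 0.05),
        shapiro_a=(float(wa.statistic), float(wa.pvalue)),
        shapiro_b=(float(wb.statistic), float(wb.pvalue)),
    )


def correlate_eer_wrr(result: ExperimentResult) -> float:
    """Pearson correlation between per-repetition EER and mean test WRR."""
    eers = np.asarray(result.eers, dtype=float)
    wrrs = np.asarray(result.wrrs, dtype=float)
    if np.std(eers) == 0 or np.std(wrrs) == 0:
        raise ValueError("correlation undefined: zero variance in EER or WRR")
    r, _ = sps.pearsonr(eers, wrrs)
    return float(r)


def fit_log_regression(x: list[float], y: list[float]) -> RegressionFit:
    """Ordinary least squares of y on ln(x): y = a + b * ln(x), plus R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching x and y with at least 2 points")
    if np.any(x <= 0):
        raise ValueError("all x (speaker counts) must be positive")
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise ValueError("all x equal: singular design")
    design = np.column_stack([np.ones_like(lx), lx])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(
        intercept_a=float(coef[0]),
        slope_b=float(coef[1]),
        r_squared=min(max(r2, 0.0), 1.0),
    )


def save_results(results: list[ExperimentResult], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)


def summary_frame(results: list[ExperimentResult]):
    """One-row-per-experiment summary table (exportable with .to_csv)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "experiment": r.spec.name,
                "n_speakers": r.spec.n_speakers,
                "repetitions": r.spec.repetitions,
                "mean_eer_pct": r.mean_eer,
                "std_eer_pct": r.std_eer,
                "mean_wrr_pct": float(np.mean(r.wrrs)),
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Desk-scale configuration presets (1-CPU runs)


def reduced_configs(
    steps: int = 200,
    learning_rate: float = 2e-3,
    seed: int = 0,
) -> tuple[EncoderConfig, TrainConfig, EvalConfig, FrontendConfig]:
    """Reduced encoder for desk-scale studies: 2 LSTM layers x 64, 32-dim."""
    return (
        EncoderConfig(num_recurrent_layers=2, hidden_units=64, embedding_dim=32),
        TrainConfig(
            learning_rate=learning_rate,
            steps=steps,
            n_speakers=10,
            m_utterances=4,
            seed=seed,
        ),
        EvalConfig(),
        FrontendConfig(crop_frames_min=80, crop_frames_max=100),
    )


def tiny_configs(
    steps: int = 40,
    learning_rate: float = 3e-3,
    seed: int = 0,
) -> tuple[EncoderConfig, TrainConfig, EvalConfig, FrontendConfig]:
    """Smallest useful system, for many-repetition statistical studies."""
    return (
        EncoderConfig(num_recurrent_layers=1, hidden_units=32, embedding_dim=16),
        TrainConfig(
            learning_rate=learning_rate,
            steps=steps,
            n_speakers=8,
            m_utterances=2,
            seed=seed,
        ),
        EvalConfig(),
        FrontendConfig(crop_frames_min=50, crop_frames_max=70),
    )
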