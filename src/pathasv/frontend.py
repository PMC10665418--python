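"""Waveform conditioning and feature extraction for the verification system.

Pipeline order: low-energy pruning (30 dB below the utterance's own peak),
short-time-energy voice activity detection (30 ms window, 6 ms maximum
bridged silence, 8 ms moving-average smoothing), extraction of contiguous
voiced "partial utterances" of at least 1825 ms, then 40-dimensional
log-mel filterbank energies (25 ms window, 10 ms hop, 512-point FFT).
Training batches hold N speakers x M partials, all cropped to a common
randomly drawn frame length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .corpus_io import SAMPLE_RATE

LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class FrontendConfig:
    prune_threshold_db: float = 30.0
    vad_window_ms: float = 30.0
    vad_max_silence_ms: float = 6.0
    vad_smoothing_ms: float = 8.0
    vad_threshold_db: float = 30.0  # below peak envelope
    vad_abs_floor: float = 1e-6    # mean-square floor; all-silence safety
    min_partial_ms: float = 1825.0
    n_mels: int = 40
    win_ms: float = 25.0
    hop_ms: float = 10.0
    n_fft: int = 512
    sample_rate: int = SAMPLE_RATE
    mel_fmin: float = 0.0
    mel_fmax: float = 8000.0
    # Common crop length for training batches is drawn uniformly from this
    # inclusive frame range (kept inside the minimum partial length).
    crop_frames_min: int = 140
    crop_frames_max: int = 180

    def __post_init__(self) -> None:
        if not (self.win_ms > self.hop_ms > 0):
            raise ValueError("need win_ms > hop_ms > 0")
        if self.n_fft < self.win_samples:
            raise ValueError("n_fft must be >= window length in samples")
        if not (0 < self.crop_frames_min <= self.crop_frames_max):
            raise ValueError("invalid crop frame bounds")

    @property
    def win_samples(self) -> int:
        return int(round(self.win_ms * self.sample_rate / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_ms * self.sample_rate / 1000.0))

    @property
    def min_partial_samples(self) -> int:
        return int(round(self.min_partial_ms * self.sample_rate / 1000.0))


@dataclass(frozen=True)
class FeatureMatrix:
    """T x n_mels log-mel energies for one partial (or whole) utterance."""

    frames: np.ndarray
    utterance_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=np.float64))
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x n_mels array with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class TrainingBatch:
    features: np.ndarray       # (N*M, L, n_mels), rows grouped by speaker
    speaker_index: np.ndarray  # (N*M,) int, row -> batch-local speaker
    n_speakers: int
    m_utterances: int

    @property
    def crop_frames(self) -> int:
        return self.features.shape[1]


def prune_low_energy(
    waveform: np.ndarray, config: FrontendConfig = FrontendConfig()
) -> np.ndarray:
    """Remove frames more than `prune_threshold_db` below the peak level.

    Levels are measured as RMS over non-overlapping 10 ms frames, relative
    to the loudest frame of the utterance itself (absolute sound pressure
    is unrecoverable from digital samples).  Surviving frames are
    concatenated in order; fully silent input yields an empty array.
    """
    x = np.asarray(waveform, dtype=np.float64)
    frame = config.hop_samples
    if x.size == 0:
        return x[:0]
    n_frames = int(np.ceil(x.size / frame))
    padded = np.pad(x, (0, n_frames * frame - x.size))
    frames = padded.reshape(n_frames, frame)
    rms = np.sqrt((frames**2).mean(axis=1))
    peak = rms.max()
    if peak <= 0:
        return x[:0]
    keep = rms > peak * 10.0 ** (-config.prune_threshold_db / 20.0)
    kept = frames[keep].reshape(-1)
    # Drop padding samples if the final frame survived.
    tail_pad = n_frames * frame - x.size
    if tail_pad and keep[-1]:
        kept = kept[:-tail_pad]
    return kept


def detect_voice_activity(
    waveform: np.ndarray, config: FrontendConfig = FrontendConfig()
) -> list[tuple[int, int]]:
    """Locate speech as half-open [start, end) sample intervals.

    A per-sample mean-square envelope over the 30 ms analysis window is
    smoothed with the 8 ms moving average; samples within
    `vad_threshold_db` of the peak envelope are active.  Silent gaps no
    longer than `vad_max_silence_ms` are bridged.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        return []
    sr = config.sample_rate
    win = max(1, int(round(config.vad_window_ms * sr / 1000.0)))
    smooth = max(1, int(round(config.vad_smoothing_ms * sr / 1000.0)))
    env = uniform_filter1d(x**2, size=win, mode="nearest")
    env = uniform_filter1d(env, size=smooth, mode="nearest")
    peak = env.max()
    thresh = max(peak * 10.0 ** (-config.vad_threshold_db / 10.0), config.vad_abs_floor)
    active = env >= thresh
    if not active.any():
        return []
    # Bridge short silences.
    max_gap = int(round(config.vad_max_silence_ms * sr / 1000.0))
    mask = active.astype(np.int8)
    starts = list(np.flatnonzero(np.diff(np.r_[0, mask]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[mask, 0]) == -1) + 1)
    intervals: list[tuple[int, int]] = []
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s - cur_e <= max_gap:
            cur_e = e
        else:
            intervals.append((int(cur_s), int(cur_e)))
            cur_s, cur_e = s, e
    intervals.append((int(cur_s), int(cur_e)))
    return intervals


def extract_partials(
    waveform: np.ndarray,
    vad_intervals: list[tuple[int, int]],
    config: FrontendConfig = FrontendConfig(),
) -> list[np.ndarray]:
    """Keep each contiguous voiced stretch of at least `min_partial_ms`."""
    x = np.asarray(waveform, dtype=np.float64)
    min_len = config.min_partial_samples
    return [x[s:e] for s, e in vad_intervals if e - s >= min_len]


def mel_filterbank(config: FrontendConfig = FrontendConfig()) -> np.ndarray:
    """Slaney-style triangular mel filterbank, (n_mels, n_fft//2 + 1)."""

    def hz_to_mel(f):
        f = np.asarray(f, dtype=np.float64)
        # Slaney: linear below 1 kHz, logarithmic above.
        min_log_hz = 1000.0
        lin = f / (200.0 / 3.0)
        log_step = np.log(6.4) / 27.0
        return np.where(
            f >= min_log_hz,
            15.0 + np.log(np.maximum(f, min_log_hz) / min_log_hz) / log_step,
            lin,
        )

    def mel_to_hz(m):
        m = np.asarray(m, dtype=np.float64)
        log_step = np.log(6.4) / 27.0
        return np.where(m >= 15.0, 1000.0 * np.exp(log_step * (m - 15.0)), m * (200.0 / 3.0))

    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, config.sample_rate / 2.0, n_bins)
    mel_pts = np.linspace(
        hz_to_mel(config.mel_fmin), hz_to_mel(config.mel_fmax), config.n_mels + 2
    )
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((config.n_mels, n_bins))
    for i in range(config.n_mels):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - left) / max(center - left, 1e-12)
        down = (right - fft_freqs) / max(right - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        # Slaney area normalization.
        fb[i] *= 2.0 / max(right - left, 1e-12)
    return fb


def log_mel(
    waveform: np.ndarray,
    config: FrontendConfig = FrontendConfig(),
    utterance_id: str = "",
    _fb_cache: dict = {},
) -> FeatureMatrix:
    """Compute T x n_mels log-mel filterbank energies.

    Frames of `win_ms` at `hop_ms` steps, Hann-windowed, no padding:
    T = 1 + floor((samples - win) / hop).  A floor of 1e-10 on the mel
    energies keeps the log finite.
    """
    x = np.asarray(waveform, dtype=np.float64)
    win, hop = config.win_samples, config.hop_samples
    if x.size < win:
        raise ValueError(
            f"input has {x.size} samples; log_mel needs at least {win} "
            f"(one {config.win_ms} ms window)"
        )
    n_frames = 1 + (x.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(win)[None, :]
    spectrum = np.abs(np.fft.rfft(frames, n=config.n_fft, axis=1)) ** 2
    key = (config.n_mels, config.n_fft, config.sample_rate, config.mel_fmin, config.mel_fmax)
    if key not in _fb_cache:
        _fb_cache[key] = mel_filterbank(config)
    mel = spectrum @ _fb_cache[key].T
    return FeatureMatrix(
        frames=np.log(np.maximum(mel, LOG_FLOOR)), utterance_id=utterance_id
    )


def waveform_to_partial_features(
    waveform: np.ndarray,
    config: FrontendConfig = FrontendConfig(),
    utterance_id: str = "",
) -> list[FeatureMatrix]:
    """Full conditioning pipeline: prune -> VAD -> partials -> log-mel."""
    pruned = prune_low_energy(waveform, config)
    if pruned.size == 0:
        return []
    intervals = detect_voice_activity(pruned, config)
    partials = extract_partials(pruned, intervals, config)
    return [
        log_mel(p, config, utterance_id=f"{utterance_id}#p{i}")
        for i, p in enumerate(partials)
    ]


def concatenated_features(
    waveform: np.ndarray,
    config: FrontendConfig = FrontendConfig(),
    utterance_id: str = "",
) -> FeatureMatrix | None:
    """Evaluation-side features: partials concatenated before framing."""
    pruned = prune_low_energy(waveform, config)
    if pruned.size == 0:
        return None
    intervals = detect_voice_activity(pruned, config)
    partials = extract_partials(pruned, intervals, config)
    if not partials:
        return None
    return log_mel(np.concatenate(partials), config, utterance_id=utterance_id)


def make_training_batch(
    speaker_features: dict[str, list[FeatureMatrix]],
    n_speakers: int,
    m_utterances: int,
    rng: np.random.Generator,
    config: FrontendConfig = FrontendConfig(),
) -> TrainingBatch:
    """Assemble an N x M batch of random fixed-length feature crops.

    Speakers are sampled without replacement from those holding at least M
    partials; M distinct partials are drawn per selected speaker; one crop
    length L is drawn per batch and every partial is randomly cropped to L
    frames.
    """
    eligible = [
        spk
        for spk, feats in speaker_features.items()
        if len(feats) >= m_utterances
    ]
    if len(eligible) < n_speakers:
        raise ValueError(
            f"need {n_speakers} speakers with >= {m_utterances} partials, "
            f"have {len(eligible)}"
        )
    chosen = rng.choice(np.array(sorted(eligible)), size=n_speakers, replace=False)
    crop = int(rng.integers(config.crop_frames_min, config.crop_frames_max + 1))
    rows, index = [], []
    for j, spk in enumerate(chosen):
        feats = speaker_features[spk]
        picks = rng.choice(len(feats), size=m_utterances, replace=False)
        for i in picks:
            fm = feats[int(i)].frames
            if fm.shape[0] < crop:
                raise ValueError(
                    f"partial of speaker {spk} has {fm.shape[0]} frames < crop {crop}"
                )
            start = int(rng.integers(0, fm.shape[0] - crop + 1))
            rows.append(fm[start : start + crop])
            index.append(j)
    return TrainingBatch(
        features=np.stack(rows),
        speaker_index=np.array(index, dtype=np.int64),
        n_speakers=n_speakers,
        m_utterances=m_utterances,
    )
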