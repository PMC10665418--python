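"""Synthetic pathological-speech corpus generator.

The real clinical corpus this package analyzes is not distributable, so
this module builds a stand-in with the statistical structure the analysis
depends on:

* every speaker has a stable vocal identity (fundamental frequency and a
  personal set of formant resonances) so that verification has something
  to verify;
* the clinical groups carry group-specific acoustic perturbations —
  dysphonia as jitter/shimmer/breathiness, cleft lip and palate as
  hypernasality (extra nasal resonance plus an antiresonance notch),
  dysarthria as slowed articulation with flattened prosodic modulation,
  dysglossia as displaced formant targets;
* each microphone label applies a fixed, distinguishable coloration
  filter and noise floor;
* age and word-recognition-rate metadata are drawn from per-group
  normal distributions patterned on the clinical dataset's summary
  statistics, with WRR sampled independently of the acoustic identity;
* utterances contain voiced phrases separated by genuine silences so the
  voice-activity-detection stage is exercised.

Synthesis is classic source–filter: a jittered/shimmered glottal pulse
train, spectrally tilted, driven through a cascade of second-order formant
resonators, with aspiration noise mixed in at the source.  The output is
deterministic given the seeds (hierarchical: master seed -> per-speaker
seed -> per-utterance seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .corpus_io import (
    SAMPLE_RATE,
    CorpusManifest,
    Group,
    Microphone,
    QualityFlag,
    SpeakerRecord,
    SubsetLabel,
    UtteranceRecord,
    write_manifest,
    write_wav,
)


@dataclass(frozen=True)
class PathologyParams:
    """Acoustic perturbation knobs operationalizing the clinical labels."""

    jitter_pct: float = 0.4        # cycle-to-cycle f0 perturbation, percent
    shimmer_pct: float = 2.0       # cycle-to-cycle amplitude perturbation, percent
    breathiness: float = 0.05      # aspiration-noise mix in [0, 1]
    nasality: float = 0.0          # nasal resonance/antiresonance strength in [0, 1]
    articulation_slowdown: float = 1.0  # syllable-rate divisor, >= 1

    def __post_init__(self) -> None:
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter/shimmer must be >= 0")
        if not (0.0 <= self.breathiness <= 1.0 and 0.0 <= self.nasality <= 1.0):
            raise ValueError("breathiness and nasality must be in [0, 1]")
        if self.articulation_slowdown < 1.0:
            raise ValueError("articulation_slowdown must be >= 1")


@dataclass(frozen=True)
class SpeakerProfile:
    speaker_id: str
    f0_base: float
    formant_freqs: tuple[float, ...]
    formant_bandwidths: tuple[float, ...]
    speaking_rate: float           # syllables per second, before slowdown
    group: Group
    pathology_params: PathologyParams
    microphone: Microphone
    age: float
    sex: str
    wrr: float
    rng_seed: int
    f0_mod_depth: float = 0.08     # prosodic f0 modulation (fraction of f0)
    formant_mod_depth: float = 1.0  # scales per-syllable formant excursions

    def __post_init__(self) -> None:
        if self.f0_base <= 0:
            raise ValueError("f0_base must be positive")
        freqs = tuple(float(f) for f in self.formant_freqs)
        if any(b >= a for a, b in zip(freqs[1:], freqs[:-1])):
            raise ValueError("formant_freqs must be strictly increasing")
        if not (0.0 <= self.wrr <= 100.0):
            raise ValueError("wrr must be in [0, 100]")
        object.__setattr__(self, "formant_freqs", freqs)
        object.__setattr__(
            self, "formant_bandwidths", tuple(float(b) for b in self.formant_bandwidths)
        )


@dataclass(frozen=True)
class GroupSpec:
    """Speaker count and metadata distributions for one group/microphone cell."""

    label: str
    group: Group
    microphone: Microphone
    count: int
    age_mean: float
    age_std: float
    age_min: float
    age_max: float
    wrr_mean: float
    wrr_std: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


# Per-group metadata distributions patterned on the clinical dataset's
# summary table (age and WRR mean +/- std per group/microphone cell).
TABLE_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("dysglossia-dnt", Group.DYSGLOSSIA, Microphone.DNT, 0, 60.91, 11.95, 21.0, 94.0, 62.61, 15.96),
    GroupSpec("dysarthria-plant", Group.DYSARTHRIA, Microphone.PLANT, 0, 62.70, 15.29, 21.0, 94.0, 69.11, 12.70),
    GroupSpec("dysphonia-logi", Group.DYSPHONIA, Microphone.LOGI, 0, 59.28, 10.67, 21.0, 94.0, 51.78, 15.84),
    GroupSpec("ctrl-plant-A", Group.CONTROL, Microphone.PLANT, 0, 23.93, 15.62, 21.0, 94.0, 73.72, 15.69),
    GroupSpec("CLP-dnt", Group.CLP, Microphone.DNT, 0, 9.69, 3.98, 2.0, 20.0, 48.28, 17.30),
    GroupSpec("CLP-plant", Group.CLP, Microphone.PLANT, 0, 9.27, 2.58, 2.0, 20.0, 57.61, 13.86),
    GroupSpec("ctrl-plant-C", Group.CONTROL, Microphone.PLANT, 0, 12.16, 3.72, 2.0, 20.0, 65.87, 12.44),
)


def table_group_specs(counts: dict[str, int]) -> tuple[GroupSpec, ...]:
    """TABLE_GROUPS with per-label speaker counts filled in."""
    known = {g.label for g in TABLE_GROUPS}
    unknown = set(counts) - known
    if unknown:
        raise KeyError(f"unknown group labels: {sorted(unknown)}")
    return tuple(
        replace(g, count=counts.get(g.label, 0))
        for g in TABLE_GROUPS
        if counts.get(g.label, 0) > 0
    )


@dataclass(frozen=True)
class SynthConfig:
    groups: tuple[GroupSpec, ...]
    utterances_per_speaker: int = 10
    duration_range: tuple[float, float] = (2.8, 4.2)
    lead_silence_range: tuple[float, float] = (0.08, 0.20)
    tail_silence_range: tuple[float, float] = (0.05, 0.15)
    mid_silence_range: tuple[float, float] = (0.25, 0.50)
    # A mid-utterance pause is inserted only when both resulting phrases
    # stay above this length (keeps one training-grade partial per phrase).
    min_phrase_s: float = 2.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.utterances_per_speaker < 0:
            raise ValueError("utterances_per_speaker must be >= 0")
        if self.duration_range[0] <= 0 or self.duration_range[0] > self.duration_range[1]:
            raise ValueError("invalid duration_range")

    @staticmethod
    def demo(
        n_per_group: dict[str, int] | int = 3,
        utterances_per_speaker: int = 10,
        master_seed: int = 0,
        **kwargs,
    ) -> "SynthConfig":
        if isinstance(n_per_group, int):
            n_per_group = {g.label: n_per_group for g in TABLE_GROUPS}
        return SynthConfig(
            groups=table_group_specs(n_per_group),
            utterances_per_speaker=utterances_per_speaker,
            master_seed=master_seed,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Profile sampling

_ADULT_F0 = {"m": (85.0, 155.0), "f": (165.0, 255.0)}
_CHILD_F0 = (210.0, 330.0)
_BASE_FORMANTS = np.array([500.0, 1500.0, 2480.0, 3450.0])


def _sample_pathology(group: Group, rng: np.random.Generator) -> PathologyParams:
    if group is Group.DYSPHONIA:
        return PathologyParams(
            jitter_pct=rng.uniform(1.5, 4.0),
            shimmer_pct=rng.uniform(6.0, 14.0),
            breathiness=rng.uniform(0.25, 0.55),
            nasality=rng.uniform(0.0, 0.05),
            articulation_slowdown=1.0,
        )
    if group is Group.CLP:
        return PathologyParams(
            jitter_pct=rng.uniform(0.3, 1.0),
            shimmer_pct=rng.uniform(2.0, 5.0),
            breathiness=rng.uniform(0.05, 0.15),
            nasality=rng.uniform(0.35, 0.75),
            articulation_slowdown=1.0,
        )
    if group is Group.DYSARTHRIA:
        return PathologyParams(
            jitter_pct=rng.uniform(0.8, 2.0),
            shimmer_pct=rng.uniform(3.0, 7.0),
            breathiness=rng.uniform(0.1, 0.25),
            nasality=rng.uniform(0.0, 0.1),
            articulation_slowdown=rng.uniform(1.3, 1.9),
        )
    if group is Group.DYSGLOSSIA:
        return PathologyParams(
            jitter_pct=rng.uniform(0.4, 1.2),
            shimmer_pct=rng.uniform(2.0, 5.0),
            breathiness=rng.uniform(0.05, 0.2),
            nasality=rng.uniform(0.0, 0.15),
            articulation_slowdown=rng.uniform(1.0, 1.2),
        )
    return PathologyParams(
        jitter_pct=rng.uniform(0.2, 0.6),
        shimmer_pct=rng.uniform(1.0, 3.0),
        breathiness=rng.uniform(0.02, 0.08),
        nasality=rng.uniform(0.0, 0.05),
        articulation_slowdown=1.0,
    )


def make_profiles(config: SynthConfig) -> list[SpeakerProfile]:
    """Draw the speaker population; deterministic given `master_seed`."""
    total = sum(g.count for g in config.groups)
    if total == 0:
        return []
    master = np.random.SeedSequence(config.master_seed)
    children = master.spawn(total)
    profiles: list[SpeakerProfile] = []
    idx = 0
    for gspec in config.groups:
        for k in range(gspec.count):
            ss = children[idx]
            idx += 1
            rng = np.random.default_rng(ss)
            age = float(
                np.clip(
                    rng.normal(gspec.age_mean, gspec.age_std),
                    gspec.age_min,
                    gspec.age_max,
                )
            )
            sex = "m" if rng.random() < 0.5 else "f"
            is_child = age <= 20.0
            if is_child:
                f0 = rng.uniform(*_CHILD_F0)
                tract_scale = 1.15 + 0.20 * (1.0 - min(age, 16.0) / 16.0)
            else:
                f0 = rng.uniform(*_ADULT_F0[sex])
                tract_scale = 1.0 if sex == "m" else 1.12
            formants = _BASE_FORMANTS * tract_scale * rng.uniform(0.88, 1.12, size=4)
            pathology = _sample_pathology(gspec.group, rng)
            if gspec.group is Group.DYSGLOSSIA:
                # Structural articulation disorder: displaced F2/F3 targets.
                formants[1] *= rng.uniform(0.78, 1.25)
                formants[2] *= rng.uniform(0.85, 1.15)
            formants = np.sort(formants)
            # Enforce strict increase with a minimal spacing.
            for i in range(1, 4):
                formants[i] = max(formants[i], formants[i - 1] * 1.08)
            bandwidths = np.array([80.0, 100.0, 140.0, 190.0]) * rng.uniform(
                0.8, 1.3, size=4
            )
            f0_mod = rng.uniform(0.05, 0.11)
            formant_mod = 1.0
            if gspec.group is Group.DYSARTHRIA:
                f0_mod *= 0.4
                formant_mod = 0.4
            # WRR drawn after (and independently of) the acoustic identity.
            wrr = float(np.clip(rng.normal(gspec.wrr_mean, gspec.wrr_std), 0.0, 100.0))
            profiles.append(
                SpeakerProfile(
                    speaker_id=f"{gspec.label}-s{k:04d}",
                    f0_base=float(f0),
                    formant_freqs=tuple(formants),
                    formant_bandwidths=tuple(bandwidths),
                    speaking_rate=rng.uniform(3.2, 5.2),
                    group=gspec.group,
                    pathology_params=pathology,
                    microphone=gspec.microphone,
                    age=age,
                    sex=sex,
                    wrr=wrr,
                    rng_seed=int(ss.generate_state(1)[0] % 2**31),
                    f0_mod_depth=float(f0_mod),
                    formant_mod_depth=formant_mod,
                )
            )
    return profiles


# ---------------------------------------------------------------------------
# Waveform synthesis

_MIC_FIR_CACHE: dict[Microphone, np.ndarray] = {}
_MIC_NOISE_DB = {Microphone.DNT: 55.0, Microphone.PLANT: 50.0, Microphone.LOGI: 52.0}


def _mic_fir(mic: Microphone) -> np.ndarray:
    """Fixed coloration filter per microphone label (arbitrary but stable)."""
    if mic not in _MIC_FIR_CACHE:
        if mic is Microphone.DNT:
            gains = [1.0, 1.0, 1.25, 1.5, 1.6]
        elif mic is Microphone.PLANT:
            gains = [0.6, 1.0, 1.2, 1.0, 0.7]
        else:  # logi
            gains = [1.4, 1.2, 1.0, 0.75, 0.5]
        _MIC_FIR_CACHE[mic] = signal.firwin2(
            65, [0.0, 0.15, 0.4, 0.7, 1.0], gains
        )
    return _MIC_FIR_CACHE[mic]


def _resonator(f: float, bw: float) -> tuple[np.ndarray, np.ndarray]:
    """Second-order all-pole resonator at f Hz with bandwidth bw Hz."""
    r = np.exp(-np.pi * bw / SAMPLE_RATE)
    theta = 2.0 * np.pi * f / SAMPLE_RATE
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    # Unity gain at the resonance peak keeps cascades bounded.
    b = np.array([(1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2 * theta) + r * r)])
    return b, a


def _synth_phrase(
    profile: SpeakerProfile, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """One continuous voiced stretch of `n_samples` samples."""
    p = profile.pathology_params
    fs = SAMPLE_RATE
    # --- glottal source: jittered/shimmered pulse train --------------------
    mean_period = fs / profile.f0_base
    n_pulses = int(n_samples / mean_period * 1.4) + 8
    t_approx = np.arange(n_pulses) * mean_period / fs
    syll_rate = profile.speaking_rate / p.articulation_slowdown
    contour = 1.0 + profile.f0_mod_depth * np.sin(
        2.0 * np.pi * (0.45 * syll_rate) * t_approx + rng.uniform(0, 2 * np.pi)
    )
    f0_t = profile.f0_base * contour
    periods = fs / f0_t * (1.0 + p.jitter_pct / 100.0 * rng.standard_normal(n_pulses))
    onsets = np.cumsum(periods).astype(np.int64)
    onsets = onsets[onsets < n_samples - 1]
    amps = 1.0 + p.shimmer_pct / 100.0 * rng.standard_normal(onsets.size)
    excitation = np.zeros(n_samples)
    excitation[onsets] = np.abs(amps)
    # Spectral tilt of the glottal source (~ -12 dB/oct): two one-pole lowpasses.
    excitation = signal.lfilter([1.0], [1.0, -0.92], excitation)
    excitation = signal.lfilter([1.0], [1.0, -0.75], excitation)
    # Aspiration noise mixed at the source.
    if p.breathiness > 0:
        src_rms = np.sqrt(np.mean(excitation**2)) or 1.0
        excitation = excitation + (
            p.breathiness * src_rms * rng.standard_normal(n_samples)
        )
    # --- vocal tract: per-syllable formant targets, state carried over ------
    syll_len = max(1, int(round(fs / syll_rate)))
    bounds = list(range(0, n_samples, syll_len)) + [n_samples]
    zis = [None] * len(profile.formant_freqs)
    out = np.empty(n_samples)
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        seg = excitation[s0:s1]
        for fi, (f, bw) in enumerate(
            zip(profile.formant_freqs, profile.formant_bandwidths)
        ):
            # Articulatory excursion around the speaker's formant target.
            f_target = f * (
                1.0
                + 0.06
                * profile.formant_mod_depth
                * rng.standard_normal()
            )
            f_target = float(np.clip(f_target, 120.0, 0.47 * fs))
            b, a = _resonator(f_target, bw)
            zi = zis[fi]
            if zi is None:
                zi = signal.lfiltic(b, a, [0.0])
            seg, zis[fi] = signal.lfilter(b, a, seg, zi=zi)
        out[s0:s1] = seg
    # --- nasality: nasal resonance + antiresonance notch --------------------
    if p.nasality > 0:
        bn, an = _resonator(280.0, 120.0)
        nasal = signal.lfilter(bn, an, out)
        bz, az = signal.iirnotch(750.0, Q=4.0, fs=fs)
        notched = signal.lfilter(bz, az, out)
        out = (1.0 - p.nasality) * out + p.nasality * (0.6 * notched + 0.8 * nasal)
    # --- syllabic amplitude envelope (kept well above the VAD floor) --------
    t = np.arange(n_samples) / fs
    env = 0.85 + 0.15 * np.sin(
        2.0 * np.pi * syll_rate * t + rng.uniform(0, 2 * np.pi)
    )
    return out * env


def synth_utterance(
    profile: SpeakerProfile,
    duration: float,
    utt_seed: int,
    config: SynthConfig | None = None,
) -> np.ndarray:
    """Synthesize one utterance: silences around (and between) voiced phrases.

    Deterministic given (profile, utt_seed).  Peak amplitude <= 1.
    """
    if duration < 0.5:
        raise ValueError("duration must be >= 0.5 s")
    cfg = config or SynthConfig(groups=())
    rng = np.random.default_rng(utt_seed)
    fs = SAMPLE_RATE
    n_total = int(round(duration * fs))
    lead = int(rng.uniform(*cfg.lead_silence_range) * fs)
    tail = int(rng.uniform(*cfg.tail_silence_range) * fs)
    voiced = n_total - lead - tail
    if voiced < int(0.3 * fs):  # very short utterance: drop the pauses
        lead = tail = 0
        voiced = n_total
    min_phrase = int(cfg.min_phrase_s * fs)
    mid = int(rng.uniform(*cfg.mid_silence_range) * fs)
    pieces: list[np.ndarray] = [np.zeros(lead)]
    if voiced - mid >= 2 * min_phrase:
        split = int(rng.uniform(min_phrase, voiced - mid - min_phrase))
        pieces.append(_synth_phrase(profile, split, rng))
        pieces.append(np.zeros(mid))
        pieces.append(_synth_phrase(profile, voiced - mid - split, rng))
    else:
        pieces.append(_synth_phrase(profile, voiced, rng))
    pieces.append(np.zeros(tail))
    wave = np.concatenate(pieces)
    # Microphone channel: coloration FIR plus label-specific noise floor.
    wave = signal.fftconvolve(wave, _mic_fir(profile.microphone), mode="same")
    peak = np.max(np.abs(wave)) or 1.0
    wave = wave / peak * 0.85
    noise_amp = 0.85 * 10.0 ** (-_MIC_NOISE_DB[profile.microphone] / 20.0)
    wave = wave + noise_amp * rng.standard_normal(wave.size)
    return np.clip(wave, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Corpus assembly


def synth_corpus(config: SynthConfig, out_dir: str | os.PathLike) -> CorpusManifest:
    """Generate WAV files + manifest CSV; fully reproducible from master_seed."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create corpus directory {out}: {exc}") from exc
    profiles = make_profiles(config)
    speakers: list[SpeakerRecord] = []
    for prof in profiles:
        spk_dir = out / prof.speaker_id
        spk_dir.mkdir(exist_ok=True)
        utt_sseq = np.random.SeedSequence(prof.rng_seed).spawn(
            config.utterances_per_speaker + 1
        )
        dur_rng = np.random.default_rng(utt_sseq[-1])
        utterances = []
        for u in range(config.utterances_per_speaker):
            duration = float(dur_rng.uniform(*config.duration_range))
            seed = int(utt_sseq[u].generate_state(1)[0] % 2**31)
            wave = synth_utterance(prof, duration, seed, config)
            utt_id = f"{prof.speaker_id}-u{u:03d}"
            wav_path = spk_dir / f"{utt_id}.wav"
            try:
                write_wav(wav_path, wave)
            except OSError as exc:
                raise OSError(f"failed writing {wav_path}: {exc}") from exc
            utterances.append(
                UtteranceRecord(
                    utterance_id=utt_id,
                    speaker_id=prof.speaker_id,
                    wav_path=str(wav_path),
                    duration=wave.size / SAMPLE_RATE,
                    quality_flag=QualityFlag.OK,
                )
            )
        speakers.append(
            SpeakerRecord(
                speaker_id=prof.speaker_id,
                age=prof.age,
                sex=prof.sex,
                group=prof.group,
                microphone=prof.microphone,
                wrr=prof.wrr,
                utterances=tuple(utterances),
            )
        )
    manifest = CorpusManifest(speakers=tuple(speakers), subset_label=SubsetLabel.MIXED)
    write_manifest(manifest, out / "manifest.csv")
    return manifest
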