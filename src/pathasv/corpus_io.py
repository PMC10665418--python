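"""Corpus data model, exclusion filtering, and WAV/manifest I/O.

The corpus is a flat manifest binding speakers (with clinical group,
microphone label, age, sex, and word recognition rate) to their utterance
WAV files.  Audio is 16 kHz, 16-bit signed PCM, mono throughout.

The manifest on disk is a single CSV with one row per utterance; speaker
attributes are repeated on every row of that speaker.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

SAMPLE_RATE = 16_000

MANIFEST_COLUMNS = [
    "speaker_id",
    "utterance_id",
    "wav_path",
    "age",
    "sex",
    "group",
    "microphone",
    "wrr",
    "quality_flag",
    "duration_s",
]


class Group(str, enum.Enum):
    DYSGLOSSIA = "dysglossia"
    DYSARTHRIA = "dysarthria"
    DYSPHONIA = "dysphonia"
    CLP = "CLP"
    CONTROL = "control"


class Microphone(str, enum.Enum):
    DNT = "dnt"
    PLANT = "plant"
    LOGI = "logi"


class QualityFlag(str, enum.Enum):
    OK = "ok"
    NOISY = "noisy"
    TEST = "test"
    MULTI_SPEAKER = "multi_speaker"


class SubsetLabel(str, enum.Enum):
    ADULTS = "adults"
    CHILDREN = "children"
    MIXED = "mixed"


# Minimum number of retained utterances a speaker needs to stay in the corpus.
MIN_UTTERANCES = 8

# Age partition: adults are strictly above this age, children are [2, 20].
ADULT_AGE_THRESHOLD = 20.0
CHILD_MIN_AGE = 2.0


@dataclass(frozen=True)
class UtteranceRecord:
    utterance_id: str
    speaker_id: str
    wav_path: str
    duration: float
    quality_flag: QualityFlag = QualityFlag.OK

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(
                f"utterance {self.utterance_id}: duration must be > 0, "
                f"got {self.duration}"
            )


@dataclass(frozen=True)
class SpeakerRecord:
    """One speaker with clinical metadata and their utterances.

    ``wrr`` is the word recognition rate in percent, an automatic
    speech-recognition score used as an intelligibility proxy; it is
    manifest metadata here, never computed from audio.  ``None`` marks
    a missing value (such speakers are dropped by the exclusion filter).
    """

    speaker_id: str
    age: float
    sex: str
    group: Group
    microphone: Microphone
    wrr: float | None = None
    diagnosis_present: bool = True
    environment_present: bool = True
    utterances: tuple[UtteranceRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"speaker {self.speaker_id}: age must be >= 0")
        if self.wrr is not None and not (0.0 <= self.wrr <= 100.0):
            raise ValueError(
                f"speaker {self.speaker_id}: wrr must be in [0, 100], got {self.wrr}"
            )
        object.__setattr__(self, "utterances", tuple(self.utterances))

    @property
    def has_complete_metadata(self) -> bool:
        return (
            self.wrr is not None
            and self.diagnosis_present
            and self.environment_present
            and not np.isnan(self.age)
        )


@dataclass(frozen=True)
class CorpusManifest:
    speakers: tuple[SpeakerRecord, ...] = ()
    subset_label: SubsetLabel = SubsetLabel.MIXED

    def __post_init__(self) -> None:
        object.__setattr__(self, "speakers", tuple(self.speakers))
        ids = [s.speaker_id for s in self.speakers]
        if len(ids) != len(set(ids)):
            raise ValueError("speaker_id values must be unique within a manifest")

    def __len__(self) -> int:
        return len(self.speakers)

    @property
    def is_empty(self) -> bool:
        return len(self.speakers) == 0

    def n_utterances(self) -> int:
        return sum(len(s.utterances) for s in self.speakers)

    def filter_speakers(self, predicate) -> "CorpusManifest":
        return CorpusManifest(
            speakers=tuple(s for s in self.speakers if predicate(s)),
            subset_label=self.subset_label,
        )


def apply_exclusion_filters(manifest: CorpusManifest) -> CorpusManifest:
    """Apply the corpus inclusion rules and return the surviving manifest.

    A speaker survives iff (a) WRR, diagnosis, age, microphone, and
    recording environment are all present, and (b) after dropping
    utterances whose quality flag is not ``ok`` (noisy/poor-quality
    recordings, test recordings, segments containing an examiner's or
    another speaker's voice), at least ``MIN_UTTERANCES`` utterances
    remain.  Record order is preserved.  An empty input yields an empty
    manifest, not an error.
    """
    survivors: list[SpeakerRecord] = []
    for spk in manifest.speakers:
        if not spk.has_complete_metadata:
            continue
        kept = tuple(
            u for u in spk.utterances if u.quality_flag is QualityFlag.OK
        )
        if len(kept) < MIN_UTTERANCES:
            continue
        survivors.append(replace(spk, utterances=kept))
    return CorpusManifest(speakers=tuple(survivors), subset_label=manifest.subset_label)


def split_by_age(manifest: CorpusManifest) -> tuple[CorpusManifest, CorpusManifest]:
    """Partition speakers into adults (age > 20) and children (2 <= age <= 20).

    Age exactly 20 goes to the children subset (closed children interval).
    Speakers younger than 2 belong to neither subset.  Negative ages are
    rejected by SpeakerRecord itself.
    """
    adults = tuple(s for s in manifest.speakers if s.age > ADULT_AGE_THRESHOLD)
    children = tuple(
        s
        for s in manifest.speakers
        if CHILD_MIN_AGE <= s.age <= ADULT_AGE_THRESHOLD
    )
    return (
        CorpusManifest(speakers=adults, subset_label=SubsetLabel.ADULTS),
        CorpusManifest(speakers=children, subset_label=SubsetLabel.CHILDREN),
    )


# ---------------------------------------------------------------------------
# Audio I/O


def read_wav(
    path: str | os.PathLike,
    *,
    rate_policy: str = "reject",
) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV as float64 samples in [-1, 1].

    ``rate_policy`` controls non-16 kHz input: ``"reject"`` raises,
    ``"resample"`` converts to 16 kHz with a polyphase resampler.
    """
    rate, data = wavfile.read(os.fspath(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        wave = data.astype(np.float64) / 32768.0
    elif data.dtype == np.float32 or data.dtype == np.float64:
        wave = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    if rate != SAMPLE_RATE:
        if rate_policy == "reject":
            raise ValueError(
                f"{path}: sample rate {rate} Hz != required {SAMPLE_RATE} Hz "
                "(rate_policy='reject')"
            )
        if rate_policy == "resample":
            g = np.gcd(int(rate), SAMPLE_RATE)
            wave = resample_poly(wave, SAMPLE_RATE // g, int(rate) // g)
            rate = SAMPLE_RATE
        else:
            raise ValueError(f"unknown rate_policy {rate_policy!r}")
    return wave, int(rate)


def write_wav(path: str | os.PathLike, waveform: np.ndarray) -> None:
    """Write float samples in [-1, 1] as 16 kHz 16-bit PCM."""
    clipped = np.clip(np.asarray(waveform, dtype=np.float64), -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(os.fspath(path), SAMPLE_RATE, pcm)


# ---------------------------------------------------------------------------
# Manifest I/O


def manifest_to_frame(manifest: CorpusManifest) -> pd.DataFrame:
    rows = []
    for spk in manifest.speakers:
        for utt in spk.utterances:
            rows.append(
                {
                    "speaker_id": spk.speaker_id,
                    "utterance_id": utt.utterance_id,
                    "wav_path": utt.wav_path,
                    "age": spk.age,
                    "sex": spk.sex,
                    "group": spk.group.value,
                    "microphone": spk.microphone.value,
                    "wrr": spk.wrr if spk.wrr is not None else np.nan,
                    "quality_flag": utt.quality_flag.value,
                    "duration_s": utt.duration,
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(manifest: CorpusManifest, path: str | os.PathLike) -> None:
    manifest_to_frame(manifest).to_csv(os.fspath(path), index=False)


def read_manifest(
    path: str | os.PathLike,
    subset_label: SubsetLabel = SubsetLabel.MIXED,
) -> CorpusManifest:
    df = pd.read_csv(os.fspath(path), dtype={"speaker_id": str, "utterance_id": str})
    return frame_to_manifest(df, subset_label=subset_label)


def frame_to_manifest(
    df: pd.DataFrame, subset_label: SubsetLabel = SubsetLabel.MIXED
) -> CorpusManifest:
    speakers: list[SpeakerRecord] = []
    if len(df) == 0:
        return CorpusManifest(subset_label=subset_label)
    for spk_id, sub in df.groupby("speaker_id", sort=False):
        first = sub.iloc[0]
        wrr = None if pd.isna(first["wrr"]) else float(first["wrr"])
        utts = tuple(
            UtteranceRecord(
                utterance_id=str(r.utterance_id),
                speaker_id=str(spk_id),
                wav_path=str(r.wav_path),
                duration=float(r.duration_s),
                quality_flag=QualityFlag(r.quality_flag),
            )
            for r in sub.itertuples()
        )
        speakers.append(
            SpeakerRecord(
                speaker_id=str(spk_id),
                age=float(first["age"]),
                sex=str(first["sex"]),
                group=Group(first["group"]),
                microphone=Microphone(first["microphone"]),
                wrr=wrr,
                utterances=utts,
            )
        )
    return CorpusManifest(speakers=tuple(speakers), subset_label=subset_label)
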