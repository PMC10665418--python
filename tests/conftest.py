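import numpy as np
import pytest

from pathasv.corpus_io import (
    CorpusManifest,
    Group,
    Microphone,
    QualityFlag,
    SpeakerRecord,
    UtteranceRecord,
)
from pathasv.experiments_stats import FeatureStore
from pathasv.frontend import FrontendConfig
from pathasv.synthetic_data import SynthConfig, make_profiles, synth_corpus


def make_speaker(
    speaker_id="spk0",
    n_utts=9,
    age=35.0,
    wrr=70.0,
    group=Group.CONTROL,
    microphone=Microphone.PLANT,
    flags=None,
    **kwargs,
):
    """Metadata-only speaker for filter tests (wav paths are dummies)."""
    flags = flags or [QualityFlag.OK] * n_utts
    utts = tuple(
        UtteranceRecord(
            utterance_id=f"{speaker_id}-u{i}",
            speaker_id=speaker_id,
            wav_path=f"{speaker_id}-u{i}.wav",
            duration=3.0,
            quality_flag=flags[i],
        )
        for i in range(n_utts)
    )
    return SpeakerRecord(
        speaker_id=speaker_id,
        age=age,
        sex="f",
        group=group,
        microphone=microphone,
        wrr=wrr,
        utterances=utts,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A small on-disk synthetic corpus shared by the audio-level tests.

    8 speakers (one per group cell plus an extra control), 8 utterances
    each; enough for feature extraction, batching, and tiny training runs.
    """
    cfg = SynthConfig.demo(
        n_per_group={
            "dysglossia-dnt": 1,
            "dysarthria-plant": 1,
            "dysphonia-logi": 1,
            "ctrl-plant-A": 2,
            "CLP-dnt": 1,
            "CLP-plant": 1,
            "ctrl-plant-C": 1,
        },
        utterances_per_speaker=8,
        master_seed=42,
    )
    out = tmp_path_factory.mktemp("corpus")
    manifest = synth_corpus(cfg, out)
    return cfg, manifest


@pytest.fixture(scope="session")
def small_feature_store(small_corpus):
    _, manifest = small_corpus
    store = FeatureStore(FrontendConfig(crop_frames_min=60, crop_frames_max=80))
    # warm the cache once for all tests
    for s in manifest.speakers:
        store.speaker_partials(s)
    return store


@pytest.fixture(scope="session")
def demo_profiles():
    cfg = SynthConfig.demo(n_per_group=2, master_seed=1)
    return cfg, make_profiles(cfg)
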