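"""Enrollment/trial construction, cosine scoring, and equal error rate.

Evaluation follows the sliding-window d-vector recipe: the partial
utterances of a test utterance are concatenated, windows of 160 frames
with 50% overlap are each encoded, and the window d-vectors are averaged
element-wise and re-normalized.  With eval_M = 2 each test speaker
contributes one enrollment utterance (the speaker model is that single
d-vector; the probe is never part of its own enrollment) and one probe,
scored against every speaker's enrollment by cosine similarity.  The EER
is the operating point where the false acceptance rate equals the false
rejection rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import no_grad
from .frontend import FeatureMatrix
from .ge2e import Centroid, DVector, Encoder


@dataclass(frozen=True)
class EvalConfig:
    window_frames: int = 160
    overlap: float = 0.5
    eval_m: int = 2

    def __post_init__(self) -> None:
        if self.window_frames <= 0:
            raise ValueError("window_frames must be positive")
        if not (0.0 < self.overlap < 1.0):
            raise ValueError("overlap must be in (0, 1)")
        if self.eval_m < 2:
            raise ValueError("eval_m must be >= 2 (one enrollment + one probe)")


@dataclass(frozen=True)
class TrialScores:
    genuine: tuple[float, ...]
    impostor: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genuine", tuple(float(s) for s in self.genuine))
        object.__setattr__(self, "impostor", tuple(float(s) for s in self.impostor))


@dataclass(frozen=True)
class DetPoint:
    threshold: float
    far: float
    frr: float


def utterance_dvector(
    encoder: Encoder,
    features: FeatureMatrix,
    config: EvalConfig = EvalConfig(),
    speaker_id: str = "",
    utterance_id: str = "",
) -> DVector:
    """Sliding-window d-vector for one (concatenated) utterance.

    Windows of `window_frames` at 50% overlap are encoded independently
    and averaged element-wise; the mean is re-normalized to unit length.
    Inputs shorter than one window are encoded as a single window.
    """
    T = features.n_frames
    if T < 1:
        raise ValueError("cannot encode an empty feature matrix")
    win = config.window_frames
    step = max(1, int(round(win * (1.0 - config.overlap))))
    if T < win:
        starts = [0]
        win = T
    else:
        starts = list(range(0, T - win + 1, step))
    batch = np.stack([features.frames[s : s + win] for s in starts])
    with no_grad():
        emb = encoder.encode_array(batch).data
    mean = emb.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        raise ValueError("window d-vectors averaged to zero")
    return DVector(
        values=mean / norm,
        speaker_id=speaker_id,
        utterance_id=utterance_id or features.utterance_id,
    )


def cosine_score(e: DVector, c: Centroid) -> float:
    """Normalized dot product between a test d-vector and a speaker model."""
    cv = np.asarray(c.values, dtype=np.float64)
    cn = np.linalg.norm(cv)
    if cn == 0:
        raise ValueError("zero-norm centroid")
    ev = e.values
    return float(ev @ cv / (np.linalg.norm(ev) * cn))


def build_trials(
    speaker_dvectors: dict[str, list[DVector]],
    config: EvalConfig = EvalConfig(),
    rng: np.random.Generator | None = None,
) -> TrialScores:
    """All-vs-all verification trials over the test speakers.

    Per speaker, `eval_m` utterance d-vectors are drawn (seeded); one is
    the probe and the remaining eval_m - 1 form the enrollment centroid,
    so the probe never contributes to its own speaker model.  Each probe
    is scored against every speaker's enrollment centroid: one genuine
    score and (n_speakers - 1) impostor scores per probe.  Speakers with
    fewer than eval_m d-vectors are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    m = config.eval_m
    enroll: dict[str, Centroid] = {}
    probes: dict[str, DVector] = {}
    for spk in sorted(speaker_dvectors):
        dvs = speaker_dvectors[spk]
        if len(dvs) < m:
            import warnings

            warnings.warn(
                f"speaker {spk}: only {len(dvs)} utterance d-vectors "
                f"(< eval_m={m}); excluded from trials",
                stacklevel=2,
            )
            continue
        picks = rng.choice(len(dvs), size=m, replace=False)
        chosen = [dvs[int(i)] for i in picks]
        probes[spk] = chosen[0]
        enroll[spk] = Centroid(
            values=np.mean([d.values for d in chosen[1:]], axis=0),
            speaker_id=spk,
            excluded_utterance=chosen[0].utterance_id,
        )
    if len(enroll) < 2:
        raise ValueError("need at least two test speakers with enough utterances")
    genuine, impostor = [], []
    for spk, probe in probes.items():
        for other, cent in enroll.items():
            score = cosine_score(probe, cent)
            (genuine if other == spk else impostor).append(score)
    return TrialScores(genuine=tuple(genuine), impostor=tuple(impostor))


def det_curve(scores: TrialScores) -> list[DetPoint]:
    """FAR/FRR at every observed score threshold (accept iff score >= t)."""
    gen = np.asarray(scores.genuine, dtype=np.float64)
    imp = np.asarray(scores.impostor, dtype=np.float64)
    if gen.size == 0 or imp.size == 0:
        raise ValueError("both genuine and impostor scores are required")
    thresholds = np.unique(np.concatenate([gen, imp]))
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)  # all-reject sentinel
    points = []
    for t in thresholds:
        far = float(np.mean(imp >= t))
        frr = float(np.mean(gen < t))
        points.append(DetPoint(threshold=float(t), far=far, frr=frr))
    return points


def save_det_csv(scores: TrialScores, path) -> None:
    """Write the DET operating points (threshold, FAR, FRR) as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "far", "frr"])
        for p in det_curve(scores):
            writer.writerow([p.threshold, p.far, p.frr])


def compute_eer(scores: TrialScores) -> tuple[float, float]:
    """Equal error rate (percent) and its threshold.

    FAR - FRR is non-increasing in the threshold; the EER is taken at the
    sign change, linearly interpolating FAR, FRR, and the threshold
    between the two bracketing operating points (interpolation weights
    depend only on the FAR/FRR values, so the EER is invariant to any
    strictly increasing transform of the scores).  Ties resolve to the
    lower threshold.
    """
    points = det_curve(scores)
    diffs = [p.far - p.frr for p in points]
    # First index where FAR <= FRR.
    idx = next((i for i, d in enumerate(diffs) if d <= 0), len(points) - 1)
    p1 = points[idx]
    if diffs[idx] == 0 or idx == 0:
        return 100.0 * (p1.far + p1.frr) / 2.0, p1.threshold
    p0 = points[idx - 1]
    d0, d1 = diffs[idx - 1], diffs[idx]
    alpha = d0 / (d0 - d1)
    eer = p0.far + alpha * (p1.far - p0.far)
    thr = p0.threshold + alpha * (p1.threshold - p0.threshold)
    return 100.0 * eer, float(thr)
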