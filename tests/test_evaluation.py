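import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathasv.evaluation import (
    EvalConfig,
    TrialScores,
    build_trials,
    compute_eer,
    cosine_score,
    det_curve,
    utterance_dvector,
)
from pathasv.frontend import FeatureMatrix
from pathasv.ge2e import Centroid, DVector, Encoder, EncoderConfig

EC = EvalConfig()


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def eer_bruteforce(genuine, impostor):
    """Exhaustive threshold sweep under the accept-iff-score>=t convention,
    with linear interpolation at the FAR/FRR crossing (fixed convention)."""
    gen = np.asarray(genuine, float)
    imp = np.asarray(impostor, float)
    cand = np.unique(np.concatenate([gen, imp]))
    cand = np.append(cand, cand[-1] + 1.0)
    pts = [(np.mean(imp >= t), np.mean(gen < t)) for t in cand]
    diffs = [far - frr for far, frr in pts]
    for i, d in enumerate(diffs):
        if d <= 0:
            if d == 0 or i == 0:
                far, frr = pts[i]
                return 100.0 * (far + frr) / 2.0
            d0, d1 = diffs[i - 1], diffs[i]
            alpha = d0 / (d0 - d1)
            return 100.0 * (pts[i - 1][0] + alpha * (pts[i][0] - pts[i - 1][0]))
    return 50.0


class FakeWindowEncoder:
    """Duck-typed encoder recording window batches; returns mean-based units."""

    def __init__(self, dim=4):
        self.dim = dim
        self.batches = []

    def encode_array(self, x):
        from pathasv._autodiff import Tensor

        self.batches.append(np.asarray(x).shape)
        mean = np.asarray(x).mean(axis=1)[:, : self.dim]
        mean = mean + 1e-9
        return Tensor(mean / np.linalg.norm(mean, axis=1, keepdims=True))


class TestUtteranceDVector:
    def test_single_window_when_exactly_160_frames(self):
        enc = FakeWindowEncoder()
        fm = FeatureMatrix(np.random.default_rng(0).normal(size=(160, 40)), "u")
        dv = utterance_dvector(enc, fm, EC)
        assert enc.batches == [(1, 160, 40)]
        assert np.linalg.norm(dv.values) == pytest.approx(1.0, abs=1e-9)

    def test_two_windows_for_240_frames(self):
        enc = FakeWindowEncoder()
        fm = FeatureMatrix(np.random.default_rng(1).normal(size=(240, 40)), "u")
        utterance_dvector(enc, fm, EC)
        assert enc.batches == [(2, 160, 40)]

    def test_short_input_uses_single_full_window(self):
        enc = FakeWindowEncoder()
        fm = FeatureMatrix(np.random.default_rng(2).normal(size=(90, 40)), "u")
        utterance_dvector(enc, fm, EC)
        assert enc.batches == [(1, 90, 40)]

    def test_identical_windows_average_to_same_vector(self):
        enc = Encoder(
            EncoderConfig(num_recurrent_layers=1, hidden_units=8,
                          embedding_dim=4, input_dim=3),
            seed=0,
        )
        block = np.random.default_rng(3).normal(size=(160, 3))
        fm = FeatureMatrix(np.concatenate([block, block]), "u")  # 320 = 3 windows
        dv = utterance_dvector(enc, fm, EvalConfig())
        single = enc.encode_array(block[None]).data[0]
        # windows 0 and 160 are identical to `block`; window 80 differs, so
        # only check unit norm and strong alignment with the block embedding
        assert np.linalg.norm(dv.values) == pytest.approx(1.0, abs=1e-9)
        assert dv.values @ single > 0.5


class TestCosineScore:
    def test_self_similarity_is_one(self):
        v = unit([0.3, -0.4, 0.85])
        assert cosine_score(DVector(v), Centroid(v)) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_score(
            DVector(unit([1, 0])), Centroid(np.array([0.0, 2.0]))
        ) == pytest.approx(0.0, abs=1e-12)

    def test_analytic_45_degrees(self):
        e = DVector(unit([1.0, 0.0]))
        c = Centroid(np.array([1.0, 1.0]) / np.sqrt(2))
        assert cosine_score(e, c) == pytest.approx(0.70711, abs=1e-5)

    def test_zero_centroid_rejected(self):
        with pytest.raises(ValueError):
            cosine_score(DVector(unit([1, 0])), Centroid(np.zeros(2)))


def orthogonal_speaker_dvectors(n_speakers, per_speaker=2):
    """Speaker i lives on basis axis i; within-speaker vectors identical."""
    out = {}
    for i in range(n_speakers):
        v = np.zeros(n_speakers)
        v[i] = 1.0
        out[f"s{i}"] = [
            DVector(v, f"s{i}", f"s{i}-u{j}") for j in range(per_speaker)
        ]
    return out


class TestBuildTrials:
    def test_trial_counts_five_speakers(self):
        dvs = orthogonal_speaker_dvectors(5)
        scores = build_trials(dvs, EC, np.random.default_rng(0))
        assert len(scores.genuine) == 5
        assert len(scores.impostor) == 20

    def test_orthogonal_construction_scores(self):
        dvs = orthogonal_speaker_dvectors(2)
        scores = build_trials(dvs, EC, np.random.default_rng(0))
        assert all(s == pytest.approx(1.0) for s in scores.genuine)
        assert all(s == pytest.approx(0.0, abs=1e-12) for s in scores.impostor)

    def test_underpopulated_speaker_skipped_with_warning(self):
        dvs = orthogonal_speaker_dvectors(3)
        dvs["s0"] = dvs["s0"][:1]
        with pytest.warns(UserWarning, match="s0"):
            scores = build_trials(dvs, EC, np.random.default_rng(0))
        assert len(scores.genuine) == 2

    def test_probe_excluded_from_own_enrollment(self):
        # Two distinguishable d-vectors per speaker: the genuine score must
        # be cos(probe, other), never cos(probe, probe) = 1.
        a, b = unit([1.0, 0.2]), unit([1.0, -0.2])
        dvs = {
            "x": [DVector(a, "x", "x-0"), DVector(b, "x", "x-1")],
            "y": [DVector(unit([0.1, 1.0]), "y", "y-0"),
                  DVector(unit([-0.1, 1.0]), "y", "y-1")],
        }
        scores = build_trials(dvs, EC, np.random.default_rng(0))
        assert all(s < 1.0 - 1e-9 for s in scores.genuine)


class TestComputeEER:
    def test_perfect_separation(self):
        eer, _ = compute_eer(TrialScores((0.9, 0.8), (0.1, 0.2)))
        assert eer == pytest.approx(0.0)

    def test_identical_distributions_give_50(self):
        eer, _ = compute_eer(TrialScores((0.1, 0.5, 0.9), (0.1, 0.5, 0.9)))
        assert eer == pytest.approx(50.0)

    def test_hand_swept_example(self):
        eer, thr = compute_eer(TrialScores((0.6, 0.2), (0.4, 0.5)))
        assert eer == pytest.approx(50.0)
        assert 0.4 <= thr <= 0.5

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n_g = int(rng.integers(2, 50))
            n_i = int(rng.integers(2, 50))
            gen = rng.normal(0.6, 0.3, n_g)
            imp = rng.normal(0.2, 0.3, n_i)
            scores = TrialScores(tuple(gen), tuple(imp))
            eer, _ = compute_eer(scores)
            assert 0.0 <= eer <= 100.0
            assert eer == pytest.approx(eer_bruteforce(gen, imp), abs=1e-9)

    @given(
        gen=st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=20),
        imp=st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transform(self, gen, imp):
        scores = TrialScores(tuple(gen), tuple(imp))
        eer1, _ = compute_eer(scores)
        # strictly increasing and distinctness-preserving in float arithmetic
        transform = lambda s: np.asarray(s) ** 3 + 3.0 * np.asarray(s)
        scores2 = TrialScores(tuple(transform(gen)), tuple(transform(imp)))
        eer2, _ = compute_eer(scores2)
        assert eer1 == pytest.approx(eer2, abs=1e-8)

    def test_det_csv_export(self, tmp_path):
        from pathasv.evaluation import save_det_csv

        scores = TrialScores((0.9, 0.7), (0.1, 0.3))
        path = tmp_path / "det.csv"
        save_det_csv(scores, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "threshold,far,frr"
        assert len(lines) == 1 + 5  # 4 unique scores + sentinel

    def test_det_points_monotone(self):
        rng = np.random.default_rng(4)
        scores = TrialScores(
            tuple(rng.normal(0.5, 0.2, 20)), tuple(rng.normal(0.1, 0.2, 30))
        )
        pts = det_curve(scores)
        fars = [p.far for p in pts]
        frrs = [p.frr for p in pts]
        assert fars == sorted(fars, reverse=True)
        assert frrs == sorted(frrs)
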