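import numpy as np
import pytest

from pathasv._autodiff import Tensor
from pathasv.frontend import FeatureMatrix, FrontendConfig, TrainingBatch
from pathasv.ge2e import (
    Encoder,
    EncoderConfig,
    SimilarityParams,
    TrainConfig,
    _similarity_loss_tape,
    ge2e_loss,
    similarity_matrix,
    train,
)

TINY = EncoderConfig(num_recurrent_layers=1, hidden_units=16, embedding_dim=8, input_dim=5)


def brute_force_similarity(e, w, b):
    """Scalar-by-scalar evaluation of the similarity definition."""
    N, M, D = e.shape
    e = e / np.linalg.norm(e, axis=2, keepdims=True)
    S = np.zeros((N, M, N))
    for j in range(N):
        for i in range(M):
            for k in range(N):
                if k == j:
                    c = (e[j].sum(axis=0) - e[j, i]) / (M - 1)
                else:
                    c = e[k].mean(axis=0)
                cos = e[j, i] @ c / (np.linalg.norm(e[j, i]) * np.linalg.norm(c))
                S[j, i, k] = w * cos + b
    return S


def brute_force_loss(S):
    """Per-element loss summed without the log-sum-exp stabilization."""
    N, M, _ = S.shape
    total = 0.0
    for j in range(N):
        for i in range(M):
            total += -S[j, i, j] + np.log(np.exp(S[j, i]).sum())
    return total / (N * M)


class TestSimilarityMatrix:
    def test_identity_params_give_plain_cosines(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=(3, 3, 6))
        S = similarity_matrix(e, SimilarityParams(1.0, 0.0))
        assert np.all(S <= 1.0 + 1e-12) and np.all(S >= -1.0 - 1e-12)

    def test_identical_embeddings_saturate(self):
        v = np.array([1.0, 0.0, 0.0])
        e = np.tile(v, (2, 2, 1))
        S = similarity_matrix(e, SimilarityParams(3.0, 0.5))
        assert np.allclose(S, 3.0 * 1.0 + 0.5)

    def test_matches_hand_oracle_on_2x2(self):
        e = np.array(
            [[[1.0, 0.0], [np.sqrt(0.5), np.sqrt(0.5)]],
             [[0.0, 1.0], [-np.sqrt(0.5), np.sqrt(0.5)]]]
        )
        params = SimilarityParams(2.0, -0.25)
        S = similarity_matrix(e, params)
        assert np.allclose(S, brute_force_similarity(e, 2.0, -0.25), atol=1e-12)

    def test_m1_leave_one_out_undefined(self):
        e = np.ones((2, 1, 4))
        with pytest.raises(ValueError):
            similarity_matrix(e, SimilarityParams())


class TestGE2ELoss:
    @pytest.mark.parametrize("n_speakers", [2, 16])
    def test_constant_matrix_closed_form(self, n_speakers):
        S = np.full((n_speakers, 4, n_speakers), 0.37)
        assert ge2e_loss(S) == pytest.approx(np.log(n_speakers), abs=1e-12)

    def test_saturated_softmax_near_zero(self):
        S = np.full((2, 3, 2), -20.0)
        for j in range(2):
            S[j, :, j] = 20.0
        assert ge2e_loss(S) < 1e-8

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(3, 2, 3))
        assert ge2e_loss(S) == pytest.approx(brute_force_loss(S), abs=1e-6)

    def test_nonfinite_rejected(self):
        S = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError):
            ge2e_loss(S)


class TestLossGradient:
    def test_autodiff_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        N, M, D = 3, 2, 4
        e = rng.normal(size=(N * M, D))
        e /= np.linalg.norm(e, axis=1, keepdims=True)
        et = Tensor(e, requires_grad=True)
        wt = Tensor(2.0, requires_grad=True)
        bt = Tensor(-1.0, requires_grad=True)
        loss = _similarity_loss_tape(et, wt, bt, N, M)
        loss.backward()
        eps = 1e-6
        params = SimilarityParams(2.0, -1.0)

        def f(arr):
            return ge2e_loss(similarity_matrix(arr.reshape(N, M, D), params))

        for idx in [(0, 0), (2, 3), (5, 1), (3, 2)]:
            ep, em = e.copy(), e.copy()
            ep[idx] += eps
            em[idx] -= eps
            fd = (f(ep) - f(em)) / (2 * eps)
            assert fd == pytest.approx(et.grad[idx], abs=1e-4)

    def test_tape_loss_equals_numpy_loss(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            N, M, D = 4, 3, 6
            e = rng.normal(size=(N * M, D))
            loss = _similarity_loss_tape(
                Tensor(e), Tensor(5.0), Tensor(-1.0), N, M
            )
            ref = ge2e_loss(
                similarity_matrix(e.reshape(N, M, D), SimilarityParams(5.0, -1.0))
            )
            assert float(loss.data) == pytest.approx(ref, abs=1e-10)


class TestEncoder:
    def test_output_unit_norm_and_count(self):
        enc = Encoder(TINY, seed=0)
        x = np.random.default_rng(0).normal(size=(7, 12, 5))
        e = enc.encode_array(x).data
        assert e.shape == (7, 8)
        assert np.allclose(np.linalg.norm(e, axis=1), 1.0, atol=1e-6)

    def test_identical_rows_identical_embeddings(self):
        enc = Encoder(TINY, seed=1)
        row = np.random.default_rng(1).normal(size=(1, 10, 5))
        x = np.repeat(row, 3, axis=0)
        e = enc.encode_array(x).data
        assert np.allclose(e[0], e[1]) and np.allclose(e[0], e[2])

    def test_encode_batch_returns_labeled_unit_dvectors(self):
        enc = Encoder(TINY, seed=3)
        rng = np.random.default_rng(3)
        batch = TrainingBatch(
            features=rng.normal(size=(6, 10, 5)),
            speaker_index=np.array([0, 0, 1, 1, 2, 2]),
            n_speakers=3,
            m_utterances=2,
        )
        dvs = enc.encode(batch, speaker_ids=["a", "b", "c"])
        assert len(dvs) == 6
        assert [d.speaker_id for d in dvs] == ["a", "a", "b", "b", "c", "c"]
        for d in dvs:
            assert np.linalg.norm(d.values) == pytest.approx(1.0, abs=1e-6)

    def test_state_dict_roundtrip(self):
        enc = Encoder(TINY, seed=2)
        x = np.random.default_rng(2).normal(size=(2, 8, 5))
        before = enc.encode_array(x).data
        other = Encoder(TINY, seed=99)
        other.load_state_dict(enc.state_dict())
        assert np.allclose(other.encode_array(x).data, before)


def _toy_features(n_speakers=6, n_partials=3, frames=90, seed=0):
    """Separable fake speakers: distinct fixed offsets plus noise."""
    rng = np.random.default_rng(seed)
    feats = {}
    for s in range(n_speakers):
        base = rng.normal(scale=2.0, size=5)
        feats[f"s{s}"] = [
            FeatureMatrix(base + rng.normal(scale=0.3, size=(frames, 5)), f"s{s}p{j}")
            for j in range(n_partials)
        ]
    return feats


FE_TOY = FrontendConfig(crop_frames_min=20, crop_frames_max=30)


class TestTrain:
    def test_loss_decreases_on_separable_speakers(self):
        cfg = TrainConfig(
            learning_rate=5e-3, steps=40, n_speakers=4, m_utterances=2, seed=0
        )
        res = train(_toy_features(), TINY, cfg, FE_TOY)
        assert np.mean(res.loss_trace[-5:]) < res.loss_trace[0]
        assert res.params.w > 0

    def test_zero_learning_rate_keeps_parameters(self):
        cfg = TrainConfig(
            learning_rate=0.0, steps=3, n_speakers=4, m_utterances=2, seed=0
        )
        enc_before = Encoder(TINY, seed=int(np.random.default_rng(0).integers(2**31)))
        res = train(_toy_features(), TINY, cfg, FE_TOY)
        for k, v in res.encoder.state_dict().items():
            assert np.array_equal(v, enc_before.state_dict()[k])
        assert res.params == SimilarityParams(10.0, -5.0)

    def test_same_seed_identical_traces(self):
        cfg = TrainConfig(
            learning_rate=3e-3, steps=10, n_speakers=4, m_utterances=2, seed=11
        )
        a = train(_toy_features(), TINY, cfg, FE_TOY)
        b = train(_toy_features(), TINY, cfg, FE_TOY)
        assert a.loss_trace == b.loss_trace

    def test_training_separates_speakers_in_embedding_space(self):
        feats = _toy_features(n_speakers=6, n_partials=4, seed=3)
        cfg = TrainConfig(
            learning_rate=5e-3, steps=60, n_speakers=6, m_utterances=2, seed=3
        )
        res = train(feats, TINY, cfg, FE_TOY)
        embs = {}
        for spk, fms in feats.items():
            x = np.stack([fm.frames[:20] for fm in fms])
            embs[spk] = res.encoder.encode_array(x).data
        within, between = [], []
        keys = list(embs)
        for i, ka in enumerate(keys):
            ea = embs[ka]
            within.extend((ea @ ea.T)[np.triu_indices(len(ea), 1)])
            for kb in keys[i + 1 :]:
                between.extend((ea @ embs[kb].T).ravel())
        assert np.mean(within) - np.mean(between) > 0.1
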