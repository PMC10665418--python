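"""Generalized end-to-end (GE2E) speaker-verification model.

An LSTM stack with a final linear projection maps a sequence of log-mel
frames to a unit-norm d-vector.  Training optimizes the GE2E softmax
loss: for a batch of N speakers x M partial utterances, a similarity
matrix of scaled cosines between every embedding e_ji and every speaker
centroid c_k is formed (the true speaker's centroid computed leave-one-out
as c_j^(-i)), and each embedding is pushed toward its own centroid and
away from all others via a softmax cross-entropy over centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, no_grad
from .frontend import TrainingBatch, make_training_batch, FrontendConfig


@dataclass(frozen=True)
class EncoderConfig:
    num_recurrent_layers: int = 3
    hidden_units: int = 768
    embedding_dim: int = 256
    input_dim: int = 40

    def __post_init__(self) -> None:
        for name in ("num_recurrent_layers", "hidden_units", "embedding_dim", "input_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class SimilarityParams:
    w: float = 10.0
    b: float = -5.0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("similarity scale w must stay positive")


@dataclass(frozen=True)
class DVector:
    values: np.ndarray
    speaker_id: str = ""
    utterance_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("d-vector must be unit norm")


@dataclass(frozen=True)
class Centroid:
    values: np.ndarray
    speaker_id: str = ""
    excluded_utterance: str | None = None

    @staticmethod
    def from_dvectors(
        dvectors: list[DVector], exclude_utterance: str | None = None
    ) -> "Centroid":
        members = [
            d for d in dvectors if d.utterance_id != exclude_utterance
        ]
        if not members:
            raise ValueError("centroid needs at least one member d-vector")
        mean = np.mean([d.values for d in members], axis=0)
        return Centroid(
            values=mean,
            speaker_id=members[0].speaker_id,
            excluded_utterance=exclude_utterance,
        )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-5
    grad_clip_l2: float = 3.0
    steps: int = 1000
    n_speakers: int = 16
    m_utterances: int = 4
    seed: int = 0
    init_w: float = 10.0
    init_b: float = -5.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    # Early stopping on a held-out GE2E loss plateau; None disables.
    patience: int | None = None
    eval_every: int = 25


class TrainingDiverged(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Encoder


class Encoder:
    """LSTM stack + linear projection + L2 normalization.

    Weights are Xavier-normal initialized; all biases (including LSTM gate
    biases) start at zero.  The d-vector is the projection of the top
    layer's final-frame output, L2-normalized.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        d_in = config.input_dim
        H = config.hidden_units
        for layer in range(config.num_recurrent_layers):
            self.params[f"Wx{layer}"] = self._xavier(rng, d_in, 4 * H)
            self.params[f"Wh{layer}"] = self._xavier(rng, H, 4 * H)
            self.params[f"b{layer}"] = Tensor(np.zeros(4 * H), requires_grad=True)
            d_in = H
        self.params["Wp"] = self._xavier(rng, H, config.embedding_dim)
        self.params["bp"] = Tensor(np.zeros(config.embedding_dim), requires_grad=True)

    @staticmethod
    def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
        std = np.sqrt(2.0 / (fan_in + fan_out))
        return Tensor(rng.normal(0.0, std, size=(fan_in, fan_out)), requires_grad=True)

    def encode_array(self, features: np.ndarray) -> Tensor:
        """Encode a (B, T, input_dim) array into (B, embedding_dim) unit rows."""
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 3:
            raise ValueError("expected (batch, frames, input_dim) features")
        B, T, _ = features.shape
        H = self.config.hidden_units
        seq = features.transpose(1, 0, 2)  # (T, B, D) constant input
        layer_out: list[Tensor] | None = None
        for layer in range(self.config.num_recurrent_layers):
            Wx = self.params[f"Wx{layer}"]
            Wh = self.params[f"Wh{layer}"]
            b = self.params[f"b{layer}"]
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            outs: list[Tensor] = []
            for t in range(T):
                x_t = layer_out[t] if layer_out is not None else Tensor(seq[t])
                z = x_t @ Wx + h @ Wh + b
                i_g = z.slice_last(0, H).sigmoid()
                f_g = z.slice_last(H, 2 * H).sigmoid()
                g_g = z.slice_last(2 * H, 3 * H).tanh()
                o_g = z.slice_last(3 * H, 4 * H).sigmoid()
                c = f_g * c + i_g * g_g
                h = o_g * c.tanh()
                outs.append(h)
            layer_out = outs
        y = layer_out[-1] @ self.params["Wp"] + self.params["bp"]
        if not np.all(np.isfinite(y.data)):
            raise TrainingDiverged("NaN/Inf in encoder activations")
        norm = ((y * y).sum(axis=1, keepdims=True) + 1e-24).sqrt()
        return y / norm

    def encode(self, batch: TrainingBatch, speaker_ids: list[str] | None = None):
        """Encode a training batch into DVector objects (no gradients)."""
        with no_grad():
            emb = self.encode_array(batch.features).data
        out = []
        for row, j in enumerate(batch.speaker_index):
            sid = speaker_ids[j] if speaker_ids is not None else str(j)
            out.append(DVector(values=emb[row], speaker_id=sid, utterance_id=f"row{row}"))
        return out

    def parameter_list(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64)


# ---------------------------------------------------------------------------
# Similarity matrix and loss (numpy reference + tape versions)


def similarity_matrix(
    embeddings: np.ndarray, params: SimilarityParams
) -> np.ndarray:
    """Scaled-cosine similarity matrix S[j, i, k] for (N, M, D) embeddings.

    S[j,i,k] = w * cos(e_ji, c_k) + b, where c_k is the arithmetic-mean
    centroid of speaker k, except on the true-speaker block (k = j) where
    the centroid leaves out e_ji itself.  Rows are normalized to the unit
    sphere before centroids are formed (d-vectors are unit-norm by
    definition; normalizing here makes the function well-defined on
    arbitrary inputs).
    """
    e = np.asarray(embeddings, dtype=np.float64)
    if e.ndim != 3:
        raise ValueError("expected embeddings of shape (N, M, D)")
    N, M, D = e.shape
    if N < 2 or M < 2:
        raise ValueError("similarity matrix needs N >= 2 and M >= 2 "
                         "(leave-one-out centroid undefined for M = 1)")
    e_hat = e / np.linalg.norm(e, axis=2, keepdims=True)
    csum = e_hat.sum(axis=1)                  # (N, D)
    c = csum / M
    c_hat = c / np.linalg.norm(c, axis=1, keepdims=True)
    cos_all = e_hat.reshape(N * M, D) @ c_hat.T
    cos_all = cos_all.reshape(N, M, N)
    loo = (csum[:, None, :] - e_hat) / (M - 1)  # (N, M, D)
    loo_hat = loo / np.linalg.norm(loo, axis=2, keepdims=True)
    cos_loo = (e_hat * loo_hat).sum(axis=2)   # (N, M)
    S = params.w * cos_all + params.b
    jj = np.arange(N)
    S[jj, :, jj] = params.w * cos_loo + params.b
    return S


def ge2e_loss(S: np.ndarray) -> float:
    """GE2E softmax loss: mean over (j, i) of -S[j,i,j] + logsumexp_k S[j,i,k]."""
    S = np.asarray(S, dtype=np.float64)
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity matrix must be finite")
    N, M, N2 = S.shape
    if N != N2:
        raise ValueError("similarity matrix must have shape (N, M, N)")
    m = S.max(axis=2, keepdims=True)
    lse = np.log(np.exp(S - m).sum(axis=2)) + m[:, :, 0]
    jj = np.arange(N)
    diag = S[jj, :, jj]  # (N, M)
    return float(np.mean(-diag + lse))


def _similarity_loss_tape(
    emb: Tensor, w: Tensor, b: Tensor, N: int, M: int
) -> Tensor:
    """GE2E loss as a differentiable graph over (N*M, D) embeddings.

    Rows are re-normalized here so the graph computes true cosines even if
    an input row drifts off the unit sphere; this also keeps the gradient
    identical to finite differences of the numpy reference.
    """
    D = emb.shape[1]
    enorm = ((emb * emb).sum(axis=1, keepdims=True) + 1e-24).sqrt()
    emb = emb / enorm
    E3 = emb.reshape(N, M, D)
    csum = E3.sum(axis=1)                                   # (N, D)
    c = csum * (1.0 / M)
    cnorm = ((c * c).sum(axis=1, keepdims=True) + 1e-24).sqrt()
    c_hat = c / cnorm
    cos_all = (emb @ c_hat.transpose_2d()).reshape(N, M, N)
    loo = (csum.reshape(N, 1, D) + (-1.0) * E3) * (1.0 / (M - 1))
    loonorm = ((loo * loo).sum(axis=2, keepdims=True) + 1e-24).sqrt()
    loo_hat = loo / loonorm
    cos_loo = (E3 * loo_hat).sum(axis=2)                    # (N, M)
    mask = np.zeros((N, M, N))
    mask[np.arange(N), :, np.arange(N)] = 1.0
    cos_combined = cos_all * Tensor(1.0 - mask) + cos_loo.reshape(N, M, 1) * Tensor(mask)
    S = cos_combined * w + b
    m_const = Tensor(S.data.max(axis=2, keepdims=True))     # detached max
    lse = ((S - m_const).exp().sum(axis=2, keepdims=True)).log() + m_const
    diag = (S * Tensor(mask)).sum(axis=2, keepdims=True)
    return (lse - diag).mean()


# ---------------------------------------------------------------------------
# Optimizer and training loop


class Adam:
    def __init__(self, params: list[Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> float:
        """Apply one clipped Adam update; returns the pre-clip gradient norm."""
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        gnorm = float(np.sqrt(sum((g**2).sum() for g in grads)))
        clip = self.cfg.grad_clip_l2
        if clip is not None and gnorm > clip:
            grads = [g * (clip / gnorm) for g in grads]
        self.t += 1
        b1, b2, eps = self.cfg.adam_beta1, self.cfg.adam_beta2, self.cfg.adam_eps
        lr = self.cfg.learning_rate * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            p.data = p.data - lr * self.m[i] / (np.sqrt(self.v[i]) + eps)
        return gnorm

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainResult:
    encoder: Encoder
    params: SimilarityParams
    loss_trace: list[float]
    stopped_early: bool = False


def train(
    speaker_features: dict[str, list],
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    frontend_cfg: FrontendConfig = FrontendConfig(),
    val_features: dict[str, list] | None = None,
) -> TrainResult:
    """Train the encoder and similarity scale/offset from scratch.

    `speaker_features` maps speaker id to that speaker's partial-utterance
    FeatureMatrix list.  Deterministic given `train_cfg.seed`.
    """
    rng = np.random.default_rng(train_cfg.seed)
    encoder = Encoder(encoder_cfg, seed=int(rng.integers(2**31)))
    w = Tensor(float(train_cfg.init_w), requires_grad=True)
    b = Tensor(float(train_cfg.init_b), requires_grad=True)
    params = encoder.parameter_list() + [w, b]
    opt = Adam(params, train_cfg)
    trace: list[float] = []
    N, M = train_cfg.n_speakers, train_cfg.m_utterances

    val_batch = None
    if val_features is not None and train_cfg.patience is not None:
        vrng = np.random.default_rng(train_cfg.seed + 1)
        n_val = min(len(val_features), N)
        val_batch = make_training_batch(
            val_features, n_val, min(M, 2), vrng, frontend_cfg
        )
    best_val = np.inf
    stale = 0
    stopped_early = False

    for step in range(train_cfg.steps):
        batch = make_training_batch(speaker_features, N, M, rng, frontend_cfg)
        emb = encoder.encode_array(batch.features)
        loss = _similarity_loss_tape(emb, w, b, N, M)
        if not np.isfinite(loss.data):
            raise TrainingDiverged(f"loss became non-finite at step {step}")
        trace.append(float(loss.data))
        if train_cfg.learning_rate > 0:
            opt.zero_grad()
            loss.backward()
            opt.step()
            # The similarity must stay an increasing function of cosine.
            w.data = np.maximum(w.data, 1e-6)
        if val_batch is not None and (step + 1) % train_cfg.eval_every == 0:
            with no_grad():
                vemb = encoder.encode_array(val_batch.features)
                vloss = ge2e_loss(
                    similarity_matrix(
                        vemb.data.reshape(
                            val_batch.n_speakers, val_batch.m_utterances, -1
                        ),
                        SimilarityParams(max(float(w.data), 1e-6), float(b.data)),
                    )
                )
            if vloss < best_val - 1e-4:
                best_val = vloss
                stale = 0
            else:
                stale += 1
                if stale >= train_cfg.patience:
                    stopped_early = True
                    break
    return TrainResult(
        encoder=encoder,
        params=SimilarityParams(w=max(float(w.data), 1e-6), b=float(b.data)),
        loss_trace=trace,
        stopped_early=stopped_early,
    )
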