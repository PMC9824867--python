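"""Stage-attentive bidirectional LSTM classifier.

Architecture
------------
Each of the 11 stage sequences passes through its own stacked bidirectional
LSTM encoder; the concatenated forward/backward final hidden states form
one feature vector per stage ("one channel per stage").  A stage-attention
block scores each stage in (0, 1):

    score = sigmoid( MLP(AvgPool(F)) + MLP(MaxPool(F)) )

where AvgPool/MaxPool collapse each stage's feature vector to one pooled
descriptor, and the shared two-layer bottleneck MLP (11 -> 5 -> 11 at the
default 1/2 reduction, ReLU in between) mixes the 11 stage descriptors.
Each stage's feature is then scaled by its score, the 11 weighted features
are concatenated, and a ReLU hidden layer plus 3-way softmax produces the
class probabilities.  Training minimises inverse-frequency-weighted
cross-entropy with Adam.

The attention scores double as an interpretability signal: averaged or
ranked per subject they show which stages the classifier leans on.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field, replace
from io import BytesIO

import numpy as np

from . import nn
from .data import (
    LABELS,
    N_FEATURES,
    N_STAGES,
    STAGES,
    Label,
    PaddedStageBatch,
)

__all__ = [
    "ModelConfig",
    "AttentionProfile",
    "Prediction",
    "class_weights_from_counts",
    "weighted_cross_entropy",
    "StageAttentionClassifier",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; defaults are the full-scale training settings."""

    hidden_size: int = 128
    num_recurrent_layers: int = 4
    reduction_ratio: float = 0.5
    num_stages: int = N_STAGES
    input_features: int = N_FEATURES
    num_classes: int = 3
    head_hidden: int = 128
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 50
    #: global gradient-norm clip, a standard stabiliser for recurrent nets;
    #: None disables it.
    grad_clip: float | None = 5.0
    #: per-group learning-rate factors by parameter-name prefix ("lstm.",
    #: "attn.", "head."); lets short training budgets move the shallow head
    #: faster than the sensitive recurrent encoders.
    lr_multipliers: tuple[tuple[str, float], ...] = ()
    #: Adam second-moment decay; smaller values adapt faster and suit short
    #: training budgets.
    adam_beta2: float = 0.999
    #: decoupled weight decay by parameter-name prefix; counteracts the
    #: attention gate's tendency to saturate all scores upward.
    weight_decay: tuple[tuple[str, float], ...] = ()
    #: number of initial epochs during which the attention block is held
    #: fixed so the encoders and head commit first; the gates then score
    #: features whose task value is already established.
    attention_delay_epochs: int = 0
    use_attention: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if not 0.0 < self.reduction_ratio < 1.0:
            raise ValueError("reduction_ratio must be in (0, 1)")


@dataclass(frozen=True)
class AttentionProfile:
    """One subject's 11 stage-attention scores.

    ``raw_scores`` are the sigmoid outputs, each strictly in (0, 1);
    ``percent_scores`` rescale them to sum to 100 for reporting.
    """

    raw_scores: np.ndarray  # (11,)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_scores, dtype=float)
        if raw.shape != (N_STAGES,):
            raise ValueError(f"expected {N_STAGES} scores, got {raw.shape}")
        if not np.all((raw > 0.0) & (raw < 1.0)):
            raise ValueError("raw attention scores must lie strictly in (0, 1)")
        object.__setattr__(self, "raw_scores", raw)

    @property
    def percent_scores(self) -> np.ndarray:
        return 100.0 * self.raw_scores / self.raw_scores.sum()

    def top_stages(self, k: int = 3) -> list:
        """Stages of the k highest scores; ties broken earliest-stage-first."""
        order = np.argsort(-self.raw_scores, kind="stable")
        return [STAGES[i] for i in order[:k]]


@dataclass(frozen=True)
class Prediction:
    """Softmax class probabilities and the argmax label for one subject."""

    probabilities: np.ndarray  # (3,), sums to 1
    predicted_label: Label
    true_label: Label | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be a 3-simplex point")
        object.__setattr__(self, "probabilities", p)


def class_weights_from_counts(counts) -> np.ndarray:
    """Inverse-frequency loss weights: w_i = N / n_i (no renormalisation)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3,):
        raise ValueError("expected 3 class counts")
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    return counts.sum() / counts


def weighted_cross_entropy(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    class_weights: np.ndarray,
    eps: float = 1e-12,
) -> float:
    """Mean of -w_true * log(p_true) over a batch of predictions.

    ``probabilities`` is (N, 3) of softmax outputs, ``true_labels`` (N,)
    integer class indices.  With unit weights this is the ordinary
    cross-entropy.
    """
    probabilities = np.atleast_2d(np.asarray(probabilities, dtype=float))
    true_labels = np.atleast_1d(np.asarray(true_labels, dtype=np.int64))
    w = np.asarray(class_weights, dtype=float)[true_labels]
    p_true = probabilities[np.arange(len(true_labels)), true_labels]
    return float(np.mean(-w * np.log(np.clip(p_true, eps, None))))


def _stack_batch(batch: PaddedStageBatch) -> tuple[np.ndarray, np.ndarray]:
    """(S, N, T, 54) tensor with T = max reference length, plus (S,) lengths."""
    refs = [batch.arrays[s].shape[1] for s in STAGES]
    T = max(refs)
    n = batch.n_subjects
    X = np.zeros((N_STAGES, n, T, N_FEATURES))
    for k, s in enumerate(STAGES):
        X[k, :, : refs[k], :] = batch.arrays[s]
    return X, np.asarray(refs, dtype=np.int64)


class StageAttentionClassifier:
    """Trainable 3-class screener over padded 11-stage skeleton batches."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        self.params = nn.init_params(
            n_stages=c.num_stages,
            input_features=c.input_features,
            hidden_size=c.hidden_size,
            num_layers=c.num_recurrent_layers,
            reduction_ratio=c.reduction_ratio,
            head_hidden=c.head_hidden,
            num_classes=c.num_classes,
            rng=rng,
            use_attention=c.use_attention,
        )
        self._train_rng = np.random.default_rng(rng.integers(2**31))

    # -- low-level forward pieces ------------------------------------------

    def _forward(self, X, lengths):
        c = self.config
        return nn.network_forward(
            self.params, X, lengths, c.num_recurrent_layers, c.hidden_size,
            c.use_attention,
        )

    def encode_stage(
        self, padded_sequence: np.ndarray, true_length: int, stage: int
    ) -> np.ndarray:
        """Encode one stage sequence (ref_len, 54) of one subject.

        Returns the concatenated [forward final hidden || backward final
        hidden] vector of length 2*hidden_size.  The zero-padded tail is fed
        through the recurrence unmasked; ``true_length`` is accepted for
        interface completeness but does not alter the encoding.
        """
        del true_length
        seq = np.asarray(padded_sequence, dtype=float)
        if not np.all(np.isfinite(seq)):
            raise ValueError("non-finite values in input sequence")
        batch = self._encode_features_from_arrays(
            {STAGES[k]: seq[None] if k == stage else
             np.zeros((1, 1, N_FEATURES)) for k in range(N_STAGES)}
        )
        return batch[0, stage]

    def _encode_features_from_arrays(self, arrays) -> np.ndarray:
        refs = [arrays[s].shape[1] for s in STAGES]
        T = max(refs)
        n = arrays[STAGES[0]].shape[0]
        X = np.zeros((N_STAGES, n, T, N_FEATURES))
        for k, s in enumerate(STAGES):
            X[k, :, : refs[k], :] = arrays[s]
        _, _, F, _ = self._forward(X, np.asarray(refs, dtype=np.int64))
        return F

    def encode_features(self, batch: PaddedStageBatch) -> np.ndarray:
        """Pre-attention stage features for a batch, shape (N, 11, 2H)."""
        X, lengths = _stack_batch(batch)
        _, _, F, _ = self._forward(X, lengths)
        return F

    def stage_attention(self, features: np.ndarray) -> AttentionProfile:
        """Score the 11 stage features (11, 2H) of one subject."""
        scores = self.stage_attention_batch(features[None])
        return AttentionProfile(scores[0])

    def stage_attention_batch(self, features: np.ndarray) -> np.ndarray:
        """Sigmoid stage scores for (N, 11, 2H) features, shape (N, 11)."""
        F = np.asarray(features, dtype=float)
        if not np.all(np.isfinite(F)):
            raise ValueError("non-finite stage features")
        if not self.config.use_attention:
            return np.ones(F.shape[:2])
        p = self.params
        avg = F.mean(axis=2)
        mx = F.max(axis=2)
        ha = nn.relu(avg @ p["attn.W1"] + p["attn.b1"])
        hm = nn.relu(mx @ p["attn.W1"] + p["attn.b1"])
        pre = ha @ p["attn.W2"] + hm @ p["attn.W2"] + 2.0 * p["attn.b2"]
        # sigmoid is strictly inside (0, 1) in exact arithmetic but rounds
        # to 0.0/1.0 in floats once |pre| exceeds ~37; clamp to the open
        # interval so downstream invariants hold.
        return np.clip(nn.sigmoid(pre), 1e-15, 1.0 - 1e-15)

    @staticmethod
    def apply_attention(
        features: np.ndarray, profile: AttentionProfile | np.ndarray
    ) -> np.ndarray:
        """Scale stage k's feature by its raw score; concatenate all stages."""
        F = np.asarray(features, dtype=float)
        raw = (
            profile.raw_scores
            if isinstance(profile, AttentionProfile)
            else np.asarray(profile, dtype=float)
        )
        if F.shape[0] != raw.shape[0]:
            raise ValueError("feature/score stage dimensions disagree")
        return (F * raw[:, None]).reshape(-1)

    def classify(self, weighted_features: np.ndarray) -> Prediction:
        """ReLU hidden layer + 3-way softmax on the concatenated features."""
        v = np.asarray(weighted_features, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input to classification head")
        p = self.params
        r1 = nn.relu(v @ p["head.W1"] + p["head.b1"])
        probs = nn.softmax(r1 @ p["head.W2"] + p["head.b2"])
        return Prediction(probs, LABELS[int(np.argmax(probs))])

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, batch: PaddedStageBatch, class_weights=None):
        """Weighted-CE loss and analytic parameter gradients for a batch."""
        c = self.config
        X, lengths = _stack_batch(batch)
        y = batch.label_indices()
        if class_weights is None:
            class_weights = np.ones(c.num_classes)
        logits, _, _, cache = self._forward(X, lengths)
        loss, dlogits = nn.weighted_ce_and_grad(logits, y, class_weights)
        grads = nn.network_backward(
            self.params, cache, dlogits, c.num_recurrent_layers,
            c.hidden_size, c.use_attention,
        )
        return loss, grads

    def fit(
        self,
        batch: PaddedStageBatch,
        class_weights: np.ndarray | None = None,
        verbose: bool = False,
    ) -> list[float]:
        """Train with Adam on shuffled minibatches; returns per-epoch losses.

        Class weights default to inverse frequency computed from the batch's
        own label counts.
        """
        c = self.config
        y = batch.label_indices()
        if class_weights is None:
            counts = np.bincount(y, minlength=c.num_classes)
            if np.any(counts == 0):
                raise ValueError(
                    "a class is absent from the training batch; pass "
                    "class_weights explicitly"
                )
            class_weights = class_weights_from_counts(counts)
        X, lengths = _stack_batch(batch)
        n = batch.n_subjects
        opt = nn.Adam(
            self.params,
            lr=c.learning_rate,
            beta2=c.adam_beta2,
            lr_multipliers=dict(c.lr_multipliers) or None,
            weight_decay=dict(c.weight_decay) or None,
        )
        history: list[float] = []
        for epoch in range(c.epochs):
            order = self._train_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                logits, _, _, cache = self._forward(X[:, idx], lengths)
                loss, dlogits = nn.weighted_ce_and_grad(
                    logits, y[idx], class_weights
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                grads = nn.network_backward(
                    self.params, cache, dlogits, c.num_recurrent_layers,
                    c.hidden_size, c.use_attention,
                )
                if c.use_attention and epoch < c.attention_delay_epochs:
                    for k in list(grads):
                        if k.startswith("attn."):
                            del grads[k]
                if c.grad_clip is not None:
                    norm = np.sqrt(
                        sum(float(np.sum(g * g)) for g in grads.values())
                    )
                    if norm > c.grad_clip:
                        scale = c.grad_clip / norm
                        grads = {k: g * scale for k, g in grads.items()}
                opt.step(self.params, grads)
                epoch_loss += loss * len(idx)
            history.append(epoch_loss / n)
            if verbose:
                print(f"epoch {epoch + 1}/{c.epochs}  loss {history[-1]:.4f}")
        return history

    # -- inference ---------------------------------------------------------

    def predict_proba(self, batch: PaddedStageBatch) -> np.ndarray:
        X, lengths = _stack_batch(batch)
        logits, _, _, _ = self._forward(X, lengths)
        return nn.softmax(logits)

    def predict(self, batch: PaddedStageBatch) -> list[Prediction]:
        probs = self.predict_proba(batch)
        return [
            Prediction(
                p, LABELS[int(np.argmax(p))], true_label=batch.labels[i]
            )
            for i, p in enumerate(probs)
        ]

    def attention_profiles(self, batch: PaddedStageBatch) -> list[AttentionProfile]:
        """Per-subject stage-attention profiles (requires attention enabled)."""
        if not self.config.use_attention:
            raise RuntimeError("attention is disabled in this model")
        X, lengths = _stack_batch(batch)
        _, scores, _, _ = self._forward(X, lengths)
        scores = np.clip(scores, 1e-15, 1.0 - 1e-15)
        return [AttentionProfile(s) for s in scores]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: a zip archive of config JSON + named parameter arrays."""
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(asdict(self.config)))
            buf = BytesIO()
            np.savez(buf, **self.params)
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "StageAttentionClassifier":
        with zipfile.ZipFile(path) as zf:
            raw = json.loads(zf.read("config.json"))
            for key in ("lr_multipliers", "weight_decay"):
                raw[key] = tuple((k, v) for k, v in raw.get(key, ()))
            config = ModelConfig(**raw)
            with zf.open("params.npz") as fh:
                arrays = np.load(BytesIO(fh.read()))
                params = {k: arrays[k] for k in arrays.files}
        model = cls(config)
        model.params = params
        return model
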