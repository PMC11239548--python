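"""Self-attention GRU feature extractor with a closed-form ELM classifier head.

The feature extractor stacks one or more (GRU layer, self-attention) blocks.
GRU and attention weights are drawn once from a seeded uniform(-0.5, 0.5) and
left fixed (reservoir style); the learnable capacity sits entirely in the
extreme-learning-machine (ELM) head, whose output weights have a closed-form
ridge solution.  A hyperparameter optimizer can therefore score a candidate
architecture with a single linear solve instead of gradient training.

Shapes follow the convention: input sequences are (T, d_in) per record or
(n, T, d_in) batched; GRU hidden states (T, d_h); attention contexts (T, d_k).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# GRU
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GRUWeights:
    """Gate parameters of one GRU layer.

    ``input_*`` are (d_in, d_h) maps of the current input, ``recur_*`` are
    (d_h, d_h) maps of the previous hidden state, ``bias_*`` are (d_h,).
    The three gate roles are update (z), reset (r) and candidate (h~).
    """

    input_update: np.ndarray
    input_reset: np.ndarray
    input_candidate: np.ndarray
    recur_update: np.ndarray
    recur_reset: np.ndarray
    recur_candidate: np.ndarray
    bias_update: np.ndarray
    bias_reset: np.ndarray
    bias_candidate: np.ndarray

    def __post_init__(self):
        d_in, d_h = self.input_update.shape
        for name in ("input_reset", "input_candidate"):
            if getattr(self, name).shape != (d_in, d_h):
                raise ValueError(f"{name} must have shape {(d_in, d_h)}")
        for name in ("recur_update", "recur_reset", "recur_candidate"):
            if getattr(self, name).shape != (d_h, d_h):
                raise ValueError(f"{name} must have shape {(d_h, d_h)}")
        for name in ("bias_update", "bias_reset", "bias_candidate"):
            if getattr(self, name).shape != (d_h,):
                raise ValueError(f"{name} must have shape {(d_h,)}")

    @property
    def input_dim(self) -> int:
        return self.input_update.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.input_update.shape[1]


def init_gru_weights(
    d_in: int, d_h: int, rng: np.random.Generator, scale: float = 0.5
) -> GRUWeights:
    """Seeded uniform(-scale, scale) initialization of all nine arrays."""
    u = lambda *shape: rng.uniform(-scale, scale, size=shape)
    return GRUWeights(
        input_update=u(d_in, d_h), input_reset=u(d_in, d_h), input_candidate=u(d_in, d_h),
        recur_update=u(d_h, d_h), recur_reset=u(d_h, d_h), recur_candidate=u(d_h, d_h),
        bias_update=u(d_h), bias_reset=u(d_h), bias_candidate=u(d_h),
    )


def gru_cell_step(x: np.ndarray, h_prev: np.ndarray, weights: GRUWeights) -> np.ndarray:
    """One GRU step: gated convex blend of the previous state and a candidate.

    z = sigmoid(x W_z + h U_z + b_z), r = sigmoid(x W_r + h U_r + b_r),
    h~ = tanh(x W_h + U_h (r * h) + b_h), output = (1-z)*h + z*h~.

    Works on single vectors and on batched (n, d) rows alike.
    """
    w = weights
    z = _sigmoid(x @ w.input_update + h_prev @ w.recur_update + w.bias_update)
    r = _sigmoid(x @ w.input_reset + h_prev @ w.recur_reset + w.bias_reset)
    h_cand = np.tanh(x @ w.input_candidate + (r * h_prev) @ w.recur_candidate + w.bias_candidate)
    return (1.0 - z) * h_prev + z * h_cand


def gru_layer(
    seq: np.ndarray, weights: GRUWeights, h0: Optional[np.ndarray] = None
) -> np.ndarray:
    """Left-to-right recurrence over a (T, d_in) sequence; returns (T, d_h)."""
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be a non-empty (T, d_in) matrix")
    h = np.zeros(weights.hidden_dim) if h0 is None else np.asarray(h0, dtype=float)
    out = np.empty((seq.shape[0], weights.hidden_dim))
    for t in range(seq.shape[0]):
        h = gru_cell_step(seq[t], h, weights)
        out[t] = h
    return out


def _gru_layer_batch(batch: np.ndarray, weights: GRUWeights) -> np.ndarray:
    """Recurrence over an (n, T, d_in) batch; returns (n, T, d_h)."""
    n, T, _ = batch.shape
    h = np.zeros((n, weights.hidden_dim))
    out = np.empty((n, T, weights.hidden_dim))
    for t in range(T):
        h = gru_cell_step(batch[:, t, :], h, weights)
        out[:, t, :] = h
    return out


# ---------------------------------------------------------------------------
# Self-attention
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttentionParams:
    """Query/key/value projections (d_h, d_k) for scaled dot-product attention."""

    query_proj: np.ndarray
    key_proj: np.ndarray
    value_proj: np.ndarray

    def __post_init__(self):
        if not (self.query_proj.shape == self.key_proj.shape == self.value_proj.shape):
            raise ValueError("query/key/value projections must share one (d_h, d_k) shape")
        if self.key_dim < 1:
            raise ValueError("key dimension must be >= 1")

    @property
    def key_dim(self) -> int:
        return self.query_proj.shape[1]


def init_attention(d_h: int, d_k: int, rng: np.random.Generator, scale: float = 0.5) -> AttentionParams:
    u = lambda: rng.uniform(-scale, scale, size=(d_h, d_k))
    return AttentionParams(query_proj=u(), key_proj=u(), value_proj=u())


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def self_attention(hidden_states: np.ndarray, params: AttentionParams) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V over a (T, d_h) state sequence -> (T, d_k)."""
    H = np.asarray(hidden_states, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("hidden_states must be a non-empty (T, d_h) matrix")
    q, k, v = H @ params.query_proj, H @ params.key_proj, H @ params.value_proj
    if not np.all(np.isfinite(q)) or not np.all(np.isfinite(k)):
        raise FloatingPointError("non-finite attention projections")
    weights = _softmax_rows(q @ k.T / np.sqrt(params.key_dim))
    return weights @ v


def _self_attention_batch(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Batched attention over (n, T, d_h) -> (n, T, d_k)."""
    q = H @ params.query_proj
    k = H @ params.key_proj
    v = H @ params.value_proj
    scores = np.einsum("ntk,nsk->nts", q, k) / np.sqrt(params.key_dim)
    return _softmax_rows(scores) @ v


# ---------------------------------------------------------------------------
# Stacked attention-GRU feature extractor
# ---------------------------------------------------------------------------

Layer = tuple[GRUWeights, AttentionParams]


def init_layers(
    d_in: int, d_h: int, d_k: int, n_layers: int, rng: np.random.Generator
) -> list[Layer]:
    """Stack of (GRU, attention) blocks; layer i>0 consumes the previous context."""
    if n_layers < 1:
        raise ValueError("need at least one layer")
    layers = []
    in_dim = d_in
    for _ in range(n_layers):
        layers.append((init_gru_weights(in_dim, d_h, rng), init_attention(d_h, d_k, rng)))
        in_dim = d_k
    return layers


def forward_features(batch: np.ndarray, layers: Sequence[Layer]) -> np.ndarray:
    """Batched forward path: (n, T, d_in) -> pooled (n, d_k) feature matrix.

    Each block runs its GRU over the incoming sequence and attends over the
    hidden states; block outputs are summed across the stack and mean-pooled
    over time to a fixed-size feature vector per record.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 3:
        raise ValueError("batch must be (n, T, d_in)")
    current = batch
    total = None
    for gru_w, attn in layers:
        hidden = _gru_layer_batch(current, gru_w)
        context = _self_attention_batch(hidden, attn)
        total = context if total is None else total + context
        current = context
    return total.mean(axis=1)


def stack_attention_gru(seq: np.ndarray, layers: Sequence[Layer]) -> np.ndarray:
    """Single-record forward path: (T, d_in) -> (d_k,) pooled feature vector."""
    return forward_features(np.asarray(seq, dtype=float)[None, :, :], layers)[0]


# ---------------------------------------------------------------------------
# ELM head
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ELMHead:
    """Single-hidden-layer ELM: fixed random projection + ridge output weights.

    ``hidden_proj`` is (d_feat, width), fixed at creation; ``output_weights``
    (width, n_classes) is None until :func:`elm_fit`.  The tanh activation is
    odd and bounded, so a zero pre-activation maps to zero scores.
    """

    hidden_proj: np.ndarray
    hidden_bias: np.ndarray
    regularization: float
    output_weights: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")

    @property
    def width(self) -> int:
        return self.hidden_proj.shape[1]


def create_elm_head(
    d_feat: int, width: int, regularization: float, rng: np.random.Generator
) -> ELMHead:
    return ELMHead(
        hidden_proj=rng.uniform(-1.0, 1.0, size=(d_feat, width)),
        hidden_bias=rng.uniform(-1.0, 1.0, size=width),
        regularization=float(regularization),
    )


def _hidden_activations(features: np.ndarray, head: ELMHead) -> np.ndarray:
    return np.tanh(features @ head.hidden_proj + head.hidden_bias)


def solve_output_weights(H: np.ndarray, targets: np.ndarray, C: float) -> np.ndarray:
    """Ridge solution for the ELM output weights.

    Uses the dual form beta = H^T (I/C + H H^T)^-1 Y when n <= width and the
    algebraically identical primal form beta = (H^T H + I/C)^-1 H^T Y
    otherwise; both satisfy (H^T H + I/C) beta = H^T Y.
    """
    n, width = H.shape
    try:
        if n <= width:
            beta = H.T @ np.linalg.solve(np.eye(n) / C + H @ H.T, targets)
        else:
            beta = np.linalg.solve(H.T @ H + np.eye(width) / C, H.T @ targets)
    except np.linalg.LinAlgError as exc:  # cannot occur for finite C; guard anyway
        raise np.linalg.LinAlgError(f"singular ELM system (C={C}): {exc}") from exc
    return beta


def elm_fit(features: np.ndarray, targets: np.ndarray, head: ELMHead) -> ELMHead:
    """Fit the output weights on (n, d_feat) features and (n, k) one-hot targets."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if features.shape[0] != targets.shape[0]:
        raise ValueError("features and targets must have the same number of rows")
    H = _hidden_activations(features, head)
    beta = solve_output_weights(H, targets, head.regularization)
    return replace(head, output_weights=beta)


def elm_predict(features: np.ndarray, head: ELMHead) -> np.ndarray:
    """Score matrix (n, k) for fitted heads."""
    if head.output_weights is None:
        raise ValueError("head is not fitted")
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return _hidden_activations(features, head) @ head.output_weights


# ---------------------------------------------------------------------------
# Class decision
# ---------------------------------------------------------------------------

BINARY_CLASSES = ("normal", "disease")


def decide_class(score_row: np.ndarray, mode: str = "binary") -> str:
    """Map classifier scores to a label.

    binary: argmax over (normal, disease) scores.  ternary: thresholds on a
    scalar output g — g <= 1 normal, 1 < g <= 2 disease1, 2 < g <= 3
    disease2, g > 3 flagged "uncertain" for re-evaluation.
    """
    scores = np.atleast_1d(np.asarray(score_row, dtype=float))
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite classifier scores")
    if mode == "binary":
        if scores.shape[0] != 2:
            raise ValueError("binary mode expects two scores")
        return BINARY_CLASSES[int(np.argmax(scores))]
    if mode == "ternary":
        g = float(scores[0]) if scores.shape[0] == 1 else float(scores.sum())
        if g <= 1.0:
            return "normal"
        if g <= 2.0:
            return "disease1"
        if g <= 3.0:
            return "disease2"
        return "uncertain"
    raise ValueError(f"unknown mode {mode!r}")
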