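"""The neural core: BiLSTM encoding, bilinear KB attention, classifiers, CRF.

The architecture encodes a token window with a bidirectional LSTM and, at
every time step t, lets the hidden state h_t attend over the vectors v_i of
knowledge-base neighbours of the entity pair.  Attention is bilinear,

    alpha_i  propto  exp(v_i^T U_v h_t),

the KB summary is s_t = sum_i alpha_i v_i, and the fused state is
h'_t = h_t + s_t.  Because the BiLSTM state (two directions of size
``lstm_state``) is wider than the embedding space the v_i live in, the
summary is carried through a learned linear bridge P before the addition;
with no KB neighbours s_t = 0 and the fused state equals h_t exactly, so the
KB pathway degrades to the plain encoder.  Fused states are pooled into a
sentence vector by attentive pooling with a learned context vector, and a
softmax layer predicts the label.

Entity extraction uses the same encoder to emit per-token B/I/O/E position
scores — decoded greedily or by a linear-chain CRF (Viterbi) — followed by a
second stage that classifies each decoded span's type (gene vs protein) from
its fused entity representation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .corpus import TAGS, EntityMention, Sentence, Token
from .representation import KBVectorSet

INPUT_MODES = ("whole_sentence", "between_entities")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``lstm_state`` is the state size per direction, so hidden states have
    2 * lstm_state components.  Defaults follow the reference setting:
    200-dimensional embeddings, state size 200, dropout 0.3.
    """

    embed_dim: int = 200
    lstm_state: int = 200
    dropout: float = 0.3
    num_entity_tags: int = 4
    num_entity_types: int = 2
    num_relation_labels: int = 9  # 8 relation types + NONE
    input_mode: str = "between_entities"
    window_expand: int = 2
    use_kb: bool = True
    use_crf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        for name in ("embed_dim", "lstm_state", "num_entity_tags",
                     "num_entity_types", "num_relation_labels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_expand < 0:
            raise ValueError("window_expand must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def hidden_dim(self) -> int:
        return 2 * self.lstm_state


@dataclass
class AttentionState:
    """Result of one KB-attention step: weights, summary, fused state."""

    alpha: np.ndarray
    s: np.ndarray
    h_prime: np.ndarray


@dataclass
class LabelDistribution:
    """A softmax distribution over a label set, with deterministic argmax."""

    probs: np.ndarray
    labels: Optional[Sequence[str]] = None

    @property
    def argmax(self) -> int:
        # np.argmax returns the lowest index on ties
        return int(np.argmax(self.probs))

    @property
    def label(self) -> str:
        if self.labels is None:
            raise ValueError("no label names attached")
        return self.labels[self.argmax]


# ---------------------------------------------------------------------------
# Functional operations (numpy; the reference semantics of the layers)
# ---------------------------------------------------------------------------

def build_relation_input(
    sentence: Sentence,
    pair: tuple[EntityMention, EntityMention],
    mode: str = "between_entities",
    window_expand: int = 2,
) -> list[Token]:
    """Token window for a candidate pair.

    ``whole_sentence`` returns every token.  ``between_entities`` returns
    the tokens from the first entity through the second, expanded by
    ``window_expand`` words on each side (clamped to the sentence), so very
    close pairs still carry surrounding context.
    """
    if mode not in INPUT_MODES:
        raise ValueError(f"unknown input mode {mode!r}")
    if mode == "whole_sentence":
        return list(sentence.tokens)
    ranges = []
    for ent in pair:
        if not sentence.contains_span(ent.char_start, ent.char_end):
            raise ValueError(f"entity {ent.id} not inside the sentence")
        idx = [
            i
            for i, t in enumerate(sentence.tokens)
            if t.char_start < ent.char_end and ent.char_start < t.char_end
        ]
        if not idx:
            raise ValueError(f"entity {ent.id} covers no tokens")
        ranges.append((idx[0], idx[-1]))
    first = min(r[0] for r in ranges)
    last = max(r[1] for r in ranges)
    lo = max(0, first - window_expand)
    hi = min(len(sentence.tokens) - 1, last + window_expand)
    return list(sentence.tokens[lo : hi + 1])


def entity_token_indices(
    sentence: Sentence, entity: EntityMention, window: Sequence[Token]
) -> list[int]:
    """Indices (within ``window``) of the tokens covered by the entity."""
    return [
        i
        for i, t in enumerate(window)
        if t.char_start < entity.char_end and entity.char_start < t.char_end
    ]


def kb_attention(
    h: np.ndarray,
    V: KBVectorSet | np.ndarray,
    U_v: np.ndarray,
    P: np.ndarray | None = None,
) -> AttentionState:
    """Bilinear attention of a hidden state over KB vectors.

    alpha_i = exp(v_i^T U_v h) / sum_j exp(v_j^T U_v h) (max-subtracted for
    stability); s = sum_i alpha_i v_i.  The fused state is h + s when the
    dimensions agree, else h + P s with the learned bridge ``P``.  With an
    empty V, s = 0 and the fused state equals h exactly.
    """
    h = np.asarray(h, dtype=float)
    vecs = V.vectors if isinstance(V, KBVectorSet) else np.asarray(V, dtype=float)
    if vecs.ndim != 2:
        raise ValueError("V must be a (M, dim) array or KBVectorSet")
    dv = vecs.shape[1] if vecs.size else (U_v.shape[0] if U_v is not None else h.shape[0])
    if len(vecs) == 0:
        return AttentionState(np.zeros(0), np.zeros(dv), h.copy())
    U_v = np.asarray(U_v, dtype=float)
    if U_v.shape != (vecs.shape[1], h.shape[0]):
        raise ValueError(
            f"U_v shape {U_v.shape} incompatible with v dim {vecs.shape[1]} "
            f"and h dim {h.shape[0]}"
        )
    logits = vecs @ (U_v @ h)
    logits = logits - logits.max()
    w = np.exp(logits)
    alpha = w / w.sum()
    s = alpha @ vecs
    if vecs.shape[1] == h.shape[0]:
        bridged = s if P is None else P @ s
    else:
        if P is None:
            raise ValueError(
                "dim(v) != dim(h); a bridge matrix P is required"
            )
        bridged = P @ s
    return AttentionState(alpha, s, h + bridged)


def attentive_pool(
    states: np.ndarray, context: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge per-step states into one vector by learned-context attention.

    scores_t = context . tanh(h'_t); weights = softmax(scores); returns
    (merged vector, weights).
    """
    states = np.asarray(states, dtype=float)
    scores = np.tanh(states) @ context
    scores = scores - scores.max()
    w = np.exp(scores)
    beta = w / w.sum()
    return beta @ states, beta


def classify(
    h: np.ndarray,
    W: np.ndarray,
    b: np.ndarray | None = None,
    labels: Optional[Sequence[str]] = None,
) -> LabelDistribution:
    """Softmax classification p = softmax(W h (+ b))."""
    h = np.asarray(h, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape[1] != h.shape[0]:
        raise ValueError(f"W shape {W.shape} incompatible with h dim {h.shape[0]}")
    logits = W @ h
    if b is not None:
        logits = logits + b
    logits = logits - logits.max()
    e = np.exp(logits)
    return LabelDistribution(e / e.sum(), labels)


def crf_decode(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray | None = None,
    stop: np.ndarray | None = None,
) -> list[str]:
    """Viterbi decode (T, K) emission scores into BIOE tag names."""
    emissions = np.asarray(emissions, dtype=float)
    K = emissions.shape[1]
    if start is None:
        start = np.zeros(K)
    if stop is None:
        stop = np.zeros(K)
    path = nn.viterbi_decode(emissions, np.asarray(transitions, float), start, stop)
    return [TAGS[i] for i in path]


# ---------------------------------------------------------------------------
# Trainable networks (autodiff)
# ---------------------------------------------------------------------------

class RelationNetwork:
    """BiLSTM + per-step bilinear KB attention + attentive pooling + softmax.

    Token embeddings are fixed inputs; two learned argument-role vectors are
    added to the embeddings of the arg1/arg2 tokens so the directed pair
    (a, b) is distinguishable from (b, a).
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        self.config = config
        D, H2 = config.embed_dim, config.hidden_dim
        C = config.num_relation_labels
        p: dict[str, Tensor] = {}
        p.update(nn.bilstm_parameters(rng, D, config.lstm_state))
        p["att.Uv"] = nn.parameter(rng, (D, H2))
        p["att.P"] = nn.parameter(rng, (H2, D))
        p["pool.u"] = nn.parameter(rng, (H2,))
        p["out.W"] = nn.parameter(rng, (H2, C))
        p["out.b"] = nn.zeros_parameter((C,))
        p["arg1"] = nn.zeros_parameter((D,))
        p["arg2"] = nn.zeros_parameter((D,))
        self.params = p

    def forward(
        self,
        X: np.ndarray,
        arg_masks: np.ndarray,
        memory: np.ndarray,
        memory_mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Logits (B, C) for a batch of equal-length token windows.

        X: (B, T, D) embedded tokens; arg_masks: (B, T, 2) 0/1 indicators of
        arg1/arg2 tokens; memory: (B, M, D) padded KB vectors with 0/1 mask
        (B, M).  ``M`` may be zero (no KB pathway at all).
        """
        cfg = self.config
        B, T, _ = X.shape
        use_memory = cfg.use_kb and memory.shape[1] > 0
        has_any = memory_mask.any(axis=1, keepdims=True).astype(float)
        neg = (1.0 - memory_mask) * -1e9

        xs = []
        for t in range(T):
            x = Tensor(X[:, t])
            x = x + Tensor(arg_masks[:, t, 0:1]) * self.params["arg1"]
            x = x + Tensor(arg_masks[:, t, 1:2]) * self.params["arg2"]
            xs.append(nn.dropout(x, cfg.dropout, rng, train))
        hs = nn.bilstm_run(self.params, xs)

        fused = []
        if use_memory:
            for h in hs:
                q = h @ _transpose(self.params["att.Uv"])  # (B, Dv)
                scores = ad.memory_scores(memory, q) + Tensor(neg)
                alpha = ad.softmax(scores, axis=1)
                s = ad.memory_combine(alpha, memory) * Tensor(has_any)
                fused.append(h + s @ _transpose(self.params["att.P"]))
        else:
            fused = hs

        scores = ad.concat(
            [(ad.tanh(h) @ self.params["pool.u"]).reshape(B, 1) for h in fused],
            axis=1,
        )
        beta = ad.softmax(scores, axis=1)
        merged = None
        for t, h in enumerate(fused):
            term = h * beta[:, t : t + 1]
            merged = term if merged is None else merged + term
        return merged @ self.params["out.W"] + self.params["out.b"]


class TaggerNetwork:
    """Two-stage entity extractor.

    Stage 1: BiLSTM (with optional per-token KB attention) emits B/I/O/E
    position scores per token, trained with per-token cross-entropy or a
    linear-chain CRF and decoded greedily or by Viterbi.  Stage 2: a softmax
    over the entity types from the fused entity representation.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        self.config = config
        D, H2 = config.embed_dim, config.hidden_dim
        p: dict[str, Tensor] = {}
        p.update(nn.bilstm_parameters(rng, D, config.lstm_state))
        p["att.Uv"] = nn.parameter(rng, (D, H2))
        p["att.P"] = nn.parameter(rng, (H2, D))
        p["tag.W"] = nn.parameter(rng, (H2, config.num_entity_tags))
        p["tag.b"] = nn.zeros_parameter((config.num_entity_tags,))
        p.update(nn.crf_parameters(config.num_entity_tags))
        p["type.U"] = nn.parameter(rng, (D, D))
        p["type.P"] = nn.parameter(rng, (D, D))
        p["type.W"] = nn.parameter(rng, (D, config.num_entity_types))
        p["type.b"] = nn.zeros_parameter((config.num_entity_types,))
        self.params = p

    def emissions(
        self,
        X: np.ndarray,
        memory: np.ndarray,
        memory_mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Per-token tag scores (B, T, K) for equal-length sentences."""
        cfg = self.config
        B, T, _ = X.shape
        use_memory = cfg.use_kb and memory.shape[1] > 0
        has_any = memory_mask.any(axis=1, keepdims=True).astype(float)
        neg = (1.0 - memory_mask) * -1e9

        xs = [
            nn.dropout(Tensor(X[:, t]), cfg.dropout, rng, train)
            for t in range(T)
        ]
        hs = nn.bilstm_run(self.params, xs)
        out = []
        for h in hs:
            if use_memory:
                q = h @ _transpose(self.params["att.Uv"])
                scores = ad.memory_scores(memory, q) + Tensor(neg)
                alpha = ad.softmax(scores, axis=1)
                s = ad.memory_combine(alpha, memory) * Tensor(has_any)
                h = h + s @ _transpose(self.params["att.P"])
            out.append(h @ self.params["tag.W"] + self.params["tag.b"])
        return ad.stack(out, axis=1)

    def type_logits(
        self,
        reps: np.ndarray,
        memory: np.ndarray,
        memory_mask: np.ndarray,
    ) -> Tensor:
        """Stage-2 logits over entity types from (B, D) entity vectors."""
        e = Tensor(np.asarray(reps, dtype=float))
        if self.config.use_kb and memory.shape[1] > 0:
            has_any = memory_mask.any(axis=1, keepdims=True).astype(float)
            neg = (1.0 - memory_mask) * -1e9
            q = e @ _transpose(self.params["type.U"])
            scores = ad.memory_scores(memory, q) + Tensor(neg)
            alpha = ad.softmax(scores, axis=1)
            s = ad.memory_combine(alpha, memory) * Tensor(has_any)
            e = e + s @ _transpose(self.params["type.P"])
        return e @ self.params["type.W"] + self.params["type.b"]

    def decode(self, emissions: np.ndarray) -> list[str]:
        """Decode one sentence's (T, K) emission scores into tags."""
        if self.config.use_crf:
            return crf_decode(
                emissions,
                self.params["crf.trans"].data,
                self.params["crf.start"].data,
                self.params["crf.stop"].data,
            )
        return [TAGS[int(i)] for i in np.argmax(emissions, axis=1)]


def _transpose(t: Tensor) -> Tensor:
    """Transpose of a 2-D tensor, gradient-correct."""
    def backward(g):
        t._accumulate(g.T)
    return ad._op(t.data.T, (t,), backward)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    config: ModelConfig,
    params: dict[str, Tensor],
    extra: Optional[dict] = None,
) -> None:
    """Single-file archive: JSON config + named parameter arrays."""
    arrays = {f"param/{k}": v.data for k, v in params.items()}
    meta = {"config": asdict(config), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelConfig, dict[str, np.ndarray], dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {
            k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")
        }
    return ModelConfig(**meta["config"]), params, meta.get("extra", {})
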