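"""Fitting and evaluating the extractors (Model / Results objects).

:class:`RelationExtractionModel` and :class:`EntityTaggerModel` are built
from annotated documents, a knowledge store and an embedding table; their
``fit`` methods run the AdaDelta training loop and return a Results object
carrying the fitted parameters, the per-epoch log, evaluation metrics and a
``summary()`` table, in the spirit of statsmodels.

Training settings default to the reference recipe: AdaDelta with learning
rate 1.0 (admissible values 0.8 / 0.9 / 1.0), per-minibatch L2 strength
1e-5, minibatch size 10 (20 for large corpora), dropout 0.3 in the BiLSTM
layer.  Candidate pairs with no annotated relation are trained as NONE
instances; evaluation is micro-averaged precision/recall/F1 with the NONE
class excluded, and a predicted relation counts as correct only on an exact
(type, arg1, arg2) match — direction matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import autodiff as ad
from . import nn
from .corpus import (
    ENTITY_TYPES,
    NONE_LABEL,
    RELATION_TYPES,
    TAGS,
    Document,
    EntityMention,
    RelationInstance,
    Sentence,
    bioe_to_spans,
    candidate_pairs,
    spans_to_bioe,
)
from .kb import KBStore
from .model import (
    ModelConfig,
    RelationNetwork,
    TaggerNetwork,
    build_relation_input,
    entity_token_indices,
)
from .representation import EmbeddingTable, entity_representation, kb_vectors

logger = logging.getLogger(__name__)

ALLOWED_LR = (0.8, 0.9, 1.0)


@dataclass
class TrainConfig:
    """Optimization settings (AdaDelta throughout)."""

    optimizer: str = "adadelta"
    lr: float = 1.0
    rho: float = 0.95
    eps: float = 1e-6
    l2: float = 1e-5
    batch_size: int = 10
    batch_size_large: int = 20
    large_corpus_threshold: int = 2000  # instances
    max_epochs: int = 30
    patience: int = 10
    max_negative_ratio: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adadelta":
            raise ValueError("only the adadelta optimizer is supported")
        if not any(abs(self.lr - v) < 1e-12 for v in ALLOWED_LR):
            raise ValueError(f"lr must be one of {ALLOWED_LR}")
        if self.batch_size <= 0 or self.batch_size_large <= 0:
            raise ValueError("batch sizes must be positive")
        if self.max_epochs <= 0 or self.patience <= 0:
            raise ValueError("max_epochs and patience must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")

    def effective_batch_size(self, n_instances: int) -> int:
        if n_instances >= self.large_corpus_threshold:
            return self.batch_size_large
        return self.batch_size


def emit_config(model: ModelConfig, train: TrainConfig) -> str:
    """The run configuration as YAML (model + train sections)."""
    return yaml.safe_dump(
        {"model": asdict(model), "train": asdict(train)}, sort_keys=False
    )


def load_config(path_or_text: str) -> tuple[ModelConfig, TrainConfig]:
    import os

    text = (
        open(path_or_text).read()
        if os.path.exists(str(path_or_text))
        else str(path_or_text)
    )
    data = yaml.safe_load(text) or {}
    return (
        ModelConfig(**data.get("model", {})),
        TrainConfig(**data.get("train", {})),
    )


# ---------------------------------------------------------------------------
# Precision / recall / F1
# ---------------------------------------------------------------------------

@dataclass
class LabelCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class PRFReport:
    """Per-label and micro-averaged precision/recall/F1 (NONE excluded)."""

    per_label: dict[str, LabelCounts] = field(default_factory=dict)

    @property
    def micro(self) -> LabelCounts:
        return LabelCounts(
            sum(c.tp for c in self.per_label.values()),
            sum(c.fp for c in self.per_label.values()),
            sum(c.fn for c in self.per_label.values()),
        )

    @property
    def precision(self) -> float:
        return self.micro.precision

    @property
    def recall(self) -> float:
        return self.micro.recall

    @property
    def f1(self) -> float:
        return self.micro.f1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": label,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "precision": c.precision,
                "recall": c.recall,
                "f1": c.f1,
            }
            for label, c in sorted(self.per_label.items())
        ]
        m = self.micro
        rows.append(
            {
                "label": "micro",
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
            }
        )
        return pd.DataFrame(rows)


def evaluate_prf_keys(
    predicted: Iterable[tuple], gold: Iterable[tuple]
) -> PRFReport:
    """P/R/F1 over exact-match keys whose first element is the label.

    Keys are compared as sets; a predicted key counts as a true positive iff
    it appears verbatim in the gold set.  NONE-labelled keys are abstentions
    and are dropped from both sides.
    """
    pset = {k for k in predicted if k[0] != NONE_LABEL}
    gset = {k for k in gold if k[0] != NONE_LABEL}
    report = PRFReport()
    for key in pset | gset:
        counts = report.per_label.setdefault(key[0], LabelCounts())
        if key in pset and key in gset:
            counts.tp += 1
        elif key in pset:
            counts.fp += 1
        else:
            counts.fn += 1
    return report


def evaluate_prf(
    predicted: Sequence[RelationInstance], gold: Sequence[RelationInstance]
) -> PRFReport:
    """Relation P/R/F1 by exact directed (type, arg1, arg2) match."""
    return evaluate_prf_keys(
        [r.key for r in predicted], [r.key for r in gold]
    )


# ---------------------------------------------------------------------------
# Relation extraction
# ---------------------------------------------------------------------------

def relation_labels(config: ModelConfig) -> list[str]:
    """The fixed label order: the first k relation types, then NONE."""
    k = config.num_relation_labels - 1
    if k > len(RELATION_TYPES):
        raise ValueError("num_relation_labels exceeds the closed label set")
    return list(RELATION_TYPES[:k]) + [NONE_LABEL]


@dataclass
class _RelationInstanceData:
    doc_id: str
    arg1: str
    arg2: str
    label: int
    X: np.ndarray  # (T, D) embedded window
    arg_masks: np.ndarray  # (T, 2)
    memory: np.ndarray  # (M, D) KB vectors for the pair (may be empty)


class RelationExtractionModel:
    """Directed relation classification over same-sentence entity pairs.

    Each ordered candidate pair in a sentence becomes one instance; pairs
    with no annotated relation are NONE instances.  The knowledge vectors of
    an instance are the union of the reaction-neighbours of both arguments.
    """

    def __init__(
        self,
        documents: Sequence[Document],
        kb_store: KBStore,
        embeddings: EmbeddingTable,
        config: Optional[ModelConfig] = None,
    ) -> None:
        if not documents:
            raise ValueError("empty corpus")
        self.documents = list(documents)
        self.kb_store = kb_store
        self.embeddings = embeddings
        self.config = config or ModelConfig(embed_dim=embeddings.dim)
        if self.config.embed_dim != embeddings.dim:
            raise ValueError("config.embed_dim disagrees with the embedding table")
        self.labels = relation_labels(self.config)
        self._related_cache: dict[str, np.ndarray] = {}
        self.instances = self._build_instances(self.documents)

    # -- instance construction -------------------------------------------
    def _pair_memory(self, a: EntityMention, b: EntityMention) -> np.ndarray:
        names: list[str] = []
        seen: set[str] = set()
        for ent in (a, b):
            for n in self.kb_store.related_entities(ent.surface):
                if n.casefold() not in seen:
                    seen.add(n.casefold())
                    names.append(n)
        if not names:
            return np.zeros((0, self.embeddings.dim))
        return kb_vectors(names, self.embeddings).vectors

    def _build_instances(
        self, documents: Sequence[Document]
    ) -> list[_RelationInstanceData]:
        label_index = {name: i for i, name in enumerate(self.labels)}
        out: list[_RelationInstanceData] = []
        for doc in documents:
            gold = {(r.arg1, r.arg2): r.rtype for r in doc.relations}
            for sentence in doc.sentences:
                ents = doc.entities_in(sentence)
                for a, b in candidate_pairs(sentence, ents):
                    rtype = gold.get((a.id, b.id), NONE_LABEL)
                    if rtype not in label_index:
                        raise ValueError(
                            f"gold relation type {rtype!r} outside the "
                            f"configured label set"
                        )
                    window = build_relation_input(
                        sentence,
                        (a, b),
                        self.config.input_mode,
                        self.config.window_expand,
                    )
                    X = np.stack(
                        [self.embeddings.get(t.surface) for t in window]
                    )
                    masks = np.zeros((len(window), 2))
                    masks[entity_token_indices(sentence, a, window), 0] = 1.0
                    masks[entity_token_indices(sentence, b, window), 1] = 1.0
                    memory = (
                        self._pair_memory(a, b)
                        if self.config.use_kb
                        else np.zeros((0, self.embeddings.dim))
                    )
                    out.append(
                        _RelationInstanceData(
                            doc.id, a.id, b.id, label_index[rtype], X, masks, memory
                        )
                    )
        return out

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        train_config: Optional[TrainConfig] = None,
        validation_documents: Optional[Sequence[Document]] = None,
    ) -> "RelationExtractionResults":
        cfg = train_config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        net = RelationNetwork(self.config, np.random.default_rng(self.config.seed))

        instances = self.instances
        if cfg.max_negative_ratio is not None:
            instances = _cap_negatives(
                instances, len(self.labels) - 1, cfg.max_negative_ratio, rng
            )
        val_instances = (
            self._build_instances(validation_documents)
            if validation_documents
            else None
        )
        batch_size = cfg.effective_batch_size(len(instances))
        optimizer = nn.AdaDelta(
            net.params, lr=cfg.lr, rho=cfg.rho, eps=cfg.eps, l2=cfg.l2
        )

        log: list[dict] = []
        best_f1, best_params, patience_left = -1.0, None, cfg.patience
        for epoch in range(1, cfg.max_epochs + 1):
            losses = []
            for batch in _batches(instances, batch_size, rng):
                X, masks, memory, memmask, labels = _collate(batch)
                logits = net.forward(X, masks, memory, memmask, train=True, rng=rng)
                loss = ad.cross_entropy(logits, labels)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            entry = {"epoch": epoch, "loss": float(np.mean(losses))}
            if val_instances is not None:
                entry["val_f1"] = _micro_f1_on_instances(
                    net, val_instances, batch_size, self.labels
                )
                if entry["val_f1"] > best_f1 + 1e-12:
                    best_f1 = entry["val_f1"]
                    best_params = {k: p.data.copy() for k, p in net.params.items()}
                    patience_left = cfg.patience
                else:
                    patience_left -= 1
            log.append(entry)
            if val_instances is not None and patience_left <= 0:
                break
        if best_params is not None:
            for k, p in net.params.items():
                p.data = best_params[k]
        return RelationExtractionResults(self, net, cfg, pd.DataFrame(log))

    # -- inference helpers -------------------------------------------------
    def predict_instances(
        self,
        net: RelationNetwork,
        instances: Sequence[_RelationInstanceData],
        batch_size: int = 32,
    ) -> list[int]:
        return _predict_instances(net, instances, batch_size)


def _predict_instances(net, instances, batch_size: int = 32) -> list[int]:
    order = np.argsort([len(i.X) for i in instances], kind="stable")
    pred = np.zeros(len(instances), dtype=int)
    i = 0
    while i < len(order):
        j = i + 1
        T = len(instances[order[i]].X)
        while (
            j < len(order)
            and j - i < batch_size
            and len(instances[order[j]].X) == T
        ):
            j += 1
        batch = [instances[k] for k in order[i:j]]
        X, masks, memory, memmask, _ = _collate(batch)
        logits = net.forward(X, masks, memory, memmask, train=False)
        pred[order[i:j]] = np.argmax(logits.data, axis=1)
        i = j
    return pred.tolist()


def _cap_negatives(instances, none_index, ratio, rng):
    pos = [i for i in instances if i.label != none_index]
    neg = [i for i in instances if i.label == none_index]
    cap = int(np.ceil(ratio * max(len(pos), 1)))
    if len(neg) > cap:
        keep = rng.choice(len(neg), size=cap, replace=False)
        neg = [neg[k] for k in sorted(keep)]
    return pos + neg


def _batches(instances, batch_size, rng):
    """Shuffled minibatches of equal-length windows."""
    by_len: dict[int, list[int]] = {}
    for idx, inst in enumerate(instances):
        by_len.setdefault(len(inst.X), []).append(idx)
    batches = []
    for idxs in by_len.values():
        idxs = list(idxs)
        rng.shuffle(idxs)
        for i in range(0, len(idxs), batch_size):
            batches.append([instances[k] for k in idxs[i : i + batch_size]])
    rng.shuffle(batches)
    return batches


def _collate(batch):
    B = len(batch)
    T = len(batch[0].X)
    D = batch[0].X.shape[1]
    M = max((len(i.memory) for i in batch), default=0)
    X = np.stack([i.X for i in batch])
    masks = np.stack([i.arg_masks for i in batch])
    memory = np.zeros((B, M, D))
    memmask = np.zeros((B, M))
    for b, inst in enumerate(batch):
        m = len(inst.memory)
        if m:
            memory[b, :m] = inst.memory
            memmask[b, :m] = 1.0
    labels = np.array([i.label for i in batch])
    return X, masks, memory, memmask, labels


def _micro_f1_on_instances(net, instances, batch_size, labels) -> float:
    pred = _predict_instances(net, instances, batch_size)
    none_index = len(labels) - 1
    pkeys = [
        (labels[p], inst.doc_id, inst.arg1, inst.arg2)
        for p, inst in zip(pred, instances)
        if p != none_index
    ]
    gkeys = [
        (labels[inst.label], inst.doc_id, inst.arg1, inst.arg2)
        for inst in instances
        if inst.label != none_index
    ]
    return evaluate_prf_keys(pkeys, gkeys).f1


class RelationExtractionResults:
    """Fitted relation extractor: predictions, metrics, summary."""

    def __init__(
        self,
        model: RelationExtractionModel,
        net: RelationNetwork,
        train_config: TrainConfig,
        epoch_log: pd.DataFrame,
    ) -> None:
        self.model = model
        self.net = net
        self.train_config = train_config
        self.epoch_log = epoch_log

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {k: p.data for k, p in self.net.params.items()}

    def predict_document(self, doc: Document) -> Document:
        """A copy of the document with predicted relations (NONE suppressed)."""
        instances = self.model._build_instances([doc])
        pred = self.model.predict_instances(self.net, instances)
        labels = self.model.labels
        none_index = len(labels) - 1
        relations = [
            RelationInstance(f"R{n + 1}", labels[p], inst.arg1, inst.arg2)
            for n, (p, inst) in enumerate(
                (p, i) for p, i in zip(pred, instances) if p != none_index
            )
        ]
        return Document(
            doc.id, doc.text, doc.sentences, doc.entities, relations
        )

    def predict(self, documents: Sequence[Document]) -> list[Document]:
        return [self.predict_document(d) for d in documents]

    def evaluate(self, documents: Sequence[Document]) -> PRFReport:
        """Micro P/R/F1 of predictions against the documents' gold relations."""
        instances = self.model._build_instances(documents)
        pred = self.model.predict_instances(self.net, instances)
        labels = self.model.labels
        none_index = len(labels) - 1
        pkeys = [
            (labels[p], inst.doc_id, inst.arg1, inst.arg2)
            for p, inst in zip(pred, instances)
            if p != none_index
        ]
        gkeys = [
            (r.rtype, doc.id, r.arg1, r.arg2)
            for doc in documents
            for r in doc.relations
        ]
        return evaluate_prf_keys(pkeys, gkeys)

    def summary(self) -> str:
        cfg, tcfg = self.model.config, self.train_config
        lines = [
            "Relation extraction results",
            "=" * 60,
            f"instances:            {len(self.model.instances)}",
            f"labels:               {len(self.model.labels)} "
            f"({len(self.model.labels) - 1} relation types + NONE)",
            f"embeddings:           dim {cfg.embed_dim}",
            f"BiLSTM state size:    {cfg.lstm_state} per direction",
            f"dropout:              {cfg.dropout}",
            f"KB attention:         {'on' if cfg.use_kb else 'off'}",
            f"input mode:           {cfg.input_mode} "
            f"(window +/-{cfg.window_expand})",
            f"optimizer:            AdaDelta lr={tcfg.lr} l2={tcfg.l2}",
            f"epochs run:           {len(self.epoch_log)}",
            f"final train loss:     {self.epoch_log['loss'].iloc[-1]:.4f}",
        ]
        if "val_f1" in self.epoch_log:
            lines.append(
                f"best val micro-F1:    {self.epoch_log['val_f1'].max():.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Entity extraction
# ---------------------------------------------------------------------------

@dataclass
class _SentenceInstanceData:
    doc_id: str
    sentence: Sentence
    X: np.ndarray  # (T, D)
    tags: np.ndarray  # (T,)
    memory: np.ndarray  # (M, D)


@dataclass
class _EntityInstanceData:
    rep: np.ndarray  # (D,)
    memory: np.ndarray  # (M, D)
    label: int


class EntityTaggerModel:
    """Two-stage entity extraction: BIOE tagging, then type classification."""

    def __init__(
        self,
        documents: Sequence[Document],
        kb_store: KBStore,
        embeddings: EmbeddingTable,
        config: Optional[ModelConfig] = None,
    ) -> None:
        if not documents:
            raise ValueError("empty corpus")
        self.documents = list(documents)
        self.kb_store = kb_store
        self.embeddings = embeddings
        self.config = config or ModelConfig(embed_dim=embeddings.dim)
        self.tag_index = {t: i for i, t in enumerate(TAGS)}
        self.sent_instances = [
            inst for doc in documents for inst in self._sentence_instances(doc)
        ]
        self.type_instances = [
            inst for doc in documents for inst in self._type_instances(doc)
        ]

    def _sentence_memory(self, sentence: Sentence) -> np.ndarray:
        if not self.config.use_kb:
            return np.zeros((0, self.embeddings.dim))
        names: list[str] = []
        seen: set[str] = set()
        for tok in sentence.tokens:
            for n in self.kb_store.related_entities(tok.surface):
                if n.casefold() not in seen:
                    seen.add(n.casefold())
                    names.append(n)
        if not names:
            return np.zeros((0, self.embeddings.dim))
        return kb_vectors(names, self.embeddings).vectors

    def _sentence_instances(self, doc: Document):
        for sentence in doc.sentences:
            if not sentence.tokens:
                continue
            tags = spans_to_bioe(sentence, doc.entities_in(sentence))
            X = np.stack(
                [self.embeddings.get(t.surface) for t in sentence.tokens]
            )
            yield _SentenceInstanceData(
                doc.id,
                sentence,
                X,
                np.array([self.tag_index[t] for t in tags]),
                self._sentence_memory(sentence),
            )

    def _type_instances(self, doc: Document):
        for ent in doc.entities:
            records = self.kb_store.lookup_records(ent.surface)
            rep = entity_representation(ent, records, self.embeddings).vector
            if self.config.use_kb:
                memory = kb_vectors(
                    self.kb_store.related_entities(ent.surface), self.embeddings
                ).vectors
            else:
                memory = np.zeros((0, self.embeddings.dim))
            yield _EntityInstanceData(rep, memory, ENTITY_TYPES.index(ent.etype))

    def fit(self, train_config: Optional[TrainConfig] = None) -> "EntityTaggerResults":
        cfg = train_config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        net = TaggerNetwork(self.config, np.random.default_rng(self.config.seed))
        optimizer = nn.AdaDelta(
            net.params, lr=cfg.lr, rho=cfg.rho, eps=cfg.eps, l2=cfg.l2
        )
        batch_size = cfg.effective_batch_size(len(self.sent_instances))
        log = []
        for epoch in range(1, cfg.max_epochs + 1):
            losses = []
            for batch in _batches(
                [  # reuse the length-bucketed batcher via a thin adapter
                    _AsWindow(i) for i in self.sent_instances
                ],
                batch_size,
                rng,
            ):
                insts = [w.inst for w in batch]
                X = np.stack([i.X for i in insts])
                tags = np.stack([i.tags for i in insts])
                memory, memmask = _pad_memory(insts, self.embeddings.dim)
                em = net.emissions(X, memory, memmask, train=True, rng=rng)
                if self.config.use_crf:
                    loss = nn.crf_nll(net.params, em, tags)
                else:
                    B, T, K = em.shape
                    loss = ad.cross_entropy(
                        em.reshape(B * T, K), tags.reshape(-1)
                    )
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            # stage 2: entity type classification
            type_losses = []
            idxs = np.arange(len(self.type_instances))
            rng.shuffle(idxs)
            for i in range(0, len(idxs), batch_size):
                insts = [self.type_instances[k] for k in idxs[i : i + batch_size]]
                reps = np.stack([x.rep for x in insts])
                memory, memmask = _pad_memory(insts, self.embeddings.dim)
                logits = net.type_logits(reps, memory, memmask)
                loss = ad.cross_entropy(logits, np.array([x.label for x in insts]))
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                type_losses.append(float(loss.data))
            log.append(
                {
                    "epoch": epoch,
                    "loss": float(np.mean(losses)),
                    "type_loss": float(np.mean(type_losses)) if type_losses else 0.0,
                }
            )
        return EntityTaggerResults(self, net, cfg, pd.DataFrame(log))


class _AsWindow:
    """Adapter giving sentence instances the .X interface _batches expects."""

    def __init__(self, inst: _SentenceInstanceData) -> None:
        self.inst = inst
        self.X = inst.X


def _pad_memory(insts, dim):
    B = len(insts)
    M = max((len(i.memory) for i in insts), default=0)
    memory = np.zeros((B, M, dim))
    memmask = np.zeros((B, M))
    for b, inst in enumerate(insts):
        m = len(inst.memory)
        if m:
            memory[b, :m] = inst.memory
            memmask[b, :m] = 1.0
    return memory, memmask


class EntityTaggerResults:
    """Fitted entity extractor."""

    def __init__(self, model, net: TaggerNetwork, train_config, epoch_log) -> None:
        self.model = model
        self.net = net
        self.train_config = train_config
        self.epoch_log = epoch_log

    def predict_document(self, doc: Document) -> Document:
        """Decode entity spans and types; returns a copy with predictions."""
        embeddings = self.model.embeddings
        store: KBStore = self.model.kb_store
        entities: list[EntityMention] = []
        n = 0
        for sentence in doc.sentences:
            if not sentence.tokens:
                continue
            X = np.stack([embeddings.get(t.surface) for t in sentence.tokens])[
                None
            ]
            memory, memmask = _pad_memory(
                [
                    _SentenceInstanceData(
                        doc.id,
                        sentence,
                        X[0],
                        np.zeros(len(sentence.tokens), dtype=int),
                        self.model._sentence_memory(sentence),
                    )
                ],
                embeddings.dim,
            )
            em = self.net.emissions(X, memory, memmask, train=False)
            tags = self.net.decode(em.data[0])
            for s, e in bioe_to_spans(tags, sentence):
                n += 1
                surface = doc.text[s:e]
                probe = EntityMention(f"T{n}", "Gene", s, e, surface)
                records = store.lookup_records(surface)
                rep = entity_representation(probe, records, embeddings).vector
                mem = (
                    kb_vectors(store.related_entities(surface), embeddings).vectors
                    if self.model.config.use_kb
                    else np.zeros((0, embeddings.dim))
                )
                memory2 = mem[None] if len(mem) else np.zeros((1, 0, embeddings.dim))
                memmask2 = np.ones((1, len(mem))) if len(mem) else np.zeros((1, 0))
                logits = self.net.type_logits(rep[None], memory2, memmask2)
                etype = ENTITY_TYPES[int(np.argmax(logits.data[0]))]
                probe.etype = etype
                entities.append(probe)
        return Document(doc.id, doc.text, doc.sentences, entities, [])

    def evaluate(self, documents: Sequence[Document]) -> PRFReport:
        """Span-level P/R/F1: exact (type, start, end) match per document."""
        pkeys, gkeys = [], []
        for doc in documents:
            pred = self.predict_document(doc)
            pkeys += [
                (e.etype, doc.id, e.char_start, e.char_end) for e in pred.entities
            ]
            gkeys += [
                (e.etype, doc.id, e.char_start, e.char_end) for e in doc.entities
            ]
        return evaluate_prf_keys(pkeys, gkeys)

    def summary(self) -> str:
        cfg = self.model.config
        return "\n".join(
            [
                "Entity extraction results",
                "=" * 60,
                f"sentences:            {len(self.model.sent_instances)}",
                f"entities:             {len(self.model.type_instances)}",
                f"decoder:              {'CRF (Viterbi)' if cfg.use_crf else 'greedy softmax'}",
                f"KB attention:         {'on' if cfg.use_kb else 'off'}",
                f"epochs run:           {len(self.epoch_log)}",
                f"final tag loss:       {self.epoch_log['loss'].iloc[-1]:.4f}",
            ]
        )
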