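"""Synthetic corpora, knowledge stores and embeddings with planted signal.

The generator emulates the three inputs of the extraction pipeline — a
standoff-annotated corpus of gene/protein mentions with directed relation
labels, a knowledge store of annotation records plus curated reaction
models, and a text-format embedding table — with fully controllable
statistical structure, so that every component is testable without any
download and ablations can attribute performance causally.

Two independent signal channels connect a sentence's entity pair to its
relation label:

* **lexical**: with probability ``p_trigger`` a label-specific trigger token
  appears between the pair, so surface text alone gives partial
  separability;
* **knowledge**: with probability ``kb_signal`` the pair co-participates in
  a synthetic reaction that also contains a label-specific marker species,
  so reaction co-participation is predictive of the relation label and is
  only reachable through the KB-attention pathway.

Sentences are templated token streams (capitalized filler words, entity
mentions of one or two tokens, a terminal period), not natural language.
Entity types leave a trace in embedding space: gene-name and protein-name
tokens are offset in opposite directions along one embedding coordinate, so
type classification is learnable for unseen names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import (
    RELATION_TYPES,
    Document,
    EntityMention,
    RelationInstance,
    segment,
    write_corpus_dir,
)
from .kb import KBRecord, KBStore, Reaction, ReactionModel
from .representation import EmbeddingTable


@dataclass
class SynthConfig:
    """Knobs of the generator; a fixed seed gives byte-identical output."""

    vocab_size: int = 200
    n_documents: int = 50
    sentences_per_doc: int = 10
    entities_per_sentence: int = 2
    n_relation_labels: int = 4
    kb_signal: float = 1.0
    p_trigger: float = 0.5
    p_relation: float = 0.75
    annotation_tokens_per_record: int = 5
    oov_rate: float = 0.0
    kb_coverage: float = 0.75
    entity_pool: int = 300
    multi_token_entity_rate: float = 0.25
    n_distractor_reactions: int = 20
    embed_dim: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kb_signal", "p_trigger", "p_relation", "oov_rate", "kb_coverage",
                     "multi_token_entity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("vocab_size", "n_documents", "sentences_per_doc",
                     "entities_per_sentence", "n_relation_labels",
                     "entity_pool", "embed_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_relation_labels > len(RELATION_TYPES):
            raise ValueError(
                f"at most {len(RELATION_TYPES)} relation labels are defined"
            )
        if self.embed_dim < 2 * self.n_relation_labels + 1:
            raise ValueError("embed_dim too small for separated signal tokens")

    # -- derived vocabularies (deterministic) -----------------------------
    @property
    def labels(self) -> list[str]:
        return list(RELATION_TYPES[: self.n_relation_labels])

    def trigger_token(self, label_index: int) -> str:
        return f"Trig{label_index}"

    def marker_species(self, label_index: int) -> str:
        return f"Mark{label_index}"

    def filler_token(self, k: int) -> str:
        return f"Wrd{k}"

    def entity_surface_pool(self) -> list[tuple[str, str]]:
        """(surface base token, type) pairs; even indices Gene, odd Protein."""
        pool = []
        for i in range(self.entity_pool):
            if i % 2 == 0:
                pool.append((f"GEN{i:04d}", "Gene"))
            else:
                pool.append((f"PRT{i:04d}", "Protein"))
        return pool


_SUFFIXES = ("alpha", "beta", "gamma", "delta")


def _pair_label(seed: int, surface1: str, surface2: str, n_labels: int) -> int:
    """Deterministic relation label for an ordered pair of surfaces.

    The true relation between two specific molecules is a fixed fact, so a
    pair recurring across sentences always carries the same label (and hence
    a consistent planted reaction).
    """
    import hashlib

    digest = hashlib.sha256(f"{seed}|{surface1}|{surface2}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % n_labels


def generate_corpus(cfg: SynthConfig) -> list[Document]:
    """Templated documents with typed entity spans and directed relations."""
    rng = np.random.default_rng([cfg.seed, 0])
    pool = cfg.entity_surface_pool()
    docs = []
    for d in range(cfg.n_documents):
        parts: list[str] = []  # text chunks
        pos = 0
        entities: list[EntityMention] = []
        relations: list[RelationInstance] = []

        def emit(token: str) -> tuple[int, int]:
            nonlocal pos
            if parts:
                parts.append(" ")
                pos += 1
            start = pos
            parts.append(token)
            pos += len(token)
            return start, pos

        def emit_filler(n: int) -> None:
            for _ in range(n):
                emit(cfg.filler_token(int(rng.integers(cfg.vocab_size))))

        for _s in range(cfg.sentences_per_doc):
            picks = rng.choice(len(pool), size=cfg.entities_per_sentence, replace=False)
            mentions = []
            for p in picks:
                base, etype = pool[int(p)]
                surface = base
                if rng.random() < cfg.multi_token_entity_rate:
                    surface = f"{base} {_SUFFIXES[int(rng.integers(len(_SUFFIXES)))]}"
                mentions.append((surface, etype))
            has_relation = rng.random() < cfg.p_relation
            label = (
                _pair_label(
                    cfg.seed, mentions[0][0], mentions[1][0], cfg.n_relation_labels
                )
                if len(mentions) >= 2
                else 0
            )
            sentence_entities = []
            emit_filler(int(rng.integers(1, 3)))
            for j, (surface, etype) in enumerate(mentions):
                first_tok, rest = surface.split(" ", 1) if " " in surface else (surface, "")
                start, _ = emit(first_tok)
                end = start + len(first_tok)
                if rest:
                    _, end = emit(rest)
                eid = f"T{len(entities) + 1}"
                ent = EntityMention(eid, etype, start, end, surface)
                entities.append(ent)
                sentence_entities.append(ent)
                if j < cfg.entities_per_sentence - 1:
                    emit_filler(int(rng.integers(1, 3)))
                    if j == 0 and has_relation and rng.random() < cfg.p_trigger:
                        emit(cfg.trigger_token(label))
                        emit_filler(int(rng.integers(1, 3)))
            if has_relation and len(sentence_entities) >= 2:
                relations.append(
                    RelationInstance(
                        f"R{len(relations) + 1}",
                        cfg.labels[label],
                        sentence_entities[0].id,
                        sentence_entities[1].id,
                    )
                )
            # terminal period attaches to the last token
            parts.append(".")
            pos += 1
        text = "".join(parts)
        doc = Document(f"synth{d:04d}", text, segment(text), entities, relations)
        for ent in doc.entities:
            assert doc.text[ent.char_start : ent.char_end] == ent.surface
        docs.append(doc)
    return docs


def generate_kb(cfg: SynthConfig, documents: Sequence[Document]) -> KBStore:
    """Annotation records plus one curated reaction model with planted signal.

    Each distinct entity surface gets a record with probability
    ``kb_coverage``.  For each gold relation, with probability ``kb_signal``
    a reaction containing both argument surfaces and the label's marker
    species is added; distractor reactions tie random entity surfaces to
    label-free species.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    surfaces: list[str] = []
    seen = set()
    for doc in documents:
        for ent in doc.entities:
            if ent.surface not in seen:
                seen.add(ent.surface)
                surfaces.append(ent.surface)

    store = KBStore()
    label_index = {name: i for i, name in enumerate(cfg.labels)}
    for i, surface in enumerate(surfaces):
        if rng.random() >= cfg.kb_coverage:
            continue
        n_ann = cfg.annotation_tokens_per_record
        function_text = " ".join(
            cfg.filler_token(int(rng.integers(cfg.vocab_size)))
            for _ in range(n_ann)
        )
        store.add_record(
            KBRecord(
                accession=f"ACC{i:05d}",
                recommended_name=surface,
                alternative_names=[f"{surface}-like"],
                gene_names=[f"g{surface.replace(' ', '')}"],
                short_names=[],
                function_text=function_text,
            )
        )

    reactions: list[Reaction] = []
    for doc in documents:
        ents = {e.id: e for e in doc.entities}
        for rel in doc.relations:
            if rng.random() >= cfg.kb_signal:
                continue
            reactions.append(
                Reaction(
                    f"rx{len(reactions) + 1}",
                    [
                        ents[rel.arg1].surface,
                        ents[rel.arg2].surface,
                        cfg.marker_species(label_index[rel.rtype]),
                    ],
                )
            )
    for k in range(cfg.n_distractor_reactions):
        if not surfaces:
            break
        anchor = surfaces[int(rng.integers(len(surfaces)))]
        extras = [f"Spc{int(rng.integers(3 * max(cfg.n_distractor_reactions, 1)))}"
                  for _ in range(int(rng.integers(1, 3)))]
        reactions.append(Reaction(f"rx{len(reactions) + 1}", [anchor] + extras))
    store.add_model(ReactionModel("SYNMODEL0001", True, reactions))
    return store


def generate_embeddings(
    cfg: SynthConfig, documents: Optional[Sequence[Document]] = None
) -> EmbeddingTable:
    """Unit-scaled embeddings for the generator's full vocabulary.

    Trigger and marker tokens get well-separated axis-aligned vectors;
    gene/protein name tokens carry opposite offsets on the last coordinate
    (a learnable type signature); a fraction ``oov_rate`` of the filler
    vocabulary is deliberately left out of the table.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    dim = cfg.embed_dim
    table = EmbeddingTable(dim, oov_seed=cfg.seed)

    def random_vec() -> np.ndarray:
        v = rng.normal(size=dim)
        return v / np.linalg.norm(v)

    for k in range(cfg.vocab_size):
        if rng.random() < cfg.oov_rate:
            continue
        table.add(cfg.filler_token(k), random_vec())
    for l in range(cfg.n_relation_labels):
        trig = np.zeros(dim)
        trig[2 * l] = 2.0
        table.add(cfg.trigger_token(l), trig)
        mark = np.zeros(dim)
        mark[2 * l + 1] = 2.0
        table.add(cfg.marker_species(l), mark)
    type_axis = np.zeros(dim)
    type_axis[-1] = 1.2
    for base, etype in cfg.entity_surface_pool():
        offset = type_axis if etype == "Gene" else -type_axis
        table.add(base, random_vec() * 0.5 + offset)
    for suffix in _SUFFIXES:
        table.add(suffix, random_vec() * 0.5)
    for k in range(3 * max(cfg.n_distractor_reactions, 1)):
        table.add(f"Spc{k}", random_vec())
    table.add(".", random_vec() * 0.1)
    table.add("gene", type_axis.copy())
    table.add("protein", -type_axis.copy())
    return table


@dataclass
class SynthData:
    documents: list[Document]
    store: KBStore
    embeddings: EmbeddingTable


def generate(cfg: SynthConfig) -> SynthData:
    """Corpus, knowledge store and embeddings from one configuration."""
    docs = generate_corpus(cfg)
    return SynthData(docs, generate_kb(cfg, docs), generate_embeddings(cfg, docs))


def write_synth(cfg: SynthConfig, outdir: str | Path) -> None:
    """Emit corpus/ (txt/a1/a2), store.json and embeddings.txt."""
    outdir = Path(outdir)
    data = generate(cfg)
    write_corpus_dir(data.documents, outdir / "corpus")
    data.store.save(outdir / "store.json")
    data.embeddings.save(outdir / "embeddings.txt")
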