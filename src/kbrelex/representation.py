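"""Vector spaces for words, entities and knowledge-base neighbours.

Words live in a pre-trained 200-dimensional embedding space (word2vec text
format).  An entity is represented as the elementwise sum of three vectors in
that same space:

* the *word* component — the mean of the embeddings of the entity's surface
  tokens;
* the *type* component — the embedding of the lowercased type name
  ("gene" / "protein");
* the *annotation* component — the sum of the embeddings of every token in
  the names and function text of all matching knowledge-base records (a bag
  of annotation words; records are merged rather than ranked).

Out-of-vocabulary tokens receive a deterministic pseudo-random vector, drawn
componentwise from Uniform(-0.25, 0.25) and seeded by the token and the
table's ``oov_seed``, so repeated lookups and repeated runs agree exactly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import EntityMention, ParseError, tokenize
from .kb import KBRecord, collect_names

logger = logging.getLogger(__name__)

DEFAULT_DIM = 200


def _oov_vector(token: str, oov_seed: int, dim: int) -> np.ndarray:
    digest = hashlib.sha256(f"{oov_seed}\x00{token}".encode()).digest()
    seed = int.from_bytes(digest[:8], "little") % (2**63)
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.25, 0.25, size=dim)


class EmbeddingTable:
    """token -> dense vector, with a deterministic OOV policy."""

    def __init__(self, dim: int = DEFAULT_DIM, oov_seed: int = 0) -> None:
        if dim <= 0:
            raise ValueError("dim must be positive")
        self.dim = dim
        self.oov_seed = oov_seed
        self._table: dict[str, np.ndarray] = {}
        self._oov_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, token: str) -> bool:
        return token in self._table

    def add(self, token: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.dim,):
            raise ValueError(f"vector for {token!r} has shape {vector.shape}")
        self._table[token] = vector

    def get(self, token: str) -> np.ndarray:
        """Stored vector, or the cached deterministic OOV vector."""
        vec = self._table.get(token)
        if vec is not None:
            return vec
        vec = self._oov_cache.get(token)
        if vec is None:
            vec = _oov_vector(token, self.oov_seed, self.dim)
            self._oov_cache[token] = vec
        return vec

    def tokens(self) -> Iterable[str]:
        return self._table.keys()

    # -- text format ------------------------------------------------------
    @classmethod
    def load(
        cls, path: str | Path, dim: int | None = None, oov_seed: int = 0
    ) -> "EmbeddingTable":
        """Read whitespace-delimited text embeddings.

        One ``token v1 … vd`` per line; an optional leading ``count dim``
        header is tolerated.  A row whose arity disagrees with ``dim`` is a
        parse error naming the line; duplicate tokens keep the first
        occurrence with a warning.
        """
        path = Path(path)
        table: "EmbeddingTable | None" = None
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, 1):
                parts = raw.split()
                if not parts:
                    continue
                if lineno == 1 and len(parts) == 2:
                    try:
                        int(parts[0])
                        header_dim = int(parts[1])
                    except ValueError:
                        pass
                    else:
                        if dim is not None and header_dim != dim:
                            raise ParseError(
                                f"{path}:1: header dim {header_dim} != {dim}"
                            )
                        dim = header_dim
                        continue
                token, values = parts[0], parts[1:]
                if dim is None:
                    dim = len(values)
                if len(values) != dim:
                    raise ParseError(
                        f"{path}:{lineno}: expected {dim} values, got "
                        f"{len(values)}"
                    )
                if table is None:
                    table = cls(dim, oov_seed=oov_seed)
                if token in table:
                    logger.warning(
                        "%s:%d: duplicate token %r (first kept)",
                        path,
                        lineno,
                        token,
                    )
                    continue
                try:
                    table.add(token, np.array([float(v) for v in values]))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if table is None:
            table = cls(dim or DEFAULT_DIM, oov_seed=oov_seed)
        return table

    def save(self, path: str | Path, header: bool = True) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"{len(self._table)} {self.dim}\n")
            for token, vec in self._table.items():
                fh.write(token + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")


def embed_token(token: str, table: EmbeddingTable) -> np.ndarray:
    return table.get(token)


def embed_tokens(surfaces: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Stack token vectors into a (T, dim) matrix."""
    if not surfaces:
        return np.zeros((0, table.dim))
    return np.stack([table.get(s) for s in surfaces])


def annotation_vector(
    records: Sequence[KBRecord], table: EmbeddingTable
) -> np.ndarray:
    """Sum of the embeddings of every annotation token of all records.

    Annotation text is the concatenation of all names plus the function
    text of each record (taxonomy is non-lexical and excluded).  With no
    records the vector is zero.
    """
    total = np.zeros(table.dim)
    for rec in records:
        text = " ".join(collect_names(rec) + [rec.function_text])
        for tok in tokenize(text):
            total += table.get(tok.surface)
    return total


@dataclass
class EntityRepresentation:
    """The fused entity vector and its three additive components."""

    vector: np.ndarray
    word: np.ndarray
    type: np.ndarray
    annotation: np.ndarray

    @property
    def components(self) -> dict[str, np.ndarray]:
        return {"word": self.word, "type": self.type, "annotation": self.annotation}


def entity_representation(
    entity: EntityMention,
    records: Sequence[KBRecord],
    table: EmbeddingTable,
) -> EntityRepresentation:
    """word-mean + type + annotation, all in the shared embedding space."""
    toks = tokenize(entity.surface)
    if not toks:
        raise ValueError(f"entity {entity.id} has an empty surface")
    word = np.mean([table.get(t.surface) for t in toks], axis=0)
    type_vec = table.get(entity.etype.lower())
    ann = annotation_vector(records, table)
    return EntityRepresentation(word + type_vec + ann, word, type_vec, ann)


@dataclass
class KBVectorSet:
    """Vectors v_i of the knowledge-base neighbours of an entity (may be empty)."""

    entity_names: list[str] = field(default_factory=list)
    vectors: np.ndarray = field(
        default_factory=lambda: np.zeros((0, DEFAULT_DIM))
    )

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(
            self.entity_names
        ):
            raise ValueError("vectors must be (len(entity_names), dim)")

    def __len__(self) -> int:
        return len(self.entity_names)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def kb_vectors(
    related_names: Sequence[str], table: EmbeddingTable
) -> KBVectorSet:
    """One vector per related entity: the mean of its name-token embeddings."""
    names = [n for n in related_names if tokenize(n)]
    if not names:
        return KBVectorSet([], np.zeros((0, table.dim)))
    vecs = np.stack(
        [
            np.mean([table.get(t.surface) for t in tokenize(n)], axis=0)
            for n in names
        ]
    )
    return KBVectorSet(list(names), vecs)
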