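"""Offline knowledge store: protein annotation records and reaction models.

Two kinds of curated knowledge feed the extractor.  Annotation records carry
the naming and free-text function fields of a UniProt-style entry (recommended
name, alternative names, gene names, short names, function text, taxonomy).
Reaction models carry the ``listOfReactions`` content of curated SBML models:
for each reaction, the set of participating species.  Two species are
"related" when they co-participate in at least one reaction of a curated
model; those related entities are what the attention mechanism later consumes.

Name matching is exact after normalization (case-fold, trim, collapse
internal whitespace) — no stemming or fuzzy matching, so every hit is
auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

logger = logging.getLogger(__name__)


def normalize_name(name: str) -> str:
    """Case-fold, strip, and collapse internal whitespace."""
    return " ".join(name.casefold().split())


def _dedup(names: Iterable[str]) -> list[str]:
    """Order-preserving de-duplication, case-insensitive, keeps first casing."""
    seen: set[str] = set()
    out = []
    for n in names:
        key = normalize_name(n)
        if key and key not in seen:
            seen.add(key)
            out.append(n)
    return out


@dataclass
class KBRecord:
    """A protein annotation entry: names, function text, taxonomy."""

    accession: str
    recommended_name: str
    alternative_names: list[str] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)
    short_names: list[str] = field(default_factory=list)
    function_text: str = ""
    taxonomy: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.recommended_name:
            raise ValueError("recommended_name must be non-empty")
        self.alternative_names = _dedup(self.alternative_names)
        self.gene_names = _dedup(self.gene_names)
        self.short_names = _dedup(self.short_names)


def collect_names(record: KBRecord) -> list[str]:
    """All names of a record, deduplicated, in deterministic field order.

    Order: recommended name, alternative names, gene names, short names.
    Original casing is preserved; duplicates (case-insensitive) keep the
    first occurrence.
    """
    return _dedup(
        [record.recommended_name]
        + list(record.alternative_names)
        + list(record.gene_names)
        + list(record.short_names)
    )


@dataclass
class Reaction:
    """One reaction: its id and the names of all participating species.

    Participants are reactants, products and modifiers alike; the
    participant list is deduplicated but order-preserving so downstream
    output is deterministic.
    """

    reaction_id: str
    participants: list[str]

    def __post_init__(self) -> None:
        self.participants = _dedup(self.participants)
        if not self.participants:
            raise ValueError(f"reaction {self.reaction_id} has no participants")


@dataclass
class ReactionModel:
    model_id: str
    curated: bool = True
    reactions: list[Reaction] = field(default_factory=list)


class KBStore:
    """Name-indexed store of annotation records plus curated reaction models."""

    def __init__(self) -> None:
        self.records: dict[str, KBRecord] = {}
        self.name_index: dict[str, list[str]] = {}
        self.models: list[ReactionModel] = []

    # -- population -------------------------------------------------------
    def add_record(self, record: KBRecord) -> None:
        if record.accession in self.records:
            raise ValueError(f"duplicate accession {record.accession}")
        self.records[record.accession] = record
        for name in collect_names(record):
            key = normalize_name(name)
            accs = self.name_index.setdefault(key, [])
            if record.accession not in accs:
                accs.append(record.accession)

    def add_model(self, model: ReactionModel) -> bool:
        """Add a reaction model; non-curated models are refused (logged)."""
        if not model.curated:
            logger.info("skipping non-curated model %s", model.model_id)
            return False
        self.models.append(model)
        return True

    # -- lookup -----------------------------------------------------------
    def lookup_records(self, surface: str) -> list[KBRecord]:
        """All records any of whose names matches the surface (normalized)."""
        accs = self.name_index.get(normalize_name(surface), [])
        return [self.records[a] for a in accs]

    def related_entities(self, surface: str) -> list[str]:
        """Names co-participating in a reaction with any name of the entity.

        Step 1 expands the surface to all names of all matching annotation
        records; step 2 scans every reaction of every curated model whose
        participants intersect those names and collects the remaining
        participants.  The result never contains a name of the query entity
        itself; order is deterministic (model, then reaction, then
        participant order) and deduplicated.  Unknown surfaces yield [].
        """
        names = {normalize_name(surface)}
        for rec in self.lookup_records(surface):
            names.update(normalize_name(n) for n in collect_names(rec))
        related: list[str] = []
        seen: set[str] = set()
        for model in self.models:
            for reaction in model.reactions:
                participant_keys = {
                    normalize_name(p) for p in reaction.participants
                }
                if not (participant_keys & names):
                    continue
                for p in reaction.participants:
                    key = normalize_name(p)
                    if key in names or key in seen:
                        continue
                    seen.add(key)
                    related.append(p)
        return related

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "records": [
                {
                    "accession": r.accession,
                    "recommended_name": r.recommended_name,
                    "alternative_names": r.alternative_names,
                    "gene_names": r.gene_names,
                    "short_names": r.short_names,
                    "function_text": r.function_text,
                    "taxonomy": r.taxonomy,
                }
                for r in self.records.values()
            ],
            "models": [
                {
                    "model_id": m.model_id,
                    "curated": m.curated,
                    "reactions": [
                        {
                            "reaction_id": x.reaction_id,
                            "participants": x.participants,
                        }
                        for x in m.reactions
                    ],
                }
                for m in self.models
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "KBStore":
        store = cls()
        for r in data.get("records", []):
            store.add_record(KBRecord(**r))
        for m in data.get("models", []):
            store.add_model(
                ReactionModel(
                    m["model_id"],
                    m.get("curated", True),
                    [Reaction(**x) for x in m.get("reactions", [])],
                )
            )
        return store

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "KBStore":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def parse_sbml_reactions(
    sbml_path: str | Path, curated: Optional[bool] = None
) -> ReactionModel:
    """Extract the ``listOfReactions`` subtree of an SBML file (levels 2–3).

    One :class:`Reaction` per ``<reaction>`` element; participants are the
    union of reactants, products and modifiers, with species references
    resolved to the species ``name`` attribute (falling back to the ``id``).
    Everything else in the model (kinetics, compartments, rules) is ignored.
    A model without a ``listOfReactions`` yields an empty reaction list.

    Curation status is not part of SBML itself; by default a file whose stem
    starts with ``MODEL`` is treated as non-curated (BioModels naming), and
    anything else as curated.  Pass ``curated=`` to override.
    """
    sbml_path = Path(sbml_path)
    try:
        tree = etree.parse(str(sbml_path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{sbml_path}: malformed SBML: {exc}") from exc
    root = tree.getroot()

    def local(el: etree._Element) -> str:
        return etree.QName(el).localname

    model_el = next((el for el in root.iter() if local(el) == "model"), None)
    model_id = (
        model_el.get("id") if model_el is not None and model_el.get("id") else sbml_path.stem
    )
    if curated is None:
        curated = not sbml_path.stem.startswith("MODEL")

    species_name: dict[str, str] = {}
    for el in root.iter():
        if local(el) == "species":
            sid = el.get("id")
            if sid:
                species_name[sid] = el.get("name") or sid

    reactions: list[Reaction] = []
    for el in root.iter():
        if local(el) != "listOfReactions":
            continue
        for rxn in el:
            if not isinstance(rxn.tag, str) or local(rxn) != "reaction":
                continue
            rid = rxn.get("id") or f"reaction{len(reactions) + 1}"
            participants: list[str] = []
            for sub in rxn.iter():
                if local(sub) in ("speciesReference", "modifierSpeciesReference"):
                    ref = sub.get("species")
                    if ref:
                        participants.append(species_name.get(ref, ref))
            if participants:
                reactions.append(Reaction(rid, participants))
    return ReactionModel(model_id, curated, reactions)


def load_sbml_dir(store: KBStore, directory: str | Path) -> int:
    """Parse every ``*.xml``/``*.sbml`` file in a directory into the store.

    Returns the number of models actually added (non-curated ones are
    refused by the store).
    """
    added = 0
    for path in sorted(Path(directory).glob("*")):
        if path.suffix.lower() in (".xml", ".sbml"):
            if store.add_model(parse_sbml_reactions(path)):
                added += 1
    return added
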