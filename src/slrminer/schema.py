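"""Extraction schemas: which entity types exist and which relations may link them.

A schema is pure data — an ordered inventory of entity types plus a set of
typed relation rows — so that new review domains can be added by writing a
configuration file rather than code.  Two presets ship with the package:
``slr1`` (oncology outcomes: treatment arms, dosages, progression-free
survival) and ``slr2`` (renal function in Fabry disease: eGFR metrics,
numbers, subgroups, time points, patient age).

Relation rows are either directed ``refers_to`` links between two named
entity types, or the symmetric ``equivalent`` link whose arguments are
unconstrained (the ``ANY`` wildcard).  Entity-type order is significant: it
fixes the indexing of BIO tag sets derived from the schema.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

ANY = "ANY"

RELATION_LABELS = ("refers_to", "equivalent")
SYMMETRIC_LABELS = frozenset({"equivalent"})

_NAME_RE = re.compile(r"^[a-z][a-z0-9_]*$")


class SchemaError(ValueError):
    """Raised when a schema definition is malformed or names do not resolve."""


@dataclass(frozen=True)
class EntityTypeDef:
    name: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise SchemaError(f"invalid entity-type name: {self.name!r}")


@dataclass(frozen=True)
class RelationTypeDef:
    label: str
    first_arg: str
    second_arg: str

    @property
    def symmetric(self) -> bool:
        return self.label in SYMMETRIC_LABELS

    def __post_init__(self) -> None:
        if self.label not in RELATION_LABELS:
            raise SchemaError(f"unknown relation label: {self.label!r}")


@dataclass(frozen=True)
class ExtractionSchema:
    schema_id: str
    entity_types: tuple[EntityTypeDef, ...]
    relation_types: tuple[RelationTypeDef, ...] = ()
    _names: frozenset[str] = field(init=False, repr=False, compare=False, default=frozenset())

    def __post_init__(self) -> None:
        if not self.entity_types:
            raise SchemaError("a schema needs at least one entity type")
        names = [e.name for e in self.entity_types]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate entity names: {sorted(dupes)}")
        for i, r in enumerate(self.relation_types):
            for arg in (r.first_arg, r.second_arg):
                if arg != ANY and arg not in names:
                    raise SchemaError(
                        f"relation row {i} ({r.label} {r.first_arg} {r.second_arg}): "
                        f"unknown entity type {arg!r}"
                    )
        object.__setattr__(self, "_names", frozenset(names))

    @property
    def entity_names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entity_types)

    def has_entity_type(self, name: str) -> bool:
        return name in self._names

    def entity_index(self, name: str) -> int:
        return self.entity_names.index(name)

    def is_admissible_pair(self, label: str, t1: str, t2: str) -> bool:
        """True iff some relation row matches ``label`` applied to (t1, t2).

        ``ANY`` matches every entity type; symmetric labels match in either
        argument order.  Unknown type names raise :class:`SchemaError`.
        """
        if label not in RELATION_LABELS:
            raise SchemaError(f"unknown relation label: {label!r}")
        for t in (t1, t2):
            if t not in self._names:
                raise SchemaError(f"unknown entity type: {t!r}")
        for r in self.relation_types:
            if r.label != label:
                continue
            if _pair_matches(r, t1, t2):
                return True
            if r.symmetric and _pair_matches(r, t2, t1):
                return True
        return False

    def relation_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.relation_types:
            if r.label not in seen:
                seen.append(r.label)
        return tuple(seen)


def _pair_matches(row: RelationTypeDef, t1: str, t2: str) -> bool:
    return (row.first_arg in (ANY, t1)) and (row.second_arg in (ANY, t2))


def normalise_name(display: str) -> str:
    """Lowercase snake_case identifier from a display name like ``"eGFR metric"``."""
    s = re.sub(r"[^0-9a-zA-Z]+", "_", display).strip("_").lower()
    if not _NAME_RE.match(s):
        raise SchemaError(f"cannot normalise {display!r} to an identifier")
    return s


def load_schema(source: str | Path | Mapping) -> ExtractionSchema:
    """Load a schema from a preset name, a YAML/JSON file path, or a mapping.

    Preset names (``slr1``, ``slr2``) resolve to the packaged configuration
    files.  The file layout is::

        schema_id: slr2
        entities: [{name, description}, ...]
        relations: [{label, first, second}, ...]   # ANY is the wildcard
    """
    if isinstance(source, Mapping):
        data = source
    else:
        text = None
        if isinstance(source, str) and _NAME_RE.match(source):
            preset = resources.files("slrminer").joinpath(f"schemas/{source}.yaml")
            if preset.is_file():
                text = preset.read_text(encoding="utf-8")
        if text is None:
            p = Path(source)
            if not p.is_file():
                raise SchemaError(f"no such schema preset or file: {source!r}")
            text = p.read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise SchemaError("schema configuration must be a mapping")
    try:
        entities = tuple(
            EntityTypeDef(name=e["name"], description=e.get("description", ""))
            for e in data.get("entities", ())
        )
        relations = tuple(
            RelationTypeDef(label=r["label"], first_arg=r["first"], second_arg=r["second"])
            for r in data.get("relations", ())
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema configuration: {exc}") from exc
    return ExtractionSchema(
        schema_id=str(data.get("schema_id", "custom")),
        entity_types=entities,
        relation_types=relations,
    )


def write_schema(schema: ExtractionSchema) -> dict:
    """Serialise a schema to the plain mapping accepted by :func:`load_schema`."""
    return {
        "schema_id": schema.schema_id,
        "entities": [
            {"name": e.name, "description": e.description} for e in schema.entity_types
        ],
        "relations": [
            {"label": r.label, "first": r.first_arg, "second": r.second_arg}
            for r in schema.relation_types
        ],
    }


def bio_labels(schema: ExtractionSchema) -> tuple[str, ...]:
    """The BIO tag set induced by the schema: ``O`` then B-/I- per entity type.

    Index 0 is always ``O``; entity-type order follows the schema, so the tag
    set size is ``2 * n_types + 1``.
    """
    labels = ["O"]
    for e in schema.entity_types:
        labels.append(f"B-{e.name}")
        labels.append(f"I-{e.name}")
    return tuple(labels)


def dump_schema_yaml(schema: ExtractionSchema) -> str:
    return yaml.safe_dump(write_schema(schema), sort_keys=False)
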