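"""Statement database: type forest, statements, and per-situation tables.

The database is one JSON document with five sections:

``types``
    list of ``{"name": ..., "parent": ... | null}``; a forest of depth at
    most two (super-type -> subtype).  Statements attach only to leaves.
``statements``
    list of ``{"text": ..., "type": <leaf name>, "language": ...}``.
``probabilities``
    ``{"<trend>:<trust>": {"<type>": p, ...}, ...}`` — the per-situation
    likelihood that a message for that situation uses the type.  Every
    listed type must be covered for all nine situations.
``lengths``
    ``{"<trend>:<trust>": n}`` — target number of statements per message.
``order``
    ``{"<type>": rank}`` — lower rank means earlier in the message; types
    without an explicit rank get :data:`DEFAULT_RANK`, which slots them
    between "tackling things together" and general motivation.

Files are saved in a canonical form (sorted keys, two-space indent) so that
load -> save is byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .situations import Situation, enumerate_situations

__all__ = [
    "DatabaseFormatError",
    "StatementType",
    "Statement",
    "Violation",
    "StatementDatabase",
    "DEFAULT_RANK",
    "load_database",
    "save_database",
    "validate",
    "leaves",
    "statements_for",
]

#: Rank assigned to types without an explicit ordering entry.
DEFAULT_RANK = 40


class DatabaseFormatError(ValueError):
    """A database file violates the documented JSON structure."""


@dataclass(frozen=True)
class StatementType:
    name: str
    parent: str | None = None


@dataclass(frozen=True)
class Statement:
    text: str
    type_name: str
    language: str = "en"


@dataclass(frozen=True)
class Violation:
    """One machine-readable finding from :func:`validate`."""

    code: str
    path: str
    message: str
    severity: str = "error"  # "error" or "warning"


@dataclass
class StatementDatabase:
    """In-memory statement database; see the module docstring for layout."""

    types: list[StatementType]
    statements: list[Statement]
    probabilities: dict[str, dict[str, float]]  # situation key -> type -> p
    lengths: dict[str, int]  # situation key -> statement count
    order: dict[str, int]  # type name -> rank
    meta: dict = field(default_factory=dict)

    # -- hierarchy queries -------------------------------------------------
    def type_map(self) -> dict[str, StatementType]:
        return {t.name: t for t in self.types}

    def children(self, name: str) -> list[str]:
        self._require_type(name)
        return [t.name for t in self.types if t.parent == name]

    def is_leaf(self, name: str) -> bool:
        return not self.children(name)

    def leaf_names(self) -> list[str]:
        """All leaf type names in declaration order."""
        parents = {t.parent for t in self.types if t.parent is not None}
        return [t.name for t in self.types if t.name not in parents]

    def declaration_index(self, name: str) -> int:
        for i, t in enumerate(self.types):
            if t.name == name:
                return i
        raise KeyError(f"unknown statement type: {name!r}")

    def rank(self, name: str) -> int:
        return self.order.get(name, DEFAULT_RANK)

    # -- table access ------------------------------------------------------
    def probability(self, situation: Situation, type_name: str) -> float:
        self._require_type(type_name)
        try:
            return self.probabilities[situation.key][type_name]
        except KeyError as exc:
            raise KeyError(
                f"no probability for type {type_name!r} at {situation.key}"
            ) from exc

    def _require_type(self, name: str) -> None:
        if name not in {t.name for t in self.types}:
            raise KeyError(f"unknown statement type: {name!r}")


# ---------------------------------------------------------------------------
# File format


def _check(condition: bool, path: str, message: str) -> None:
    if not condition:
        raise DatabaseFormatError(f"{path}: {message}")


def load_database(path: str | Path) -> StatementDatabase:
    """Load and structurally check a database JSON file.

    Raises :class:`DatabaseFormatError` naming the offending section/path on
    any structural problem; deeper semantic checks live in :func:`validate`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    _check(isinstance(raw, dict), "$", "top level must be a JSON object")
    for section in ("types", "statements", "probabilities", "lengths", "order"):
        _check(section in raw, section, "required section is missing")
    _check(isinstance(raw["types"], list), "types", "must be a list")
    types = []
    for i, entry in enumerate(raw["types"]):
        _check(isinstance(entry, dict) and "name" in entry, f"types[{i}]",
               "each type needs a 'name'")
        types.append(StatementType(entry["name"], entry.get("parent")))
    _check(isinstance(raw["statements"], list), "statements", "must be a list")
    statements = []
    for i, entry in enumerate(raw["statements"]):
        _check(
            isinstance(entry, dict) and {"text", "type"} <= set(entry),
            f"statements[{i}]", "each statement needs 'text' and 'type'",
        )
        statements.append(
            Statement(entry["text"], entry["type"], entry.get("language", "en"))
        )
    _check(isinstance(raw["probabilities"], dict), "probabilities",
           "must be an object keyed by situation")
    probabilities = {}
    for key, row in raw["probabilities"].items():
        try:
            Situation.parse(key)
        except ValueError:
            raise DatabaseFormatError(
                f"probabilities.{key}: not a 'trend:trust' situation key"
            )
        _check(isinstance(row, dict), f"probabilities.{key}", "must be an object")
        probabilities[key] = {t: float(p) for t, p in row.items()}
    _check(isinstance(raw["lengths"], dict), "lengths", "must be an object")
    lengths = {}
    for key, value in raw["lengths"].items():
        try:
            Situation.parse(key)
        except ValueError:
            raise DatabaseFormatError(
                f"lengths.{key}: not a 'trend:trust' situation key"
            )
        _check(
            isinstance(value, int) and value > 0,
            f"lengths.{key}", "length must be a positive integer",
        )
        lengths[key] = value
    _check(isinstance(raw["order"], dict), "order", "must be an object")
    order = {name: int(rank) for name, rank in raw["order"].items()}
    return StatementDatabase(
        types=types,
        statements=statements,
        probabilities=probabilities,
        lengths=lengths,
        order=order,
        meta=raw.get("meta", {}),
    )


def save_database(db: StatementDatabase, path: str | Path) -> None:
    """Write the canonical JSON form (stable across load/save cycles)."""
    raw = {
        "meta": db.meta,
        "types": [
            {"name": t.name, "parent": t.parent} for t in db.types
        ],
        "statements": [
            {"text": s.text, "type": s.type_name, "language": s.language}
            for s in db.statements
        ],
        "probabilities": db.probabilities,
        "lengths": db.lengths,
        "order": db.order,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(raw, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Validation


def validate(db: StatementDatabase) -> list[Violation]:
    """Check every database invariant; returns findings instead of raising.

    Error codes: ``duplicate-type``, ``orphan-type``, ``depth-exceeded``,
    ``statement-on-supertype``, ``unknown-statement-type``,
    ``probability-out-of-range``, ``unknown-type-in-table``,
    ``missing-situation``, ``unknown-situation-key``, ``bad-length``,
    ``unknown-type-in-order``; warning code ``leaf-without-statement``.
    A database is generator-ready iff no *error*-severity violation remains.
    """
    out: list[Violation] = []
    names = [t.name for t in db.types]
    name_set = set(names)
    seen: set[str] = set()
    for t in db.types:
        if t.name in seen:
            out.append(Violation("duplicate-type", f"types.{t.name}",
                                 f"type {t.name!r} declared more than once"))
        seen.add(t.name)
    by_name = {t.name: t for t in db.types}
    for t in db.types:
        if t.parent is not None:
            if t.parent not in name_set:
                out.append(Violation("orphan-type", f"types.{t.name}",
                                     f"parent {t.parent!r} is not declared"))
            else:
                grand = by_name[t.parent].parent
                if grand is not None:
                    out.append(Violation(
                        "depth-exceeded", f"types.{t.name}",
                        f"{t.name!r} has a grandparent {grand!r}; the type "
                        "forest may only be two levels deep"))
    parents = {t.parent for t in db.types if t.parent is not None}
    leaf_set = name_set - parents
    for i, s in enumerate(db.statements):
        if s.type_name not in name_set:
            out.append(Violation("unknown-statement-type", f"statements[{i}]",
                                 f"type {s.type_name!r} is not declared"))
        elif s.type_name not in leaf_set:
            out.append(Violation(
                "statement-on-supertype", f"statements[{i}]",
                f"statement attached to super-type {s.type_name!r}"))
    all_keys = {s.key for s in enumerate_situations()}
    listed_types: set[str] = set()
    for key, row in db.probabilities.items():
        if key not in all_keys:
            out.append(Violation("unknown-situation-key",
                                 f"probabilities.{key}",
                                 "not one of the nine situations"))
            continue
        for type_name, p in row.items():
            listed_types.add(type_name)
            if type_name not in name_set:
                out.append(Violation(
                    "unknown-type-in-table", f"probabilities.{key}.{type_name}",
                    f"type {type_name!r} is not declared"))
            if not 0.0 <= p <= 1.0:
                out.append(Violation(
                    "probability-out-of-range",
                    f"probabilities.{key}.{type_name}",
                    f"probability {p} outside [0, 1]"))
    for type_name in sorted(listed_types & name_set):
        covered = {k for k in db.probabilities
                   if k in all_keys and type_name in db.probabilities[k]}
        if covered != all_keys:
            missing = sorted(all_keys - covered)
            out.append(Violation(
                "missing-situation", f"probabilities.*.{type_name}",
                f"type {type_name!r} lacks entries for {missing}"))
    for key, value in db.lengths.items():
        if key not in all_keys:
            out.append(Violation("unknown-situation-key", f"lengths.{key}",
                                 "not one of the nine situations"))
        if not (isinstance(value, int) and value > 0):
            out.append(Violation("bad-length", f"lengths.{key}",
                                 f"length {value!r} is not a positive integer"))
    missing_lengths = all_keys - set(db.lengths)
    for key in sorted(missing_lengths):
        out.append(Violation("missing-situation", f"lengths.{key}",
                             "no target length for this situation"))
    for type_name in db.order:
        if type_name not in name_set:
            out.append(Violation("unknown-type-in-order", f"order.{type_name}",
                                 f"type {type_name!r} is not declared"))
    with_statements = {s.type_name for s in db.statements}
    for leaf in sorted(leaf_set & listed_types):
        if leaf not in with_statements:
            out.append(Violation(
                "leaf-without-statement", f"types.{leaf}",
                f"leaf type {leaf!r} has a probability entry but no statement",
                severity="warning"))
    return out


# ---------------------------------------------------------------------------
# Hierarchy queries (module-level, matching the public surface)


def leaves(db: StatementDatabase, type_name: str) -> list[str]:
    """Leaf names under ``type_name``: its children, or itself if childless."""
    children = db.children(type_name)
    return children if children else [type_name]


def statements_for(db: StatementDatabase, type_name: str) -> list[Statement]:
    """All statements of a leaf type, in declaration order."""
    if not db.is_leaf(type_name):
        raise ValueError(
            f"{type_name!r} is a super-type; statements attach only to leaves"
        )
    return [s for s in db.statements if s.type_name == type_name]
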