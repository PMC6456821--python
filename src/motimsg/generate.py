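"""Message composition: pick statement types for a situation, fill, order.

The algorithm, given a situation and a validated statement database:

1.  *Length.*  The target number of statements is read from the length
    table (the rounded mean answer length the experts produced for that
    situation; 3 or 4 in the default table).
2.  *Mandatory types.*  Every type whose probability at the situation
    exceeds the inclusion threshold (default .5) is always included.
    Mandatory super-types are resolved to leaves: all subtypes above the
    threshold, or — if none — one subtype drawn by weighted randomized
    selection over the subtype probabilities.
3.  *Weighted fill.*  While the selection is short of the target length,
    one more leaf is drawn by weighted randomized selection (cumulative
    probability intervals, one uniform draw) over the remaining eligible
    leaves.  A selected leaf blocks itself, its siblings and its super, so
    a message never carries two statements of the same family (e.g. it
    never notes two different trends).
4.  *Realization.*  One stored statement is drawn uniformly per selected
    leaf, and statements are ordered by the order table: noting the
    situation first, then empathy, giving perspective, tackling things
    together; general motivation near the end, only the future after it.

All randomness flows through one explicit :class:`numpy.random.Generator`,
so a fixed seed reproduces the message bit for bit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .database import StatementDatabase, Statement, statements_for
from .situations import Situation

__all__ = [
    "SelectionError",
    "CompositionError",
    "SelectionTrace",
    "GeneratedMessage",
    "target_length",
    "mandatory_types",
    "weighted_select",
    "resolve_supertype",
    "select_types",
    "order_types",
    "compose_message",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Probability above which a statement type is always included.
DEFAULT_THRESHOLD = 0.5


class SelectionError(RuntimeError):
    """Weighted selection was impossible (no candidates / zero weight)."""


class CompositionError(RuntimeError):
    """A selected leaf type has no statement to realize."""


@dataclass
class SelectionTrace:
    """Record of how a message's statement types were chosen."""

    mandatory: set[str] = field(default_factory=set)
    supertype_resolutions: dict[str, list[str]] = field(default_factory=dict)
    filled: list[str] = field(default_factory=list)
    seed: int | None = None


@dataclass
class GeneratedMessage:
    situation: Situation
    statements: list[Statement]
    trace: SelectionTrace

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.statements)

    @property
    def leaf_types(self) -> list[str]:
        return [s.type_name for s in self.statements]


def target_length(situation: Situation, lengths: dict[str, int]) -> int:
    """Target statement count for a situation, from a length table."""
    try:
        return lengths[situation.key]
    except KeyError as exc:
        raise KeyError(f"no target length for situation {situation.key}") from exc


def mandatory_types(
    situation: Situation,
    db: StatementDatabase,
    threshold: float = DEFAULT_THRESHOLD,
) -> set[str]:
    """Types (super or leaf) with probability strictly above ``threshold``."""
    row = db.probabilities.get(situation.key, {})
    return {name for name, p in row.items() if p > threshold}


def weighted_select(
    candidates: Sequence[str],
    weights: Sequence[float],
    rng: np.random.Generator,
) -> str:
    """Weighted randomized selection via cumulative probability intervals.

    Weights are summed, each candidate owns an interval of width equal to
    its weight, and a single uniform draw on [0, total) picks the interval.
    """
    if len(candidates) == 0:
        raise SelectionError("no candidates to select from")
    if len(candidates) != len(weights):
        raise ValueError("candidates and weights must have equal length")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise SelectionError("total selection weight is zero")
    u = rng.uniform(0.0, total)
    edges = np.cumsum(w)
    index = int(np.searchsorted(edges, u, side="right"))
    index = min(index, len(candidates) - 1)  # guard u == total edge case
    return candidates[index]


def resolve_supertype(
    situation: Situation,
    db: StatementDatabase,
    super_name: str,
    rng: np.random.Generator,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[str]:
    """Resolve a super-type to concrete subtypes for a situation.

    All subtypes above the threshold are taken; if none qualifies, exactly
    one subtype is drawn by weighted randomized selection over the subtype
    probabilities.  If every subtype has probability zero the draw falls
    back to a uniform choice (logged), so a mandatory super never silently
    disappears.
    """
    children = db.children(super_name)
    if not children:
        raise ValueError(f"{super_name!r} has no subtypes to resolve")
    probs = {c: db.probability(situation, c) for c in children}
    above = [c for c in children if probs[c] > threshold]
    if above:
        return above
    try:
        return [weighted_select(children, [probs[c] for c in children], rng)]
    except SelectionError:
        logger.warning(
            "all subtypes of %r have zero probability at %s; "
            "falling back to a uniform choice",
            super_name, situation.key,
        )
        return [children[rng.integers(len(children))]]


def _family(db: StatementDatabase, leaf: str) -> set[str]:
    """The leaf, its siblings, and its super (the de-duplication block)."""
    parent = db.type_map()[leaf].parent
    if parent is None:
        return {leaf}
    return {parent, *db.children(parent)}


def select_types(
    situation: Situation,
    db: StatementDatabase,
    rng: np.random.Generator,
    threshold: float = DEFAULT_THRESHOLD,
    trace: SelectionTrace | None = None,
) -> list[str]:
    """Choose the leaf statement types for one message.

    Returns leaves in selection order; ordering for presentation is a
    separate step (:func:`order_types`).  Short selections (no eligible
    positive-weight leaf left) are permitted with a logged warning, as are
    selections exceeding the target when the mandatory set alone is larger.
    """
    if trace is None:
        trace = SelectionTrace()
    target = target_length(situation, db.lengths)
    mandatory = mandatory_types(situation, db, threshold)
    trace.mandatory = set(mandatory)

    selected: list[str] = []
    blocked: set[str] = set()

    def take(leaf: str) -> None:
        selected.append(leaf)
        blocked.update(_family(db, leaf))

    # Mandatory supers first (resolution may consume their mandatory leaves),
    # then mandatory leaves not already covered by a resolved super.
    for name in sorted(mandatory, key=db.declaration_index):
        if not db.is_leaf(name):
            resolved = resolve_supertype(situation, db, name, rng, threshold)
            trace.supertype_resolutions[name] = list(resolved)
            for leaf in resolved:
                if leaf not in selected:
                    take(leaf)
    for name in sorted(mandatory, key=db.declaration_index):
        if db.is_leaf(name) and name not in blocked:
            take(name)

    if len(selected) > target:
        warnings.warn(
            f"mandatory types alone exceed the target length at "
            f"{situation.key} ({len(selected)} > {target}); keeping all",
            RuntimeWarning,
            stacklevel=2,
        )

    while len(selected) < target:
        pool = [
            leaf
            for leaf in db.leaf_names()
            if leaf not in blocked
            and db.probability(situation, leaf) > 0.0
        ]
        if not pool:
            logger.warning(
                "no eligible positive-weight leaf left at %s; emitting a "
                "short message (%d of %d statements)",
                situation.key, len(selected), target,
            )
            break
        pick = weighted_select(
            pool, [db.probability(situation, leaf) for leaf in pool], rng
        )
        trace.filled.append(pick)
        take(pick)
    return selected


def order_types(leaf_names: Sequence[str], db: StatementDatabase) -> list[str]:
    """Stable sort by order-table rank; ties keep database declaration order."""
    return sorted(
        leaf_names,
        key=lambda name: (db.rank(name), db.declaration_index(name)),
    )


def compose_message(
    situation: Situation,
    db: StatementDatabase,
    rng: np.random.Generator | int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> GeneratedMessage:
    """Compose one motivational message for a situation.

    ``rng`` may be a :class:`numpy.random.Generator`, an integer seed, or
    None (fresh entropy).  The same integer seed yields an identical
    message.
    """
    seed: int | None = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng()
    trace = SelectionTrace(seed=seed)
    chosen = select_types(situation, db, rng, threshold, trace)
    ordered = order_types(chosen, db)
    statements: list[Statement] = []
    for leaf in ordered:
        pool = statements_for(db, leaf)
        if not pool:
            raise CompositionError(
                f"selected leaf type {leaf!r} has no statements"
            )
        statements.append(pool[int(rng.integers(len(pool)))])
    return GeneratedMessage(situation=situation, statements=statements,
                            trace=trace)
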