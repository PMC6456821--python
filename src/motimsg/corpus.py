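"""Expert-corpus analysis: occurrence coding, filters, GLMM tables, reliability.

The pipeline mirrors how the statement database is derived from coded
expert answers:

1.  Each answer (one expert, one situation) is a list of coded statements
    ``(text, leaf type)``.  :func:`build_occurrence` turns the corpus into
    a binary answer x type matrix; a super-type column is 1 whenever any
    of its leaves is.
2.  :func:`filter_types` removes rarely used types (fewer than 10 coded
    statement instances by default) and reports the fraction of statement
    instances that survives.
3.  :func:`fit_type_model` fits, per statement type, a random-intercept
    logistic regression (expert intercepts, saturated trend x trust cell
    means) and reads off the population-level probability of the type per
    situation; :func:`derive_probability_table` assembles the full table.
4.  :func:`derive_length_table` rounds the mean statements-per-answer per
    situation (half-up), and :func:`retain_statements` keeps only the
    statements whose type clears a minimum probability (default .05)
    somewhere.

Reliability helpers: :func:`cohens_kappa` (unweighted, marginal-product
expected agreement) for the double-coding check, and :func:`lrt` for
nested-model likelihood-ratio comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .database import Statement, StatementDatabase, StatementType
from .glmm import fit_random_intercept_logit
from .situations import Situation, enumerate_situations

__all__ = [
    "CodedAnswer",
    "OccurrenceMatrix",
    "FittedTypeModel",
    "KappaResult",
    "ModelComparisonResult",
    "build_occurrence",
    "filter_types",
    "fit_type_model",
    "derive_probability_table",
    "derive_length_table",
    "retain_statements",
    "cohens_kappa",
    "lrt",
    "read_corpus_csv",
    "write_corpus_csv",
]


@dataclass(frozen=True)
class CodedAnswer:
    """One expert's coded answer for one situation."""

    expert_id: str
    situation: Situation
    statements: tuple[tuple[str, str], ...]  # (text, leaf type name)
    answer_id: str = "0"

    def __post_init__(self):
        if not self.statements:
            raise ValueError("a coded answer needs at least one statement")


@dataclass
class OccurrenceMatrix:
    """Binary answer x type matrix with expert/situation row metadata."""

    data: pd.DataFrame  # index: (expert_id, answer_id); columns: type names
    situations: pd.Series  # situation key per row, aligned with data.index
    instance_counts: dict[str, int]  # statement instances per type
    leaf_names: list[str] = field(default_factory=list)  # columns statements attach to

    @property
    def type_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class FittedTypeModel:
    type_name: str
    probabilities: dict[str, float]  # situation key -> fitted probability
    intercept_sd: float
    converged: bool


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n: int


@dataclass(frozen=True)
class ModelComparisonResult:
    statistic: float
    df: int
    p_value: float
    label: str = ""
    converged: bool = True


def _forest(types: StatementDatabase | Iterable[StatementType]):
    """Normalize a type collection to (parent map, children map)."""
    if isinstance(types, StatementDatabase):
        types = types.types
    parent = {t.name: t.parent for t in types}
    children: dict[str, list[str]] = {name: [] for name in parent}
    for name, par in parent.items():
        if par is not None:
            if par not in children:
                raise KeyError(f"type {name!r} has undeclared parent {par!r}")
            children[par].append(name)
    return parent, children


# ---------------------------------------------------------------------------
# Occurrence coding and filtering


def build_occurrence(
    corpus: Sequence[CodedAnswer],
    types: StatementDatabase | Iterable[StatementType],
) -> OccurrenceMatrix:
    """Binary presence matrix over answers and statement types.

    A cell is 1 iff the answer contains at least one statement of the type;
    super-type columns OR their leaves.  Statement types appearing in the
    corpus but not declared in ``types`` raise a :class:`KeyError`.
    """
    if not corpus:
        raise ValueError("empty corpus")
    parent, children = _forest(types)
    columns = list(parent)
    rows = []
    index = []
    situations = []
    counts: dict[str, int] = {name: 0 for name in columns}
    for answer in corpus:
        row = dict.fromkeys(columns, 0)
        for _text, type_name in answer.statements:
            if type_name not in parent:
                raise KeyError(
                    f"answer {answer.expert_id}/{answer.answer_id} uses "
                    f"undeclared type {type_name!r}"
                )
            counts[type_name] += 1
            row[type_name] = 1
            par = parent[type_name]
            if par is not None:
                counts[par] += 1
                row[par] = 1
        rows.append(row)
        index.append((answer.expert_id, answer.answer_id))
        situations.append(answer.situation.key)
    frame = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["expert", "answer"])
    )[columns]
    supers = {par for par in parent.values() if par is not None}
    return OccurrenceMatrix(
        data=frame,
        situations=pd.Series(situations, index=frame.index, name="situation"),
        instance_counts=counts,
        leaf_names=[name for name in columns if name not in supers],
    )


def filter_types(
    matrix: OccurrenceMatrix, min_count: int = 10
) -> tuple[OccurrenceMatrix, float]:
    """Drop types with fewer than ``min_count`` coded statement instances.

    Counts are statement *instances* (a statement used twice in one answer
    counts twice), not answers.  Returns the filtered matrix and the
    fraction of leaf statement instances retained — the bookkeeping that
    yields the "97% of statements kept" style summary.
    """
    keep = [
        name
        for name in matrix.type_names
        if matrix.instance_counts.get(name, 0) >= min_count
    ]
    # Retention is bookkept over statement *instances*, which attach to
    # leaves only (super counts duplicate their leaves' instances).
    total = sum(matrix.instance_counts.get(n, 0) for n in matrix.leaf_names)
    retained = sum(
        matrix.instance_counts.get(n, 0)
        for n in matrix.leaf_names
        if n in keep
    )
    fraction = retained / total if total else 0.0
    filtered = OccurrenceMatrix(
        data=matrix.data[keep],
        situations=matrix.situations,
        instance_counts={name: matrix.instance_counts[name] for name in keep},
        leaf_names=[name for name in matrix.leaf_names if name in keep],
    )
    return filtered, fraction


# ---------------------------------------------------------------------------
# Probability / length / statement tables


def _binomial_counts(
    matrix: OccurrenceMatrix, type_name: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-expert, per-situation success and trial counts for one type."""
    if type_name not in matrix.data.columns:
        raise KeyError(f"type {type_name!r} not in occurrence matrix")
    cells = [s.key for s in enumerate_situations()]
    frame = pd.DataFrame({
        "expert": matrix.data.index.get_level_values("expert"),
        "situation": matrix.situations.to_numpy(),
        "y": matrix.data[type_name].to_numpy(),
    })
    grouped = frame.groupby(["expert", "situation"], sort=True)["y"]
    succ = grouped.sum().unstack(fill_value=0)
    tri = grouped.count().unstack(fill_value=0)
    succ = succ.reindex(columns=cells, fill_value=0)
    tri = tri.reindex(columns=cells, fill_value=0)
    return succ.to_numpy(float), tri.to_numpy(float), cells


def fit_type_model(
    matrix: OccurrenceMatrix, type_name: str, n_quad: int = 25
) -> FittedTypeModel:
    """Fit the per-type random-intercept logistic model.

    Expert is the random-intercept unit; the fixed part is the saturated
    trend x trust interaction (nine cell means), so the reported
    population-level probabilities (random intercept at zero) do not
    depend on contrast coding.  Non-convergent or separated fits fall back
    to pooled cell proportions with ``converged=False``.
    """
    successes, trials, cells = _binomial_counts(matrix, type_name)
    if successes.shape[0] < 2:
        raise ValueError("need answers from at least 2 experts")
    result = fit_random_intercept_logit(successes, trials, n_quad=n_quad)
    probs = result.probabilities
    return FittedTypeModel(
        type_name=type_name,
        probabilities={cell: float(p) for cell, p in zip(cells, probs)},
        intercept_sd=float(result.sigma),
        converged=bool(result.converged),
    )


def derive_probability_table(
    corpus: Sequence[CodedAnswer],
    types: StatementDatabase | Iterable[StatementType],
    min_count: int = 10,
    level: str = "both",
    n_quad: int = 25,
) -> dict[str, dict[str, float]]:
    """Full per-situation probability table from a coded corpus.

    ``level`` selects which columns are modelled: ``"leaf"``, ``"super"``,
    or ``"both"`` (whether the source analyses worked at super or leaf
    level is not fixed, so both are available).  The result maps situation
    key -> type -> probability, the format of the database file.
    """
    parent, children = _forest(types)
    matrix = build_occurrence(corpus, types)
    filtered, _fraction = filter_types(matrix, min_count=min_count)
    if not filtered.type_names:
        raise ValueError("no statement types survive the minimum-count filter")
    selected = []
    for name in filtered.type_names:
        is_super = bool(children.get(name))
        if level == "leaf" and is_super:
            continue
        if level == "super" and not is_super:
            continue
        selected.append(name)
    table: dict[str, dict[str, float]] = {
        s.key: {} for s in enumerate_situations()
    }
    for name in selected:
        fit = fit_type_model(filtered, name, n_quad=n_quad)
        for cell, p in fit.probabilities.items():
            table[cell][name] = p
    return table


def derive_length_table(corpus: Sequence[CodedAnswer]) -> dict[str, int]:
    """Rounded (half-up) mean statements per answer, per situation."""
    counts: dict[str, list[int]] = {}
    for answer in corpus:
        counts.setdefault(answer.situation.key, []).append(
            len(answer.statements)
        )
    missing = [
        s.key for s in enumerate_situations() if s.key not in counts
    ]
    if missing:
        raise KeyError(f"no answers for situations: {missing}")
    return {
        key: int(math.floor(np.mean(values) + 0.5))
        for key, values in counts.items()
    }


def retain_statements(
    corpus: Sequence[CodedAnswer],
    table: dict[str, dict[str, float]],
    types: StatementDatabase | Iterable[StatementType],
    threshold: float = 0.05,
) -> list[Statement]:
    """Statements whose type clears ``threshold`` in at least one situation.

    A statement survives if its leaf type — or that leaf's super-type —
    has a probability above the threshold somewhere; identical texts are
    deduplicated (first occurrence wins).
    """
    parent, _children = _forest(types)

    def max_p(name: str) -> float:
        return max(
            (row.get(name, 0.0) for row in table.values()), default=0.0
        )

    kept: list[Statement] = []
    seen_texts: set[str] = set()
    for answer in corpus:
        for text, type_name in answer.statements:
            best = max_p(type_name)
            par = parent.get(type_name)
            if par is not None:
                best = max(best, max_p(par))
            if best > threshold and text not in seen_texts:
                seen_texts.add(text)
                kept.append(Statement(text=text, type_name=type_name))
    return kept


# ---------------------------------------------------------------------------
# Reliability statistics


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa between two coders' label sequences."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("label sequences must be non-empty")
    categories = sorted(set(labels_a) | set(labels_b), key=str)
    index = {c: i for i, c in enumerate(categories)}
    confusion = np.zeros((len(categories), len(categories)))
    for a, b in zip(labels_a, labels_b):
        confusion[index[a], index[b]] += 1
    po = float(np.trace(confusion) / n)
    marg_a = confusion.sum(axis=1) / n
    marg_b = confusion.sum(axis=0) / n
    pe = float(marg_a @ marg_b)
    if pe >= 1.0 - 1e-12:
        raise ZeroDivisionError(
            "expected agreement is 1; kappa is undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(kappa=kappa, observed_agreement=po,
                       expected_agreement=pe, n=n)


def lrt(
    loglik_small: float,
    df_small: int,
    loglik_big: float,
    df_big: int,
    label: str = "",
) -> ModelComparisonResult:
    """Likelihood-ratio test of two nested maximum-likelihood fits."""
    if df_big <= df_small:
        raise ValueError("the larger model must have more parameters")
    if loglik_big < loglik_small - 1e-6:
        raise ValueError(
            "larger model has lower log-likelihood; fits are not nested "
            "or did not converge"
        )
    statistic = max(0.0, 2.0 * (loglik_big - loglik_small))
    df = df_big - df_small
    p = float(stats.chi2.sf(statistic, df))
    return ModelComparisonResult(statistic=statistic, df=df, p_value=p,
                                 label=label)


# ---------------------------------------------------------------------------
# Corpus CSV I/O
#
# Columns: expert_id,trend,trust,answer_id,statement_order,statement_text,
# type_name (UTF-8, header required).


def read_corpus_csv(path: str | Path) -> list[CodedAnswer]:
    frame = pd.read_csv(path, dtype=str)
    required = {
        "expert_id", "trend", "trust", "answer_id",
        "statement_order", "statement_text", "type_name",
    }
    if not required.issubset(frame.columns):
        raise ValueError(f"corpus CSV needs columns {sorted(required)}")
    frame["statement_order"] = frame["statement_order"].astype(int)
    answers = []
    keys = ["expert_id", "trend", "trust", "answer_id"]
    for (expert, trend, trust, answer_id), group in frame.groupby(
        keys, sort=False
    ):
        group = group.sort_values("statement_order")
        answers.append(CodedAnswer(
            expert_id=str(expert),
            situation=Situation.parse(f"{trend}:{trust}"),
            statements=tuple(
                (row.statement_text, row.type_name)
                for row in group.itertuples()
            ),
            answer_id=str(answer_id),
        ))
    return answers


def write_corpus_csv(corpus: Sequence[CodedAnswer], path: str | Path) -> None:
    rows = []
    for answer in corpus:
        for order, (text, type_name) in enumerate(answer.statements, start=1):
            rows.append({
                "expert_id": answer.expert_id,
                "trend": answer.situation.trend.value,
                "trust": answer.situation.trust.value,
                "answer_id": answer.answer_id,
                "statement_order": order,
                "statement_text": text,
                "type_name": type_name,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
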