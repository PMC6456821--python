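"""Synthetic inputs with known ground truth for every other module.

Three generators live here:

- :func:`make_default_database` — a SYNTHETIC statement database.  The
  published statement list and probability table are not distributed with
  the package, so this stand-in encodes every constraint the message
  model states: at (rising, low) the types motivation, give_perspective
  and note_pcl all exceed the .5 inclusion threshold, note_pcl_rising
  exceeds it while no motivation subtype does; note_trust has only low
  and high subtypes (experts never noted medium trust explicitly); target
  lengths are 3 at (dropping, high), (dropping, medium), (stable, high)
  and 4 elsewhere; ordering runs note-situation, empathy,
  give_perspective, together, (other), motivation, future.  Leaf
  probabilities per situation were chosen to sum approximately to the
  situation's target length, the balance an expert answer of that length
  implies.
- :func:`simulate_expert_corpus` — coded expert answers drawn from a known
  probability table with expert-level random intercepts on the log-odds
  scale, the generative mirror of the corpus-analysis model.  Answer
  lengths are forced to the true length table (trim lowest-probability
  inclusions, pad by weighted selection) so the length table is exactly
  recoverable.
- :func:`simulate_user_study` — per-situation change scores from an
  additive effect structure (condition, trend, trust, optional
  interactions) with participant random intercepts and residual noise,
  truncated to the bounded -10..10 analog scale.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .corpus import CodedAnswer
from .database import Statement, StatementDatabase, StatementType
from .generate import weighted_select
from .situations import enumerate_situations
from .study import CONDITIONS, OverallRecord, StudyRecord

__all__ = [
    "ExpertSimSpec",
    "StudySimSpec",
    "make_default_database",
    "simulate_expert_corpus",
    "simulate_user_study",
    "study_records_frame",
]


# ---------------------------------------------------------------------------
# The default (synthetic) database

_TYPES: list[tuple[str, str | None]] = [
    ("note_pcl", None),
    ("note_pcl_dropping", "note_pcl"),
    ("note_pcl_stable", "note_pcl"),
    ("note_pcl_rising", "note_pcl"),
    ("note_trust", None),
    ("note_trust_low", "note_trust"),
    ("note_trust_high", "note_trust"),
    ("empathy", None),
    ("give_perspective", None),
    ("together", None),
    ("compliment", None),
    ("normalize", None),
    ("question", None),
    ("motivation", None),
    ("motivation_hold_on", "motivation"),
    ("motivation_go_on", "motivation"),
    ("motivation_stick_to_it", "motivation"),
    ("future", None),
]

_ORDER: dict[str, int] = {
    "note_pcl": 0, "note_pcl_dropping": 0, "note_pcl_stable": 0,
    "note_pcl_rising": 0,
    "note_trust": 0, "note_trust_low": 0, "note_trust_high": 0,
    "empathy": 10,
    "give_perspective": 20,
    "together": 30,
    "compliment": 40, "normalize": 40, "question": 40,
    "motivation": 50, "motivation_hold_on": 50, "motivation_go_on": 50,
    "motivation_stick_to_it": 50,
    "future": 60,
}

_LENGTHS: dict[str, int] = {
    "dropping:low": 4, "dropping:medium": 3, "dropping:high": 3,
    "stable:low": 4, "stable:medium": 4, "stable:high": 3,
    "rising:low": 4, "rising:medium": 4, "rising:high": 4,
}

# Leaf probabilities per situation.  Hand-tuned synthetic values honouring
# the stated constraints (see the module docstring); per situation they sum
# to roughly the target length.
_LEAF_PROBS: dict[str, dict[str, float]] = {
    "dropping:low": {
        "note_pcl_dropping": 0.80, "note_pcl_stable": 0.02,
        "note_pcl_rising": 0.02, "note_trust_low": 0.50,
        "note_trust_high": 0.02, "empathy": 0.15, "give_perspective": 0.55,
        "together": 0.35, "compliment": 0.10, "normalize": 0.45,
        "question": 0.10, "motivation_hold_on": 0.05,
        "motivation_go_on": 0.45, "motivation_stick_to_it": 0.25,
        "future": 0.30,
    },
    "dropping:medium": {
        "note_pcl_dropping": 0.80, "note_pcl_stable": 0.02,
        "note_pcl_rising": 0.02, "note_trust_low": 0.30,
        "note_trust_high": 0.05, "empathy": 0.08, "give_perspective": 0.30,
        "together": 0.20, "compliment": 0.35, "normalize": 0.20,
        "question": 0.08, "motivation_hold_on": 0.05,
        "motivation_go_on": 0.40, "motivation_stick_to_it": 0.15,
        "future": 0.15,
    },
    "dropping:high": {
        "note_pcl_dropping": 0.80, "note_pcl_stable": 0.02,
        "note_pcl_rising": 0.02, "note_trust_low": 0.02,
        "note_trust_high": 0.48, "empathy": 0.05, "give_perspective": 0.15,
        "together": 0.10, "compliment": 0.60, "normalize": 0.08,
        "question": 0.05, "motivation_hold_on": 0.03,
        "motivation_go_on": 0.45, "motivation_stick_to_it": 0.10,
        "future": 0.20,
    },
    "stable:low": {
        "note_pcl_dropping": 0.02, "note_pcl_stable": 0.80,
        "note_pcl_rising": 0.02, "note_trust_low": 0.45,
        "note_trust_high": 0.02, "empathy": 0.25, "give_perspective": 0.60,
        "together": 0.35, "compliment": 0.08, "normalize": 0.40,
        "question": 0.12, "motivation_hold_on": 0.30,
        "motivation_go_on": 0.10, "motivation_stick_to_it": 0.35,
        "future": 0.25,
    },
    "stable:medium": {
        "note_pcl_dropping": 0.02, "note_pcl_stable": 0.80,
        "note_pcl_rising": 0.02, "note_trust_low": 0.30,
        "note_trust_high": 0.05, "empathy": 0.20, "give_perspective": 0.55,
        "together": 0.30, "compliment": 0.20, "normalize": 0.35,
        "question": 0.12, "motivation_hold_on": 0.25,
        "motivation_go_on": 0.15, "motivation_stick_to_it": 0.30,
        "future": 0.25,
    },
    "stable:high": {
        "note_pcl_dropping": 0.02, "note_pcl_stable": 0.80,
        "note_pcl_rising": 0.02, "note_trust_low": 0.02,
        "note_trust_high": 0.48, "empathy": 0.08, "give_perspective": 0.25,
        "together": 0.15, "compliment": 0.52, "normalize": 0.10,
        "question": 0.08, "motivation_hold_on": 0.10,
        "motivation_go_on": 0.25, "motivation_stick_to_it": 0.15,
        "future": 0.20,
    },
    "rising:low": {
        "note_pcl_dropping": 0.02, "note_pcl_stable": 0.02,
        "note_pcl_rising": 0.80, "note_trust_low": 0.45,
        "note_trust_high": 0.02, "empathy": 0.45, "give_perspective": 0.70,
        "together": 0.30, "compliment": 0.05, "normalize": 0.35,
        "question": 0.10, "motivation_hold_on": 0.40,
        "motivation_go_on": 0.05, "motivation_stick_to_it": 0.35,
        "future": 0.00,
    },
    "rising:medium": {
        "note_pcl_dropping": 0.02, "note_pcl_stable": 0.02,
        "note_pcl_rising": 0.80, "note_trust_low": 0.30,
        "note_trust_high": 0.05, "empathy": 0.55, "give_perspective": 0.65,
        "together": 0.30, "compliment": 0.08, "normalize": 0.40,
        "question": 0.10, "motivation_hold_on": 0.35,
        "motivation_go_on": 0.05, "motivation_stick_to_it": 0.30,
        "future": 0.10,
    },
    "rising:high": {
        "note_pcl_dropping": 0.02, "note_pcl_stable": 0.02,
        "note_pcl_rising": 0.80, "note_trust_low": 0.03,
        "note_trust_high": 0.45, "empathy": 0.40, "give_perspective": 0.60,
        "together": 0.30, "compliment": 0.20, "normalize": 0.30,
        "question": 0.10, "motivation_hold_on": 0.35,
        "motivation_go_on": 0.05, "motivation_stick_to_it": 0.30,
        "future": 0.15,
    },
}

# Super-type probabilities (fit separately from data in the real pipeline,
# so they are stated directly rather than derived from the leaves).
_SUPER_PROBS: dict[str, dict[str, float]] = {
    "note_pcl": {key: 0.85 for key in _LENGTHS},
    "note_trust": {
        "dropping:low": 0.48, "dropping:medium": 0.34, "dropping:high": 0.48,
        "stable:low": 0.45, "stable:medium": 0.34, "stable:high": 0.45,
        "rising:low": 0.46, "rising:medium": 0.34, "rising:high": 0.46,
    },
    "motivation": {
        "dropping:low": 0.50, "dropping:medium": 0.55, "dropping:high": 0.50,
        "stable:low": 0.55, "stable:medium": 0.50, "stable:high": 0.45,
        "rising:low": 0.65, "rising:medium": 0.50, "rising:high": 0.55,
    },
}

# Synthetic statements, three per leaf, authored for this stand-in database.
_STATEMENTS: dict[str, list[str]] = {
    "note_pcl_dropping": [
        "I can see from your scores that your complaints have been decreasing.",
        "Your questionnaire shows your symptoms are coming down.",
        "The graph of your scores shows a clear improvement.",
    ],
    "note_pcl_stable": [
        "Your scores have stayed about the same over the past sessions.",
        "I see little change in your complaints from session to session.",
        "Your symptom scores are holding steady at the moment.",
    ],
    "note_pcl_rising": [
        "I can see from your scores that your complaints have increased.",
        "Your questionnaire shows your symptoms have been getting worse.",
        "The graph shows a rise in your symptom scores lately.",
    ],
    "note_trust_low": [
        "You indicated that you have little confidence in a good result right now.",
        "I see that you doubt whether this treatment will work out for you.",
        "You mentioned not having much trust in a good outcome.",
    ],
    "note_trust_high": [
        "You indicated that you are confident about a good outcome.",
        "I see that you trust this treatment will work out for you.",
        "You mentioned having good faith in where this is going.",
    ],
    "empathy": [
        "I am sorry to hear that.",
        "That sounds really difficult.",
        "I understand this is hard for you.",
    ],
    "give_perspective": [
        "It is often hard work before results become visible.",
        "Complaints can get worse for a while before they start to improve.",
        "This phase of the treatment is demanding for almost everyone.",
    ],
    "together": [
        "Let's look together at what you need to keep going.",
        "We will work through this together.",
        "Together we can find a way that works for you.",
    ],
    "compliment": [
        "You are doing really well.",
        "You have been working hard, and it shows.",
        "You should be proud of what you have achieved so far.",
    ],
    "normalize": [
        "It is completely normal to find this phase difficult.",
        "Many people feel exactly this way at this point in the treatment.",
        "Doubts like these are a common part of therapy.",
    ],
    "question": [
        "What would help you to keep going?",
        "Shall we look at what makes this hard for you?",
        "What do you need right now to continue?",
    ],
    "motivation_hold_on": [
        "Hold on!",
        "Keep holding on, even when it is tough.",
        "Try to hang in there.",
    ],
    "motivation_go_on": [
        "Go on like this!",
        "Keep up this good progress.",
        "Continue just the way you are going.",
    ],
    "motivation_stick_to_it": [
        "Stick with it!",
        "It is important to stay with the program now.",
        "Keep at it, session by session.",
    ],
    "future": [
        "Things will get better.",
        "There are better days ahead of you.",
        "In time, these complaints will fade.",
    ],
}


def make_default_database(seed: int = 0) -> StatementDatabase:
    """Build the bundled synthetic statement database.

    The content is fixed (the seed is accepted for interface symmetry with
    the other generators but the database is deterministic).  See the
    module docstring for the constraints it encodes.
    """
    del seed  # content is fixed; parameter kept for a uniform interface
    probabilities: dict[str, dict[str, float]] = {}
    for key in _LENGTHS:
        row = dict(_LEAF_PROBS[key])
        for super_name, per_situation in _SUPER_PROBS.items():
            row[super_name] = per_situation[key]
        probabilities[key] = row
    statements = [
        Statement(text=text, type_name=leaf)
        for leaf, texts in _STATEMENTS.items()
        for text in texts
    ]
    return StatementDatabase(
        types=[StatementType(name, parent) for name, parent in _TYPES],
        statements=statements,
        probabilities=probabilities,
        lengths=dict(_LENGTHS),
        order=dict(_ORDER),
        meta={
            "name": "motimsg-default",
            "synthetic": True,
            "language": "en",
            "note": (
                "Synthetic stand-in database; statements and probabilities "
                "are illustrative, not the published expert-derived tables."
            ),
        },
    )


# ---------------------------------------------------------------------------
# Expert-corpus simulation


@dataclass
class ExpertSimSpec:
    """Generative settings for a coded expert corpus.

    ``true_table`` maps situation key -> leaf type -> inclusion
    probability (log-odds conditional on a zero intercept);
    ``answers_per_situation`` defaults to 2, each situation shown twice.
    ``intercept_sd`` is the expert random-intercept SD on the log-odds
    scale.
    """

    true_table: Mapping[str, Mapping[str, float]]
    true_lengths: Mapping[str, int]
    n_experts: int = 13
    answers_per_situation: int = 2
    intercept_sd: float = 0.5
    seed: int = 0
    force_lengths: bool = True

    def __post_init__(self):
        if self.n_experts < 1:
            raise ValueError("need at least one expert")
        if self.intercept_sd < 0:
            raise ValueError("intercept_sd must be non-negative")


def simulate_expert_corpus(spec: ExpertSimSpec) -> list[CodedAnswer]:
    """Draw a coded corpus from a known leaf-probability table.

    Per expert a normal random intercept (sd ``intercept_sd``) shifts every
    leaf's log-odds; per answer each leaf is included independently with
    the shifted probability.  With ``force_lengths`` (default) the
    statement count of each answer is then forced to the true length
    table: lowest-probability inclusions are trimmed first, and missing
    slots are padded by weighted selection over the excluded leaves, so
    the length table is exactly recoverable from the corpus.
    """
    rng = np.random.default_rng(spec.seed)
    situations = enumerate_situations()
    leaf_names = sorted({
        name for row in spec.true_table.values() for name in row
    })
    corpus: list[CodedAnswer] = []
    for e in range(spec.n_experts):
        expert_id = f"expert{e + 1:03d}"
        intercept = rng.normal(0.0, spec.intercept_sd) if spec.intercept_sd else 0.0
        for situation in situations:
            row = spec.true_table[situation.key]
            probs = {}
            for name in leaf_names:
                p = float(row.get(name, 0.0))
                p = min(max(p, 1e-9), 1 - 1e-9)
                probs[name] = float(expit(logit(p) + intercept))
            for a in range(spec.answers_per_situation):
                included = [
                    name for name in leaf_names
                    if rng.random() < probs[name]
                ]
                if spec.force_lengths:
                    target = int(spec.true_lengths[situation.key])
                    included = _force_length(
                        included, probs, target, rng
                    )
                if not included:
                    # Degenerate draw with forcing disabled: keep the single
                    # most probable leaf so the answer is non-empty.
                    included = [max(probs, key=probs.get)]
                statements = tuple(
                    (_statement_text(name, rng), name) for name in included
                )
                corpus.append(CodedAnswer(
                    expert_id=expert_id,
                    situation=situation,
                    statements=statements,
                    answer_id=f"{situation.key}#{a + 1}",
                ))
    return corpus


def _force_length(
    included: list[str],
    probs: Mapping[str, float],
    target: int,
    rng: np.random.Generator,
) -> list[str]:
    included = sorted(included, key=lambda n: probs[n], reverse=True)
    if len(included) > target:
        return included[:target]
    pool = [n for n in probs if n not in included and probs[n] > 1e-6]
    while len(included) < target and pool:
        pick = weighted_select(pool, [probs[n] for n in pool], rng)
        included.append(pick)
        pool.remove(pick)
    return included


def _statement_text(type_name: str, rng: np.random.Generator) -> str:
    variant = int(rng.integers(1, 4))
    return f"[synthetic] {type_name} statement v{variant}"


# ---------------------------------------------------------------------------
# User-study simulation


@dataclass
class StudySimSpec:
    """Effect structure for a simulated 3 x 3 x 3 mixed-design study.

    Scores are ``grand_mean + condition + trend + trust + interaction +
    participant intercept + residual``, truncated to the bounded
    [-10, 10] analog scale.  Default noise levels (participant SD 1.5,
    residual SD 2.5) are illustrative moderate values for a bounded
    -10..10 change scale; the source study reports no raw-scale effect
    sizes to copy.
    """

    n_participants: int = 207
    grand_mean: float = 0.0
    condition_effects: Mapping[str, float] = field(default_factory=dict)
    trend_effects: Mapping[str, float] = field(default_factory=dict)
    trust_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )  # keys: (condition, trend) or (condition, trust) or (trend, trust)
    participant_sd: float = 1.5
    residual_sd: float = 2.5
    outcome_correlation: float = 0.6  # between motivation and trust residuals
    fbh_loading_sd: float = 0.5  # item noise around the participant FBH level
    seed: int = 0


def simulate_user_study(
    spec: StudySimSpec,
) -> tuple[list[StudyRecord], list[OverallRecord]]:
    """Simulate per-situation and overall records for the mixed design.

    Participants are assigned to the three message-type conditions in
    balanced round-robin order; each sees all nine situations.  Both
    outcomes (motivation / trust change) share the effect structure and
    have correlated residuals.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    situations = enumerate_situations()
    records: list[StudyRecord] = []
    overall: list[OverallRecord] = []
    cov = np.array([
        [1.0, spec.outcome_correlation],
        [spec.outcome_correlation, 1.0],
    ]) * spec.residual_sd**2
    chol = np.linalg.cholesky(cov) if spec.residual_sd > 0 else np.zeros((2, 2))
    for i in range(spec.n_participants):
        pid = f"p{i + 1:04d}"
        condition = CONDITIONS[i % len(CONDITIONS)]
        intercept = (
            rng.normal(0.0, spec.participant_sd) if spec.participant_sd else 0.0
        )
        d_mot_all = []
        d_tru_all = []
        for situation in situations:
            mean = (
                spec.grand_mean
                + spec.condition_effects.get(condition, 0.0)
                + spec.trend_effects.get(situation.trend.value, 0.0)
                + spec.trust_effects.get(situation.trust.value, 0.0)
                + spec.interaction_effects.get(
                    (condition, situation.trend.value), 0.0)
                + spec.interaction_effects.get(
                    (condition, situation.trust.value), 0.0)
                + spec.interaction_effects.get(
                    (situation.trend.value, situation.trust.value), 0.0)
                + intercept
            )
            noise = chol @ rng.standard_normal(2)
            d_mot = float(np.clip(mean + noise[0], -10, 10))
            d_tru = float(np.clip(mean + noise[1], -10, 10))
            d_mot_all.append(d_mot)
            d_tru_all.append(d_tru)
            records.append(StudyRecord(
                participant_id=pid, condition=condition,
                trend=situation.trend.value, trust=situation.trust.value,
                d_motivation=d_mot, d_trust=d_tru,
            ))
        fbh_level = float(np.mean(d_mot_all))
        fbh_items = tuple(
            float(np.clip(fbh_level + rng.normal(0.0, spec.fbh_loading_sd),
                          -10, 10))
            for _ in range(7)
        )
        overall.append(OverallRecord(
            participant_id=pid, condition=condition,
            overall_d_motivation=float(np.clip(np.mean(d_mot_all), -10, 10)),
            overall_d_trust=float(np.clip(np.mean(d_tru_all), -10, 10)),
            fbh_items=fbh_items,
        ))
    return records, overall


def study_records_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Convenience: StudyRecord list -> analysis-ready DataFrame."""
    return pd.DataFrame([r.__dict__ for r in records])
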