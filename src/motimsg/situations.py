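"""Situation model: symptom trend, initial trust, and the brief PCL.

A patient's *situation* is summarized by two ordinal labels: the direction
of their brief PCL (PTSD Checklist) symptom-score trend across therapy
sessions (dropping / stable / rising) and their self-rated initial trust in
a good therapy outcome (low / medium / high).  The cross of the two label
sets gives nine situations, and every downstream table (probabilities,
message lengths) is keyed by them.

The brief PCL used here consists of items 2, 3, 6, 7, 16 and 17 of the full
checklist, each answered on an ordinal scale (1-5 by default).  A response
gives a summed severity score plus a screening indication: the respondent
screens positive when at least one item of each symptom-cluster pair
(2/3, 6/7, 16/17) is rated 3 or higher.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trend",
    "Trust",
    "Situation",
    "BriefPCLScore",
    "BRIEF_PCL_ITEMS",
    "enumerate_situations",
    "classify_trend",
    "score_brief_pcl",
    "read_pcl_series",
    "read_brief_pcl_response",
]


class Trend(str, enum.Enum):
    """Direction of the summed brief-PCL score across sessions."""

    DROPPING = "dropping"
    STABLE = "stable"
    RISING = "rising"


class Trust(str, enum.Enum):
    """Initial trust in a good therapy outcome."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass(frozen=True, order=True)
class Situation:
    """One of the nine (trend, trust) cells conditioning message generation."""

    trend: Trend
    trust: Trust

    @property
    def key(self) -> str:
        """Canonical string key ``"<trend>:<trust>"`` used in table files."""
        return f"{self.trend.value}:{self.trust.value}"

    @classmethod
    def parse(cls, key: str) -> "Situation":
        """Parse a ``"trend:trust"`` key (e.g. ``"rising:low"``)."""
        try:
            trend_s, trust_s = key.split(":")
            return cls(Trend(trend_s), Trust(trust_s))
        except ValueError as exc:
            raise ValueError(f"not a valid situation key: {key!r}") from exc

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


#: Item numbers of the brief PCL, in canonical order.
BRIEF_PCL_ITEMS: tuple[int, ...] = (2, 3, 6, 7, 16, 17)


class BriefPCLScore(NamedTuple):
    total: int
    ptsd_indication: bool


def enumerate_situations() -> list[Situation]:
    """All nine situations, trend-major then trust, in a fixed order.

    The order is ``dropping < stable < rising`` crossed with
    ``low < medium < high`` — the declaration order of the two enums.
    """
    return [Situation(trend, trust) for trend in Trend for trust in Trust]


def classify_trend(
    scores: Sequence[float],
    stable_band: float = 0.5,
) -> Trend:
    """Classify a per-session PCL score series into a trend label.

    The series is reduced to its ordinary least-squares slope in
    score-points per session.  Slopes below ``-stable_band`` are *dropping*,
    above ``+stable_band`` *rising*, and anything in between *stable*.  The
    label is invariant to adding a constant to every score.

    Parameters
    ----------
    scores
        Summed brief-PCL scores, one per session, in session order.
    stable_band
        Half-width of the slope interval labelled stable, in score-points
        per session.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("trend classification needs at least 2 sessions")
    if stable_band < 0:
        raise ValueError("stable_band must be non-negative")
    sessions = np.arange(1, scores.size + 1, dtype=float)
    slope = np.polyfit(sessions, scores, 1)[0]
    if slope < -stable_band:
        return Trend.DROPPING
    if slope > stable_band:
        return Trend.RISING
    return Trend.STABLE


def score_brief_pcl(
    item_scores: Mapping[int, int],
    item_scale: tuple[int, int] = (1, 5),
) -> BriefPCLScore:
    """Score a brief-PCL response and apply the screening rule.

    The indication is positive iff each of the item pairs (2, 3), (6, 7)
    and (16, 17) contains at least one rating of 3 or higher.

    Parameters
    ----------
    item_scores
        Map from item number (must be exactly the six brief-PCL items) to
        the ordinal rating.
    item_scale
        Inclusive (low, high) bounds of the rating scale.
    """
    lo, hi = item_scale
    got = set(item_scores)
    expected = set(BRIEF_PCL_ITEMS)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"brief PCL response must have exactly items {sorted(expected)}; "
            f"missing={missing} unexpected={extra}"
        )
    for item, score in item_scores.items():
        if not isinstance(score, (int, np.integer)) or not lo <= score <= hi:
            raise ValueError(
                f"item {item} score {score!r} outside scale [{lo}, {hi}]"
            )
    total = int(sum(item_scores[i] for i in BRIEF_PCL_ITEMS))
    indication = all(
        max(item_scores[a], item_scores[b]) >= 3
        for a, b in ((2, 3), (6, 7), (16, 17))
    )
    return BriefPCLScore(total=total, ptsd_indication=indication)


def read_pcl_series(path: str | Path) -> np.ndarray:
    """Read a per-session PCL score series from a two-column CSV.

    The file must have a header with columns ``session`` (1-based,
    consecutive) and ``score``; scores are returned in session order.
    """
    frame = pd.read_csv(path)
    required = {"session", "score"}
    if not required.issubset(frame.columns):
        raise ValueError(f"PCL series CSV needs columns {sorted(required)}")
    frame = frame.sort_values("session")
    sessions = frame["session"].to_numpy()
    if not np.array_equal(sessions, np.arange(1, len(sessions) + 1)):
        raise ValueError("sessions must be consecutive integers starting at 1")
    return frame["score"].to_numpy(dtype=float)


def read_brief_pcl_response(path: str | Path) -> dict[int, int]:
    """Read a brief-PCL response from a JSON ``{"item": score}`` map."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return {int(item): int(score) for item, score in raw.items()}
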