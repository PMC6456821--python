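"""User-study statistics: power, deviation tests, reliability, model ladder.

The evaluation design is a 3 x 3 x 3 mixed layout: message type
(personalized / general / none) between subjects, and the nine situations
(PCL trend x initial trust) within subjects, with change scores for
*motivation to continue* and *trust in a good outcome* on bounded -10..10
analog scales.

Provided here:

- :func:`anova_power_n` — a priori total sample size for a one-way
  fixed-effects ANOVA via the noncentral-F power function (the G*Power
  style calculation; balanced allocation by default).
- :func:`one_sample_t` and :func:`cronbach_alpha` — the deviation-from-zero
  test for the overall change scores and the internal-consistency check
  for the 7-item feeling-of-being-heard scale.
- :func:`fit_ladder` — the nested model-comparison ladder M0..M7 on the
  per-situation data: random participant intercept throughout, fixed
  effects added in the order message type, PCL trend, initial trust,
  trust x trend, message x trend, message x trust, three-way.  All models
  are fit by maximum likelihood (not REML) so the likelihood-ratio tests
  on fixed effects are valid.
- :func:`posthoc_pairwise` — refits on each two-level subset of a factor
  and reports the pairwise contrast.  No multiplicity correction is
  applied by default; a Bonferroni flag is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .corpus import ModelComparisonResult, lrt

__all__ = [
    "CONDITIONS",
    "StudyRecord",
    "OverallRecord",
    "LadderResult",
    "PairwiseContrast",
    "anova_power",
    "anova_power_n",
    "one_sample_t",
    "cronbach_alpha",
    "fit_ladder",
    "posthoc_pairwise",
    "records_to_frame",
    "read_records_csv",
    "read_overall_csv",
    "LADDER_STEPS",
]

CONDITIONS = ("personalized", "general", "none")


@dataclass(frozen=True)
class StudyRecord:
    """Per-participant, per-situation change scores."""

    participant_id: str
    condition: str
    trend: str
    trust: str
    d_motivation: float
    d_trust: float


@dataclass(frozen=True)
class OverallRecord:
    """End-of-study overall change scores and feeling-of-being-heard items."""

    participant_id: str
    condition: str
    overall_d_motivation: float
    overall_d_trust: float
    fbh_items: tuple[float, ...]  # 7 items; averaged into one scale score

    @property
    def fbh_score(self) -> float:
        return float(np.mean(self.fbh_items))


@dataclass
class LadderResult:
    outcome: str
    steps: list[ModelComparisonResult]
    loglikelihoods: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class PairwiseContrast:
    level_a: str
    level_b: str
    estimate: float  # mean(level_b) - mean(level_a), model-based
    ci_low: float
    ci_high: float
    p_value: float


# ---------------------------------------------------------------------------
# A priori power analysis


def anova_power(
    n_total: int, k_groups: int, cohens_f: float, alpha: float
) -> float:
    """Power of the one-way fixed-effects ANOVA F test at total size N.

    Uses noncentrality ``lambda = f^2 * N`` with ``df1 = k - 1`` and
    ``df2 = N - k``.
    """
    if n_total <= k_groups:
        return 0.0
    df1, df2 = k_groups - 1, n_total - k_groups
    crit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, cohens_f**2 * n_total))


def anova_power_n(
    k_groups: int,
    cohens_f: float,
    alpha: float = 0.05,
    power: float = 0.9,
    balanced: bool = True,
    n_max: int = 1_000_000,
) -> int:
    """Smallest total N reaching the target power for a one-way ANOVA.

    With ``balanced=True`` (the default, and what a G*Power-style a priori
    calculation assumes) only totals divisible by ``k_groups`` are
    considered, i.e. equal group sizes; ``balanced=False`` scans every
    integer.
    """
    if k_groups < 2:
        raise ValueError("need at least 2 groups")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie strictly in (0, 1)")
    if cohens_f <= 0:
        raise ValueError(
            "effect size must be positive: with f = 0 power never exceeds "
            "alpha and no finite N suffices"
        )
    step = k_groups if balanced else 1
    start = k_groups + 1
    if balanced:
        start = 2 * k_groups  # at least 2 per group
    n = start if start % step == 0 or not balanced else start + (
        step - start % step
    )
    while n <= n_max:
        if anova_power(n, k_groups, cohens_f, alpha) >= power:
            return n
        n += step
    raise RuntimeError(f"no N <= {n_max} reaches the target power")


# ---------------------------------------------------------------------------
# Simple tests and reliability


def one_sample_t(
    values: Sequence[float], mu0: float = 0.0
) -> tuple[float, int, float]:
    """Classical one-sample t test against ``mu0``; two-sided p."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic is undefined")
    df = x.size - 1
    t = float((x.mean() - mu0) / (sd / np.sqrt(x.size)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(var_items)/var(total))``."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need a respondents x items matrix, >= 2 of each")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of the summed scale")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


# ---------------------------------------------------------------------------
# The model-comparison ladder

#: (label, fixed-effects formula, cumulative fixed-effect df) for M0..M7.
LADDER_STEPS: list[tuple[str, str]] = [
    ("M0", "1"),
    ("M1", "C(condition)"),
    ("M2", "C(condition) + C(trend)"),
    ("M3", "C(condition) + C(trend) + C(trust)"),
    ("M4", "C(condition) + C(trend) + C(trust) + C(trust):C(trend)"),
    ("M5", "C(condition) + C(trend) + C(trust) + C(trust):C(trend)"
           " + C(condition):C(trend)"),
    ("M6", "C(condition) + C(trend) + C(trust) + C(trust):C(trend)"
           " + C(condition):C(trend) + C(condition):C(trust)"),
    ("M7", "C(condition) * C(trend) * C(trust)"),
]


def records_to_frame(records) -> pd.DataFrame:
    """Normalize study records (frame or StudyRecord list) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame([r.__dict__ for r in records])
    required = {
        "participant_id", "condition", "trend", "trust",
        "d_motivation", "d_trust",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"study records lack columns {sorted(missing)}")
    return frame


def _outcome_column(outcome: str) -> str:
    try:
        return {"motivation": "d_motivation", "trust": "d_trust"}[outcome]
    except KeyError:
        raise ValueError("outcome must be 'motivation' or 'trust'")


def _fit_mixed(formula: str, frame: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, frame, groups=frame["participant_id"])
        last_error: Exception | None = None
        for method in (None, "bfgs", "powell"):
            try:
                if method is None:
                    return model.fit(reml=False)
                return model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_error = exc
        raise last_error


def fit_ladder(records, outcome: str = "motivation") -> LadderResult:
    """Fit M0..M7 by ML and return the seven likelihood-ratio comparisons.

    Every model keeps a random participant intercept; the degrees of
    freedom of each comparison are those of the added fixed-effect terms
    (2, 2, 2, 4, 4, 4, 8 for three-level factors).  A step whose larger
    model fails to improve the likelihood numerically is reported with the
    statistic clamped at zero and flagged not converged.
    """
    frame = records_to_frame(records)
    if frame["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    cells = set(map(tuple, frame[["trend", "trust"]].drop_duplicates().values))
    if len(cells) < 9:
        raise ValueError("all 9 situations must be represented")
    column = _outcome_column(outcome)
    fits = []
    dfs = []
    for _label, fixed in LADDER_STEPS:
        result = _fit_mixed(f"{column} ~ {fixed}", frame)
        fits.append(result)
        dfs.append(int(result.k_fe))  # fixed-effect parameter count
    steps: list[ModelComparisonResult] = []
    lls = [float(f.llf) for f in fits]
    for i in range(1, len(fits)):
        label = f"M{i - 1}vsM{i}"
        try:
            step = lrt(lls[i - 1], dfs[i - 1], lls[i], dfs[i], label=label)
        except ValueError:
            # Numerical non-improvement: fall back to the preceding model.
            step = ModelComparisonResult(
                statistic=0.0, df=dfs[i] - dfs[i - 1], p_value=1.0,
                label=label, converged=False,
            )
            lls[i] = lls[i - 1]
        steps.append(step)
    return LadderResult(outcome=outcome, steps=steps, loglikelihoods=lls)


def posthoc_pairwise(
    records,
    factor: str = "condition",
    outcome: str = "motivation",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[PairwiseContrast]:
    """Pairwise contrasts from refits on each two-level subset of a factor.

    Each pair of factor levels is analyzed in isolation with the same
    random-participant-intercept model; the reported estimate is the
    model-based difference (second level minus first), with a Wald
    interval and p value.  ``bonferroni=True`` widens intervals and
    adjusts p for the number of pairs.
    """
    frame = records_to_frame(records)
    if factor not in frame.columns:
        raise KeyError(f"unknown factor {factor!r}")
    column = _outcome_column(outcome)
    levels = list(pd.unique(frame[factor]))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    pairs = [
        (levels[i], levels[j])
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
    ]
    m = len(pairs)
    contrasts = []
    for a, b in pairs:
        subset = frame[frame[factor].isin([a, b])].copy()
        if subset[factor].nunique() < 2:
            raise KeyError(f"level without data among {a!r}, {b!r}")
        subset["_level"] = (subset[factor] == b).astype(int)
        result = _fit_mixed(f"{column} ~ _level", subset)
        est = float(result.params["_level"])
        se = float(result.bse["_level"])
        p = float(result.pvalues["_level"])
        level_alpha = alpha / m if bonferroni else alpha
        z = stats.norm.ppf(1 - level_alpha / 2)
        if bonferroni:
            p = min(1.0, p * m)
        contrasts.append(PairwiseContrast(
            level_a=str(a), level_b=str(b), estimate=est,
            ci_low=est - z * se, ci_high=est + z * se, p_value=p,
        ))
    return contrasts


# ---------------------------------------------------------------------------
# CSV I/O


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Per-situation records CSV: participant_id, condition, trend, trust,
    d_motivation, d_trust."""
    frame = pd.read_csv(path)
    return records_to_frame(frame)


def read_overall_csv(path: str | Path) -> list[OverallRecord]:
    """Overall records CSV with fbh_item1..fbh_item7 columns."""
    frame = pd.read_csv(path)
    item_cols = [f"fbh_item{i}" for i in range(1, 8)]
    required = {
        "participant_id", "condition",
        "overall_d_motivation", "overall_d_trust", *item_cols,
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"overall CSV lacks columns {sorted(missing)}")
    return [
        OverallRecord(
            participant_id=str(row.participant_id),
            condition=str(row.condition),
            overall_d_motivation=float(row.overall_d_motivation),
            overall_d_trust=float(row.overall_d_trust),
            fbh_items=tuple(
                float(getattr(row, col)) for col in item_cols
            ),
        )
        for row in frame.itertuples()
    ]
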