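"""CAN scoring: individual-level consequence/norm sensitivity and overall
action preference.

Given a participant's four cell action probabilities the three scores are
pure algebra, no model fitting involved::

    C = (p1 - p2 + p3 - p4) / 2      consequence sensitivity, in [-1, 1]
    N = (p3 - p1 + p4 - p2) / 2      norm sensitivity,        in [-1, 1]
    A = (p1 + p2 + p3 + p4) / 4      overall action preference, in [0, 1]

C averages the benefit-greater minus benefit-smaller contrast over the two
norm conditions; N averages the prescriptive minus proscriptive contrast
over the two consequence conditions; A is the grand mean action rate.
Because the scores are per participant they feed directly into t tests,
correlations and any other conventional analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Battery, CellProbabilities

__all__ = [
    "CANParameters",
    "can_parameters",
    "can_scores",
    "ParameterTest",
    "GroupSummary",
    "group_summary",
    "Classification",
    "classify_group",
]

PARAMETER_NULLS = {"C": 0.0, "N": 0.0, "A": 0.5}


@dataclass(frozen=True)
class CANParameters:
    """Individual CAN scores; C and N live in [-1, 1], A in [0, 1]."""

    C: float
    N: float
    A: float

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.N, self.A], dtype=float)


def can_parameters(cells: CellProbabilities) -> CANParameters:
    """Exact algebraic CAN scores from one participant's cell probabilities."""
    p1, p2, p3, p4 = cells.as_array()
    return CANParameters(
        C=(p1 - p2 + p3 - p4) / 2.0,
        N=(p3 - p1 + p4 - p2) / 2.0,
        A=(p1 + p2 + p3 + p4) / 4.0,
    )


def can_scores(battery: Battery) -> pd.DataFrame:
    """Score every participant in a battery.

    Returns one row per participant with columns ``participant, p1..p4,
    C, N, A`` plus ``group`` / ``trait`` when the battery carries them.
    """
    frame = battery.cell_probabilities_frame()
    frame["C"] = (frame.p1 - frame.p2 + frame.p3 - frame.p4) / 2.0
    frame["N"] = (frame.p3 - frame.p1 + frame.p4 - frame.p2) / 2.0
    frame["A"] = (frame.p1 + frame.p2 + frame.p3 + frame.p4) / 4.0
    return frame


@dataclass(frozen=True)
class ParameterTest:
    """One-sample two-tailed t test of a CAN score against its null value
    (0 for C and N, 0.5 for A)."""

    parameter: str
    null_value: float
    n: int
    mean: float
    sd: float
    se: float
    t: float
    df: int
    p_value: float
    degenerate: bool  # zero sample variance: t undefined

    @property
    def significant_mean_shift(self) -> bool | None:
        """Whether the mean differs from the null; ``None`` while degenerate
        with mean exactly at the null (no evidence either way)."""
        if self.degenerate:
            return self.mean != self.null_value
        return None


@dataclass(frozen=True)
class GroupSummary:
    n: int
    tests: dict  # parameter -> ParameterTest

    def __getitem__(self, parameter: str) -> ParameterTest:
        return self.tests[parameter]


def _one_sample(values: np.ndarray, parameter: str) -> ParameterTest:
    null = PARAMETER_NULLS[parameter]
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return ParameterTest(parameter, null, n, mean, 0.0, 0.0,
                             float("nan"), n - 1, float("nan"), True)
    se = sd / np.sqrt(n)
    t = (mean - null) / se
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return ParameterTest(parameter, null, n, mean, sd, float(se),
                         float(t), n - 1, p, False)


def group_summary(scores) -> GroupSummary:
    """Means, SDs and one-sample tests (C vs 0, N vs 0, A vs 0.5).

    ``scores`` is either the frame from :func:`can_scores` or an iterable
    of :class:`CANParameters`.  Requires n >= 2 (no variance estimate
    otherwise); all-identical samples are flagged degenerate rather than
    producing an infinite t.
    """
    if isinstance(scores, pd.DataFrame):
        values = {p: scores[p].to_numpy(dtype=float) for p in ("C", "N", "A")}
    else:
        arr = np.array([s.as_array() for s in scores], dtype=float)
        if arr.ndim != 2:
            raise ValueError("need a sequence of CANParameters")
        values = {p: arr[:, j] for j, p in enumerate(("C", "N", "A"))}
    n = len(values["C"])
    if n < 2:
        raise ValueError("group_summary needs at least 2 participants")
    return GroupSummary(n=n, tests={p: _one_sample(v, p) for p, v in values.items()})


@dataclass(frozen=True)
class Classification:
    """Qualitative reading of a group's mean CAN profile.

    ``summary`` is ``pure_morality`` when the group is neutral overall
    (A not different from 0.5) yet sensitive to at least one moral
    principle, ``random`` when neutral and insensitive to both, and
    ``mixed`` otherwise.
    """

    consequence_label: str  # supporting | opposing | insensitive
    norm_label: str  # supporting | opposing | insensitive
    overall_label: str  # action_preference | inaction_preference | neutral
    summary: str  # mixed | pure_morality | random


def _signed_label(test: ParameterTest, alpha: float,
                  positive: str, negative: str, neutral: str) -> str:
    if test.degenerate:
        significant = test.mean != test.null_value
    else:
        significant = test.p_value < alpha
    if not significant:
        return neutral
    return positive if test.mean > test.null_value else negative


def classify_group(summary: GroupSummary, alpha: float = 0.05) -> Classification:
    """Apply the sign-and-significance decision rules at level ``alpha``."""
    c_label = _signed_label(summary["C"], alpha, "supporting", "opposing",
                            "insensitive")
    n_label = _signed_label(summary["N"], alpha, "supporting", "opposing",
                            "insensitive")
    a_label = _signed_label(summary["A"], alpha, "action_preference",
                            "inaction_preference", "neutral")
    if a_label == "neutral":
        if c_label == "insensitive" and n_label == "insensitive":
            overall = "random"
        else:
            overall = "pure_morality"
    else:
        overall = "mixed"
    return Classification(c_label, n_label, a_label, overall)
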