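"""Side-by-side group comparison of the tree-model and CAN pipelines.

For a two-group battery the harness runs, per parameter, the ΔG²
likelihood-ratio test on the group-level CNI fit and the independent-
samples t test on the individual CAN scores, flags whether the two
frameworks reach the same conclusion, checks the algebraic identities
linking the two parameterizations, and (when a trait column is present)
computes Pearson correlations between the trait and the individual
C/N/A scores.

The identities being checked, writing ``C̄, N̄, Ā`` for mean CAN scores
and ``C*, N*, I*`` for the fitted CNI parameters:

* H1 — ``C̄ ≈ C*`` (the two C definitions coincide algebraically);
* H2 — ``N* ≈ N̄ / (1 − C*)`` (the sequential tree inflates N);
* H3 — ``Ā − 0.5`` and ``I* − 0.5`` have opposite signs
  (``Ā − 0.5 = (1−C)(1−N)(0.5−I)`` for tree-generated cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .can import can_scores
from .data import Battery
from .mpt import ConstraintTest, FitResult, delta_g2_test, fit_model

__all__ = [
    "TwoSampleResult",
    "compare_groups_can",
    "compare_groups_cni",
    "HypothesisChecks",
    "run_hypothesis_checks",
    "CorrelationResult",
    "correlate_traits",
    "ComparisonRow",
    "ComparisonReport",
    "build_comparison_report",
]

#: CNI parameter paired with the CAN score playing the analogous role
PARAMETER_PAIRING = {"C": "C", "N": "N", "I": "A"}


@dataclass(frozen=True)
class TwoSampleResult:
    parameter: str
    groups: tuple
    means: tuple
    t: float
    df: int
    p_value: float
    cohens_d: float
    n: tuple


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    return float(np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                         / (len(a) + len(b) - 2)))


def compare_groups_can(
    battery: Battery,
    group_column: str = "group",
    welch: bool = False,
) -> dict[str, TwoSampleResult]:
    """Independent-samples t tests on individual C, N, A between two groups.

    Pooled-variance Student's t by default (df = n1 + n2 − 2), Welch's
    correction behind the ``welch`` flag; Cohen's d always uses the pooled
    SD.  Exactly two groups are required — run pairwise for more.
    """
    scores = can_scores(battery)
    if group_column not in scores.columns:
        raise KeyError(f"no such column: {group_column}")
    labels = sorted(scores[group_column].dropna().unique())
    if len(labels) != 2:
        raise ValueError(
            f"expected exactly 2 groups, found {len(labels)}: {labels};"
            " compare pairs of groups separately"
        )
    out = {}
    for param in ("C", "N", "A"):
        a = scores.loc[scores[group_column] == labels[0], param].to_numpy(float)
        b = scores.loc[scores[group_column] == labels[1], param].to_numpy(float)
        res = stats.ttest_ind(a, b, equal_var=not welch)
        sp = _pooled_sd(a, b)
        d = (a.mean() - b.mean()) / sp if sp > 0 else (
            0.0 if a.mean() == b.mean() else float("inf"))
        out[param] = TwoSampleResult(
            parameter=param,
            groups=tuple(labels),
            means=(float(a.mean()), float(b.mean())),
            t=float(res.statistic),
            df=int(round(res.df)),
            p_value=float(res.pvalue) if sp > 0 else (1.0 if d == 0 else 0.0),
            cohens_d=float(d),
            n=(len(a), len(b)),
        )
    return out


def compare_groups_cni(
    battery: Battery,
    group_column: str = "group",
    model: str = "cni",
) -> dict[str, ConstraintTest]:
    """Per-parameter ΔG² equality tests between the two groups' tree fits."""
    counts = battery.counts_by_group(group_column)
    if len(counts) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(counts)}")
    from .mpt import _get_model  # parameter names of the chosen tree

    names = _get_model(model).param_names
    return {p: delta_g2_test(counts, model=model, parameter=p) for p in names}


@dataclass(frozen=True)
class HypothesisChecks:
    """Numeric agreement checks between the CNI fit and mean CAN scores."""

    evaluable: bool
    c_can: float
    c_cni: float
    n_can: float
    n_cni: float
    a_can: float
    i_cni: float
    h1_discrepancy: float  # |C̄ − C*|
    h2_discrepancy: float  # |N* − N̄/(1 − C*)|
    h3_reversed: bool | None  # sign(Ā−0.5) opposite sign(I*−0.5); None at boundary
    boundary_tol: float
    fit: FitResult | None = None
    note: str = ""


def run_hypothesis_checks(
    battery: Battery,
    boundary_tol: float = 1e-3,
) -> HypothesisChecks:
    """Fit the CNI tree to the pooled counts and compare with CAN means."""
    scores = can_scores(battery)
    c_can = float(scores["C"].mean())
    n_can = float(scores["N"].mean())
    a_can = float(scores["A"].mean())
    fit = fit_model(battery.aggregate_counts(), model="cni")
    est = fit.estimate()
    if not fit.converged:
        return HypothesisChecks(
            evaluable=False, c_can=c_can, c_cni=float("nan"), n_can=n_can,
            n_cni=float("nan"), a_can=a_can, i_cni=float("nan"),
            h1_discrepancy=float("nan"), h2_discrepancy=float("nan"),
            h3_reversed=None, boundary_tol=boundary_tol, fit=fit,
            note="CNI fit did not converge",
        )
    h1 = abs(c_can - est.C)
    if 1.0 - est.C < boundary_tol:
        h2 = float("nan")
        note = "C at 1: N̄/(1−C) undefined"
    else:
        h2 = abs(est.N - n_can / (1.0 - est.C))
        note = ""
    da = a_can - 0.5
    di = est.I - 0.5
    if abs(da) < boundary_tol or abs(di) < boundary_tol:
        h3: bool | None = None  # boundary case: both at 0.5
    else:
        h3 = bool((da > 0) != (di > 0))
    return HypothesisChecks(
        evaluable=True, c_can=c_can, c_cni=float(est.C), n_can=n_can,
        n_cni=float(est.N), a_can=a_can, i_cni=float(est.I),
        h1_discrepancy=float(h1), h2_discrepancy=float(h2), h3_reversed=h3,
        boundary_tol=boundary_tol, fit=fit, note=note,
    )


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def correlate_traits(
    battery: Battery,
    trait_column: str = "trait",
) -> dict[str, CorrelationResult]:
    """Pearson correlation of a trait with each individual CAN score.

    Participants without a trait value are dropped listwise; a trait or
    score with zero variance yields a degenerate (NaN) result rather than
    an error.
    """
    scores = can_scores(battery)
    if trait_column not in scores.columns:
        raise KeyError(f"no such column: {trait_column}")
    scores = scores.dropna(subset=[trait_column])
    if len(scores) < 3:
        raise ValueError("need trait values for at least 3 participants")
    trait = scores[trait_column].to_numpy(float)
    out = {}
    for param in ("C", "N", "A"):
        x = scores[param].to_numpy(float)
        if np.std(trait) == 0 or np.std(x) == 0:
            out[param] = CorrelationResult(param, float("nan"), float("nan"),
                                           len(x), degenerate=True)
            continue
        r, p = stats.pearsonr(trait, x)
        out[param] = CorrelationResult(param, float(r), float(p), len(x))
    return out


@dataclass(frozen=True)
class ComparisonRow:
    """One parameter's group test in both frameworks."""

    cni_parameter: str
    delta_g2: float
    df_cni: int
    p_cni: float
    cohens_w: float
    can_parameter: str
    t: float
    df_can: int
    p_can: float
    cohens_d: float
    agreement: bool


@dataclass(frozen=True)
class ComparisonReport:
    groups: tuple
    alpha: float
    rows: tuple
    hypothesis_checks: HypothesisChecks
    correlations: dict | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_text(self) -> str:
        g1, g2 = self.groups
        lines = [
            f"Group comparison: {g1} vs {g2} (alpha = {self.alpha:g})",
            f"{'CNI':>4} {'dG2':>8} {'df':>3} {'p':>8} | "
            f"{'CAN':>4} {'t':>8} {'df':>4} {'p':>8} {'d':>7} | agree",
        ]
        for r in self.rows:
            lines.append(
                f"{r.cni_parameter:>4} {r.delta_g2:8.2f} {r.df_cni:>3} "
                f"{r.p_cni:8.4f} | {r.can_parameter:>4} {r.t:8.2f} "
                f"{r.df_can:>4} {r.p_can:8.4f} {r.cohens_d:7.3f} | "
                f"{'yes' if r.agreement else 'NO'}"
            )
        hc = self.hypothesis_checks
        if hc.evaluable:
            h3 = {True: "reversed", False: "NOT reversed", None: "boundary"}[
                hc.h3_reversed]
            lines += [
                "",
                f"H1  |mean C_CAN - C_CNI|        = {hc.h1_discrepancy:.4f}",
                f"H2  |N_CNI - N_CAN/(1-C_CNI)|   = {hc.h2_discrepancy:.4f}",
                f"H3  sign(A-0.5) vs sign(I-0.5)  : {h3}",
            ]
        if self.correlations:
            lines.append("")
            for param, res in self.correlations.items():
                lines.append(
                    f"trait ~ {param}: r = {res.r:+.3f}, p = {res.p_value:.4f},"
                    f" n = {res.n}"
                )
        return "\n".join(lines)


def build_comparison_report(
    battery: Battery,
    group_column: str = "group",
    trait_column: str | None = None,
    alpha: float = 0.05,
    model: str = "cni",
) -> ComparisonReport:
    """Assemble the full two-framework comparison for a two-group battery."""
    cni_tests = compare_groups_cni(battery, group_column, model=model)
    can_tests = compare_groups_can(battery, group_column)
    rows = []
    pairing = {p: p if p in ("C", "N") else "A" for p in cni_tests}
    for cni_param, can_param in pairing.items():
        g2_test = cni_tests[cni_param]
        t_test = can_tests[can_param]
        agreement = (g2_test.p_value < alpha) == (t_test.p_value < alpha)
        rows.append(
            ComparisonRow(
                cni_parameter=cni_param,
                delta_g2=g2_test.delta_g2,
                df_cni=g2_test.df,
                p_cni=g2_test.p_value,
                cohens_w=g2_test.cohens_w,
                can_parameter=can_param,
                t=t_test.t,
                df_can=t_test.df,
                p_can=t_test.p_value,
                cohens_d=t_test.cohens_d,
                agreement=agreement,
            )
        )
    correlations = None
    if trait_column is not None:
        correlations = correlate_traits(battery, trait_column)
    groups = tuple(sorted(battery.df[group_column].dropna().unique()))
    return ComparisonReport(
        groups=groups,
        alpha=alpha,
        rows=tuple(rows),
        hypothesis_checks=run_hypothesis_checks(battery),
        correlations=correlations,
    )
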