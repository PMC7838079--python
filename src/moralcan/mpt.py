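"""Multinomial-processing-tree models of moral-dilemma responses.

Three three-parameter trees map latent probabilities onto the four cell
action probabilities ``(p1, p2, p3, p4)`` defined in :mod:`moralcan.data`:

* **CNI** — consequences first, then norms, then a generalized
  inaction/action stage::

      p1 = C + (1-C)(1-N)(1-I)
      p2 =     (1-C)(1-N)(1-I)
      p3 = C + (1-C)N + (1-C)(1-N)(1-I)
      p4 =     (1-C)N + (1-C)(1-N)(1-I)

* **NCI** — the same stages with norms considered before consequences::

      p1 = (1-N)C + (1-N)(1-C)(1-I)
      p2 =          (1-N)(1-C)(1-I)
      p3 = N + (1-N)C + (1-N)(1-C)(1-I)
      p4 = N +          (1-N)(1-C)(1-I)

* **DNA** — norm and consequence drives act in parallel: with probability
  D the choice is principle-driven (norm-dominant with probability N),
  otherwise an overall action preference A applies::

      p1 = (1-D)A + D(1-N)
      p2 = (1-D)A
      p3 = (1-D)A + D
      p4 = (1-D)A + DN

Fitting maximizes the product-binomial likelihood of aggregated
action/inaction counts over the four cells (per group), reports the G²
deviance against the saturated model, and supports likelihood-ratio
(ΔG²) tests of equality constraints across groups or point constraints
on single parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .data import CellCounts, CellProbabilities

__all__ = [
    "CNIParameters",
    "NCIParameters",
    "DNAParameters",
    "FitResult",
    "ConstraintTest",
    "MODELS",
    "cni_forward",
    "nci_forward",
    "dna_forward",
    "cni_invert",
    "nci_invert",
    "dna_invert",
    "fit_model",
    "delta_g2_test",
    "g2_grid_minimum",
]

_EPS = 1e-6  # parameter box during optimization
_BOUNDARY_TOL = 1e-4


class DegenerateParameterizationError(ValueError):
    """Closed-form inversion hit a zero denominator (boundary parameters)."""


class InconsistentCellsError(ValueError):
    """Cell probabilities violate the tree's structural equality."""


class OptimizationError(RuntimeError):
    """The optimizer failed to produce a valid (non-negative ΔG²) solution."""


# -- parameter containers ---------------------------------------------------


@dataclass(frozen=True)
class CNIParameters:
    C: float
    N: float
    I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.N, self.I], dtype=float)


@dataclass(frozen=True)
class NCIParameters:
    N: float
    C: float
    I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.C, self.I], dtype=float)


@dataclass(frozen=True)
class DNAParameters:
    D: float
    N: float
    A: float

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.N, self.A], dtype=float)


def _validate_range(theta: np.ndarray, names: Sequence[str]) -> None:
    t = np.asarray(theta, dtype=float)
    lo = t.reshape(len(names), -1).min(axis=1)
    hi = t.reshape(len(names), -1).max(axis=1)
    for name, a, b in zip(names, lo, hi):
        if a < 0.0 or b > 1.0:
            raise ValueError(f"parameter {name} outside [0, 1]")


# -- forward maps (vectorized over trailing axes) ---------------------------


def _cni_cells(theta: np.ndarray) -> np.ndarray:
    c, n, i = theta
    q2 = (1 - c) * (1 - n) * (1 - i)
    u = (1 - c) * n
    return np.stack([c + q2, q2 + np.zeros_like(c + n + i), c + u + q2, u + q2])


def _nci_cells(theta: np.ndarray) -> np.ndarray:
    n, c, i = theta
    s = (1 - n) * c
    q2 = (1 - n) * (1 - c) * (1 - i)
    return np.stack([s + q2, q2 + np.zeros_like(s), n + s + q2, n + q2])


def _dna_cells(theta: np.ndarray) -> np.ndarray:
    d, n, a = theta
    b = (1 - d) * a
    return np.stack([b + d * (1 - n), b + np.zeros_like(n), b + d, b + d * n])


def _cni_jacobian(theta: np.ndarray) -> np.ndarray:
    c, n, i = theta
    dq2 = np.array([-(1 - n) * (1 - i), -(1 - c) * (1 - i), -(1 - c) * (1 - n)])
    du = np.array([-n, 1 - c, 0.0])
    e1 = np.array([1.0, 0.0, 0.0])
    return np.stack([e1 + dq2, dq2, e1 + du + dq2, du + dq2])


def _nci_jacobian(theta: np.ndarray) -> np.ndarray:
    n, c, i = theta
    ds = np.array([-c, 1 - n, 0.0])
    dq2 = np.array([-(1 - c) * (1 - i), -(1 - n) * (1 - i), -(1 - n) * (1 - c)])
    e1 = np.array([1.0, 0.0, 0.0])
    return np.stack([ds + dq2, dq2, e1 + ds + dq2, e1 + dq2])


def _dna_jacobian(theta: np.ndarray) -> np.ndarray:
    d, n, a = theta
    db = np.array([-a, 0.0, 1 - d])
    return np.stack(
        [
            db + np.array([1 - n, -d, 0.0]),
            db,
            db + np.array([1.0, 0.0, 0.0]),
            db + np.array([n, d, 0.0]),
        ]
    )


# -- closed-form inversions -------------------------------------------------


def _cni_invert_array(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    p1, p2, p3, p4 = p
    d_pro = p1 - p2
    d_pre = p3 - p4
    if abs(d_pro - d_pre) > tol:
        raise InconsistentCellsError(
            "cells inconsistent with the CNI tree: p1-p2 = "
            f"{d_pro:.6g} but p3-p4 = {d_pre:.6g}"
        )
    c = (d_pro + d_pre) / 2.0
    denom = 2.0 - p1 + p2 - p3 + p4  # = 2(1-C)
    if abs(denom) <= tol:
        raise DegenerateParameterizationError(
            "C = 1: the N denominator 2 - p1 + p2 - p3 + p4 is zero"
        )
    n = (-p1 - p2 + p3 + p4) / denom
    rem = (1.0 - c) * (1.0 - n)
    if abs(rem) <= tol:
        raise DegenerateParameterizationError(
            "N = 1 (or C = 1): the I denominator (1-C)(1-N) is zero"
        )
    i = 1.0 - p2 / rem
    return np.array([c, n, i])


def _nci_invert_array(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    p1, p2, p3, p4 = p
    d_gt = p3 - p1
    d_lt = p4 - p2
    if abs(d_gt - d_lt) > tol:
        raise InconsistentCellsError(
            "cells inconsistent with the NCI tree: p3-p1 = "
            f"{d_gt:.6g} but p4-p2 = {d_lt:.6g}"
        )
    n = (d_gt + d_lt) / 2.0
    if abs(1.0 - n) <= tol:
        raise DegenerateParameterizationError("N = 1: the C denominator is zero")
    c = (p1 - p2 + p3 - p4) / (2.0 * (1.0 - n))
    rem = (1.0 - n) * (1.0 - c)
    if abs(rem) <= tol:
        raise DegenerateParameterizationError("C = 1: the I denominator is zero")
    i = 1.0 - p2 / rem
    return np.array([n, c, i])


def _dna_invert_array(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    p1, p2, p3, p4 = p
    d_direct = p3 - p2
    d_sum = (p1 - p2) + (p4 - p2)
    if abs(d_direct - d_sum) > tol:
        raise InconsistentCellsError(
            "cells inconsistent with the DNA tree: p3-p2 = "
            f"{d_direct:.6g} but (p1-p2)+(p4-p2) = {d_sum:.6g}"
        )
    d = d_direct
    if abs(d) <= tol:
        raise DegenerateParameterizationError("D = 0: N is unidentified")
    n = (p4 - p2) / d
    if abs(1.0 - d) <= tol:
        raise DegenerateParameterizationError("D = 1: A is unidentified")
    a = p2 / (1.0 - d)
    return np.array([d, n, a])


# -- model registry ---------------------------------------------------------


@dataclass(frozen=True)
class TreeModel:
    name: str
    param_names: tuple[str, str, str]
    forward: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    invert: Callable[[np.ndarray], np.ndarray]
    container: type
    #: attainable [lo, hi] interval of each cell probability when the first
    #: parameter is fixed and the other two range over [0, 1]
    slice_ranges: Callable[[float], tuple] = None


def _cni_slice_ranges(c: float):
    return ((c, 1.0), (0.0, 1.0 - c), (c, 1.0), (0.0, 1.0 - c))


def _nci_slice_ranges(n: float):
    return ((0.0, 1.0 - n), (0.0, 1.0 - n), (n, 1.0), (n, 1.0))


def _dna_slice_ranges(d: float):
    return ((0.0, 1.0), (0.0, 1.0 - d), (d, 1.0), (0.0, 1.0))


MODELS: dict[str, TreeModel] = {
    "cni": TreeModel("cni", ("C", "N", "I"), _cni_cells, _cni_jacobian,
                     _cni_invert_array, CNIParameters, _cni_slice_ranges),
    "nci": TreeModel("nci", ("N", "C", "I"), _nci_cells, _nci_jacobian,
                     _nci_invert_array, NCIParameters, _nci_slice_ranges),
    "dna": TreeModel("dna", ("D", "N", "A"), _dna_cells, _dna_jacobian,
                     _dna_invert_array, DNAParameters, _dna_slice_ranges),
}


def _get_model(model: str | TreeModel) -> TreeModel:
    if isinstance(model, TreeModel):
        return model
    try:
        return MODELS[model.lower()]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")


def _as_theta(params, model: TreeModel) -> np.ndarray:
    if isinstance(params, (CNIParameters, NCIParameters, DNAParameters)):
        theta = params.as_array()
    else:
        theta = np.asarray(params, dtype=float)
    if theta.shape[0] != 3:
        raise ValueError("expected 3 parameters")
    _validate_range(theta, model.param_names)
    return theta


def cni_forward(params) -> CellProbabilities:
    """Cell probabilities implied by CNI parameters ``(C, N, I)``."""
    return CellProbabilities.from_array(_cni_cells(_as_theta(params, MODELS["cni"])))


def nci_forward(params) -> CellProbabilities:
    """Cell probabilities implied by NCI parameters ``(N, C, I)``."""
    return CellProbabilities.from_array(_nci_cells(_as_theta(params, MODELS["nci"])))


def dna_forward(params) -> CellProbabilities:
    """Cell probabilities implied by DNA parameters ``(D, N, A)``."""
    return CellProbabilities.from_array(_dna_cells(_as_theta(params, MODELS["dna"])))


def cni_invert(cells: CellProbabilities) -> CNIParameters:
    """Closed-form CNI parameters from cell probabilities.

    Uses ``C = ((p1-p2) + (p3-p4))/2``,
    ``N = (-p1 - p2 + p3 + p4) / (2 - p1 + p2 - p3 + p4)`` and
    ``I = 1 - p2 / ((1-C)(1-N))``; exact round trip with
    :func:`cni_forward` for interior parameters.
    """
    return CNIParameters(*_cni_invert_array(cells.as_array()))


def nci_invert(cells: CellProbabilities) -> NCIParameters:
    """Closed-form NCI parameters (norms-first tree) from cell probabilities."""
    return NCIParameters(*_nci_invert_array(cells.as_array()))


def dna_invert(cells: CellProbabilities) -> DNAParameters:
    """Closed-form DNA parameters (parallel-drive tree) from cell probabilities."""
    return DNAParameters(*_dna_invert_array(cells.as_array()))


# -- likelihood machinery ---------------------------------------------------


def _counts_arrays(counts: CellCounts) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(counts.actions, dtype=float)
    n = np.asarray(counts.totals, dtype=float)
    return a, n - a


def _saturated_loglik(counts: CellCounts) -> float:
    a, b = _counts_arrays(counts)
    n = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(a > 0, a * np.log(a / n), 0.0) + np.where(
            b > 0, b * np.log(b / n), 0.0
        )
    return float(ll.sum())


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one tree model to one or more groups."""

    model: str
    estimates: dict  # group label -> parameter container
    g2: float
    df: int
    p_value: float
    log_likelihood: float
    converged: bool
    n_starts_used: int
    boundary_parameters: tuple = ()
    constraints: dict = field(default_factory=dict)

    def estimate(self, group=None):
        if group is None and len(self.estimates) == 1:
            return next(iter(self.estimates.values()))
        return self.estimates[group]


@dataclass(frozen=True)
class ConstraintTest:
    """Likelihood-ratio (ΔG²) test of a nested constraint."""

    model: str
    constraint: str
    delta_g2: float
    df: int
    p_value: float
    unconstrained: FitResult
    constrained: FitResult
    cohens_w: float


class _ParameterLayout:
    """Maps the free optimization vector onto per-group parameter triples.

    ``constraints`` maps a parameter name to ``"equal"`` (shared across
    groups) or to a float (fixed for every group).
    """

    def __init__(self, model: TreeModel, group_labels: Sequence,
                 constraints: Mapping | None):
        self.model = model
        self.groups = list(group_labels)
        self.constraints = dict(constraints or {})
        for name in self.constraints:
            if name not in model.param_names:
                raise ValueError(
                    f"unknown parameter {name!r} for model {model.name};"
                    f" expected one of {model.param_names}"
                )
        self.slots: dict[tuple, int] = {}  # (group, param) -> free index
        self.fixed: dict[tuple, float] = {}
        idx = 0
        shared: dict[str, int] = {}
        for g in self.groups:
            for name in model.param_names:
                spec = self.constraints.get(name)
                if spec is None:
                    self.slots[(g, name)] = idx
                    idx += 1
                elif spec == "equal":
                    if name not in shared:
                        shared[name] = idx
                        idx += 1
                    self.slots[(g, name)] = shared[name]
                else:
                    value = float(spec)
                    if not 0.0 <= value <= 1.0:
                        raise ValueError(f"fixed value for {name} outside [0, 1]")
                    self.fixed[(g, name)] = value
        self.n_free = idx

    def theta(self, x: np.ndarray) -> dict:
        """Free vector (probability scale) -> {group: (3,) array}."""
        out = {}
        for g in self.groups:
            t = np.empty(3)
            for j, name in enumerate(self.model.param_names):
                key = (g, name)
                t[j] = x[self.slots[key]] if key in self.slots else self.fixed[key]
            out[g] = t
        return out

    def n_constraints(self) -> int:
        per_equal = max(len(self.groups) - 1, 0)
        n = 0
        for name, spec in self.constraints.items():
            n += per_equal if spec == "equal" else len(self.groups)
        return n


def _nll_and_grad(x: np.ndarray, layout: _ParameterLayout,
                  counts: Mapping) -> tuple[float, np.ndarray]:
    theta_by_group = layout.theta(special.expit(x))
    nll = 0.0
    grad_p = np.zeros(layout.n_free)  # gradient on the probability scale
    for g, theta in theta_by_group.items():
        a, b = _counts_arrays(counts[g])
        q = layout.model.forward(theta)
        q = np.clip(q, 1e-12, 1 - 1e-12)
        nll -= float(a @ np.log(q) + b @ np.log(1 - q))
        w = a / q - b / (1 - q)  # d loglik / d q_i
        contrib = -(w @ layout.model.jacobian(theta))
        for j, name in enumerate(layout.model.param_names):
            key = (g, name)
            if key in layout.slots:
                grad_p[layout.slots[key]] += contrib[j]
    sig = special.expit(x)
    return nll, grad_p * sig * (1 - sig)


def _default_starts(layout: _ParameterLayout, counts: Mapping) -> list[np.ndarray]:
    """Fixed 3x3x3 interior grid plus the clamped closed-form inversion of
    the observed proportions (per group; shared slots get the mean)."""
    grid_values = (0.25, 0.5, 0.75)
    starts = []
    for combo in itertools.product(grid_values, repeat=3):
        x = np.empty(layout.n_free)
        for (g, name), idx in layout.slots.items():
            x[idx] = combo[layout.model.param_names.index(name)]
        starts.append(x)

    inv = np.full(layout.n_free, np.nan)
    weight = np.zeros(layout.n_free)
    for g in layout.groups:
        p = np.clip(counts[g].proportions.as_array(), 0.02, 0.98)
        try:
            theta = layout.model.invert(p)
        except (InconsistentCellsError, DegenerateParameterizationError):
            # proportions rarely sit exactly on the tree manifold; project
            # the structural differences onto their average first
            p1, p2, p3, p4 = p
            if layout.model.name == "cni":
                c = ((p1 - p2) + (p3 - p4)) / 2
                shift = (p1 - p2 - c) / 2
                p = np.array([p1 - shift, p2 + shift, p3 + shift, p4 - shift])
            try:
                theta = layout.model.invert(np.clip(p, 0.02, 0.98))
            except (InconsistentCellsError, DegenerateParameterizationError):
                theta = np.full(3, 0.5)
        theta = np.clip(theta, 0.02, 0.98)
        for j, name in enumerate(layout.model.param_names):
            key = (g, name)
            if key in layout.slots:
                idx = layout.slots[key]
                if np.isnan(inv[idx]):
                    inv[idx] = 0.0
                inv[idx] += theta[j]
                weight[idx] += 1.0
    inv = np.where(weight > 0, inv / np.maximum(weight, 1), 0.5)
    starts.append(inv)
    return starts


def _fit_layout(layout: _ParameterLayout, counts: Mapping,
                extra_starts: Sequence[np.ndarray] = (),
                starts: Sequence[np.ndarray] | None = None):
    start_list = list(starts) if starts is not None else _default_starts(layout, counts)
    start_list = start_list + [np.asarray(s, dtype=float) for s in extra_starts]
    best = None
    converged = False
    for x0 in start_list:
        x0 = np.clip(x0, _EPS, 1 - _EPS)
        res = optimize.minimize(
            _nll_and_grad,
            special.logit(x0),
            args=(layout, counts),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)
    return best, converged, len(start_list)


def fit_model(
    counts,
    model: str | TreeModel = "cni",
    constraints: Mapping | None = None,
    starts: Sequence[np.ndarray] | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Fit a processing tree to aggregated cell counts by maximum likelihood.

    Parameters
    ----------
    counts
        A single :class:`~moralcan.data.CellCounts` or a mapping
        ``{group label: CellCounts}`` fit jointly.
    model
        ``"cni"``, ``"nci"`` or ``"dna"``.
    constraints
        Optional mapping ``{parameter name: "equal" | value}``; ``"equal"``
        ties the parameter across groups, a float fixes it in every group.
    starts, extra_starts
        Override or augment the fixed multi-start set (probability scale).

    Returns
    -------
    FitResult
        With G² against the saturated model, ``df = 4·groups − free
        parameters``, and a chi-square upper-tail p-value.
    """
    tree = _get_model(model)
    if isinstance(counts, CellCounts):
        counts_map: Mapping = {None: counts}
    else:
        counts_map = dict(counts)
        if not counts_map:
            raise ValueError("no groups to fit")
    layout = _ParameterLayout(tree, list(counts_map), constraints)
    best, converged, n_starts = _fit_layout(
        layout, counts_map, extra_starts=extra_starts, starts=starts
    )

    theta_by_group = layout.theta(special.expit(best.x))
    ll_sat = sum(_saturated_loglik(c) for c in counts_map.values())
    log_lik = -float(best.fun)
    g2 = max(2.0 * (ll_sat - log_lik), 0.0)
    df = 4 * len(counts_map) - layout.n_free
    p_value = float(stats.chi2.sf(g2, df)) if df > 0 else float("nan")

    boundary = tuple(
        (g, name)
        for (g, name), idx in layout.slots.items()
        if min(special.expit(best.x[idx]), 1 - special.expit(best.x[idx]))
        < _BOUNDARY_TOL
    )
    estimates = {
        g: tree.container(*np.round(theta, 12)) for g, theta in theta_by_group.items()
    }
    return FitResult(
        model=tree.name,
        estimates=estimates,
        g2=float(g2),
        df=int(df),
        p_value=p_value,
        log_likelihood=log_lik,
        converged=converged,
        n_starts_used=n_starts,
        boundary_parameters=boundary,
        constraints=dict(constraints or {}),
    )


def delta_g2_test(
    counts_by_group,
    model: str | TreeModel = "cni",
    parameter: str = "N",
    value: float | None = None,
) -> ConstraintTest:
    """Likelihood-ratio test of one parameter constraint.

    With ``value=None``, ``counts_by_group`` must hold at least two groups
    and the parameter is forced equal across them (df = groups − 1).  With
    a ``value``, the parameter is fixed to it (df = number of groups,
    typically one group).

    The constrained fit reuses the unconstrained optimum as a warm start.
    A ΔG² below −1e−6 after retrying with a denser start grid raises
    :class:`OptimizationError`; smaller negatives round to zero.
    """
    tree = _get_model(model)
    if isinstance(counts_by_group, CellCounts):
        counts_by_group = {None: counts_by_group}
    counts_map = dict(counts_by_group)
    if value is None and len(counts_map) < 2:
        raise ValueError("equality constraint needs at least two groups")

    free = fit_model(counts_map, tree)
    constraint = {parameter: "equal" if value is None else float(value)}

    warm_layout = _ParameterLayout(tree, list(counts_map), constraint)
    warm = np.empty(warm_layout.n_free)
    theta_free = {g: free.estimates[g].as_array() for g in counts_map}
    fill = np.zeros(warm_layout.n_free)
    for (g, name), idx in warm_layout.slots.items():
        j = tree.param_names.index(name)
        if fill[idx] == 0:
            warm[idx] = 0.0
        warm[idx] += theta_free[g][j]
        fill[idx] += 1
    warm = warm / np.maximum(fill, 1)

    constrained = fit_model(counts_map, tree, constraints=constraint,
                            extra_starts=[warm])
    delta = constrained.g2 - free.g2
    if delta < -1e-6:
        dense = [
            np.full(warm_layout.n_free, v) for v in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        constrained = fit_model(counts_map, tree, constraints=constraint,
                                extra_starts=[warm] + dense)
        delta = constrained.g2 - free.g2
        if delta < -1e-6:
            raise OptimizationError(
                f"constrained G² below unconstrained by {-delta:.3g};"
                " increase the number of starts"
            )
    delta = max(delta, 0.0)
    df = warm_layout.n_constraints()
    total_n = sum(sum(c.totals) for c in counts_map.values())
    label = (
        f"{parameter} equal across groups"
        if value is None
        else f"{parameter} = {float(value):g}"
    )
    return ConstraintTest(
        model=tree.name,
        constraint=label,
        delta_g2=float(delta),
        df=int(df),
        p_value=float(stats.chi2.sf(delta, df)),
        unconstrained=free,
        constrained=constrained,
        cohens_w=float(np.sqrt(delta / total_n)),
    )


# -- brute-force reference --------------------------------------------------


def _binom_ll_in_range(a: np.ndarray, b: np.ndarray, lo: float, hi: float
                       ) -> np.ndarray:
    """max over q in [lo, hi] of a·ln q + b·ln(1-q), per instance (0·ln 0 = 0)."""
    n = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.clip(np.where(n > 0, a / n, 0.5), max(lo, 0.0), min(hi, 1.0))
        ll = np.where(a > 0, a * np.log(np.clip(q, 1e-300, None)), 0.0) + np.where(
            b > 0, b * np.log(np.clip(1 - q, 1e-300, None)), 0.0
        )
    return ll


def _grid_pass(tree, grid1, inner, A32, B32, best, ll_slice_bound,
               slack, chunk):
    """One exhaustive sweep over ``grid1`` x ``inner`` slices, updating
    ``best`` in place; slices that provably cannot improve any instance
    (per-cell likelihood bound below the running best) are skipped."""
    t2, t3 = inner
    all_rows = np.arange(A32.shape[0])
    for j, t1 in enumerate(grid1):
        if ll_slice_bound is None:
            rows = all_rows
        else:
            rows = np.flatnonzero(ll_slice_bound[j] >= best - slack)
            if rows.size == 0:
                continue
        q = tree.forward(
            np.stack([np.full_like(t2, np.float32(t1)), t2, t3])
        )
        np.clip(q, np.float32(1e-30), None, out=q)
        lq = np.log(q)
        l1q = np.log(np.clip(np.float32(1.0) - q, np.float32(1e-30), None))
        Ar, Br = A32[rows], B32[rows]
        for lo in range(0, t2.size, chunk):
            hi = min(lo + chunk, t2.size)
            ll = Ar @ lq[:, lo:hi] + Br @ l1q[:, lo:hi]
            best[rows] = np.maximum(best[rows], ll.max(axis=1))


def g2_grid_minimum(
    counts_list: Sequence[CellCounts],
    model: str | TreeModel = "cni",
    step: float = 0.001,
    chunk: int = 250_000,
) -> np.ndarray:
    """Exhaustive grid-search G² minima, as an independent reference.

    Evaluates the model deviance at every point of a uniform
    ``step``-spaced grid over the unit cube of parameters and returns, for
    each counts instance, the smallest G² found.  A preliminary sweep at
    ten times the step (a subset of the fine grid) seeds per-instance
    incumbents, and fine slices are skipped only when a per-cell bound —
    the binomial log-likelihood maximized over the cell-probability
    interval attainable within the slice — proves no grid point in them
    can beat the incumbent.  The result is identical to the plain
    exhaustive sweep.  Intended for validating :func:`fit_model` on small
    problems, not for data analysis.
    """
    tree = _get_model(model)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    A = np.stack([np.asarray(c.actions, dtype=float) for c in counts_list])
    B = np.stack(
        [np.asarray(c.totals, dtype=float) - np.asarray(c.actions, dtype=float)
         for c in counts_list]
    )
    A32 = A.astype(np.float32)
    B32 = B.astype(np.float32)
    ll_sat = np.array([_saturated_loglik(c) for c in counts_list])
    best = np.full(len(counts_list), -np.inf, dtype=np.float32)

    # seeding sweep on the 10x-coarser subgrid (its points all lie on the
    # fine grid, so `best` stays a certificate of attainable values)
    coarse = grid[:: max(int(round(0.01 / step)), 1)]
    if coarse[-1] != grid[-1]:
        coarse = np.append(coarse, grid[-1])
    cg2, cg3 = np.meshgrid(coarse.astype(np.float32),
                           coarse.astype(np.float32), indexing="ij")
    _grid_pass(tree, coarse, (cg2.ravel(), cg3.ravel()), A32, B32, best,
               None, 0.0, chunk)

    bound = None
    if tree.slice_ranges is not None:
        bound = np.empty((grid.size, len(counts_list)))
        for j, t1 in enumerate(grid):
            bound[j] = sum(
                _binom_ll_in_range(A[:, i], B[:, i], lo, hi)
                for i, (lo, hi) in enumerate(tree.slice_ranges(float(t1)))
            )

    g2_, g3_ = np.meshgrid(grid.astype(np.float32), grid.astype(np.float32),
                           indexing="ij")
    _grid_pass(tree, grid, (g2_.ravel(), g3_.ravel()), A32, B32, best,
               bound, np.float32(1e-3), chunk)
    return np.maximum(2.0 * (ll_sat - best.astype(float)), 0.0)
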