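"""Trial-level data model for four-cell moral-dilemma batteries.

A battery crosses norm type (proscriptive / prescriptive) with consequence
type (benefits greater / smaller than costs), giving four dilemma variants
("cells").  Every participant answers each variant with a binary
action/inaction response, typically six trials per cell (24 trials total).

The four cells carry a fixed index shared by every module in the package:

==== ============== ====================
cell norm           consequences
==== ============== ====================
1    proscriptive   benefits > costs
2    proscriptive   benefits < costs
3    prescriptive   benefits > costs
4    prescriptive   benefits < costs
==== ============== ====================

``p1 .. p4`` always denote the probability of choosing *action* in the
corresponding cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORM_PROSCRIPTIVE = "proscriptive"
NORM_PRESCRIPTIVE = "prescriptive"
CONSEQUENCES_GREATER = "greater"
CONSEQUENCES_SMALLER = "smaller"

#: cell index -> (norm, consequences); the package-wide design convention
CELL_DESIGN: dict[int, tuple[str, str]] = {
    1: (NORM_PROSCRIPTIVE, CONSEQUENCES_GREATER),
    2: (NORM_PROSCRIPTIVE, CONSEQUENCES_SMALLER),
    3: (NORM_PRESCRIPTIVE, CONSEQUENCES_GREATER),
    4: (NORM_PRESCRIPTIVE, CONSEQUENCES_SMALLER),
}

#: canonical column names of the long table
CANONICAL_COLUMNS = ("participant", "dilemma", "norm", "consequence", "response")
OPTIONAL_COLUMNS = ("group", "trait")

_DEFAULT_NORM_VALUES = {
    "proscriptive": NORM_PROSCRIPTIVE,
    "prescriptive": NORM_PRESCRIPTIVE,
    "pro": NORM_PROSCRIPTIVE,
    "pre": NORM_PRESCRIPTIVE,
}
_DEFAULT_CONSEQUENCE_VALUES = {
    "greater": CONSEQUENCES_GREATER,
    "smaller": CONSEQUENCES_SMALLER,
    "benefits_greater": CONSEQUENCES_GREATER,
    "benefits_smaller": CONSEQUENCES_SMALLER,
    "gt": CONSEQUENCES_GREATER,
    "lt": CONSEQUENCES_SMALLER,
}
_DEFAULT_RESPONSE_VALUES = {"0": 0, "1": 1, "0.0": 0, "1.0": 1}


class SchemaError(ValueError):
    """A required column is missing or a value cannot be decoded."""


class BatteryValidationError(ValueError):
    """The trial table violates the four-cell battery design."""


class UnknownParticipantError(KeyError):
    """A participant id is not present in the battery."""


@dataclass(frozen=True)
class CellProbabilities:
    """Per-participant action probabilities for the four design cells."""

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self) -> None:
        for name, value in zip(("p1", "p2", "p3", "p4"), self.as_array()):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)

    @classmethod
    def from_array(cls, p: Sequence[float]) -> "CellProbabilities":
        p = np.asarray(p, dtype=float)
        if p.shape != (4,):
            raise ValueError(f"expected 4 cell probabilities, got shape {p.shape}")
        return cls(*p.tolist())


@dataclass(frozen=True)
class CellCounts:
    """Action / total trial counts per cell — the sufficient statistic for
    the product-binomial likelihood used by the tree models."""

    actions: tuple[int, int, int, int]
    totals: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        a = np.asarray(self.actions)
        n = np.asarray(self.totals)
        if a.shape != (4,) or n.shape != (4,):
            raise ValueError("actions and totals must each have 4 entries")
        if np.any(n <= 0):
            raise ValueError("every cell needs at least one trial")
        if np.any(a < 0) or np.any(a > n):
            raise ValueError("need 0 <= actions_i <= totals_i in every cell")
        object.__setattr__(self, "actions", tuple(int(x) for x in a))
        object.__setattr__(self, "totals", tuple(int(x) for x in n))

    @property
    def proportions(self) -> CellProbabilities:
        a = np.asarray(self.actions, dtype=float)
        n = np.asarray(self.totals, dtype=float)
        return CellProbabilities.from_array(a / n)

    def __add__(self, other: "CellCounts") -> "CellCounts":
        return CellCounts(
            tuple(a + b for a, b in zip(self.actions, other.actions)),
            tuple(a + b for a, b in zip(self.totals, other.totals)),
        )


def _assign_cells(df: pd.DataFrame) -> pd.Series:
    cell = pd.Series(0, index=df.index, dtype=np.int8)
    for idx, (norm, cons) in CELL_DESIGN.items():
        cell[(df["norm"] == norm) & (df["consequence"] == cons)] = idx
    return cell


class Battery:
    """A validated long-format table of dilemma responses.

    Parameters
    ----------
    df
        Long table with canonical columns ``participant, dilemma, norm,
        consequence, response`` and optionally ``group`` and ``trait``.
        Norm / consequence / response values must already be canonical
        (use :func:`read_long_table` to decode files with other codings).
    allow_incomplete
        Participants lacking trials in one or more cells are a hard error
        by default, because the CAN formulas are undefined without all four
        cells.  If true, such participants are dropped with a log message
        instead.
    """

    def __init__(self, df: pd.DataFrame, allow_incomplete: bool = False):
        df = df.copy()
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

        bad_norm = set(df["norm"].unique()) - {NORM_PROSCRIPTIVE, NORM_PRESCRIPTIVE}
        if bad_norm:
            raise SchemaError(f"unknown norm value(s): {sorted(map(str, bad_norm))}")
        bad_cons = set(df["consequence"].unique()) - {
            CONSEQUENCES_GREATER,
            CONSEQUENCES_SMALLER,
        }
        if bad_cons:
            raise SchemaError(
                f"unknown consequence value(s): {sorted(map(str, bad_cons))}"
            )
        responses = pd.to_numeric(df["response"], errors="coerce")
        if responses.isna().any() or not set(responses.unique()) <= {0, 1}:
            bad = sorted(set(df["response"][~responses.isin([0, 1])].astype(str)))
            raise SchemaError(f"response must be binary 0/1; found {bad}")
        df["response"] = responses.astype(np.int8)
        df["cell"] = _assign_cells(df)

        counts = df.groupby(["participant", "cell"], sort=True).size()
        incomplete = sorted(
            pid
            for pid in df["participant"].unique()
            if any((pid, c) not in counts.index for c in range(1, 5))
        )
        if incomplete:
            if not allow_incomplete:
                raise BatteryValidationError(
                    "participant(s) missing trials in at least one of the four "
                    f"cells: {', '.join(map(str, incomplete))}"
                )
            logger.warning(
                "dropping %d participant(s) with incomplete batteries: %s",
                len(incomplete),
                ", ".join(map(str, incomplete)),
            )
            df = df[~df["participant"].isin(incomplete)]
            if df.empty:
                raise BatteryValidationError("no complete participants remain")

        self.df = df.reset_index(drop=True)

    # -- basic properties --------------------------------------------------

    @property
    def participants(self) -> list:
        return sorted(self.df["participant"].unique())

    @property
    def n_participants(self) -> int:
        return self.df["participant"].nunique()

    @property
    def has_groups(self) -> bool:
        return "group" in self.df.columns and self.df["group"].notna().any()

    @property
    def has_traits(self) -> bool:
        return "trait" in self.df.columns and self.df["trait"].notna().any()

    def groups(self) -> list:
        if not self.has_groups:
            return []
        return sorted(self.df["group"].dropna().unique())

    # -- per-participant and aggregated views ------------------------------

    def cell_probabilities(self, participant_id) -> CellProbabilities:
        """Empirical action probability per cell for one participant."""
        sub = self.df[self.df["participant"] == participant_id]
        if sub.empty:
            raise UnknownParticipantError(participant_id)
        p = np.empty(4)
        for c in range(1, 5):
            trials = sub[sub["cell"] == c]["response"]
            p[c - 1] = trials.mean()
        return CellProbabilities.from_array(p)

    def cell_probabilities_frame(self) -> pd.DataFrame:
        """One row per participant: p1..p4 plus group / trait when present."""
        g = self.df.groupby(["participant", "cell"], sort=True)["response"].mean()
        wide = g.unstack("cell")
        wide.columns = [f"p{c}" for c in wide.columns]
        wide = wide.reset_index()
        for col in OPTIONAL_COLUMNS:
            if col in self.df.columns:
                extra = self.df.groupby("participant", sort=True)[col].first()
                wide[col] = wide["participant"].map(extra)
        return wide

    def aggregate_counts(self, group=None, group_column: str = "group") -> CellCounts:
        """Pooled action / total counts per cell, optionally for one group."""
        df = self.df
        if group is not None:
            if group_column not in df.columns:
                raise SchemaError(f"no such column: {group_column}")
            df = df[df[group_column] == group]
            if df.empty:
                raise BatteryValidationError(f"no participants in group {group!r}")
        actions = []
        totals = []
        for c in range(1, 5):
            cell = df[df["cell"] == c]["response"]
            actions.append(int(cell.sum()))
            totals.append(int(len(cell)))
        return CellCounts(tuple(actions), tuple(totals))

    def counts_by_group(self, group_column: str = "group") -> dict:
        if group_column not in self.df.columns:
            raise SchemaError(f"no such column: {group_column}")
        return {
            g: self.aggregate_counts(group=g, group_column=group_column)
            for g in sorted(self.df[group_column].dropna().unique())
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, Battery):
            return NotImplemented
        cols = [c for c in (*CANONICAL_COLUMNS, *OPTIONAL_COLUMNS) if c in self.df]
        if cols != [c for c in (*CANONICAL_COLUMNS, *OPTIONAL_COLUMNS) if c in other.df]:
            return False
        key = ["participant", "cell", "dilemma"]
        a = self.df.sort_values(key).reset_index(drop=True)
        b = other.df.sort_values(key).reset_index(drop=True)
        return a[cols].equals(b[cols])


# -- file I/O ---------------------------------------------------------------


def _decode(series: pd.Series, mapping: Mapping, what: str) -> pd.Series:
    as_str = series.astype(str).str.strip().str.lower()
    table = {str(k).strip().lower(): v for k, v in mapping.items()}
    decoded = as_str.map(table)
    if decoded.isna().any():
        bad = sorted(set(as_str[decoded.isna()]))
        raise SchemaError(f"unknown {what} code(s): {bad}")
    return decoded


def read_long_table(
    path,
    column_map: Mapping[str, str] | None = None,
    response_values: Mapping | None = None,
    norm_values: Mapping | None = None,
    consequence_values: Mapping | None = None,
    allow_incomplete: bool = False,
    sep: str = ",",
) -> Battery:
    """Read a delimited long-format trial table into a validated battery.

    ``column_map`` maps canonical names (``participant``, ``dilemma``,
    ``norm``, ``consequence``, ``response``, optionally ``group`` and
    ``trait``) to the column names used in the file; unmapped names are
    taken verbatim.  The ``*_values`` mappings decode file codings (e.g.
    ``{"yes": 1, "no": 0}``) into the canonical ones.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    column_map = dict(column_map or {})
    rename = {}
    for canonical in (*CANONICAL_COLUMNS, *OPTIONAL_COLUMNS):
        actual = column_map.get(canonical, canonical)
        if actual in df.columns:
            rename[actual] = canonical
        elif canonical in CANONICAL_COLUMNS:
            raise SchemaError(
                f"missing required column {canonical!r} (looked for {actual!r})"
            )
    df = df.rename(columns=rename)
    df = df[[c for c in (*CANONICAL_COLUMNS, *OPTIONAL_COLUMNS) if c in df.columns]]

    df["norm"] = _decode(df["norm"], norm_values or _DEFAULT_NORM_VALUES, "norm")
    df["consequence"] = _decode(
        df["consequence"],
        consequence_values or _DEFAULT_CONSEQUENCE_VALUES,
        "consequence",
    )
    df["response"] = _decode(
        df["response"], response_values or _DEFAULT_RESPONSE_VALUES, "response"
    )
    return Battery(df, allow_incomplete=allow_incomplete)


def write_long_table(battery: Battery, path, header_comments: Iterable[str] = ()) -> None:
    """Write the canonical long CSV (optionally with ``#`` comment header)."""
    cols = [c for c in (*CANONICAL_COLUMNS, *OPTIONAL_COLUMNS) if c in battery.df.columns]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        battery.df[cols].to_csv(fh, index=False)


def write_wide_counts(battery: Battery, path) -> None:
    """Export one row per participant with 16 count columns
    (``actions_1..4``, ``totals_1..4`` interleaved per cell); export only —
    the long format is canonical."""
    rows = []
    for pid in battery.participants:
        sub = battery.df[battery.df["participant"] == pid]
        row: dict = {"participant": pid}
        for c in range(1, 5):
            cell = sub[sub["cell"] == c]["response"]
            row[f"actions_{c}"] = int(cell.sum())
            row[f"totals_{c}"] = int(len(cell))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
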