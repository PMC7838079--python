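"""Synthetic populations and trial-level dilemma responses.

Participants receive latent parameters drawn from a mean-calibrated
logit-normal: each latent is ``expit(mu + sd * Z)`` with ``mu`` chosen so
that the population *mean* equals the requested value (for ``sd = 0`` the
draw is the mean itself).  Latents feed one of the forward processes —
the CNI, NCI or DNA tree, or direct cell probabilities — and each cell's
responses are independent Bernoulli trials at that cell probability.

Randomness is governed by a single seed; per-participant generators are
spawned from it, so participant ``k``'s data do not depend on how many
other participants are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .data import (
    Battery,
    CELL_DESIGN,
    CellProbabilities,
)
from .mpt import MODELS

__all__ = ["PopulationSpec", "simulate_population", "simulate_responses",
           "simulate_battery"]

PROCESSES = ("cni", "nci", "dna", "direct")

_DIRECT_NAMES = ("p1", "p2", "p3", "p4")


@dataclass(frozen=True)
class PopulationSpec:
    """Study-design description for one simulated sample.

    Defaults mirror the original moral-dilemma batteries: 24 trials per
    participant, six per cell.
    """

    n_participants: int
    process: str = "cni"
    latent_means: tuple = (0.3, 0.5, 0.4)
    latent_sds: tuple = (0.0, 0.0, 0.0)
    trials_per_cell: int = 6
    seed: int = 0
    group: str | None = None

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise ValueError(f"process must be one of {PROCESSES}")
        k = 4 if self.process == "direct" else 3
        means = tuple(float(v) for v in self.latent_means)
        sds = tuple(float(v) for v in self.latent_sds)
        if len(means) != k:
            raise ValueError(f"{self.process!r} needs {k} latent means")
        if len(sds) == 1:
            sds = sds * k
        if len(sds) != k:
            raise ValueError(f"{self.process!r} needs {k} latent sds (or one)")
        if any(not 0.0 <= m <= 1.0 for m in means):
            raise ValueError("latent means must lie in [0, 1]")
        if any(s < 0 for s in sds):
            raise ValueError("latent sds must be nonnegative")
        if self.n_participants < 1 or self.trials_per_cell < 1:
            raise ValueError("n_participants and trials_per_cell must be >= 1")
        object.__setattr__(self, "latent_means", means)
        object.__setattr__(self, "latent_sds", sds)

    @property
    def param_names(self) -> tuple:
        if self.process == "direct":
            return _DIRECT_NAMES
        return MODELS[self.process].param_names


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(61)


def _logitnormal_mean(mu: float, sd: float) -> float:
    # E[expit(mu + sd Z)] by Gauss-Hermite quadrature
    return float(
        (_GH_WEIGHTS * special.expit(mu + np.sqrt(2.0) * sd * _GH_NODES)).sum()
        / np.sqrt(np.pi)
    )


def _calibrated_mu(mean: float, sd: float) -> float:
    """Location of the logit-normal whose *mean* (not median) is ``mean``."""
    if sd == 0.0 or mean in (0.0, 1.0):
        return float(special.logit(np.clip(mean, 1e-12, 1 - 1e-12)))
    return float(
        optimize.brentq(lambda mu: _logitnormal_mean(mu, sd) - mean, -60.0, 60.0)
    )


def simulate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw per-participant latent parameters.

    Returns a frame with one row per participant, columns named after the
    process parameters (``C, N, I`` / ``N, C, I`` / ``D, N, A`` /
    ``p1..p4``).  Reproducible given ``spec.seed``; with zero sds every
    participant gets exactly the latent means.
    """
    names = spec.param_names
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    cols = {}
    z = rng.standard_normal((spec.n_participants, len(names)))
    for j, (name, mean, sd) in enumerate(
        zip(names, spec.latent_means, spec.latent_sds)
    ):
        if sd == 0.0:
            cols[name] = np.full(spec.n_participants, mean)
        else:
            mu = _calibrated_mu(mean, sd)
            cols[name] = special.expit(mu + sd * z[:, j])
    frame = pd.DataFrame(cols)
    frame.insert(0, "participant", [f"s{k:04d}" for k in range(spec.n_participants)])
    return frame


def _cells_from_latents(latents: pd.DataFrame, process: str) -> np.ndarray:
    if process == "direct":
        return latents[list(_DIRECT_NAMES)].to_numpy(dtype=float)
    model = MODELS[process]
    theta = latents[list(model.param_names)].to_numpy(dtype=float).T
    return model.forward(theta).T


def simulate_responses(
    latents: pd.DataFrame,
    process: str = "cni",
    trials_per_cell: int = 6,
    seed: int = 0,
    group: str | None = None,
    traits: Sequence[float] | None = None,
) -> Battery:
    """Bernoulli trial-level responses for a frame of latent parameters.

    Each participant's cell-``i`` responses are independent Bernoulli
    draws at the probability the process's forward mapping assigns to that
    cell.  Per-participant random streams are spawned from ``seed``.
    """
    if process not in PROCESSES:
        raise ValueError(f"process must be one of {PROCESSES}")
    cells = _cells_from_latents(latents, process)
    n = len(latents)
    K = int(trials_per_cell)
    children = np.random.SeedSequence(seed).spawn(n)

    norm_col = []
    cons_col = []
    for c in range(1, 5):
        norm, cons = CELL_DESIGN[c]
        norm_col += [norm] * K
        cons_col += [cons] * K
    dilemma_col = [f"d{c}_{t + 1}" for c in range(1, 5) for t in range(K)]

    frames = []
    for k in range(n):
        rng = np.random.default_rng(children[k])
        p = np.repeat(cells[k], K)
        responses = (rng.random(4 * K) < p).astype(np.int8)
        frame = pd.DataFrame(
            {
                "participant": latents["participant"].iloc[k],
                "dilemma": dilemma_col,
                "norm": norm_col,
                "consequence": cons_col,
                "response": responses,
            }
        )
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    if group is not None:
        df["group"] = group
    if traits is not None:
        trait_map = dict(zip(latents["participant"], np.asarray(traits, float)))
        df["trait"] = df["participant"].map(trait_map)
    return Battery(df)


def simulate_battery(spec: PopulationSpec,
                     traits: Sequence[float] | None = None
                     ) -> tuple[pd.DataFrame, Battery]:
    """Population draw plus trial simulation with seeds split from
    ``spec.seed``; returns ``(latents, battery)``."""
    pop_seed, resp_seed = np.random.SeedSequence(spec.seed).generate_state(2) >> 1
    latents = simulate_population(replace(spec, seed=int(pop_seed)))
    battery = simulate_responses(
        latents,
        process=spec.process,
        trials_per_cell=spec.trials_per_cell,
        seed=int(resp_seed),
        group=spec.group,
        traits=traits,
    )
    return latents, battery


def expected_cells(spec: PopulationSpec) -> CellProbabilities:
    """Cell probabilities implied by the latent *means* (exact when all
    sds are zero; otherwise a plug-in approximation)."""
    if spec.process == "direct":
        return CellProbabilities(*spec.latent_means)
    model = MODELS[spec.process]
    return CellProbabilities.from_array(
        model.forward(np.asarray(spec.latent_means, dtype=float))
    )
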