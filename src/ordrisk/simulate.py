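"""Synthetic choice generation from classic-utility agents.

Used for model-recovery studies: agents with known risk (alpha) and
ambiguity (beta) attitudes evaluate each lottery with the classic power
utility, Gaussian noise is added to the subjective-value difference, and
the lottery is chosen whenever the noisy difference is positive. At zero
noise the policy is the deterministic utility argmax.

The default simulation grid crosses sample size and noise level over the
seven cells (30,0.1), (30,0.3), (30,0.5), (60,0.3), (60,0.5), (120,0.5),
(300,0.5), with per-agent parameters drawn uniformly from alpha in
[0.1, 1.6] and beta in [-1.4, 1.4].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import sv_classic
from .task_design import TrialSpec, design_to_frame, get_scale

__all__ = [
    "ALPHA_RANGE",
    "BETA_RANGE",
    "DEFAULT_GRID_CELLS",
    "AgentParams",
    "SimulationGrid",
    "ChoiceDataset",
    "draw_agents",
    "simulate_choices",
    "run_simulation_grid",
]

ALPHA_RANGE = (0.1, 1.6)
BETA_RANGE = (-1.4, 1.4)
DEFAULT_GRID_CELLS = (
    (30, 0.1),
    (30, 0.3),
    (30, 0.5),
    (60, 0.3),
    (60, 0.5),
    (120, 0.5),
    (300, 0.5),
)

DATASET_COLUMNS = [
    "subject_id",
    "domain",
    "trial_index",
    "level",
    "win_prob",
    "ambiguity",
    "is_catch",
    "chose_lottery",
]


@dataclass(frozen=True)
class AgentParams:
    """True generating parameters of one simulated subject."""

    alpha: float
    beta: float
    noise_sd: float

    def __post_init__(self) -> None:
        if not (ALPHA_RANGE[0] <= self.alpha <= ALPHA_RANGE[1]):
            raise ValueError(f"alpha must lie in {ALPHA_RANGE}")
        if not (BETA_RANGE[0] <= self.beta <= BETA_RANGE[1]):
            raise ValueError(f"beta must lie in {BETA_RANGE}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SimulationGrid:
    """(n_subjects, noise_sd) cells plus a master seed."""

    cells: tuple[tuple[int, float], ...] = DEFAULT_GRID_CELLS
    seed: int = 0


@dataclass
class ChoiceDataset:
    """Long table of subjects x trials with binary choices.

    ``table`` has one row per (subject, trial); ``true_params`` carries the
    generating parameters when the data are simulated, else None.
    """

    table: pd.DataFrame
    true_params: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")

    @property
    def n_subjects(self) -> int:
        return self.table["subject_id"].nunique()

    @property
    def subject_ids(self) -> list:
        return sorted(self.table["subject_id"].unique())


def draw_agents(
    n: int, seed: int | np.random.Generator, noise_sd: float = 0.0
) -> list[AgentParams]:
    """Draw ``n`` agents with uniform attitudes over the constraint ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphas = rng.uniform(*ALPHA_RANGE, size=n)
    betas = rng.uniform(*BETA_RANGE, size=n)
    return [AgentParams(a, b, noise_sd) for a, b in zip(alphas, betas)]


def simulate_choices(
    agents: list[AgentParams],
    design: list[TrialSpec],
    seed: int | np.random.Generator,
) -> ChoiceDataset:
    """Simulate every agent through the design.

    Per trial the lottery's and the certain option's subjective values are
    computed with the classic utility model; a single zero-mean Gaussian
    draw with sd ``noise_sd`` is added to their difference and the lottery
    is chosen iff the noisy difference is positive.
    """
    if not agents:
        raise ValueError("need at least one agent")
    if not design:
        raise ValueError("design must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base = design_to_frame(design)
    domain = base["domain"].iloc[0]
    scale = get_scale(domain)
    if scale.amounts is None:
        raise ValueError(
            "classic-utility simulation needs objective amounts "
            f"(domain {domain!r} has none)"
        )
    amounts = np.asarray(scale.amounts)[base["level"].to_numpy() - 1]
    P = base["win_prob"].to_numpy()
    A = base["ambiguity"].to_numpy()
    certain_amount = scale.amounts[0]

    frames = []
    records = []
    for sid, agent in enumerate(agents):
        sv_lottery = sv_classic(P, A, amounts, agent.alpha, agent.beta)
        sv_certain = certain_amount**agent.alpha
        diff = sv_lottery - sv_certain
        if agent.noise_sd > 0:
            diff = diff + rng.normal(0.0, agent.noise_sd, size=diff.shape)
        frame = base.copy()
        frame.insert(0, "subject_id", sid)
        frame["chose_lottery"] = diff > 0
        frames.append(frame)
        records.append(
            {
                "subject_id": sid,
                "alpha": agent.alpha,
                "beta": agent.beta,
                "noise_sd": agent.noise_sd,
            }
        )
    table = pd.concat(frames, ignore_index=True)[
        DATASET_COLUMNS + ["repetition"]
    ]
    return ChoiceDataset(table=table, true_params=pd.DataFrame(records))


def run_simulation_grid(
    grid: SimulationGrid, design: list[TrialSpec]
) -> dict[tuple[int, float], ChoiceDataset]:
    """One simulated dataset per (n_subjects, noise_sd) cell, seeded off the grid seed."""
    out: dict[tuple[int, float], ChoiceDataset] = {}
    root = np.random.SeedSequence(grid.seed)
    children = root.spawn(len(grid.cells))
    for (n, noise), ss in zip(grid.cells, children):
        rng = np.random.default_rng(ss)
        agents = draw_agents(n, rng, noise_sd=noise)
        out[(n, noise)] = simulate_choices(agents, design, rng)
    return out
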