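"""Trial tables for the risk/ambiguity task in both outcome domains.

The task offers a choice between a small certain outcome (level 1: $5 or
"slight improvement") and a lottery over a better outcome (levels 2-4).
Lotteries are risky (win probability 25/50/75%, fully displayed) or
ambiguous (nominal probability 50%, a fraction of the display occluded:
24/50/74%, plus a fully occluded 100% condition in the online variant).
Catch (attention-check) trials pit the certain level-1 outcome against a
lottery over the same level-1 outcome, a dominated option.

The in-person variant repeats each non-catch (level x uncertainty) cell 4
times and contains 84 trials per domain, 12 of them catch; the online
variant halves the repetitions and adds the 100%-ambiguity condition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeScale",
    "TrialSpec",
    "DesignVariant",
    "IN_PERSON",
    "ONLINE",
    "MONETARY_SCALE",
    "MEDICAL_SCALE",
    "get_variant",
    "get_scale",
    "build_design",
    "summarize_design",
    "design_to_frame",
    "design_from_frame",
]

RISK_PROBABILITIES = (0.25, 0.5, 0.75)
AMBIGUITY_LEVELS = (0.24, 0.5, 0.74)
AMBIGUOUS_P = 0.5
CERTAIN_LEVEL = 1
DOMAINS = ("monetary", "medical")


@dataclass(frozen=True)
class OutcomeScale:
    """The 4-level ordinal outcome scale of one domain.

    The certain option's outcome is always level 1 ($5 / slight
    improvement). ``amounts`` carries the dollar values for the monetary
    domain and is None for the medical domain, whose levels have no
    objective magnitude.
    """

    domain: str
    labels: tuple[str, str, str, str]
    amounts: tuple[float, float, float, float] | None = None
    level_of_certain: int = CERTAIN_LEVEL

    def __post_init__(self) -> None:
        if len(self.labels) != 4:
            raise ValueError("exactly 4 outcome levels required")
        if self.level_of_certain != 1:
            raise ValueError("certain option must be the level-1 outcome")
        if self.amounts is not None and list(self.amounts) != sorted(self.amounts):
            raise ValueError("amounts must be strictly ordered")

    def amount_of(self, level: int) -> float:
        if self.amounts is None:
            raise ValueError(f"{self.domain} outcomes carry no objective amount")
        return self.amounts[level - 1]


MONETARY_SCALE = OutcomeScale(
    domain="monetary",
    labels=("$5", "$8", "$12", "$25"),
    amounts=(5.0, 8.0, 12.0, 25.0),
)
MEDICAL_SCALE = OutcomeScale(
    domain="medical",
    labels=(
        "slight improvement",
        "moderate improvement",
        "major improvement",
        "complete recovery",
    ),
)


@dataclass(frozen=True)
class TrialSpec:
    """One lottery-vs-certain decision problem.

    Risky trials have ``ambiguity == 0`` and ``win_prob`` in {.25,.5,.75};
    ambiguous trials have ``win_prob == 0.5`` and a nonzero occluded
    fraction. The certain alternative is always the level-1 outcome at
    P=1, A=0 and is implicit.
    """

    domain: str
    level: int
    win_prob: float
    ambiguity: float
    is_catch: bool
    repetition: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.level not in (1, 2, 3, 4):
            raise ValueError("level must lie in 1..4")
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")
        if self.ambiguity == 0.0:
            if self.win_prob not in RISK_PROBABILITIES:
                raise ValueError("risky trials need P in {0.25, 0.5, 0.75}")
        else:
            if self.win_prob != AMBIGUOUS_P:
                raise ValueError("ambiguous trials fix P = 0.5")
        if self.is_catch and self.level != CERTAIN_LEVEL:
            raise ValueError("catch trials use the level-1 outcome")


@dataclass(frozen=True)
class DesignVariant:
    """Named task variant (study arm) controlling repetitions and conditions."""

    name: str
    repetitions_per_cell: int
    ambiguity_levels: tuple[float, ...]
    catch_repetitions: int

    @property
    def uncertainty_conditions(self) -> list[tuple[float, float]]:
        """(P, A) pairs: risky conditions then ambiguous conditions."""
        risky = [(p, 0.0) for p in RISK_PROBABILITIES]
        ambiguous = [(AMBIGUOUS_P, a) for a in self.ambiguity_levels]
        return risky + ambiguous

    @property
    def catch_trial_count(self) -> int:
        return len(self.uncertainty_conditions) * self.catch_repetitions

    @property
    def total_trials(self) -> int:
        n_cells = 3 * len(self.uncertainty_conditions)
        return n_cells * self.repetitions_per_cell + self.catch_trial_count


# 3 levels x 6 conditions x 4 reps = 72 non-catch + 6 x 2 = 12 catch -> 84
IN_PERSON = DesignVariant(
    name="in_person",
    repetitions_per_cell=4,
    ambiguity_levels=AMBIGUITY_LEVELS,
    catch_repetitions=2,
)
# online: reps halved, 100% ambiguity added; catch once per condition
ONLINE = DesignVariant(
    name="online",
    repetitions_per_cell=2,
    ambiguity_levels=AMBIGUITY_LEVELS + (1.0,),
    catch_repetitions=1,
)

_VARIANTS = {v.name: v for v in (IN_PERSON, ONLINE)}
_SCALES = {"monetary": MONETARY_SCALE, "medical": MEDICAL_SCALE}


def get_variant(name: str | DesignVariant) -> DesignVariant:
    if isinstance(name, DesignVariant):
        return name
    try:
        return _VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; expected one of {sorted(_VARIANTS)}"
        ) from None


def get_scale(domain: str) -> OutcomeScale:
    try:
        return _SCALES[domain]
    except KeyError:
        raise ValueError(
            f"unknown domain {domain!r}; expected one of {sorted(_SCALES)}"
        ) from None


def build_design(
    variant: str | DesignVariant,
    domain: str,
    shuffle_seed: int | None = None,
) -> list[TrialSpec]:
    """Enumerate the full trial table of one variant in one domain.

    Non-catch trials cross lottery levels {2,3,4} with every uncertainty
    condition, each repeated ``repetitions_per_cell`` times; catch trials
    repeat the level-1 lottery over every uncertainty condition. The order
    is the deterministic enumeration unless ``shuffle_seed`` is given, in
    which case a seeded uniform shuffle is applied.
    """
    variant = get_variant(variant)
    get_scale(domain)  # validates the domain name
    trials: list[TrialSpec] = []
    for level in (2, 3, 4):
        for p, a in variant.uncertainty_conditions:
            for rep in range(1, variant.repetitions_per_cell + 1):
                trials.append(TrialSpec(domain, level, p, a, False, rep))
    for p, a in variant.uncertainty_conditions:
        for rep in range(1, variant.catch_repetitions + 1):
            trials.append(TrialSpec(domain, CERTAIN_LEVEL, p, a, True, rep))
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        trials = [trials[i] for i in rng.permutation(len(trials))]
    return trials


def summarize_design(trials: list[TrialSpec]) -> pd.DataFrame:
    """Cell-count table over (level, win_prob, ambiguity, is_catch)."""
    counts = Counter(
        (t.level, t.win_prob, t.ambiguity, t.is_catch) for t in trials
    )
    frame = pd.DataFrame(
        [
            {
                "level": lvl,
                "win_prob": p,
                "ambiguity": a,
                "is_catch": catch,
                "count": n,
            }
            for (lvl, p, a, catch), n in sorted(counts.items())
        ],
        columns=["level", "win_prob", "ambiguity", "is_catch", "count"],
    )
    return frame


def design_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """Long-format table with one row per trial (CSV interchange layout)."""
    return pd.DataFrame(
        {
            "domain": [t.domain for t in trials],
            "trial_index": np.arange(len(trials)),
            "level": [t.level for t in trials],
            "win_prob": [t.win_prob for t in trials],
            "ambiguity": [t.ambiguity for t in trials],
            "is_catch": [t.is_catch for t in trials],
            "repetition": [t.repetition for t in trials],
        }
    )


def design_from_frame(frame: pd.DataFrame) -> list[TrialSpec]:
    return [
        TrialSpec(
            domain=row.domain,
            level=int(row.level),
            win_prob=float(row.win_prob),
            ambiguity=float(row.ambiguity),
            is_catch=bool(row.is_catch),
            repetition=int(row.repetition),
        )
        for row in frame.itertuples()
    ]
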