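"""Subjective-value equations, choice rules and hyperprior settings.

Three subjective-value (SV) models for choices between a certain option and
a lottery that is either risky (known win probability ``P``) or ambiguous
(a fraction ``A`` of the probability display is occluded, in which case the
nominal probability is 0.5):

* **Classic utility** — power utility with a linear ambiguity penalty on the
  perceived probability: ``SV = (P - beta * A / 2) * V ** alpha``.
* **Estimated value** — for ordinal outcomes without a cash amount, the value
  of level ``i`` is the cumulative sum of nonnegative increments
  ``nu_1..nu_i``; there is no separate risk-attitude parameter (curvature is
  absorbed by the increments): ``SV = (P - beta * A / 2) * sum(nu_1..nu_i)``.
* **No-subjective-parameters baseline** — the ordinal category index serves
  as the value and ambiguity is penalized with a fixed unit weight:
  ``SV = (P - A / 2) * level``.

Two choice rules map an SV difference to the probability of picking the
lottery: a logistic rule with inverse temperature ``gamma`` and a
trembling-hand rule in which the chooser lapses to a 50/50 guess with
probability ``delta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "HyperpriorSettings",
    "SubjectParams",
    "sv_classic",
    "sv_estimated",
    "sv_fixed",
    "choice_prob_logistic",
    "choice_prob_trembling",
    "prior_mean_alpha",
]


@dataclass(frozen=True)
class HyperpriorSettings:
    """Group-level prior specification shared by all hierarchical fits.

    Defaults encode slight risk aversion (central prior mean of alpha
    2*4/(4+7) = 8/11 ~ 0.73) and slight ambiguity aversion (mu_beta
    centered at 0.65).

    Conventions: ``Normal(loc, scale)`` optionally truncated;
    ``Gamma(shape, rate)``; ``LogNormal(log_loc, log_scale)``;
    subject-level alpha is ``2 * Beta(alpha_shape1, alpha_shape2)``.
    """

    # alpha ~ 2 * Beta(a1, a2); a1 ~ N(4,1) on [0,inf), a2 ~ N(7,3) on [0,inf)
    alpha_shape1_loc: float = 4.0
    alpha_shape1_scale: float = 1.0
    alpha_shape2_loc: float = 7.0
    alpha_shape2_scale: float = 3.0
    # beta ~ N(mu_beta, sigma_beta) on (beta_lower, beta_upper)
    beta_group_mean_loc: float = 0.65
    beta_group_mean_scale: float = 1.0
    beta_group_sd_shape: float = 2.0
    beta_group_sd_rate: float = 1.0
    beta_lower: float = -1.5
    beta_upper: float = 1.5
    # gamma ~ LogNormal(0, 0.25), one per subject (shared across its trials)
    gamma_log_loc: float = 0.0
    gamma_log_scale: float = 0.25
    # delta ~ Beta(d1, d2); d1, d2 ~ N(2,1) on [1,inf)
    delta_shape_loc: float = 2.0
    delta_shape_scale: float = 1.0
    delta_shape_lower: float = 1.0
    # nu_i ~ N(mu_nu_i, sigma_nu_i) on [0,inf)
    nu_group_mean_loc: float = 4.0
    nu_group_mean_scale: float = 2.0
    nu_group_sd_shape: float = 3.0
    nu_group_sd_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "alpha_shape1_scale",
            "alpha_shape2_scale",
            "beta_group_mean_scale",
            "beta_group_sd_shape",
            "beta_group_sd_rate",
            "gamma_log_scale",
            "delta_shape_scale",
            "nu_group_mean_scale",
            "nu_group_sd_shape",
            "nu_group_sd_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.beta_lower < 0 < self.beta_upper):
            raise ValueError("beta bounds must bracket 0")
        if self.beta_lower != -self.beta_upper:
            raise ValueError("beta bounds must be symmetric about 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HyperpriorSettings":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @classmethod
    def shipped_default(cls) -> "HyperpriorSettings":
        """The default configuration as shipped in the package data."""
        text = (
            resources.files("ordrisk") / "data" / "default_hyperpriors.yaml"
        ).read_text()
        return cls(**yaml.safe_load(text))


@dataclass
class SubjectParams:
    """Per-subject latent parameters; fields absent from a model are None."""

    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    nu_increments: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta is not None and not (-1.5 <= self.beta <= 1.5):
            raise ValueError("beta must lie in [-1.5, 1.5]")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.delta is not None and not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        if self.nu_increments is not None and any(v < 0 for v in self.nu_increments):
            raise ValueError("nu increments must be nonnegative")


def _check_pav(P, A) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any((P <= 0) | (P > 1)):
        raise ValueError("P must lie in (0, 1]")
    if np.any((A < 0) | (A > 1)):
        raise ValueError("A must lie in [0, 1]")
    return P, A


def sv_classic(P, A, V, alpha, beta):
    """Classic-utility subjective value ``(P - beta*A/2) * V**alpha``.

    ``P`` is the objective win probability (0.5 on ambiguous trials), ``A``
    the occluded fraction, ``V`` the dollar amount, ``alpha`` the risk
    attitude (curvature; <1 risk-averse) and ``beta`` the ambiguity attitude
    (>0 ambiguity-averse). Broadcasts over array inputs.
    """
    P, A = _check_pav(P, A)
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    beta = np.asarray(beta, dtype=float)
    out = (P - beta * A / 2.0) * V**alpha
    return out if out.ndim else float(out)


def sv_estimated(P, A, level, nu_increments, beta):
    """Estimated-value SV: ``(P - beta*A/2) * cumsum(nu)[level]``.

    ``nu_increments`` are the four nonnegative per-level additive values;
    the value of ordinal level ``i`` is ``nu_1 + ... + nu_i``. The certain
    option is level 1 at P=1, A=0, i.e. ``nu_1``.
    """
    P, A = _check_pav(P, A)
    level = np.asarray(level)
    if np.any((level < 1) | (level > 4)):
        raise ValueError("level must lie in 1..4")
    nu = np.asarray(nu_increments, dtype=float)
    if nu.shape[-1] != 4:
        raise ValueError("nu_increments must have 4 entries")
    if np.any(nu < 0):
        raise ValueError("nu increments must be nonnegative")
    cum = np.cumsum(nu, axis=-1)
    if cum.ndim == 1:
        value = cum[level - 1]
    else:  # one nu row per trial
        value = np.take_along_axis(cum, (level - 1).reshape(-1, 1), axis=-1)[:, 0]
    beta = np.asarray(beta, dtype=float)
    out = (P - beta * A / 2.0) * value
    return out if out.ndim else float(out)


def sv_fixed(P, A, level):
    """Baseline SV with no subject parameters: ``(P - A/2) * level``."""
    P, A = _check_pav(P, A)
    level = np.asarray(level)
    if np.any((level < 1) | (level > 4)):
        raise ValueError("level must lie in 1..4")
    out = (P - A / 2.0) * level.astype(float)
    return out if out.ndim else float(out)


def _logistic(x):
    # numerically stable sigmoid
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def choice_prob_logistic(sv_safe, sv_risky, gamma):
    """P(choose lottery) under the logistic rule, inverse temperature gamma.

    ``1 / (1 + exp(gamma * (sv_safe - sv_risky)))``; strictly increasing in
    ``sv_risky`` and stable for large SV differences.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be positive")
    out = _logistic(
        gamma * (np.asarray(sv_risky, dtype=float) - np.asarray(sv_safe, dtype=float))
    )
    return out if out.ndim else float(out)


def choice_prob_trembling(sv_safe, sv_risky, delta):
    """P(choose lottery) under the trembling-hand rule with lapse rate delta.

    ``(1 - delta) * logistic(sv_risky - sv_safe) + delta / 2``; the lapse
    mixes in a 50/50 guess, bounding the probability in
    [delta/2, 1 - delta/2].
    """
    delta = np.asarray(delta, dtype=float)
    if np.any((delta < 0) | (delta > 1)):
        raise ValueError("delta must lie in [0, 1]")
    base = _logistic(
        np.asarray(sv_risky, dtype=float) - np.asarray(sv_safe, dtype=float)
    )
    out = (1.0 - delta) * base + delta * 0.5
    return out if out.ndim else float(out)


def prior_mean_alpha(settings: HyperpriorSettings | None = None) -> float:
    """Plug-in central prior mean of the risk attitude alpha.

    Evaluates ``2 * a / (a + b)`` at the location values of the two
    Beta-shape hyperpriors (the mean of ``2 * Beta(a, b)``); the shipped
    defaults give 8/11, slight risk aversion.
    """
    s = settings or HyperpriorSettings()
    a, b = s.alpha_shape1_loc, s.alpha_shape2_loc
    return 2.0 * a / (a + b)
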