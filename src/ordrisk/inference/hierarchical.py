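"""Hierarchical Bayesian choice models fitted with the in-package NUTS sampler.

Four model structures, matching the fitted model set:

* classic utility + logistic choice rule,
* classic utility + trembling-hand choice rule,
* estimated value (cumulative ordinal increments) + logistic rule,
* no-subjective-parameters baseline (category index as value) with a single
  shared inverse temperature.

Each model exposes the joint log-density and its analytic gradient in an
unconstrained parameterization (log transforms for positives, scaled-logit
transforms for bounded parameters, with the appropriate Jacobian terms).
Subject-level parameters are partially pooled through the group-level
hyperpriors; all priors follow the shipped :class:`HyperpriorSettings`.

The per-subject likelihood is Bernoulli over the probability of choosing
the lottery given the subjective-value difference between lottery and
certain option. Catch trials never enter the likelihood.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from ..models import HyperpriorSettings
from ..simulate import ChoiceDataset
from ..task_design import get_scale
from .distributions import (
    beta_logpdf,
    gamma_logpdf,
    log_sigmoid,
    norm_logpdf,
    sigmoid,
    truncnorm_logpdf,
    truncnorm_lower_logpdf,
)
from .nuts import sample_nuts

__all__ = [
    "SV_MODELS",
    "CHOICE_RULES",
    "ModelSpec",
    "SamplerSettings",
    "PosteriorFit",
    "fit_model",
    "diagnostics",
    "extract_subject_estimates",
    "save_fit",
    "load_fit",
]

log = logging.getLogger(__name__)

SV_MODELS = ("classic_utility", "estimated_value", "no_subjective_params")
CHOICE_RULES = ("logistic", "trembling_hand")


@dataclass(frozen=True)
class ModelSpec:
    """Which subjective-value model and choice rule to fit."""

    sv_model: str
    choice_rule: str = "logistic"
    hyperpriors: HyperpriorSettings = field(default_factory=HyperpriorSettings)

    def __post_init__(self) -> None:
        if self.sv_model not in SV_MODELS:
            raise ValueError(f"unknown sv_model {self.sv_model!r}")
        if self.choice_rule not in CHOICE_RULES:
            raise ValueError(f"unknown choice_rule {self.choice_rule!r}")
        if self.choice_rule == "trembling_hand" and self.sv_model != "classic_utility":
            raise ValueError(
                "the trembling-hand rule is only paired with the classic utility model"
            )

    @property
    def name(self) -> str:
        if self.choice_rule == "trembling_hand":
            return "trembling_hand"
        return self.sv_model


@dataclass(frozen=True)
class SamplerSettings:
    """NUTS settings; the defaults are the standard 4 x (1000 tune + 1000 draws)
    at 80% target acceptance.

    ``dense_mass`` (default on) estimates a dense inverse mass matrix from
    the final warmup window; the hierarchical posteriors here have strongly
    correlated group-level and subject-level parameters, which a diagonal
    metric handles poorly."""

    draws: int = 1000
    tune: int = 1000
    chains: int = 4
    target_accept: float = 0.8
    seed: int = 0
    dense_mass: bool = True

    def __post_init__(self) -> None:
        if self.draws < 1 or self.tune < 1:
            raise ValueError("draws and tune must be >= 1")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split R-hat")
        if not (0 < self.target_accept < 1):
            raise ValueError("target_accept must lie in (0, 1)")


class _TrialData:
    """Vectorized non-catch trial arrays for one dataset."""

    def __init__(self, data: ChoiceDataset, needs_amounts: bool):
        df = data.table
        df = df[~df["is_catch"].astype(bool)]
        if df.empty:
            raise ValueError("no non-catch trials to fit")
        self.subject_ids = sorted(df["subject_id"].unique())
        if len(self.subject_ids) < 2:
            raise ValueError("need at least 2 subjects for a hierarchical fit")
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        self.subject_idx = df["subject_id"].map(index).to_numpy()
        self.n_subjects = len(self.subject_ids)
        self.P = df["win_prob"].to_numpy(dtype=float)
        self.A = df["ambiguity"].to_numpy(dtype=float)
        self.level = df["level"].to_numpy(dtype=int)
        self.choice = df["chose_lottery"].to_numpy(dtype=float)
        self.n_trials = len(df)
        domain = df["domain"].iloc[0]
        self.domain = domain
        scale = get_scale(domain)
        if needs_amounts:
            if scale.amounts is None:
                raise ValueError(
                    f"the classic utility model needs objective amounts; "
                    f"domain {domain!r} has none"
                )
            self.V = np.asarray(scale.amounts, dtype=float)[self.level - 1]
            self.certain_V = float(scale.amounts[0])
        else:
            self.V = None
            self.certain_V = None


def _bincount(idx, weights, n):
    return np.bincount(idx, weights=weights, minlength=n)


class _ClassicLogistic:
    """Classic utility (alpha, beta) with per-subject inverse temperature."""

    def __init__(self, data: _TrialData, hp: HyperpriorSettings):
        self.d = data
        self.hp = hp
        S = data.n_subjects
        self.S = S
        self.sl_b = slice(4, 4 + S)
        self.sl_beta = slice(4 + S, 4 + 2 * S)
        self.sl_gamma = slice(4 + 2 * S, 4 + 3 * S)
        self.ndim = 4 + 3 * S
        self.lnV = np.log(data.V)
        self.ln_c = np.log(data.certain_V)

    # unconstrained layout: [z_a1, z_a2, mu_beta, z_sigma_beta,
    #                        z_b (S), z_beta (S), z_gamma (S)]
    def _unpack(self, z):
        hp = self.hp
        a1 = np.exp(z[0])
        a2 = np.exp(z[1])
        mu_b = z[2]
        sig_b = np.exp(z[3])
        b = sigmoid(z[self.sl_b])
        alpha = 2.0 * b
        s = sigmoid(z[self.sl_beta])
        beta = hp.beta_lower + (hp.beta_upper - hp.beta_lower) * s
        gamma = np.exp(z[self.sl_gamma])
        return a1, a2, mu_b, sig_b, b, alpha, s, beta, gamma

    def _sv_diff(self, alpha, beta):
        d = self.d
        a_t = alpha[d.subject_idx]
        b_t = beta[d.subject_idx]
        Va = d.V**a_t
        ca = d.certain_V**a_t
        w = d.P - b_t * d.A / 2.0
        return w * Va - ca, w, Va, ca

    def logp_grad(self, z):
        d, hp, S = self.d, self.hp, self.S
        a1, a2, mu_b, sig_b, b, alpha, s, beta, gamma = self._unpack(z)
        grad = np.zeros_like(z)
        lp = 0.0

        # hyperpriors on the Beta shapes of alpha/2
        lp1, dx1, _, _ = truncnorm_lower_logpdf(
            a1, hp.alpha_shape1_loc, hp.alpha_shape1_scale
        )
        lp2, dx2, _, _ = truncnorm_lower_logpdf(
            a2, hp.alpha_shape2_loc, hp.alpha_shape2_scale
        )
        lp += float(lp1 + lp2) + z[0] + z[1]
        grad[0] = dx1 * a1 + 1.0
        grad[1] = dx2 * a2 + 1.0

        # subject alpha/2 ~ Beta(a1, a2)
        lpb, _, da1, da2 = beta_logpdf(b, a1, a2)
        lp += float(np.sum(lpb)) + float(
            np.sum(log_sigmoid(z[self.sl_b]) + log_sigmoid(-z[self.sl_b]))
        )
        grad[0] += float(np.sum(da1)) * a1
        grad[1] += float(np.sum(da2)) * a2
        # beta-prior gradient wrt z_b, with the Jacobian's own derivative
        db_prior = (a1 - 1.0) * (1.0 - b) - (a2 - 1.0) * b + (1.0 - 2.0 * b)

        # ambiguity-attitude hierarchy
        lp_mu, dmu0, _, _ = norm_logpdf(
            mu_b, hp.beta_group_mean_loc, hp.beta_group_mean_scale
        )
        lp_s, dsig0 = gamma_logpdf(sig_b, hp.beta_group_sd_shape, hp.beta_group_sd_rate)
        lp += float(lp_mu + lp_s) + z[3]
        lp_beta, dbeta, dmu_b, dsig_b = truncnorm_logpdf(
            beta, mu_b, sig_b, hp.beta_lower, hp.beta_upper
        )
        width = hp.beta_upper - hp.beta_lower
        lp += float(np.sum(lp_beta)) + S * np.log(width) + float(
            np.sum(log_sigmoid(z[self.sl_beta]) + log_sigmoid(-z[self.sl_beta]))
        )
        grad[2] = dmu0 + float(np.sum(dmu_b))
        grad[3] = (dsig0 + float(np.sum(dsig_b))) * sig_b + 1.0
        dz_beta = dbeta * width * s * (1.0 - s) + (1.0 - 2.0 * s)

        # per-subject log inverse temperature ~ Normal(0, 0.25) in log space
        lp_g, dz_g, _, _ = norm_logpdf(
            z[self.sl_gamma], hp.gamma_log_loc, hp.gamma_log_scale
        )
        lp += float(np.sum(lp_g))
        dz_gamma = dz_g.copy()

        # Bernoulli likelihood through the logistic rule
        diff, w, Va, ca = self._sv_diff(alpha, beta)
        g_t = gamma[d.subject_idx]
        x = g_t * diff
        sign = 2.0 * d.choice - 1.0
        lp += float(np.sum(log_sigmoid(sign * x)))
        gx = d.choice - sigmoid(x)
        gd = gx * g_t
        d_alpha = _bincount(
            d.subject_idx, gd * (w * Va * self.lnV - ca * self.ln_c), S
        )
        d_beta_lik = _bincount(d.subject_idx, gd * (-(d.A / 2.0) * Va), S)
        d_gamma_lik = _bincount(d.subject_idx, gx * diff, S)

        grad[self.sl_b] = db_prior + d_alpha * 2.0 * b * (1.0 - b)
        grad[self.sl_beta] = dz_beta + d_beta_lik * width * s * (1.0 - s)
        grad[self.sl_gamma] = dz_gamma + d_gamma_lik * gamma
        return lp, grad

    def pointwise_loglik(self, z):
        d = self.d
        _, _, _, _, _, alpha, _, beta, gamma = self._unpack(z)
        diff, _, _, _ = self._sv_diff(alpha, beta)
        x = gamma[d.subject_idx] * diff
        return log_sigmoid((2.0 * d.choice - 1.0) * x)

    def constrain_draws(self, z):
        hp = self.hp
        width = hp.beta_upper - hp.beta_lower
        return {
            "alpha1": np.exp(z[..., 0]),
            "alpha2": np.exp(z[..., 1]),
            "mu_beta": z[..., 2],
            "sigma_beta": np.exp(z[..., 3]),
            "alpha": 2.0 * sigmoid(z[..., self.sl_b]),
            "beta": hp.beta_lower + width * sigmoid(z[..., self.sl_beta]),
            "gamma": np.exp(z[..., self.sl_gamma]),
        }

    param_dims = {
        "alpha": ("subject",),
        "beta": ("subject",),
        "gamma": ("subject",),
    }

    def initial_point(self, rng):
        z = np.empty(self.ndim)
        z[0] = np.log(self.hp.alpha_shape1_loc)
        z[1] = np.log(self.hp.alpha_shape2_loc)
        z[2] = self.hp.beta_group_mean_loc
        z[3] = 0.0
        z[self.sl_b] = -0.5  # alpha near 0.75
        z[self.sl_beta] = 0.0  # beta near 0
        z[self.sl_gamma] = 0.0  # gamma near 1
        return z + rng.uniform(-0.5, 0.5, size=self.ndim)


class _ClassicTrembling:
    """Classic utility with a trembling-hand (lapse) choice rule."""

    def __init__(self, data: _TrialData, hp: HyperpriorSettings):
        self.d = data
        self.hp = hp
        S = data.n_subjects
        self.S = S
        self.sl_b = slice(6, 6 + S)
        self.sl_beta = slice(6 + S, 6 + 2 * S)
        self.sl_delta = slice(6 + 2 * S, 6 + 3 * S)
        self.ndim = 6 + 3 * S
        self.lnV = np.log(data.V)
        self.ln_c = np.log(data.certain_V)

    # layout: [z_a1, z_a2, mu_beta, z_sigma_beta, z_d1, z_d2,
    #          z_b (S), z_beta (S), z_delta (S)]
    def _unpack(self, z):
        hp = self.hp
        a1, a2 = np.exp(z[0]), np.exp(z[1])
        mu_b, sig_b = z[2], np.exp(z[3])
        d1 = hp.delta_shape_lower + np.exp(z[4])
        d2 = hp.delta_shape_lower + np.exp(z[5])
        b = sigmoid(z[self.sl_b])
        alpha = 2.0 * b
        s = sigmoid(z[self.sl_beta])
        beta = hp.beta_lower + (hp.beta_upper - hp.beta_lower) * s
        delta = sigmoid(z[self.sl_delta])
        return a1, a2, mu_b, sig_b, d1, d2, b, alpha, s, beta, delta

    def _choice_logp(self, diff, z_delta):
        """Stable per-trial log P(observed choice) and intermediates."""
        ld = log_sigmoid(z_delta)  # log delta
        l1md = log_sigmoid(-z_delta)  # log(1 - delta)
        ls_d = log_sigmoid(diff)
        ls_md = log_sigmoid(-diff)
        log_p = np.logaddexp(l1md + ls_d, ld + np.log(0.5))
        log_1mp = np.logaddexp(l1md + ls_md, ld + np.log(0.5))
        return ld, l1md, ls_d, ls_md, log_p, log_1mp

    def logp_grad(self, z):
        d, hp, S = self.d, self.hp, self.S
        a1, a2, mu_b, sig_b, d1, d2, b, alpha, s, beta, delta = self._unpack(z)
        grad = np.zeros_like(z)
        lp = 0.0

        lp1, dx1, _, _ = truncnorm_lower_logpdf(
            a1, hp.alpha_shape1_loc, hp.alpha_shape1_scale
        )
        lp2, dx2, _, _ = truncnorm_lower_logpdf(
            a2, hp.alpha_shape2_loc, hp.alpha_shape2_scale
        )
        lp += float(lp1 + lp2) + z[0] + z[1]
        grad[0] = dx1 * a1 + 1.0
        grad[1] = dx2 * a2 + 1.0

        lpb, _, da1, da2 = beta_logpdf(b, a1, a2)
        lp += float(np.sum(lpb)) + float(
            np.sum(log_sigmoid(z[self.sl_b]) + log_sigmoid(-z[self.sl_b]))
        )
        grad[0] += float(np.sum(da1)) * a1
        grad[1] += float(np.sum(da2)) * a2
        db_prior = (a1 - 1.0) * (1.0 - b) - (a2 - 1.0) * b + (1.0 - 2.0 * b)

        lp_mu, dmu0, _, _ = norm_logpdf(
            mu_b, hp.beta_group_mean_loc, hp.beta_group_mean_scale
        )
        lp_s, dsig0 = gamma_logpdf(sig_b, hp.beta_group_sd_shape, hp.beta_group_sd_rate)
        lp += float(lp_mu + lp_s) + z[3]
        lp_beta, dbeta, dmu_b, dsig_b = truncnorm_logpdf(
            beta, mu_b, sig_b, hp.beta_lower, hp.beta_upper
        )
        width = hp.beta_upper - hp.beta_lower
        lp += float(np.sum(lp_beta)) + S * np.log(width) + float(
            np.sum(log_sigmoid(z[self.sl_beta]) + log_sigmoid(-z[self.sl_beta]))
        )
        grad[2] = dmu0 + float(np.sum(dmu_b))
        grad[3] = (dsig0 + float(np.sum(dsig_b))) * sig_b + 1.0
        dz_beta = dbeta * width * s * (1.0 - s) + (1.0 - 2.0 * s)

        # lapse-rate hierarchy: delta ~ Beta(d1, d2), shapes truncated >= 1
        lp_d1, dxd1, _, _ = truncnorm_lower_logpdf(
            d1, hp.delta_shape_loc, hp.delta_shape_scale, lower=hp.delta_shape_lower
        )
        lp_d2, dxd2, _, _ = truncnorm_lower_logpdf(
            d2, hp.delta_shape_loc, hp.delta_shape_scale, lower=hp.delta_shape_lower
        )
        lp += float(lp_d1 + lp_d2) + z[4] + z[5]
        grad[4] = dxd1 * (d1 - hp.delta_shape_lower) + 1.0
        grad[5] = dxd2 * (d2 - hp.delta_shape_lower) + 1.0

        lpd, _, dd1, dd2 = beta_logpdf(delta, d1, d2)
        lp += float(np.sum(lpd)) + float(
            np.sum(log_sigmoid(z[self.sl_delta]) + log_sigmoid(-z[self.sl_delta]))
        )
        grad[4] += float(np.sum(dd1)) * (d1 - hp.delta_shape_lower)
        grad[5] += float(np.sum(dd2)) * (d2 - hp.delta_shape_lower)
        dz_delta = (
            (d1 - 1.0) * (1.0 - delta) - (d2 - 1.0) * delta + (1.0 - 2.0 * delta)
        )

        # likelihood
        a_t = alpha[d.subject_idx]
        b_t = beta[d.subject_idx]
        Va = d.V**a_t
        ca = d.certain_V**a_t
        w = d.P - b_t * d.A / 2.0
        diff = w * Va - ca
        zd_t = z[self.sl_delta][d.subject_idx]
        ld, l1md, ls_d, ls_md, log_p, log_1mp = self._choice_logp(diff, zd_t)
        chose = d.choice > 0.5
        lp += float(np.sum(np.where(chose, log_p, log_1mp)))

        sig_diff = sigmoid(diff)
        # d loglik / d diff, computed through log-space ratios for stability
        gd = np.where(
            chose,
            np.exp(l1md + ls_d - log_p) * sigmoid(-diff),
            -np.exp(l1md + ls_md - log_1mp) * sig_diff,
        )
        # d loglik / d z_delta (bounded once the Jacobian delta(1-delta) is folded in)
        gzd = np.where(
            chose,
            (0.5 - sig_diff) * np.exp(ld + l1md - log_p),
            (sig_diff - 0.5) * np.exp(ld + l1md - log_1mp),
        )

        d_alpha = _bincount(d.subject_idx, gd * (w * Va * self.lnV - ca * self.ln_c), S)
        d_beta_lik = _bincount(d.subject_idx, gd * (-(d.A / 2.0) * Va), S)
        d_delta_lik = _bincount(d.subject_idx, gzd, S)

        grad[self.sl_b] = db_prior + d_alpha * 2.0 * b * (1.0 - b)
        grad[self.sl_beta] = dz_beta + d_beta_lik * width * s * (1.0 - s)
        grad[self.sl_delta] = dz_delta + d_delta_lik
        return lp, grad

    def pointwise_loglik(self, z):
        d = self.d
        _, _, _, _, _, _, _, alpha, _, beta, _ = self._unpack(z)
        a_t = alpha[d.subject_idx]
        w = d.P - beta[d.subject_idx] * d.A / 2.0
        diff = w * d.V**a_t - d.certain_V**a_t
        zd_t = z[self.sl_delta][d.subject_idx]
        _, _, _, _, log_p, log_1mp = self._choice_logp(diff, zd_t)
        return np.where(d.choice > 0.5, log_p, log_1mp)

    def constrain_draws(self, z):
        hp = self.hp
        width = hp.beta_upper - hp.beta_lower
        return {
            "alpha1": np.exp(z[..., 0]),
            "alpha2": np.exp(z[..., 1]),
            "mu_beta": z[..., 2],
            "sigma_beta": np.exp(z[..., 3]),
            "delta1": hp.delta_shape_lower + np.exp(z[..., 4]),
            "delta2": hp.delta_shape_lower + np.exp(z[..., 5]),
            "alpha": 2.0 * sigmoid(z[..., self.sl_b]),
            "beta": hp.beta_lower + width * sigmoid(z[..., self.sl_beta]),
            "delta": sigmoid(z[..., self.sl_delta]),
        }

    param_dims = {
        "alpha": ("subject",),
        "beta": ("subject",),
        "delta": ("subject",),
    }

    def initial_point(self, rng):
        z = np.empty(self.ndim)
        z[0] = np.log(self.hp.alpha_shape1_loc)
        z[1] = np.log(self.hp.alpha_shape2_loc)
        z[2] = self.hp.beta_group_mean_loc
        z[3] = 0.0
        z[4] = z[5] = 0.0  # delta shapes near 2
        z[self.sl_b] = -0.5
        z[self.sl_beta] = 0.0
        z[self.sl_delta] = -2.0  # lapse rate near 0.12
        return z + rng.uniform(-0.5, 0.5, size=self.ndim)


class _EstimatedValueLogistic:
    """Cumulative ordinal-increment values with a logistic choice rule."""

    N_LEVELS = 4

    def __init__(self, data: _TrialData, hp: HyperpriorSettings):
        self.d = data
        self.hp = hp
        S = data.n_subjects
        self.S = S
        K = self.N_LEVELS
        self.sl_mu_nu = slice(2, 2 + K)
        self.sl_sigma_nu = slice(2 + K, 2 + 2 * K)
        base = 2 + 2 * K
        self.sl_beta = slice(base, base + S)
        self.sl_nu = slice(base + S, base + S + S * K)
        self.sl_gamma = slice(base + S + S * K, base + S + S * K + S)
        self.ndim = base + S + S * K + S

    # layout: [mu_beta, z_sigma_beta, z_mu_nu (4), z_sigma_nu (4),
    #          z_beta (S), z_nu (S*4), z_gamma (S)]
    def _unpack(self, z):
        hp = self.hp
        mu_b, sig_b = z[0], np.exp(z[1])
        mu_nu = np.exp(z[self.sl_mu_nu])
        sigma_nu = np.exp(z[self.sl_sigma_nu])
        s = sigmoid(z[self.sl_beta])
        beta = hp.beta_lower + (hp.beta_upper - hp.beta_lower) * s
        nu = np.exp(z[self.sl_nu]).reshape(self.S, self.N_LEVELS)
        gamma = np.exp(z[self.sl_gamma])
        return mu_b, sig_b, mu_nu, sigma_nu, s, beta, nu, gamma

    def logp_grad(self, z):
        d, hp, S, K = self.d, self.hp, self.S, self.N_LEVELS
        mu_b, sig_b, mu_nu, sigma_nu, s, beta, nu, gamma = self._unpack(z)
        grad = np.zeros_like(z)
        lp = 0.0

        # ambiguity-attitude hierarchy (same block as the classic model)
        lp_mu, dmu0, _, _ = norm_logpdf(
            mu_b, hp.beta_group_mean_loc, hp.beta_group_mean_scale
        )
        lp_s, dsig0 = gamma_logpdf(sig_b, hp.beta_group_sd_shape, hp.beta_group_sd_rate)
        lp += float(lp_mu + lp_s) + z[1]
        lp_beta, dbeta, dmu_b, dsig_b = truncnorm_logpdf(
            beta, mu_b, sig_b, hp.beta_lower, hp.beta_upper
        )
        width = hp.beta_upper - hp.beta_lower
        lp += float(np.sum(lp_beta)) + S * np.log(width) + float(
            np.sum(log_sigmoid(z[self.sl_beta]) + log_sigmoid(-z[self.sl_beta]))
        )
        grad[0] = dmu0 + float(np.sum(dmu_b))
        grad[1] = (dsig0 + float(np.sum(dsig_b))) * sig_b + 1.0
        dz_beta = dbeta * width * s * (1.0 - s) + (1.0 - 2.0 * s)

        # increment-value hierarchy: nu_si ~ N(mu_nu_i, sigma_nu_i) on [0, inf)
        lp_mn, dmn, _, _ = truncnorm_lower_logpdf(
            mu_nu, hp.nu_group_mean_loc, hp.nu_group_mean_scale
        )
        lp += float(np.sum(lp_mn)) + float(np.sum(z[self.sl_mu_nu]))
        lp_sn, dsn = gamma_logpdf(sigma_nu, hp.nu_group_sd_shape, hp.nu_group_sd_rate)
        lp += float(np.sum(lp_sn)) + float(np.sum(z[self.sl_sigma_nu]))
        lp_nu, dnu, dmu_nu, dsigma_nu = truncnorm_lower_logpdf(
            nu, mu_nu[None, :], sigma_nu[None, :]
        )
        lp += float(np.sum(lp_nu)) + float(np.sum(z[self.sl_nu]))
        grad[self.sl_mu_nu] = (dmn + dmu_nu.sum(axis=0)) * mu_nu + 1.0
        grad[self.sl_sigma_nu] = (dsn + dsigma_nu.sum(axis=0)) * sigma_nu + 1.0

        # per-subject log inverse temperature
        lp_g, dz_g, _, _ = norm_logpdf(
            z[self.sl_gamma], hp.gamma_log_loc, hp.gamma_log_scale
        )
        lp += float(np.sum(lp_g))

        # likelihood
        cum = np.cumsum(nu, axis=1)
        C_t = cum[d.subject_idx, d.level - 1]
        b_t = beta[d.subject_idx]
        w = d.P - b_t * d.A / 2.0
        diff = w * C_t - nu[d.subject_idx, 0]
        g_t = gamma[d.subject_idx]
        x = g_t * diff
        sign = 2.0 * d.choice - 1.0
        lp += float(np.sum(log_sigmoid(sign * x)))
        gx = d.choice - sigmoid(x)
        gd = gx * g_t

        d_nu_lik = np.zeros((S, K))
        gdw = gd * w
        for i in range(K):
            mask = d.level >= i + 1
            d_nu_lik[:, i] = _bincount(d.subject_idx[mask], gdw[mask], S)
        d_nu_lik[:, 0] -= _bincount(d.subject_idx, gd, S)
        d_beta_lik = _bincount(d.subject_idx, gd * (-(d.A / 2.0) * C_t), S)
        d_gamma_lik = _bincount(d.subject_idx, gx * diff, S)

        grad[self.sl_beta] = dz_beta + d_beta_lik * width * s * (1.0 - s)
        grad[self.sl_nu] = ((dnu + d_nu_lik) * nu + 1.0).ravel()
        grad[self.sl_gamma] = dz_g + d_gamma_lik * gamma
        return lp, grad

    def pointwise_loglik(self, z):
        d = self.d
        _, _, _, _, _, beta, nu, gamma = self._unpack(z)
        cum = np.cumsum(nu, axis=1)
        C_t = cum[d.subject_idx, d.level - 1]
        w = d.P - beta[d.subject_idx] * d.A / 2.0
        diff = w * C_t - nu[d.subject_idx, 0]
        x = gamma[d.subject_idx] * diff
        return log_sigmoid((2.0 * d.choice - 1.0) * x)

    def constrain_draws(self, z):
        hp = self.hp
        width = hp.beta_upper - hp.beta_lower
        lead = z.shape[:-1]
        return {
            "mu_beta": z[..., 0],
            "sigma_beta": np.exp(z[..., 1]),
            "mu_nu": np.exp(z[..., self.sl_mu_nu]),
            "sigma_nu": np.exp(z[..., self.sl_sigma_nu]),
            "beta": hp.beta_lower + width * sigmoid(z[..., self.sl_beta]),
            "nu": np.exp(z[..., self.sl_nu]).reshape(
                *lead, self.S, self.N_LEVELS
            ),
            "gamma": np.exp(z[..., self.sl_gamma]),
        }

    param_dims = {
        "mu_nu": ("level",),
        "sigma_nu": ("level",),
        "beta": ("subject",),
        "nu": ("subject", "level"),
        "gamma": ("subject",),
    }

    def initial_point(self, rng):
        z = np.empty(self.ndim)
        z[0] = self.hp.beta_group_mean_loc
        z[1] = 0.0
        z[self.sl_mu_nu] = np.log(self.hp.nu_group_mean_loc)
        z[self.sl_sigma_nu] = np.log(2.0)
        z[self.sl_beta] = 0.0
        z[self.sl_nu] = np.log(self.hp.nu_group_mean_loc)
        z[self.sl_gamma] = 0.0
        return z + rng.uniform(-0.5, 0.5, size=self.ndim)


class _FixedLogistic:
    """Baseline: category index as value, one shared inverse temperature."""

    def __init__(self, data: _TrialData, hp: HyperpriorSettings):
        self.d = data
        self.hp = hp
        self.ndim = 1
        self.diff = (data.P - data.A / 2.0) * data.level - 1.0

    def logp_grad(self, z):
        hp = self.hp
        gamma = np.exp(z[0])
        lp_g, dz_g, _, _ = norm_logpdf(z[0], hp.gamma_log_loc, hp.gamma_log_scale)
        x = gamma * self.diff
        sign = 2.0 * self.d.choice - 1.0
        lp = float(lp_g) + float(np.sum(log_sigmoid(sign * x)))
        gx = self.d.choice - sigmoid(x)
        grad = np.array([float(dz_g) + float(np.sum(gx * self.diff)) * gamma])
        return lp, grad

    def pointwise_loglik(self, z):
        x = np.exp(z[0]) * self.diff
        return log_sigmoid((2.0 * self.d.choice - 1.0) * x)

    def constrain_draws(self, z):
        return {"gamma_shared": np.exp(z[..., 0])}

    param_dims: dict = {}

    def initial_point(self, rng):
        return np.array([0.0]) + rng.uniform(-0.5, 0.5, size=1)


def _build_model(spec: ModelSpec, data: ChoiceDataset):
    needs_amounts = spec.sv_model == "classic_utility"
    trial_data = _TrialData(data, needs_amounts=needs_amounts)
    if spec.sv_model == "classic_utility":
        cls = (
            _ClassicTrembling
            if spec.choice_rule == "trembling_hand"
            else _ClassicLogistic
        )
    elif spec.sv_model == "estimated_value":
        cls = _EstimatedValueLogistic
    else:
        cls = _FixedLogistic
    return cls(trial_data, spec.hyperpriors), trial_data


@dataclass
class PosteriorFit:
    """MCMC draws, per-trial pointwise log-likelihood and diagnostics."""

    idata: az.InferenceData
    spec: ModelSpec
    subject_ids: list
    n_trials: int

    @property
    def pointwise_loglik(self) -> np.ndarray:
        """(total draws, trials) matrix pooled over chains."""
        ll = self.idata.log_likelihood["chose_lottery"].to_numpy()
        return ll.reshape(-1, ll.shape[-1])

    def diagnostics(self) -> dict:
        return diagnostics(self)


def fit_model(
    spec: ModelSpec,
    data: ChoiceDataset,
    settings: SamplerSettings | None = None,
) -> PosteriorFit:
    """Fit one hierarchical model by NUTS and package the result.

    The returned fit carries the full posterior (group-level and subject-
    level parameters on their natural scales), the per-trial pointwise
    log-likelihood needed for PSIS-LOO, and sampler statistics. Divergent
    transitions are reported in ``sample_stats`` and surfaced by
    :func:`diagnostics`; they never fail silently.
    """
    settings = settings or SamplerSettings()
    model, trial_data = _build_model(spec, data)
    res = sample_nuts(
        model.logp_grad,
        model.ndim,
        draws=settings.draws,
        tune=settings.tune,
        chains=settings.chains,
        target_accept=settings.target_accept,
        seed=settings.seed,
        initial_point=model.initial_point,
        dense_mass=settings.dense_mass,
    )
    chains, draws, _ = res.position.shape
    posterior = model.constrain_draws(res.position)
    ll = np.empty((chains, draws, trial_data.n_trials))
    for c in range(chains):
        for i in range(draws):
            ll[c, i] = model.pointwise_loglik(res.position[c, i])
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite pointwise log-likelihood in the fit")
    coords = {
        "subject": trial_data.subject_ids,
        "level": [1, 2, 3, 4],
        "trial": np.arange(trial_data.n_trials),
    }
    dims = {k: list(v) for k, v in model.param_dims.items()}
    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"chose_lottery": ll},
        sample_stats={
            "diverging": res.diverging,
            "lp": res.logp,
            "tree_depth": res.tree_depth,
            "acceptance_rate": res.accept_rate,
            "n_steps": res.n_leapfrog,
        },
        coords=coords,
        dims={**dims, "chose_lottery": ["trial"]},
    )
    idata.posterior.attrs.update(
        {
            "model": spec.name,
            "sv_model": spec.sv_model,
            "choice_rule": spec.choice_rule,
            "seed": settings.seed,
            "draws": settings.draws,
            "tune": settings.tune,
            "chains": settings.chains,
            "target_accept": settings.target_accept,
            "domain": trial_data.domain,
        }
    )
    fit = PosteriorFit(
        idata=idata,
        spec=spec,
        subject_ids=trial_data.subject_ids,
        n_trials=trial_data.n_trials,
    )
    n_div = res.n_divergences
    if n_div:
        log.warning("%d divergent transitions in %s fit", n_div, spec.name)
    return fit


def diagnostics(fit: PosteriorFit) -> dict:
    """Max split R-hat, min bulk ESS and divergence count over all parameters."""
    posterior = fit.idata.posterior
    if posterior.sizes["chain"] < 2:
        raise ValueError("split R-hat needs at least 2 chains")
    rhat = az.rhat(posterior)
    ess = az.ess(posterior, method="bulk")
    max_rhat = max(float(v.max()) for v in rhat.data_vars.values())
    min_ess = min(float(v.min()) for v in ess.data_vars.values())
    n_div = int(fit.idata.sample_stats["diverging"].sum())
    return {"max_rhat": max_rhat, "min_ess": min_ess, "n_divergences": n_div}


def extract_subject_estimates(
    fit: PosteriorFit, parameters: list[str] | None = None
) -> pd.DataFrame:
    """Posterior means and sds of the per-subject parameters, one row per subject.

    Increment values (nu) are reported as the additive level-to-level gains,
    i.e. on the same scale as the group means. Models without subject-level
    parameters yield an empty table. ``parameters`` restricts the output to
    the named subject-level parameters; naming one the fitted model lacks is
    an error.
    """
    posterior = fit.idata.posterior
    subject_vars = [v for v in posterior.data_vars if "subject" in posterior[v].dims]
    if parameters is not None:
        missing = sorted(set(parameters) - set(subject_vars))
        if missing:
            raise KeyError(
                f"model {fit.spec.name!r} has no subject-level parameters {missing}"
            )
        subject_vars = [v for v in subject_vars if v in parameters]
    if not subject_vars:
        return pd.DataFrame(index=pd.Index([], name="subject_id"))
    out = pd.DataFrame(index=pd.Index(fit.subject_ids, name="subject_id"))
    for var in subject_vars:
        da = posterior[var]
        mean = da.mean(dim=("chain", "draw"))
        sd = da.std(dim=("chain", "draw"))
        if "level" in da.dims:
            for lvl in da["level"].to_numpy():
                out[f"{var}{lvl}_mean"] = mean.sel(level=lvl).to_numpy()
                out[f"{var}{lvl}_sd"] = sd.sel(level=lvl).to_numpy()
        else:
            out[f"{var}_mean"] = mean.to_numpy()
            out[f"{var}_sd"] = sd.to_numpy()
    return out


def save_fit(fit: PosteriorFit, path: str | Path) -> Path:
    """Persist a fit; NetCDF when a backend is available, .npz otherwise."""
    path = Path(path)
    try:
        fit.idata.to_netcdf(str(path))
        return path
    except (ImportError, ModuleNotFoundError, ValueError):
        pass
    npz_path = path.with_suffix(".npz")
    payload = {}
    for group in ("posterior", "log_likelihood", "sample_stats"):
        ds = getattr(fit.idata, group)
        for name, da in ds.data_vars.items():
            payload[f"{group}/{name}"] = da.to_numpy()
    meta = {
        "sv_model": fit.spec.sv_model,
        "choice_rule": fit.spec.choice_rule,
        "subject_ids": list(map(str, fit.subject_ids)),
        "n_trials": fit.n_trials,
    }
    np.savez_compressed(npz_path, _meta=json.dumps(meta), **payload)
    return npz_path


def load_fit(path: str | Path) -> az.InferenceData:
    """Load a persisted fit back into an InferenceData object."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as archive:
            groups: dict[str, dict] = {}
            for key in archive.files:
                if key == "_meta":
                    continue
                group, name = key.split("/", 1)
                groups.setdefault(group, {})[name] = archive[key]
        return az.from_dict(
            posterior=groups.get("posterior"),
            log_likelihood=groups.get("log_likelihood"),
            sample_stats=groups.get("sample_stats"),
        )
    return az.from_netcdf(str(path))
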