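"""PSIS-LOO model comparison (Table-2-style ranking with stacking weights).

Out-of-sample predictive fit is estimated per trial by Pareto-smoothed
importance-sampling leave-one-out cross-validation (PSIS-LOO) on the
pointwise log-likelihood matrix; models are ranked by expected log
pointwise predictive density (ELPD, higher is better) and weighted by
stacking of predictive distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .inference.hierarchical import PosteriorFit

__all__ = ["LooResult", "ComparisonTable", "psis_loo", "compare"]

_K_WARN = 0.7  # Pareto-k above this makes the importance estimate unreliable
# below this spread a trial's likelihood is effectively constant across
# draws and its leave-one-out density is known exactly (no importance
# sampling needed; the Pareto fit breaks down on constant weights)
_DEGENERATE_SPAN = 1e-6


@dataclass
class LooResult:
    """PSIS-LOO estimate for one fitted model."""

    elpd_loo: float
    p_loo: float
    se: float
    pareto_k: np.ndarray
    pointwise: np.ndarray  # per-trial elpd contributions
    warning: bool

    @property
    def n_trials(self) -> int:
        return self.pointwise.size


def _loglik_array(fit: PosteriorFit | np.ndarray) -> np.ndarray:
    """(chain, draw, trial) log-likelihood array from either input form."""
    if isinstance(fit, PosteriorFit):
        return fit.idata.log_likelihood["chose_lottery"].to_numpy()
    matrix = np.asarray(fit, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, trials)")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("log-likelihood matrix must be finite")
    if matrix.shape[0] < 100:
        raise ValueError("need at least 100 draws for PSIS-LOO")
    return matrix[None, :, :]


def psis_loo(fit: PosteriorFit | np.ndarray) -> LooResult:
    """PSIS-LOO from a fit or a raw (draws x trials) log-likelihood matrix.

    Raw matrices are treated as a single chain with unit relative
    efficiency. Trials whose likelihood is constant across draws are scored
    exactly (their LOO density equals their posterior density); the rest go
    through the Pareto-smoothed importance-sampling estimator. A result
    with any Pareto-k diagnostic above 0.7 carries ``warning=True``: those
    trials' importance weights have heavy tails and the corresponding
    contributions are unreliable.
    """
    ll3 = _loglik_array(fit)
    n_chains, n_draws, n_trials = ll3.shape
    flat = ll3.reshape(-1, n_trials)
    total_draws = flat.shape[0]

    span = flat.max(axis=0) - flat.min(axis=0)
    degenerate = span < _DEGENERATE_SPAN
    loo_i = np.empty(n_trials)
    pareto_k = np.zeros(n_trials)

    if degenerate.any():
        loo_i[degenerate] = (
            logsumexp(flat[:, degenerate], axis=0) - np.log(total_draws)
        )
    if (~degenerate).any():
        kept = ll3[:, :, ~degenerate]
        idata = az.from_dict(log_likelihood={"chose_lottery": kept})
        if n_chains == 1:
            reff = 1.0
        else:
            # relative MCMC efficiency from the log-likelihood draws
            ess = az.ess(az.convert_to_dataset(kept), method="mean")["x"]
            reff = float(np.nanmean(ess.to_numpy())) / total_draws
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            elpd = az.loo(idata, pointwise=True, reff=reff)
        sub_loo = np.asarray(elpd.loo_i, dtype=float)
        sub_k = np.asarray(elpd.pareto_k, dtype=float)
        # a non-finite PSIS entry means the smoothing failed on near-constant
        # weights; the exact posterior density is the correct limit there
        bad = ~np.isfinite(sub_loo)
        if bad.any():
            kept_flat = kept.reshape(-1, kept.shape[-1])
            sub_loo[bad] = (
                logsumexp(kept_flat[:, bad], axis=0) - np.log(total_draws)
            )
            sub_k[bad] = 0.0
        loo_i[~degenerate] = sub_loo
        pareto_k[~degenerate] = sub_k

    # lppd - elpd_loo is the effective parameter count; degenerate trials
    # contribute exactly zero to it
    lppd_i = logsumexp(flat, axis=0) - np.log(total_draws)
    return LooResult(
        elpd_loo=float(loo_i.sum()),
        p_loo=float((lppd_i - loo_i).sum()),
        se=float(np.sqrt(n_trials * np.var(loo_i))),
        pareto_k=pareto_k,
        pointwise=loo_i,
        warning=bool(np.any(pareto_k > _K_WARN)),
    )


def _stacking_weights(pointwise: np.ndarray) -> np.ndarray:
    """Stacking of predictive distributions: maximize the summed log of the
    weighted pointwise LOO densities over the simplex (softmax-parameterized
    to keep the optimization unconstrained)."""
    n_models, n_trials = pointwise.shape
    shifted = pointwise - pointwise.max(axis=0, keepdims=True)

    def objective(theta):
        w = softmax(np.append(theta, 0.0))
        dens = w @ np.exp(shifted)
        obj = -np.sum(np.log(np.maximum(dens, 1e-300)))
        grad_w = -(np.exp(shifted) / np.maximum(dens, 1e-300)).sum(axis=1)
        jac = -np.outer(w[:-1], w)  # d w_j / d theta_m = w_m (delta_mj - w_j)
        jac[:, : n_models - 1] += np.diag(w[:-1])
        return obj, jac @ grad_w

    res = minimize(
        objective,
        np.zeros(n_models - 1),
        jac=True,
        method="BFGS",
        options={"maxiter": 500},
    )
    return softmax(np.append(res.x, 0.0))


@dataclass
class ComparisonTable:
    """Ranked LOO comparison; rank 0 is the best-predicting model."""

    table: pd.DataFrame

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def to_csv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={
                "rank": "Rank",
                "elpd_loo": "LOO",
                "p_loo": "p_loo",
                "d_loo": "d_loo",
                "weight": "Weight",
                "se": "SE",
            }
        )
        out.to_csv(path, index_label="model")


def compare(results: dict[str, PosteriorFit | LooResult]) -> ComparisonTable:
    """Rank >= 2 models fitted to the same trials.

    ELPD differences (d_loo) are taken against the best model and weights
    are stacking weights of the predictive distributions. Exact ties in the
    pointwise predictive density split weights evenly. Rank ties are broken
    by model name for a stable ordering.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 models to compare")
    loos = {
        name: (res if isinstance(res, LooResult) else psis_loo(res))
        for name, res in results.items()
    }
    n_trials = {name: r.n_trials for name, r in loos.items()}
    if len(set(n_trials.values())) != 1:
        raise ValueError(f"models were fitted to different trial counts: {n_trials}")

    names = sorted(loos)
    pointwise = np.stack([loos[n].pointwise for n in names])
    if np.allclose(pointwise, pointwise[0], atol=1e-10):
        weights = dict.fromkeys(names, 1.0 / len(names))
    else:
        w = _stacking_weights(pointwise)
        weights = dict(zip(names, w))

    rows = []
    for name in names:
        r = loos[name]
        rows.append(
            {
                "model": name,
                "elpd_loo": r.elpd_loo,
                "p_loo": r.p_loo,
                "weight": weights[name],
                "se": r.se,
                "warning": r.warning,
            }
        )
    frame = pd.DataFrame(rows).set_index("model")
    frame = frame.loc[
        sorted(frame.index, key=lambda n: (-frame.loc[n, "elpd_loo"], n))
    ]
    frame["rank"] = np.arange(len(frame))
    frame["d_loo"] = frame["elpd_loo"].iloc[0] - frame["elpd_loo"]
    frame = frame[["rank", "elpd_loo", "p_loo", "d_loo", "weight", "se", "warning"]]
    return ComparisonTable(table=frame)
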