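"""No-U-Turn sampler with multinomial trajectory sampling.

A self-contained NUTS implementation over a user-supplied log-density and
gradient in unconstrained space. Warmup follows the windowed scheme that is
standard in modern HMC tooling: dual-averaging step-size adaptation toward
a target acceptance statistic throughout warmup, and a diagonal mass matrix
re-estimated over a sequence of doubling memory windows. Trajectories are
grown by doubling until a U-turn or the maximum tree depth, with biased
progressive (multinomial) sampling of the proposal and a divergence check
on the energy error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "sample_nuts"]

log = logging.getLogger(__name__)

_DIVERGENCE_THRESHOLD = 1000.0  # energy error declaring a divergent transition


@dataclass
class NutsResult:
    """Posterior draws in unconstrained space plus sampler statistics."""

    position: np.ndarray  # (chains, draws, ndim)
    logp: np.ndarray  # (chains, draws)
    diverging: np.ndarray  # (chains, draws) bool
    tree_depth: np.ndarray  # (chains, draws) int
    accept_rate: np.ndarray  # (chains, draws)
    n_leapfrog: np.ndarray  # (chains, draws) int
    step_size: np.ndarray  # (chains,)

    @property
    def n_divergences(self) -> int:
        return int(self.diverging.sum())


class _DualAverage:
    """Nesterov dual averaging of log step size (Hoffman & Gelman)."""

    def __init__(self, eps0: float, target: float):
        self.target = target
        self.restart(eps0)

    def restart(self, eps0: float) -> None:
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0

    def update(self, accept_stat: float) -> float:
        self.m += 1
        gamma, t0, kappa = 0.05, 10.0, 0.75
        w = 1.0 / (self.m + t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.m) / gamma * self.h_bar
        eta = self.m**-kappa
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted_eps(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Streaming mean/variance for the mass-matrix windows."""

    def __init__(self, ndim: int, dense: bool = False):
        self.dense = dense
        self.n = 0
        self.mean = np.zeros(ndim)
        self.m2 = np.zeros((ndim, ndim)) if dense else np.zeros(ndim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        if self.dense:
            self.m2 += np.outer(delta, x - self.mean)
        else:
            self.m2 += delta * (x - self.mean)

    def variance(self):
        if self.n < 2:
            if self.dense:
                return np.eye(self.mean.size)
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # shrink toward a small (co)variance, as in Stan's warmup
        w = self.n / (self.n + 5.0)
        if self.dense:
            d = self.mean.size
            if self.n < 2 * d:
                # too few samples to resolve a d x d covariance: an
                # ill-conditioned dense metric is far worse than none,
                # so keep only its diagonal
                return w * np.diag(var) + (1.0 - w) * 1e-3
            return w * var + (1.0 - w) * 1e-3 * np.eye(d)
        return w * var + (1.0 - w) * 1e-3


class _Metric:
    """Euclidean metric: the inverse mass matrix is the (co)variance
    estimate of the unconstrained posterior, diagonal or dense."""

    def __init__(self, value: np.ndarray):
        self.dense = value.ndim == 2
        self.value = value
        if self.dense:
            self._chol = np.linalg.cholesky(value)
            # momentum covariance is the inverse of `value`
            self._l_inv_t = np.linalg.inv(self._chol).T

    def sample_momentum(self, rng, ndim: int) -> np.ndarray:
        z = rng.standard_normal(ndim)
        if self.dense:
            return self._l_inv_t @ z
        return z / np.sqrt(self.value)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        if self.dense:
            return self.value @ p
        return self.value * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(np.dot(p, self.velocity(p)))


def _warmup_schedule(tune: int) -> tuple[int, int, int]:
    """(init_buffer, term_buffer, base_window) scaled to the warmup length."""
    if tune >= 150:
        return 75, 50, 25
    init_buf = max(1, int(0.15 * tune))
    term_buf = max(1, int(0.10 * tune))
    base = max(1, tune - init_buf - term_buf)
    return init_buf, term_buf, base


def _find_initial_step_size(logp_grad, q, metric, rng, target=0.8) -> float:
    """Double/halve a trial step until the one-step accept ratio crosses 1/2."""
    eps = 1.0
    lp, grad = logp_grad(q)
    p = metric.sample_momentum(rng, q.size)

    def energy_error(eps):
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * metric.velocity(p1)
        lp1, grad1 = logp_grad(q1)
        p2 = p1 + 0.5 * eps * grad1
        h0 = lp - metric.kinetic(p)
        h1 = lp1 - metric.kinetic(p2)
        return h1 - h0

    d_h = energy_error(eps)
    if not np.isfinite(d_h):
        d_h = -np.inf
    direction = 1.0 if d_h > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        d_h = energy_error(eps)
        if not np.isfinite(d_h):
            d_h = -np.inf
        if (direction == 1.0 and d_h <= np.log(0.5)) or (
            direction == -1.0 and d_h >= np.log(0.5)
        ):
            break
        if not (1e-8 < eps < 1e3):
            break
    return float(np.clip(eps, 1e-8, 1e3))


class _Tree:
    """Recursive trajectory builder for one NUTS transition."""

    __slots__ = ("logp_grad", "metric", "eps", "h0", "rng", "sum_accept", "n_leap")

    def __init__(self, logp_grad, metric, eps, h0, rng):
        self.logp_grad = logp_grad
        self.metric = metric
        self.eps = eps
        self.h0 = h0
        self.rng = rng
        self.sum_accept = 0.0
        self.n_leap = 0

    def leapfrog(self, q, p, grad, direction):
        eps = self.eps * direction
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * self.metric.velocity(p1)
        lp1, grad1 = self.logp_grad(q1)
        p2 = p1 + 0.5 * eps * grad1
        self.n_leap += 1
        return q1, p2, lp1, grad1

    def build(self, q, p, grad, depth, direction):
        """Returns (minus_state, plus_state, proposal, log_w, rho, stop)
        where states are (q, p, grad) tuples and proposal is (q, lp, diverged)."""
        if depth == 0:
            q1, p1, lp1, grad1 = self.leapfrog(q, p, grad, direction)
            if np.all(np.isfinite(p1)) and np.isfinite(lp1):
                h1 = lp1 - self.metric.kinetic(p1)
            else:
                h1 = -np.inf
            d_h = h1 - self.h0
            diverged = not np.isfinite(d_h) or d_h < -_DIVERGENCE_THRESHOLD
            self.sum_accept += float(np.exp(min(0.0, d_h))) if np.isfinite(d_h) else 0.0
            state = (q1, p1, grad1)
            log_w = d_h if not diverged else -np.inf
            return state, state, (q1, lp1, diverged), log_w, p1.copy(), diverged

        # first half (inner subtree)
        minus, plus, prop1, log_w1, rho1, stop1 = self.build(
            q, p, grad, depth - 1, direction
        )
        if stop1:
            return minus, plus, prop1, log_w1, rho1, True
        # second half grows from the outer edge in the same direction
        edge = plus if direction > 0 else minus
        minus2, plus2, prop2, log_w2, rho2, stop2 = self.build(
            edge[0], edge[1], edge[2], depth - 1, direction
        )
        if direction > 0:
            plus = plus2
        else:
            minus = minus2
        log_w = np.logaddexp(log_w1, log_w2)
        # multinomial choice between the two halves' proposals
        if np.isfinite(log_w2) and np.log(self.rng.uniform()) < log_w2 - log_w:
            prop = prop2
        else:
            prop = prop1
        rho = rho1 + rho2
        stop = stop2 or self._turning(rho, minus[1], plus[1])
        return minus, plus, prop, log_w, rho, stop

    def _turning(self, rho, p_minus, p_plus) -> bool:
        return (
            np.dot(rho, self.metric.velocity(p_minus)) <= 0.0
            or np.dot(rho, self.metric.velocity(p_plus)) <= 0.0
        )


def _nuts_transition(logp_grad, q, lp, grad, metric, eps, max_treedepth, rng):
    p0 = metric.sample_momentum(rng, q.size)
    h0 = lp - metric.kinetic(p0)
    tree = _Tree(logp_grad, metric, eps, h0, rng)
    minus = plus = (q, p0, grad)
    rho = p0.copy()
    log_w_tot = 0.0  # weight of the initial point, exp(h0 - h0)
    q_new, lp_new = q, lp
    diverged = False
    depth = 0
    for depth in range(1, max_treedepth + 1):
        direction = 1.0 if rng.uniform() < 0.5 else -1.0
        edge = plus if direction > 0 else minus
        sub_minus, sub_plus, prop, log_w_sub, rho_sub, stop = tree.build(
            edge[0], edge[1], edge[2], depth - 1, direction
        )
        if direction > 0:
            plus = sub_plus
        else:
            minus = sub_minus
        if prop[2]:
            diverged = True
        if stop:
            depth -= 1
            break
        # biased progressive sampling: favor the fresh subtree
        if np.isfinite(log_w_sub) and np.log(rng.uniform()) < log_w_sub - log_w_tot:
            q_new, lp_new = prop[0], prop[1]
        log_w_tot = np.logaddexp(log_w_tot, log_w_sub)
        rho = rho + rho_sub
        if tree._turning(rho, minus[1], plus[1]):
            break
    accept_stat = tree.sum_accept / max(tree.n_leap, 1)
    if q_new is not q:
        lp_new, grad_new = logp_grad(q_new)
    else:
        grad_new = grad
    return q_new, lp_new, grad_new, accept_stat, diverged, depth, tree.n_leap


def _sample_chain(
    logp_grad, q0, draws, tune, target_accept, max_treedepth, dense_mass, rng
):
    ndim = q0.size
    lp, grad = logp_grad(q0)
    if not np.isfinite(lp):
        raise ValueError("non-finite log-density at the initial point")
    metric = _Metric(np.ones(ndim))
    eps = _find_initial_step_size(logp_grad, q0, metric, rng, target_accept)
    da = _DualAverage(eps, target_accept)
    init_buf, term_buf, base = _warmup_schedule(tune)
    window_end = min(init_buf + base, tune - term_buf)
    # a dense estimate is only trustworthy from a long, late window, once
    # the chain has settled; earlier windows stay diagonal
    dense_now = dense_mass and window_end == tune - term_buf
    welford = _Welford(ndim, dense_now)
    next_window = base

    q = q0.copy()
    pos = np.empty((draws, ndim))
    out_lp = np.empty(draws)
    out_div = np.zeros(draws, dtype=bool)
    out_depth = np.zeros(draws, dtype=int)
    out_acc = np.empty(draws)
    out_leap = np.zeros(draws, dtype=int)

    for m in range(tune + draws):
        warming = m < tune
        q, lp, grad, acc, div, depth, n_leap = _nuts_transition(
            logp_grad, q, lp, grad, metric, eps, max_treedepth, rng
        )
        if warming:
            eps = da.update(acc)
            in_window = init_buf <= m < tune - term_buf
            if in_window:
                welford.add(q)
                if m + 1 == window_end:
                    metric = _Metric(welford.variance())
                    next_window *= 2
                    window_end = min(window_end + next_window, tune - term_buf)
                    # absorb a final fragment shorter than the next window
                    if tune - term_buf - window_end < next_window * 2:
                        window_end = tune - term_buf
                    dense_now = dense_mass and window_end == tune - term_buf
                    welford = _Welford(ndim, dense_now)
                    da.restart(eps)
            if m + 1 == tune:
                eps = da.adapted_eps
        else:
            i = m - tune
            pos[i] = q
            out_lp[i] = lp
            out_div[i] = div
            out_depth[i] = depth
            out_acc[i] = acc
            out_leap[i] = n_leap
    return pos, out_lp, out_div, out_depth, out_acc, out_leap, eps


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    ndim: int,
    draws: int = 1000,
    tune: int = 1000,
    chains: int = 4,
    target_accept: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
    initial_point: Callable[[np.random.Generator], np.ndarray] | np.ndarray | None = None,
    max_treedepth: int = 10,
    dense_mass: bool = False,
) -> NutsResult:
    """Run independent NUTS chains over ``logp_grad``.

    ``logp_grad(q)`` must return the log-density and its gradient at the
    unconstrained point ``q``. ``initial_point`` may be a fixed vector or a
    callable drawing one start per chain; the default is uniform jitter on
    (-1, 1) per coordinate. ``dense_mass`` estimates a full covariance
    (inverse mass) matrix during warmup instead of a diagonal one, which
    pays off when parameters are strongly linearly correlated, as the
    group-level and subject-level parameters of a hierarchical model are.
    """
    if draws < 1 or tune < 1:
        raise ValueError("draws and tune must be >= 1")
    if chains < 1:
        raise ValueError("chains must be >= 1")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    results = []
    for chain, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        if initial_point is None:
            q0 = rng.uniform(-1.0, 1.0, size=ndim)
        elif callable(initial_point):
            q0 = np.asarray(initial_point(rng), dtype=float)
        else:
            q0 = np.asarray(initial_point, dtype=float).copy()
        results.append(
            _sample_chain(
                logp_grad, q0, draws, tune, target_accept, max_treedepth,
                dense_mass, rng
            )
        )
        log.info("chain %d finished (step size %.4g)", chain, results[-1][-1])
    return NutsResult(
        position=np.stack([r[0] for r in results]),
        logp=np.stack([r[1] for r in results]),
        diverging=np.stack([r[2] for r in results]),
        tree_depth=np.stack([r[3] for r in results]),
        accept_rate=np.stack([r[4] for r in results]),
        n_leapfrog=np.stack([r[5] for r in results]),
        step_size=np.array([r[6] for r in results]),
    )
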