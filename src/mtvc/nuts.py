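"""Self-contained No-U-Turn Sampler with dual-averaging step-size
adaptation.

Implements the slice-sampling tree variant (Hoffman & Gelman's
Algorithm 6): trajectories grow by recursive doubling until either end
makes a U-turn, the energy error exceeds the divergence threshold, or
the tree-depth / leapfrog-count limits are hit.  The mass matrix is the
identity by default, with an optional fixed diagonal metric hook.

The sampler is generic: it takes any callable ``logp_grad(u) ->
(logp, grad)`` on an unconstrained space.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "NUTSConfig",
    "HMCState",
    "ChainResult",
    "leapfrog",
    "find_reasonable_epsilon",
    "DualAveraging",
    "sample_chain",
    "sample_chains",
]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass(frozen=True)
class NUTSConfig:
    """Run settings.  Defaults follow the study protocol: 2000 iterations
    with the first 1000 discarded as warm-up, tree depth capped at 10 and
    at most 1000 leapfrog steps per iteration."""

    n_iter: int = 2000
    n_warmup: int = 1000
    target_accept: float = 0.8
    max_tree_depth: int = 10
    max_leapfrog: int = 1000
    divergence_threshold: float = 1000.0
    step_size: float | None = None
    adapt: bool = True
    adapt_metric: bool = True
    mass_diag: np.ndarray | None = None
    seed: int = 0
    store_warmup: bool = False

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iter:
            raise ValueError("n_warmup must be smaller than n_iter")
        if self.max_tree_depth < 1:
            raise ValueError("max_tree_depth must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class HMCState:
    """Position with consistent log-density and gradient."""

    position: np.ndarray
    logp: float
    grad: np.ndarray
    momentum: np.ndarray | None = None

    @classmethod
    def at(cls, position: np.ndarray, logp_grad: LogpGrad) -> "HMCState":
        logp, grad = logp_grad(np.asarray(position, dtype=float))
        return cls(position=np.asarray(position, dtype=float), logp=logp, grad=grad)


@dataclass
class ChainResult:
    """Post-warm-up draws with per-iteration sampler statistics."""

    positions: np.ndarray  # (n_kept, dim)
    n_leapfrog: np.ndarray
    tree_depth: np.ndarray
    divergent: np.ndarray
    accept_stat: np.ndarray
    step_size: np.ndarray
    warmup_positions: np.ndarray | None = None
    step_size_trace: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.positions.shape[0]


def leapfrog(
    position: np.ndarray,
    momentum: np.ndarray,
    grad: np.ndarray,
    eps: float,
    logp_grad: LogpGrad,
    inv_mass: np.ndarray | float = 1.0,
) -> HMCState:
    """One leapfrog step: half-kick, drift, half-kick.

    Non-finite log densities at the proposal are passed through (the
    caller treats them as divergences).
    """
    p_half = momentum + 0.5 * eps * grad
    q_new = position + eps * (inv_mass * p_half)
    logp_new, grad_new = logp_grad(q_new)
    if not np.isfinite(logp_new):
        logp_new = -np.inf
        grad_new = np.zeros_like(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return HMCState(position=q_new, logp=logp_new, grad=grad_new, momentum=p_new)


def _kinetic(p: np.ndarray, inv_mass: np.ndarray | float) -> float:
    return 0.5 * float(p @ (inv_mass * p))


def find_reasonable_epsilon(
    state: HMCState,
    logp_grad: LogpGrad,
    rng: np.random.Generator,
    inv_mass: np.ndarray | float = 1.0,
    mass: np.ndarray | float = 1.0,
) -> float:
    """Double/halve the step size until the one-step Metropolis
    acceptance probability crosses 1/2 (Hoffman-Gelman heuristic)."""
    eps = 1.0
    p = np.sqrt(mass) * rng.standard_normal(state.position.shape)
    h0 = state.logp - _kinetic(p, inv_mass)
    nxt = leapfrog(state.position, p, state.grad, eps, logp_grad, inv_mass)
    h1 = nxt.logp - _kinetic(nxt.momentum, inv_mass)
    # shrink first if the step explodes immediately
    while not np.isfinite(h1):
        eps *= 0.5
        nxt = leapfrog(state.position, p, state.grad, eps, logp_grad, inv_mass)
        h1 = nxt.logp - _kinetic(nxt.momentum, inv_mass)
        if eps < 1e-10:
            raise RuntimeError("could not find a stable initial step size")
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    while direction * (h1 - h0) > -direction * np.log(2.0):
        eps *= 2.0 ** direction
        if eps > 1e7 or eps < 1e-10:
            break
        nxt = leapfrog(state.position, p, state.grad, eps, logp_grad, inv_mass)
        h1 = nxt.logp - _kinetic(nxt.momentum, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
    return eps


@dataclass
class DualAveraging:
    """Nesterov dual averaging of log step size (gamma=0.05, t0=10,
    kappa=0.75), targeting a given mean acceptance statistic."""

    eps0: float
    target_accept: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _m: int = field(default=0, init=False)
    _h_bar: float = field(default=0.0, init=False)
    _log_eps_bar: float = field(default=0.0, init=False)
    _mu: float = field(init=False)

    def __post_init__(self) -> None:
        self._mu = float(np.log(10.0 * self.eps0))
        self._log_eps = float(np.log(self.eps0))

    def update(self, accept_stat: float) -> float:
        """Feed one iteration's mean acceptance; returns the next eps."""
        self._m += 1
        m = self._m
        w = 1.0 / (m + self.t0)
        self._h_bar = (1.0 - w) * self._h_bar + w * (self.target_accept - accept_stat)
        self._log_eps = self._mu - np.sqrt(m) / self.gamma * self._h_bar
        eta = m ** (-self.kappa)
        self._log_eps_bar = eta * self._log_eps + (1.0 - eta) * self._log_eps_bar
        return float(np.exp(self._log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


class _TreeContext:
    """Per-iteration bookkeeping shared across the recursion."""

    __slots__ = ("n_leapfrog", "divergent", "sum_alpha", "n_alpha")

    def __init__(self) -> None:
        self.n_leapfrog = 0
        self.divergent = False
        self.sum_alpha = 0.0
        self.n_alpha = 0


def _build_tree(
    state: HMCState,
    log_slice: float,
    direction: int,
    depth: int,
    eps: float,
    h0: float,
    logp_grad: LogpGrad,
    inv_mass: np.ndarray | float,
    threshold: float,
    ctx: _TreeContext,
    rng: np.random.Generator,
):
    """Recursive doubling (Algorithm 6, slice variant).

    Returns (minus_state, plus_state, proposal, n_valid, keep_going).
    """
    if depth == 0:
        nxt = leapfrog(
            state.position, state.momentum, state.grad, direction * eps, logp_grad, inv_mass
        )
        ctx.n_leapfrog += 1
        h1 = nxt.logp - _kinetic(nxt.momentum, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        n_valid = 1 if log_slice <= h1 else 0
        keep = log_slice < threshold + h1
        if abs(h0 - h1) > threshold:
            ctx.divergent = True
            keep = False
        ctx.sum_alpha += float(np.exp(min(0.0, h1 - h0)))
        ctx.n_alpha += 1
        return nxt, nxt, nxt, n_valid, keep
    minus, plus, prop, n_valid, keep = _build_tree(
        state, log_slice, direction, depth - 1, eps, h0, logp_grad, inv_mass, threshold, ctx, rng
    )
    if keep:
        if direction == -1:
            minus, _, prop2, n2, keep2 = _build_tree(
                minus, log_slice, direction, depth - 1, eps, h0,
                logp_grad, inv_mass, threshold, ctx, rng,
            )
        else:
            _, plus, prop2, n2, keep2 = _build_tree(
                plus, log_slice, direction, depth - 1, eps, h0,
                logp_grad, inv_mass, threshold, ctx, rng,
            )
        if n2 > 0 and rng.uniform() < n2 / max(n_valid + n2, 1):
            prop = prop2
        n_valid += n2
        keep = keep2 and _no_uturn(minus, plus, inv_mass)
    return minus, plus, prop, n_valid, keep


def _no_uturn(minus: HMCState, plus: HMCState, inv_mass: np.ndarray | float) -> bool:
    dq = plus.position - minus.position
    return (dq @ (inv_mass * minus.momentum)) >= 0 and (
        dq @ (inv_mass * plus.momentum)
    ) >= 0


def sample_chain(
    logp_grad: LogpGrad, init: np.ndarray, cfg: NUTSConfig = NUTSConfig()
) -> ChainResult:
    """Run warm-up with step-size adaptation, then sampling.

    Deterministic given ``cfg.seed``.  Raises if the log density is not
    finite at the initial point.
    """
    rng = np.random.default_rng(cfg.seed)
    state = HMCState.at(init, logp_grad)
    if not np.isfinite(state.logp):
        raise ValueError(
            "log density is not finite at the initial point; re-initialize"
        )
    dim = state.position.shape[0]
    if cfg.mass_diag is not None:
        mass = np.asarray(cfg.mass_diag, dtype=float)
        inv_mass = 1.0 / mass
    else:
        mass = 1.0
        inv_mass = 1.0
    # warm-up metric estimation: draws from the second quarter of warm-up
    # feed a diagonal metric switched in at mid-warm-up (then the step
    # size is re-initialized and re-adapted on the new scale)
    metric_switch = (
        cfg.n_warmup // 2
        if (cfg.adapt_metric and cfg.mass_diag is None and cfg.n_warmup >= 100)
        else None
    )
    metric_buf: list[np.ndarray] = []

    if cfg.step_size is not None:
        eps = float(cfg.step_size)
    else:
        eps = find_reasonable_epsilon(state, logp_grad, rng, inv_mass, mass)
    da = DualAveraging(eps0=eps, target_accept=cfg.target_accept)
    adapting = cfg.adapt and cfg.step_size is None

    n_kept = cfg.n_iter - cfg.n_warmup
    positions = np.empty((n_kept, dim))
    n_leapfrog = np.zeros(n_kept, dtype=int)
    tree_depth = np.zeros(n_kept, dtype=int)
    divergent = np.zeros(n_kept, dtype=bool)
    accept_stat = np.zeros(n_kept)
    step_sizes = np.zeros(n_kept)
    warmup_positions = (
        np.empty((cfg.n_warmup, dim)) if cfg.store_warmup else None
    )
    eps_trace = np.zeros(cfg.n_iter)

    for it in range(cfg.n_iter):
        p = np.sqrt(mass) * rng.standard_normal(dim)
        h0 = state.logp - _kinetic(p, inv_mass)
        log_slice = h0 + np.log(rng.uniform())
        state.momentum = p
        minus = HMCState(state.position, state.logp, state.grad, p.copy())
        plus = HMCState(state.position, state.logp, state.grad, p.copy())
        proposal = state
        ctx = _TreeContext()
        n_valid = 1
        depth = 0
        keep = True
        while keep and depth < cfg.max_tree_depth and ctx.n_leapfrog < cfg.max_leapfrog:
            direction = -1 if rng.uniform() < 0.5 else 1
            if direction == -1:
                minus, _, prop2, n2, keep2 = _build_tree(
                    minus, log_slice, direction, depth, eps, h0,
                    logp_grad, inv_mass, cfg.divergence_threshold, ctx, rng,
                )
            else:
                _, plus, prop2, n2, keep2 = _build_tree(
                    plus, log_slice, direction, depth, eps, h0,
                    logp_grad, inv_mass, cfg.divergence_threshold, ctx, rng,
                )
            if keep2 and n2 > 0 and rng.uniform() < n2 / n_valid:
                proposal = prop2
            n_valid += n2
            keep = keep2 and _no_uturn(minus, plus, inv_mass)
            depth += 1
        state = HMCState(proposal.position, proposal.logp, proposal.grad)

        alpha = ctx.sum_alpha / max(ctx.n_alpha, 1)
        eps_trace[it] = eps
        if it < cfg.n_warmup:
            if adapting:
                eps = da.update(alpha)
            if cfg.store_warmup:
                warmup_positions[it] = state.position
            if metric_switch is not None:
                if metric_switch // 2 <= it < metric_switch:
                    metric_buf.append(state.position.copy())
                if it == metric_switch - 1 and len(metric_buf) >= 10:
                    draws = np.asarray(metric_buf)
                    var = draws.var(axis=0, ddof=1)
                    w = len(draws)
                    # regularize toward unit scale (Stan-style shrinkage)
                    inv_mass = w / (w + 5.0) * var + 5.0 / (w + 5.0)
                    mass = 1.0 / inv_mass
                    metric_buf.clear()
                    if adapting:
                        eps = find_reasonable_epsilon(
                            state, logp_grad, rng, inv_mass, mass
                        )
                        da = DualAveraging(
                            eps0=eps, target_accept=cfg.target_accept
                        )
            if it == cfg.n_warmup - 1 and adapting:
                eps = da.adapted
        else:
            k = it - cfg.n_warmup
            positions[k] = state.position
            n_leapfrog[k] = ctx.n_leapfrog
            tree_depth[k] = depth
            divergent[k] = ctx.divergent
            accept_stat[k] = alpha
            step_sizes[k] = eps

    return ChainResult(
        positions=positions,
        n_leapfrog=n_leapfrog,
        tree_depth=tree_depth,
        divergent=divergent,
        accept_stat=accept_stat,
        step_size=step_sizes,
        warmup_positions=warmup_positions,
        step_size_trace=eps_trace,
    )


def sample_chains(
    logp_grad: LogpGrad,
    inits: list[np.ndarray],
    cfg: NUTSConfig = NUTSConfig(),
) -> list[ChainResult]:
    """Several independent chains (seeded ``cfg.seed + chain index``),
    e.g. the three parallel chains used for the R-hat diagnostic."""
    results = []
    for c, init in enumerate(inits):
        cfg_c = NUTSConfig(**{**cfg.__dict__, "seed": cfg.seed + c})
        results.append(sample_chain(logp_grad, init, cfg_c))
    return results
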