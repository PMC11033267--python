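"""No-U-Turn sampler with dual-averaging step-size and diagonal mass
adaptation.

A self-contained implementation of dynamic Hamiltonian Monte Carlo:
multinomial sampling over the trajectory, a doubling tree with the
generalized U-turn criterion, dual averaging toward a target acceptance
statistic, and windowed estimation of a diagonal mass matrix during warmup.
Everything is driven by a single ``logp_grad`` callable and a seeded
``numpy.random.Generator``, so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_chain", "ChainResult"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    samples: np.ndarray  # (n_draws, dim) post-warmup positions
    logp: np.ndarray  # (n_draws,)
    divergent: np.ndarray  # (n_draws,) bool
    treedepth: np.ndarray  # (n_draws,) int
    accept_stat: np.ndarray  # (n_draws,)
    energy: np.ndarray  # (n_draws,)
    step_size: float
    inv_mass: np.ndarray


class _State:
    __slots__ = ("theta", "p", "grad", "logp")

    def __init__(self, theta, p, grad, logp):
        self.theta = theta
        self.p = p
        self.grad = grad
        self.logp = logp


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p * inv_mass, p))


def _leapfrog(state, eps, inv_mass, logp_grad):
    p = state.p + 0.5 * eps * state.grad
    theta = state.theta + eps * inv_mass * p
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return _State(theta, p, grad, logp)


def _uturn(state_m, state_p, inv_mass):
    dtheta = state_p.theta - state_m.theta
    return (
        np.dot(dtheta, inv_mass * state_m.p) < 0.0
        or np.dot(dtheta, inv_mass * state_p.p) < 0.0
    )


class _Subtree:
    __slots__ = (
        "state_m", "state_p", "proposal", "log_sum_w",
        "sum_accept", "n_leap", "turning", "diverging",
    )


def _build_tree(state, depth, direction, eps, H0, inv_mass, logp_grad, rng):
    if depth == 0:
        new = _leapfrog(state, direction * eps, inv_mass, logp_grad)
        t = _Subtree()
        t.state_m = t.state_p = t.proposal = new
        if np.isfinite(new.logp):
            H = -new.logp + _kinetic(new.p, inv_mass)
            dH = H - H0
        else:
            dH = np.inf
        t.diverging = not np.isfinite(dH) or dH > _DIVERGENCE_THRESHOLD
        t.log_sum_w = -dH if not t.diverging else -np.inf
        t.sum_accept = np.exp(min(0.0, -dH)) if np.isfinite(dH) else 0.0
        t.n_leap = 1
        t.turning = False
        return t

    left = _build_tree(state, depth - 1, direction, eps, H0, inv_mass, logp_grad, rng)
    if left.turning or left.diverging:
        return left
    edge = left.state_p if direction > 0 else left.state_m
    right = _build_tree(edge, depth - 1, direction, eps, H0, inv_mass, logp_grad, rng)

    t = _Subtree()
    t.sum_accept = left.sum_accept + right.sum_accept
    t.n_leap = left.n_leap + right.n_leap
    t.diverging = right.diverging
    t.log_sum_w = np.logaddexp(left.log_sum_w, right.log_sum_w)
    if np.log(rng.uniform()) < right.log_sum_w - t.log_sum_w:
        t.proposal = right.proposal
    else:
        t.proposal = left.proposal
    if direction > 0:
        t.state_m, t.state_p = left.state_m, right.state_p
    else:
        t.state_m, t.state_p = right.state_m, left.state_p
    t.turning = right.turning or _uturn(t.state_m, t.state_p, inv_mass)
    return t


def _find_reasonable_epsilon(state, inv_mass, logp_grad, rng):
    eps = 1.0
    p = rng.standard_normal(state.theta.size) / np.sqrt(inv_mass)
    s = _State(state.theta, p, state.grad, state.logp)
    H0 = -s.logp + _kinetic(p, inv_mass)
    new = _leapfrog(s, eps, inv_mass, logp_grad)
    H = -new.logp + _kinetic(new.p, inv_mass) if np.isfinite(new.logp) else np.inf
    ratio = H0 - H
    direction = 1.0 if ratio > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        new = _leapfrog(s, eps, inv_mass, logp_grad)
        H = -new.logp + _kinetic(new.p, inv_mass) if np.isfinite(new.logp) else np.inf
        ratio = H0 - H
        if (direction > 0 and ratio <= np.log(0.5)) or (
            direction < 0 and ratio >= np.log(0.5)
        ):
            break
    return max(eps, 1e-10)


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x):
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self):
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit scale as Stan does
        w = self.n / (self.n + 5.0)
        return w * var + (1.0 - w) * 1e-3


def _adaptation_schedule(n_warmup):
    """(step-size-only buffer, mass-estimation window ends, terminal buffer)."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init = min(75, int(0.15 * n_warmup))
    term = min(50, int(0.10 * n_warmup))
    window_ends = []
    size = max(25, int(0.05 * n_warmup))
    pos = init
    while pos + size < n_warmup - term:
        if pos + 3 * size >= n_warmup - term:
            size = n_warmup - term - pos  # absorb the remainder
        window_ends.append(pos + size)
        pos += size
        size *= 2
    if not window_ends:
        window_ends = [n_warmup - term]
    return init, window_ends, term


def sample_chain(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> ChainResult:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics."""
    dim = theta0.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(theta0)
    if not np.isfinite(logp):
        raise FloatingPointError("non-finite log density at the initial position")
    state = _State(np.array(theta0, dtype=float), np.zeros(dim), grad, logp)

    eps = _find_reasonable_epsilon(state, inv_mass, logp_grad, rng)
    # dual averaging (Nesterov) toward the target acceptance statistic
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init_buf, window_ends, _ = _adaptation_schedule(n_warmup)
    welford = _Welford(dim)

    samples = np.empty((n_draws, dim))
    out_logp = np.empty(n_draws)
    out_div = np.zeros(n_draws, dtype=bool)
    out_depth = np.zeros(n_draws, dtype=np.int64)
    out_accept = np.empty(n_draws)
    out_energy = np.empty(n_draws)

    for it in range(n_warmup + n_draws):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        state = _State(state.theta, p0, state.grad, state.logp)
        H0 = -state.logp + _kinetic(p0, inv_mass)
        state_m = state_p = state
        proposal = state
        log_sum_w = 0.0
        sum_accept, n_leap = 0.0, 0
        diverged = False
        depth = 0
        while depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            edge = state_p if direction > 0 else state_m
            tree = _build_tree(edge, depth, direction, eps, H0, inv_mass, logp_grad, rng)
            sum_accept += tree.sum_accept
            n_leap += tree.n_leap
            if tree.diverging:
                diverged = True
                break
            if not tree.turning:
                # biased progressive sampling favoring the new subtree
                if np.log(rng.uniform()) < tree.log_sum_w - log_sum_w:
                    proposal = tree.proposal
            log_sum_w = np.logaddexp(log_sum_w, tree.log_sum_w)
            if direction > 0:
                state_p = tree.state_p
            else:
                state_m = tree.state_m
            depth += 1
            if tree.turning or _uturn(state_m, state_p, inv_mass):
                break
        state = proposal
        accept_stat = sum_accept / max(n_leap, 1)

        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            eta = da_count**-kappa
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= init_buf:
                welford.update(state.theta)
            if window_ends and it + 1 == window_ends[0]:
                inv_mass = welford.variance()
                welford = _Welford(dim)
                window_ends.pop(0)
                eps = _find_reasonable_epsilon(state, inv_mass, logp_grad, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            i = it - n_warmup
            samples[i] = state.theta
            out_logp[i] = state.logp
            out_div[i] = diverged
            out_depth[i] = depth
            out_accept[i] = accept_stat
            out_energy[i] = H0

    return ChainResult(
        samples=samples,
        logp=out_logp,
        divergent=out_div,
        treedepth=out_depth,
        accept_stat=out_accept,
        energy=out_energy,
        step_size=eps,
        inv_mass=inv_mass,
    )
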