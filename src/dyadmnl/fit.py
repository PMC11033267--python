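"""Posterior sampling, convergence checking and summaries."""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nuts import sample_chain
from ._posterior import Posterior
from .model import ModelSpec

__all__ = ["McmcConfig", "PosteriorSamples", "Diagnostics", "fit", "diagnose", "summarize"]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.  The default mirrors the original study-scale
    protocol of 3 chains x 10000 iterations with 5000 warmup; ``desk()``
    gives a profile sized for laptop-scale synthetic studies."""

    chains: int = 3
    iterations: int = 10000
    warmup: int = 5000
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not (0 <= self.warmup < self.iterations):
            raise ValueError("warmup must satisfy 0 <= warmup < iterations")

    @classmethod
    def desk(cls, seed: int = 0, iterations: int = 1500, chains: int = 3) -> "McmcConfig":
        return cls(chains=chains, iterations=iterations, warmup=iterations // 2, seed=seed)

    @property
    def n_draws(self) -> int:
        return self.iterations - self.warmup


@dataclass
class PosteriorSamples:
    """Retained post-warmup draws plus everything needed downstream.

    ``draws`` maps block names (alpha, beta_I, sigma_I, L_I, ...) to arrays
    of shape (chains, n_draws, ...); ``theta`` keeps the raw unconstrained
    positions (used for whole-model convergence checks);
    ``pointwise_loglik`` is (chains, n_draws, n_events) and feeds WAIC.
    """

    draws: dict
    theta: np.ndarray
    pointwise_loglik: np.ndarray
    sample_stats: dict
    spec: ModelSpec
    mcmc: McmcConfig
    data: object = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """A block with chain and draw axes merged: (chains*draws, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def loglik_matrix(self) -> np.ndarray:
        """Pointwise log-likelihood as a (total draws x events) matrix."""
        return self.pointwise_loglik.reshape(-1, self.pointwise_loglik.shape[-1])

    def to_inferencedata(self):
        import arviz as az

        posterior = {"theta": self.theta}
        for name, arr in self.draws.items():
            posterior[name] = arr
        return az.from_dict(
            posterior=posterior,
            sample_stats={
                "diverging": self.sample_stats["divergent"],
                "lp": self.sample_stats["logp"],
                "energy": self.sample_stats["energy"],
                "tree_depth": self.sample_stats["treedepth"],
                "acceptance_rate": self.sample_stats["accept_stat"],
            },
            log_likelihood={"y": self.pointwise_loglik},
        )


@dataclass
class Diagnostics:
    rhat: np.ndarray  # per unconstrained coordinate
    ess: np.ndarray
    divergences: np.ndarray  # per chain
    warnings: list

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat))

    @property
    def min_ess(self) -> float:
        return float(np.nanmin(self.ess))


def fit(
    spec: ModelSpec,
    data,
    mcmc: McmcConfig,
    likelihood: bool = True,
    progress: bool = False,
) -> PosteriorSamples:
    """Sample the posterior of a model variant with NUTS.

    Chains run sequentially with independent sub-streams of ``mcmc.seed``;
    identical seed and config give identical results.  ``likelihood=False``
    samples the prior (useful for prior-predictive and calibration checks).
    """
    post = Posterior(spec, data, likelihood=likelihood)
    n_draws = mcmc.n_draws
    chains = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=mcmc.seed, spawn_key=(c,)))
        theta0 = post.initial_position(rng)
        lp0, grad0 = post.logp_grad(theta0)
        if not np.all(np.isfinite(grad0)):
            bad = int(np.flatnonzero(~np.isfinite(grad0))[0])
            name = next(n for n, sl in post.slices.items() if sl.start <= bad < sl.stop)
            raise FloatingPointError(f"non-finite gradient at init in block {name!r}")
        if progress:
            print(f"[dyadmnl] chain {c + 1}/{mcmc.chains} ...", flush=True)
        chains.append(
            sample_chain(
                post.logp_grad,
                theta0,
                mcmc.warmup,
                n_draws,
                rng,
                target_accept=mcmc.target_accept,
                max_treedepth=mcmc.max_treedepth,
            )
        )

    theta = np.stack([ch.samples for ch in chains])
    stats = {
        "logp": np.stack([ch.logp for ch in chains]),
        "divergent": np.stack([ch.divergent for ch in chains]),
        "treedepth": np.stack([ch.treedepth for ch in chains]),
        "accept_stat": np.stack([ch.accept_stat for ch in chains]),
        "energy": np.stack([ch.energy for ch in chains]),
        "step_size": np.array([ch.step_size for ch in chains]),
    }

    # constrain every retained draw and collect pointwise log-likelihoods
    draws: dict[str, list] = {}
    pll = np.zeros((mcmc.chains, n_draws, data.n_events if likelihood else 0))
    for c in range(mcmc.chains):
        for d in range(n_draws):
            params = post.constrain(theta[c, d])
            for name in _tracked_blocks(spec):
                draws.setdefault(name, []).append(getattr(params, name))
            if likelihood:
                pll[c, d] = post.pointwise_loglik(theta[c, d])
    out = {}
    for name, values in draws.items():
        arr = np.stack(values)
        out[name] = arr.reshape((mcmc.chains, n_draws) + arr.shape[1:])

    return PosteriorSamples(
        draws=out,
        theta=theta,
        pointwise_loglik=pll,
        sample_stats=stats,
        spec=spec,
        mcmc=mcmc,
        data=data,
        meta={"scaler": getattr(data, "scaler", None), "likelihood": likelihood},
    )


def _tracked_blocks(spec: ModelSpec):
    names = ["alpha", "sigma_I", "sigma_R", "L_I", "L_R"]
    if spec.has_fixed:
        names += ["beta_I", "beta_R", "beta_H"]
    if spec.has_household:
        names += ["sigma_hI", "sigma_hR", "L_hI", "L_hR"]
    return names


def diagnose(samples: PosteriorSamples) -> Diagnostics:
    """Rank-normalized split R-hat and bulk ESS over every sampled
    coordinate, plus per-chain divergence counts."""
    import arviz as az

    if samples.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    idata = az.from_dict(posterior={"theta": samples.theta})
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rhat = az.rhat(idata)["theta"].values
        ess = az.ess(idata)["theta"].values
    div = samples.sample_stats["divergent"].sum(axis=1)
    warns = []
    total = samples.n_chains * samples.n_draws
    if div.sum() / total > 0.10:
        warns.append(f"divergence rate {div.sum() / total:.1%} exceeds 10%")
    return Diagnostics(rhat=rhat, ess=ess, divergences=div, warnings=warns)


def summarize(
    samples: PosteriorSamples,
    credible_level: float = 0.95,
    blocks: list[str] | None = None,
) -> pd.DataFrame:
    """Posterior mean, SD and percentile interval per scalar parameter.

    Interval endpoints are empirical percentiles of the pooled draws
    (2.5/97.5 at the default level).
    """
    if samples.n_draws * samples.n_chains == 0:
        raise ValueError("no draws to summarize")
    lo_q = 100 * (1 - credible_level) / 2
    hi_q = 100 - lo_q
    rows = []
    for name in blocks or samples.draws:
        flat = samples.stacked(name)
        flat2 = flat.reshape(flat.shape[0], -1)
        shape = samples.draws[name].shape[2:]
        for j in range(flat2.shape[1]):
            idx = np.unravel_index(j, shape) if shape else ()
            label = name + ("[" + ",".join(map(str, idx)) + "]" if idx else "")
            col = flat2[:, j]
            rows.append(
                {
                    "parameter": label,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)) if col.size > 1 else 0.0,
                    "lower": float(np.percentile(col, lo_q)),
                    "upper": float(np.percentile(col, hi_q)),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")
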