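"""Shared fixtures: small synthetic study populations and, for the
expensive end-to-end checks, one session-scoped parameter-recovery study
(simulate -> fit two variants) reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from dyadmnl import (
    McmcConfig,
    ModelSpec,
    build_design,
    fit,
)
from dyadmnl.synthetic import (
    SimulationConfig,
    draw_truth,
    simulate_community,
    simulate_observations,
)


def planted_truth(cfg: SimulationConfig):
    """Moderate, fixed effect sizes for the K=8 recovery study: |beta| <= 1,
    sigma <= 0.6, and two planted random-effect correlations (+0.5 between
    the first two initiator categories, -0.5 for recipients)."""
    Kp = cfg.K - 1
    corr_I = np.eye(Kp)
    corr_I[0, 1] = corr_I[1, 0] = 0.5
    corr_R = np.eye(Kp)
    corr_R[0, 1] = corr_R[1, 0] = -0.5
    return draw_truth(
        cfg,
        {
            "alpha": [0.4, -0.3, 0.2, 0.0, -0.2, 0.3, -0.4],
            "beta_I": [
                [0.8, 0.5, -0.4],
                [-0.6, 0.3, 0.2],
                [0.5, -0.5, 0.0],
                [0.0, 0.4, -0.3],
                [-0.4, 0.0, 0.5],
                [0.3, -0.2, 0.0],
                [0.6, 0.0, -0.5],
            ],
            "beta_R": [
                [-0.5, 0.2, 0.3],
                [0.4, -0.3, 0.0],
                [0.0, 0.5, -0.2],
                [0.6, 0.0, 0.4],
                [-0.3, 0.3, 0.0],
                [0.5, -0.4, 0.2],
                [0.0, 0.2, 0.5],
            ],
            "beta_H": [0.5, -0.4, 0.3, 0.0, 0.4, -0.3, 0.2],
            "corr_I": corr_I,
            "corr_R": corr_R,
            "scale_I": [0.6, 0.6, 0.5, 0.4, 0.5, 0.4, 0.5],
            "scale_R": [0.6, 0.6, 0.5, 0.4, 0.5, 0.4, 0.5],
        },
    )


@pytest.fixture(scope="session")
def k4_study():
    """A small K=4 community with known, modest truth (no fit attached)."""
    cfg = SimulationConfig(
        n_children=20, n_households=8, n_categories=4, n_events=400, seed=42
    )
    roster = simulate_community(cfg)
    truth = draw_truth(
        cfg,
        {
            "alpha": [0.3, -0.2, 0.1],
            "beta_I": [[0.5, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            "scale_I": [0.3, 0.3, 0.3],
            "scale_R": [0.2, 0.2, 0.2],
        },
    )
    events, ledger = simulate_observations(roster, truth, cfg)
    data = build_design(events, roster, cfg.taxonomy())
    return {"cfg": cfg, "roster": roster, "truth": truth, "events": events,
            "ledger": ledger, "data": data}


@pytest.fixture(scope="session")
def recovery_study():
    """Scaled-down recovery study: variant iF generator with K=8 categories,
    60 children in 25 households, 2500 events.  The generating variant is
    refitted at 3 chains x 1500 iterations (900 warmup, acceptance target
    0.95 — the slowest coordinates are the random-effect scales and
    correlation parameters, so the protocol leans on adaptation); the
    intercept-only comparison fit uses a lighter 3 x 1000 protocol since
    only its pointwise log-likelihood enters the WAIC comparison."""
    cfg = SimulationConfig(
        n_children=60, n_households=25, n_categories=8, n_events=2500, seed=77
    )
    roster = simulate_community(cfg)
    truth = planted_truth(cfg)
    events, ledger = simulate_observations(roster, truth, cfg)
    data = build_design(events, roster, cfg.taxonomy())
    spec_iF = ModelSpec(variant="iF", K=cfg.K)
    spec_i = ModelSpec(variant="i", K=cfg.K)
    samples_iF = fit(
        spec_iF, data,
        McmcConfig(chains=3, iterations=1500, warmup=900, seed=101, target_accept=0.95),
    )
    samples_i = fit(spec_i, data, McmcConfig(chains=3, iterations=1000, warmup=500, seed=102))
    return {
        "cfg": cfg,
        "roster": roster,
        "truth": truth,
        "events": events,
        "ledger": ledger,
        "data": data,
        "samples_iF": samples_iF,
        "samples_i": samples_i,
    }


@pytest.fixture(scope="session")
def calibration_study():
    """Intercept-dominated K=4 study fitted with variant i, for the check
    that zero-random-effect predictions reproduce empirical frequencies."""
    cfg = SimulationConfig(
        n_children=30, n_households=12, n_categories=4, n_events=1200, seed=55
    )
    roster = simulate_community(cfg)
    truth = draw_truth(
        cfg,
        {
            "alpha": [0.6, -0.4, 0.2],
            "scale_I": [0.15, 0.15, 0.15],
            "scale_R": [0.15, 0.15, 0.15],
        },
    )
    events, _ = simulate_observations(roster, truth, cfg)
    data = build_design(events, roster, cfg.taxonomy())
    samples = fit(ModelSpec(variant="i", K=4), data, McmcConfig.desk(seed=7, iterations=800))
    return {"cfg": cfg, "truth": truth, "events": events, "data": data, "samples": samples}
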