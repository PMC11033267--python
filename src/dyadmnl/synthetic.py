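"""Synthetic communities and observation datasets with known ground truth.

The generator emulates the demographic structure of a village study
population — ~213 children in ~70 households (sizes 1-9, mean ~3),
near-balanced sexes, ages 0-12 — and draws directed dyadic behavior events
from the full model's generative process (intercepts, fixed effects, and
correlated individual- and household-level random effects), so parameter
recovery can be checked against a stored truth.

Dyad exposure (who is observed with whom, and how often) is a nuisance
process the model itself never touches: each directed dyad receives a
Gamma-distributed weight (an overdispersed, negative-binomial-like law),
multiplied up for same-household dyads, and the configured number of events
is allocated to dyads by a single multinomial draw on those weights.
Exposure is independent of behavior category given the dyad.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import BehaviorTaxonomy, ChildRecord, ObservationEvent
from .model import category_probabilities, cholesky_from_corr, sample_lkj_cholesky

__all__ = ["SimulationConfig", "TruthBundle", "simulate_community", "draw_truth",
           "simulate_observations", "write_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults reproduce the study-scale conditions; ``reduced(K)`` presets
    are available through ``n_categories`` for desk-scale recovery work."""

    n_children: int = 213
    n_households: int = 70
    max_household_size: int = 9
    sex_ratio: float = 0.49  # probability male
    age_beta_a: float = 1.2  # ages ~ 12 * Beta(a, b): mean ~4.2 y, SD ~2.7 y
    age_beta_b: float = 2.2
    n_categories: int = 19
    n_events: int = 6507
    exposure_gamma_shape: float = 0.6  # overdispersion of per-dyad weights
    same_household_multiplier: float = 8.0
    child_activity_shape: float = 1.5  # per-child activity multiplier spread
    n_covariates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (self.n_households <= self.n_children <= self.n_households * self.max_household_size):
            raise ValueError("household size constraints are infeasible")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be a probability")
        if self.same_household_multiplier <= 0 or self.exposure_gamma_shape <= 0:
            raise ValueError("exposure parameters must be positive")
        if self.child_activity_shape <= 0:
            raise ValueError("child_activity_shape must be positive")

    @property
    def K(self) -> int:
        return self.n_categories

    def taxonomy(self) -> BehaviorTaxonomy:
        return BehaviorTaxonomy.default() if self.K == 19 else BehaviorTaxonomy.reduced(self.K)


def _as_array(x, shape):
    a = np.zeros(shape) if x is None else np.asarray(x, dtype=float)
    if a.shape != shape:
        raise ValueError(f"expected shape {shape}, got {a.shape}")
    return a


@dataclass
class TruthBundle:
    """Ground-truth parameters plus the realized random effects.

    ``corr_*`` are correlation matrices (identity when the block is
    inactive), ``scale_*`` per-category SDs, ``nu_*`` the realized
    individual effects (I x K-1) and ``h_*`` household effects (H x K-1).
    """

    alpha: np.ndarray
    beta_I: np.ndarray
    beta_R: np.ndarray
    beta_H: np.ndarray
    corr_I: np.ndarray
    corr_R: np.ndarray
    corr_hI: np.ndarray
    corr_hR: np.ndarray
    scale_I: np.ndarray
    scale_R: np.ndarray
    scale_hI: np.ndarray
    scale_hR: np.ndarray
    nu_I: np.ndarray
    nu_R: np.ndarray
    h_I: np.ndarray
    h_R: np.ndarray
    category_tally: dict = field(default_factory=dict)

    def validate(self):
        Kp = self.alpha.shape[0]
        for name in ("corr_I", "corr_R", "corr_hI", "corr_hR"):
            R = getattr(self, name)
            cholesky_from_corr(R)  # raises on asymmetry / non-PSD
            if R.shape != (Kp, Kp):
                raise ValueError(f"{name} has wrong shape")
        for name in ("scale_I", "scale_R", "scale_hI", "scale_hR"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        return self

    def to_json(self, path) -> None:
        payload = {
            k: np.asarray(getattr(self, k)).tolist()
            for k in (
                "alpha", "beta_I", "beta_R", "beta_H",
                "corr_I", "corr_R", "corr_hI", "corr_hR",
                "scale_I", "scale_R", "scale_hI", "scale_hR",
                "nu_I", "nu_R", "h_I", "h_R",
            )
        }
        payload["category_tally"] = {str(k): int(v) for k, v in self.category_tally.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        with open(path) as fh:
            payload = json.load(fh)
        tally = {int(k): v for k, v in payload.pop("category_tally", {}).items()}
        return cls(**{k: np.asarray(v) for k, v in payload.items()}, category_tally=tally)


def simulate_community(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[ChildRecord]:
    """Draw a roster: children partitioned into households, with sexes and
    ages at study start.

    Household sizes come from sequential preferential assignment (every
    household starts with one child; the rest join with probability
    proportional to current size, capped at ``max_household_size``), which
    produces right-skewed sizes in 1..9 with mean n_children/n_households.
    """
    rng = rng or np.random.default_rng(config.seed)
    H, n = config.n_households, config.n_children
    sizes = np.ones(H, dtype=np.int64)
    for _ in range(n - H):
        w = np.where(sizes < config.max_household_size, sizes.astype(float), 0.0)
        sizes[rng.choice(H, p=w / w.sum())] += 1
    roster = []
    child = 0
    for h in range(H):
        for _ in range(sizes[h]):
            child += 1
            sex = "male" if rng.uniform() < config.sex_ratio else "female"
            age = 12.0 * rng.beta(config.age_beta_a, config.age_beta_b)
            roster.append(
                ChildRecord(
                    child_id=f"c{child:04d}",
                    sex=sex,
                    household_id=f"h{h + 1:03d}",
                    age_at_study_start=round(float(age), 3),
                )
            )
    return roster


def draw_truth(
    config: SimulationConfig,
    recipe: str | dict | TruthBundle = "zero",
    rng: np.random.Generator | None = None,
) -> TruthBundle:
    """Build a ``TruthBundle`` and realize its random effects.

    ``recipe`` is ``"zero"`` (all effects off), ``"prior"`` (draw every
    component from the model priors: standard normal intercepts and fixed
    effects, LKJ(2) correlations, half-normal scales), a partial dict of
    explicit components, or a ready TruthBundle (revalidated, effects
    redrawn only if absent).
    """
    rng = rng or np.random.default_rng(config.seed)
    Kp, m, I, H = config.K - 1, config.n_covariates, config.n_children, config.n_households
    eye = np.eye(Kp)

    if isinstance(recipe, TruthBundle):
        return recipe.validate()
    if recipe == "zero":
        comp: dict = {}
    elif recipe == "prior":
        comp = {
            "alpha": rng.standard_normal(Kp),
            "beta_I": rng.standard_normal((Kp, m)),
            "beta_R": rng.standard_normal((Kp, m)),
            "beta_H": rng.standard_normal(Kp),
            "corr_I": _lkj_corr(Kp, rng),
            "corr_R": _lkj_corr(Kp, rng),
            "scale_I": np.abs(rng.standard_normal(Kp)),
            "scale_R": np.abs(rng.standard_normal(Kp)),
        }
    elif isinstance(recipe, dict):
        comp = dict(recipe)
    else:
        raise ValueError(f"unknown truth recipe {recipe!r}")

    t = TruthBundle(
        alpha=_as_array(comp.get("alpha"), (Kp,)),
        beta_I=_as_array(comp.get("beta_I"), (Kp, m)),
        beta_R=_as_array(comp.get("beta_R"), (Kp, m)),
        beta_H=_as_array(comp.get("beta_H"), (Kp,)),
        corr_I=_corr_component(comp, "corr_I", eye),
        corr_R=_corr_component(comp, "corr_R", eye),
        corr_hI=_corr_component(comp, "corr_hI", eye),
        corr_hR=_corr_component(comp, "corr_hR", eye),
        scale_I=_as_array(comp.get("scale_I"), (Kp,)),
        scale_R=_as_array(comp.get("scale_R"), (Kp,)),
        scale_hI=_as_array(comp.get("scale_hI"), (Kp,)),
        scale_hR=_as_array(comp.get("scale_hR"), (Kp,)),
        nu_I=np.zeros((I, Kp)),
        nu_R=np.zeros((I, Kp)),
        h_I=np.zeros((H, Kp)),
        h_R=np.zeros((H, Kp)),
    ).validate()

    # realize correlated effects: rows ~ MVN(0, D R D), non-centered draw
    for eff, corr, scale, rows in (
        ("nu_I", t.corr_I, t.scale_I, I),
        ("nu_R", t.corr_R, t.scale_R, I),
        ("h_I", t.corr_hI, t.scale_hI, H),
        ("h_R", t.corr_hR, t.scale_hR, H),
    ):
        if np.any(scale > 0):
            A = scale[:, None] * cholesky_from_corr(corr)
            setattr(t, eff, rng.standard_normal((rows, Kp)) @ A.T)
    return t


def _corr_component(comp: dict, name: str, eye: np.ndarray) -> np.ndarray:
    v = comp.get(name)
    return eye.copy() if v is None else np.asarray(v, dtype=float)


def _lkj_corr(d, rng, shape=2.0):
    L = sample_lkj_cholesky(d, shape, rng)
    return L @ L.T


def simulate_observations(
    roster: list[ChildRecord],
    truth: TruthBundle,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Draw events from the generative model; returns (events, ledger).

    The ledger is a DataFrame with one row per directed dyad that was
    allocated at least one event (columns: initiator_id, recipient_id,
    same_household, n_events).  ``truth.category_tally`` is filled with the
    realized per-category counts.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(roster)
    if n < 2:
        raise ValueError("need at least two children")
    K = config.K
    ids = [r.child_id for r in roster]
    house = np.array([r.household_id for r in roster])
    sexes = np.array([0.0 if r.sex == "female" else 1.0 for r in roster])
    ages = np.array([r.age_at_study_start for r in roster])
    house_index = {h: i for i, h in enumerate(dict.fromkeys(house))}
    h_of = np.array([house_index[h] for h in house])

    # per-dyad exposure weights: child-level activity multipliers (some
    # children are seen far more than others) times Gamma dyad mixing
    # (negative-binomial-like) times a same-household multiplier
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = ii != jj
    ii, jj = ii[mask], jj[mask]
    ka = config.child_activity_shape
    activity = rng.gamma(ka, 1.0 / ka, size=n)
    w = activity[ii] * activity[jj] * rng.gamma(config.exposure_gamma_shape, 1.0, size=ii.size)
    same = house[ii] == house[jj]
    w *= np.where(same, config.same_household_multiplier, 1.0)
    if config.n_events == 0:
        return [], pd.DataFrame(columns=["initiator_id", "recipient_id", "same_household", "n_events"])
    counts = rng.multinomial(config.n_events, w / w.sum())

    used = counts > 0
    ev_i = np.repeat(ii[used], counts[used])
    ev_j = np.repeat(jj[used], counts[used])
    order = rng.permutation(ev_i.size)
    ev_i, ev_j = ev_i[order], ev_j[order]

    # covariates exactly as the design builder constructs them: ages fixed
    # per child, standardized over the generated event list
    age_i, age_j = ages[ev_i], ages[ev_j]
    zi = (age_i - age_i.mean()) / age_i.std()
    zj = (age_j - age_j.mean()) / age_j.std()
    X_I = np.column_stack([zi, sexes[ev_i], zi * sexes[ev_i]])
    X_R = np.column_stack([zj, sexes[ev_j], zj * sexes[ev_j]])
    x_H = (house[ev_i] == house[ev_j]).astype(float)

    eta = (
        truth.alpha
        + truth.nu_I[ev_i]
        + truth.nu_R[ev_j]
        + truth.h_I[h_of[ev_i]]
        + truth.h_R[h_of[ev_j]]
        + X_I @ truth.beta_I.T
        + X_R @ truth.beta_R.T
        + x_H[:, None] * truth.beta_H
    )
    probs = category_probabilities(eta)  # (N, K)
    u = rng.uniform(size=ev_i.size)
    codes = 1 + (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    codes = np.minimum(codes, K)

    start = np.datetime64("1958-09-01")
    offsets = np.sort(rng.integers(0, 730, size=ev_i.size))
    events = [
        ObservationEvent(
            event_id=m + 1,
            episode_id=int(offsets[m]) * 4 + int(rng.integers(0, 4)),
            date=str(start + offsets[m]),
            initiator_id=ids[ev_i[m]],
            recipient_id=ids[ev_j[m]],
            behavior_code=int(codes[m]),
            initiator_age=round(float(age_i[m]), 3),
            recipient_age=round(float(age_j[m]), 3),
        )
        for m in range(ev_i.size)
    ]
    tally = {k: int(np.sum(codes == k)) for k in range(1, K + 1)}
    truth.category_tally = tally
    ledger = pd.DataFrame(
        {
            "initiator_id": [ids[i] for i in ii[used]],
            "recipient_id": [ids[j] for j in jj[used]],
            "same_household": same[used],
            "n_events": counts[used],
        }
    )
    return events, ledger


def write_dataset(out_dir, roster, events, truth: TruthBundle | None = None) -> None:
    """Write roster.csv / observations.csv (the formats read by the data
    loaders) plus truth.json into a directory."""
    import os

    from .data_io import write_observations, write_roster

    os.makedirs(out_dir, exist_ok=True)
    write_roster(os.path.join(out_dir, "roster.csv"), roster)
    write_observations(os.path.join(out_dir, "observations.csv"), events)
    if truth is not None:
        truth.to_json(os.path.join(out_dir, "truth.json"))
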