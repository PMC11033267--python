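"""Posterior post-processing: correlation recomposition, random-effect
scales, predicted-probability scenarios and contrasts, age-trend labels,
and descriptive dyad summaries.

"Significant" throughout means that the 95% posterior percentile interval
excludes zero; a Bonferroni-adjusted flag over all category pairs is also
provided where many pairs are tested at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import category_probabilities

__all__ = [
    "CorrelationSummary",
    "PredictionScenario",
    "PredictionCurve",
    "TrendLabel",
    "DyadSummary",
    "recompose_correlations",
    "random_effect_sds",
    "predict_probabilities",
    "contrast",
    "label_age_trend",
    "dyad_descriptives",
]

_ROLE_TO_CHOL = {
    "initiator": "L_I",
    "recipient": "L_R",
    "household_initiator": "L_hI",
    "household_recipient": "L_hR",
}
_ROLE_TO_SIGMA = {
    "initiator": "sigma_I",
    "recipient": "sigma_R",
    "household_initiator": "sigma_hI",
    "household_recipient": "sigma_hR",
}


def _contrast_labels(samples) -> list[str]:
    tax = samples.data.taxonomy
    return [lab for i, lab in enumerate(tax.labels, start=1) if i != tax.reference_index]


@dataclass
class CorrelationSummary:
    role: str
    labels: list
    mean: np.ndarray  # (K', K') posterior mean correlation matrix
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray  # bool, interval excludes 0
    pairs: pd.DataFrame  # long form, one row per unordered pair

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]


def recompose_correlations(samples, role: str, credible_level: float = 0.95) -> CorrelationSummary:
    """Posterior correlations between random effects across categories.

    Per draw the correlation matrix is recomposed as R = L L' from the
    sampled Cholesky factor for the role, then summarized elementwise with
    percentile intervals.  Raises if the role is absent from the variant
    (household roles under variants i/iF).
    """
    key = _ROLE_TO_CHOL.get(role)
    if key is None:
        raise ValueError(f"unknown role {role!r}")
    if key not in samples.draws:
        raise ValueError(f"role {role!r} is not part of variant {samples.spec.variant!r}")
    L = samples.stacked(key)  # (S, K', K')
    R = np.einsum("sij,skj->sik", L, L)
    lo_q = 100 * (1 - credible_level) / 2
    mean = R.mean(axis=0)
    lower = np.percentile(R, lo_q, axis=0)
    upper = np.percentile(R, 100 - lo_q, axis=0)
    sig = (lower > 0) | (upper < 0)
    np.fill_diagonal(sig, False)

    labels = _contrast_labels(samples)
    Kp = len(labels)
    n_pairs = Kp * (Kp - 1) // 2
    bonf_lo = 100 * (0.05 / n_pairs) / 2 if n_pairs else lo_q
    rows = []
    for k in range(Kp):
        for l in range(k):
            blo = np.percentile(R[:, k, l], bonf_lo)
            bhi = np.percentile(R[:, k, l], 100 - bonf_lo)
            rows.append(
                {
                    "behavior_a": labels[k],
                    "behavior_b": labels[l],
                    "rho_mean": mean[k, l],
                    "lower": lower[k, l],
                    "upper": upper[k, l],
                    "significant": bool(sig[k, l]),
                    "significant_bonferroni": bool(blo > 0 or bhi < 0),
                }
            )
    return CorrelationSummary(
        role=role,
        labels=labels,
        mean=mean,
        lower=lower,
        upper=upper,
        significant=sig,
        pairs=pd.DataFrame(rows),
    )


def random_effect_sds(samples, role: str) -> pd.DataFrame:
    """Posterior mean and SD of the random-effect scale per category
    (the layout of a variance-component table: one row per behavior)."""
    key = _ROLE_TO_SIGMA.get(role)
    if key is None:
        raise ValueError(f"unknown role {role!r}")
    if key not in samples.draws:
        raise ValueError(f"role {role!r} is not part of variant {samples.spec.variant!r}")
    sig = samples.stacked(key)  # (S, K')
    return pd.DataFrame(
        {
            "sd_mean": sig.mean(axis=0),
            "sd_sd": sig.std(axis=0, ddof=1),
        },
        index=pd.Index(_contrast_labels(samples), name="behavior"),
    )


@dataclass(frozen=True)
class PredictionScenario:
    """Covariate cell(s) at which to predict, on the natural scale.

    One covariate may vary over a grid; the rest are held fixed.  Ages left
    as ``None`` default to the event-level sample mean stored in the
    scaler; sexes are 0=female, 1=male; ``same_household`` is 0/1.  Random
    effects are set to zero ("average" initiator and recipient).
    """

    varying: str | None = None  # "initiator_age" | "recipient_age" | None
    grid: tuple = ()
    initiator_age: float | None = None
    recipient_age: float | None = None
    initiator_sex: float = 0.0
    recipient_sex: float = 0.0
    same_household: float = 0.0

    def cells(self, scaler: dict) -> tuple[np.ndarray, ...]:
        """(age_I, age_R, sex_I, sex_R, x_H) arrays over the grid."""
        n = len(self.grid) if self.varying else 1
        ai = np.full(n, self.initiator_age if self.initiator_age is not None else scaler["initiator_age"][0])
        aj = np.full(n, self.recipient_age if self.recipient_age is not None else scaler["recipient_age"][0])
        if self.varying == "initiator_age":
            ai = np.asarray(self.grid, dtype=float)
        elif self.varying == "recipient_age":
            aj = np.asarray(self.grid, dtype=float)
        elif self.varying is not None:
            raise ValueError(f"cannot vary covariate {self.varying!r}")
        si = np.full(n, float(self.initiator_sex))
        sj = np.full(n, float(self.recipient_sex))
        xh = np.full(n, float(self.same_household))
        return ai, aj, si, sj, xh


@dataclass
class PredictionCurve:
    grid: np.ndarray  # grid of the varying covariate (or a single cell)
    labels: list  # K category labels
    mean: np.ndarray  # (G, K) posterior mean probabilities
    lower: np.ndarray  # (G, K)
    upper: np.ndarray  # (G, K)
    draw_probs: np.ndarray = field(repr=False, default=None)  # (S, G, K)
    varying: str | None = None


def _scenario_probs(samples, scenario: PredictionScenario) -> tuple[np.ndarray, np.ndarray]:
    scaler = samples.meta.get("scaler") or samples.data.scaler
    ai, aj, si, sj, xh = scenario.cells(scaler)
    mi, sdi = scaler["initiator_age"]
    mj, sdj = scaler["recipient_age"]
    zi = (ai - mi) / sdi
    zj = (aj - mj) / sdj
    for ages, what in ((ai, "initiator_age"), (aj, "recipient_age")):
        rng = scaler.get(what + "_range")
        if rng is not None and (ages.min() < rng[0] or ages.max() > rng[1]):
            warnings.warn(f"{what} outside the observed range {rng}", stacklevel=3)
    alpha = samples.stacked("alpha")  # (S, K')
    eta = np.broadcast_to(alpha[:, None, :], (alpha.shape[0], zi.size, alpha.shape[1])).copy()
    if samples.spec.has_fixed:
        X_I = np.column_stack([zi, si, zi * si])
        X_R = np.column_stack([zj, sj, zj * sj])
        B_I = samples.stacked("beta_I")  # (S, K', m)
        B_R = samples.stacked("beta_R")
        b_H = samples.stacked("beta_H")  # (S, K')
        eta += np.einsum("gm,skm->sgk", X_I, B_I)
        eta += np.einsum("gm,skm->sgk", X_R, B_R)
        eta += xh[None, :, None] * b_H[:, None, :]
    probs = category_probabilities(eta)  # (S, G, K)
    grid = np.asarray(scenario.grid, dtype=float) if scenario.varying else np.array([0.0])
    return probs, grid


def predict_probabilities(samples, scenario: PredictionScenario, credible_level: float = 0.95) -> PredictionCurve:
    """Predicted behavior probabilities at zero random effects.

    Per posterior draw the full K-simplex is computed from the intercepts
    and (for variants with fixed effects) the scenario covariates; the band
    is the percentile interval across draws.
    """
    probs, grid = _scenario_probs(samples, scenario)
    lo_q = 100 * (1 - credible_level) / 2
    return PredictionCurve(
        grid=grid,
        labels=list(samples.data.taxonomy.labels),
        mean=probs.mean(axis=0),
        lower=np.percentile(probs, lo_q, axis=0),
        upper=np.percentile(probs, 100 - lo_q, axis=0),
        draw_probs=probs,
        varying=scenario.varying,
    )


def contrast(samples, scenario_a: PredictionScenario, scenario_b: PredictionScenario, credible_level: float = 0.95) -> pd.DataFrame:
    """Per-category difference of predicted probabilities (a minus b),
    with a percentile interval and a significance flag."""
    if scenario_a.varying != scenario_b.varying or tuple(scenario_a.grid) != tuple(scenario_b.grid):
        raise ValueError("scenarios must share the same varying covariate and grid")
    pa, grid = _scenario_probs(samples, scenario_a)
    pb, _ = _scenario_probs(samples, scenario_b)
    diff = pa - pb  # (S, G, K)
    lo_q = 100 * (1 - credible_level) / 2
    lower = np.percentile(diff, lo_q, axis=0)
    upper = np.percentile(diff, 100 - lo_q, axis=0)
    labels = list(samples.data.taxonomy.labels)
    rows = []
    for g in range(diff.shape[1]):
        for k, lab in enumerate(labels):
            rows.append(
                {
                    "grid_point": grid[g] if scenario_a.varying else np.nan,
                    "behavior": lab,
                    "difference": diff[:, g, k].mean(),
                    "lower": lower[g, k],
                    "upper": upper[g, k],
                    "significant": bool(lower[g, k] > 0 or upper[g, k] < 0),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendLabel:
    kind: str  # "increasing" | "decreasing" | "peaked"
    peak_interval: tuple | None = None  # [a, a+1) yearly interval when peaked


def label_age_trend(curve: PredictionCurve, tol: float = 1e-6) -> dict:
    """Classify each category's posterior-mean age curve.

    Monotone (within ``tol``) curves are labelled increasing/decreasing;
    otherwise the curve is "peaked" and the argmax grid cell is reported as
    the yearly interval [floor(age*), floor(age*)+1).
    """
    if curve.varying not in ("initiator_age", "recipient_age"):
        raise ValueError("age-trend labels require a curve over an age grid")
    out = {}
    ages = curve.grid
    for k, lab in enumerate(curve.labels):
        y = curve.mean[:, k]
        d = np.diff(y)
        if np.all(d >= -tol) and y[-1] >= y[0]:
            out[lab] = TrendLabel("increasing")
        elif np.all(d <= tol):
            out[lab] = TrendLabel("decreasing")
        else:
            a = float(ages[int(np.argmax(y))])
            lo = float(np.floor(a))
            out[lab] = TrendLabel("peaked", (lo, lo + 1.0))
    return out


@dataclass
class DyadSummary:
    """Descriptive tallies over directed dyads.

    ``table`` has one row per (same_household x same_sex x behavior) cell
    with the total observations, the number of unique directed dyads that
    exhibited the behavior, and the average per dyad; ``per_child`` and
    ``per_household`` give mean/SD of occurrence counts, where every event
    credits both of its participants (and both their households).
    """

    table: pd.DataFrame
    per_child: tuple  # (mean, sd)
    per_household: tuple
    n_events: int
    n_children: int
    n_households: int


def dyad_descriptives(events, roster, taxonomy=None) -> DyadSummary:
    from .data_io import BehaviorTaxonomy

    taxonomy = taxonomy or BehaviorTaxonomy()
    sex = {r.child_id: r.sex for r in roster}
    house = {r.child_id: r.household_id for r in roster}
    df = pd.DataFrame(
        {
            "initiator_id": [e.initiator_id for e in events],
            "recipient_id": [e.recipient_id for e in events],
            "behavior": [taxonomy.labels[e.behavior_code - 1] for e in events],
        }
    )
    df["same_household"] = df.apply(lambda r: house[r.initiator_id] == house[r.recipient_id], axis=1)
    df["same_sex"] = df.apply(lambda r: sex[r.initiator_id] == sex[r.recipient_id], axis=1)
    df["dyad"] = df["initiator_id"] + "->" + df["recipient_id"]
    grouped = (
        df.groupby(["same_household", "same_sex", "behavior"], observed=True)
        .agg(total=("dyad", "size"), dyads=("dyad", "nunique"))
        .reset_index()
    )
    grouped["avg_per_dyad"] = grouped["total"] / grouped["dyads"]

    counts = pd.concat([df["initiator_id"], df["recipient_id"]]).value_counts()
    child_counts = np.array([counts.get(r.child_id, 0) for r in roster], dtype=float)
    house_ids = list(dict.fromkeys(r.household_id for r in roster))
    hcounts = pd.concat(
        [df["initiator_id"].map(house), df["recipient_id"].map(house)]
    ).value_counts()
    house_counts = np.array([hcounts.get(h, 0) for h in house_ids], dtype=float)

    def _ms(x):
        return (float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)

    return DyadSummary(
        table=grouped,
        per_child=_ms(child_counts),
        per_household=_ms(house_counts),
        n_events=len(df),
        n_children=len(roster),
        n_households=len(house_ids),
    )
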