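"""WAIC model comparison and Akaike-style model weights.

WAIC is computed on the deviance scale from the pointwise log-likelihood
matrix (posterior draws x events):

    lppd   = sum_n log( mean_s exp(ll_{s,n}) )          (log-sum-exp over draws)
    p_waic = sum_n var_s( ll_{s,n} )                    (sample variance)
    WAIC   = -2 (lppd - p_waic)

Model weights are exp(-dWAIC/2) normalized over the candidate set, read as
the probability that each model predicts best on new data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["WaicResult", "ComparisonTable", "waic", "compare"]


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    se_waic: float
    n_events: int


@dataclass
class ComparisonTable:
    """Per-model WAIC, delta against the best (lowest-WAIC) model, and
    Akaike weight; rows sorted by WAIC ascending."""

    table: pd.DataFrame

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a (draws x events) pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a (draws, events) matrix")
    S, N = ll.shape
    if S < 2:
        raise ValueError("WAIC needs at least 2 posterior draws (variance undefined)")
    lppd_n = logsumexp(ll, axis=0) - np.log(S)
    p_n = ll.var(axis=0, ddof=1)
    elpd_n = lppd_n - p_n
    lppd = float(lppd_n.sum())
    p_waic = float(p_n.sum())
    w = -2.0 * (lppd - p_waic)
    se = float(np.sqrt(N * np.var(-2.0 * elpd_n, ddof=1))) if N > 1 else 0.0
    return WaicResult(lppd=lppd, p_waic=p_waic, waic=w, se_waic=se, n_events=N)


def compare(models) -> ComparisonTable:
    """Rank models by WAIC.

    ``models`` is a sequence of (name, WaicResult-or-float) pairs or a dict.
    Weights are invariant to adding a constant to every WAIC.
    """
    if isinstance(models, dict):
        models = list(models.items())
    models = list(models)
    if not models:
        raise ValueError("compare() needs at least one model")
    names, values, ses = [], [], []
    for name, w in models:
        names.append(name)
        if isinstance(w, WaicResult):
            values.append(w.waic)
            ses.append(w.se_waic)
        else:
            values.append(float(w))
            ses.append(np.nan)
    values = np.asarray(values)
    delta = values - values.min()
    raw = np.exp(-0.5 * delta)
    weight = raw / raw.sum()
    df = pd.DataFrame(
        {"waic": values, "se_waic": ses, "delta_waic": delta, "weight": weight},
        index=pd.Index(names, name="model"),
    ).sort_values("waic")
    return ComparisonTable(table=df)


def pairwise_delta_se(ll_a: np.ndarray, ll_b: np.ndarray) -> float:
    """Standard error of the WAIC difference between two models fitted to
    the same events, from the paired pointwise contributions."""
    if ll_a.shape[1] != ll_b.shape[1]:
        raise ValueError("models were fitted to different numbers of events")
    N = ll_a.shape[1]
    elpd_a = logsumexp(ll_a, axis=0) - np.log(ll_a.shape[0]) - ll_a.var(axis=0, ddof=1)
    elpd_b = logsumexp(ll_b, axis=0) - np.log(ll_b.shape[0]) - ll_b.var(axis=0, ddof=1)
    diff = -2.0 * (elpd_a - elpd_b)
    return float(np.sqrt(N * np.var(diff, ddof=1)))
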