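"""Multilevel multinomial logistic model variants for dyadic events.

The outcome of each directed event is one of K behavior categories.  For
k = 1..K-1 the log-odds against the reference category K are

    log(pi_k / pi_K) = alpha_k + nu^I_{k,i} + nu^R_{k,j}
                       [+ h^I_{k,[i]} + h^R_{k,[j]}]          (variants ih, ihF)
                       [+ sum_m beta_{k,Im} x_Im + sum_m beta_{k,Rm} x_Rm
                        + beta_{k,H} x_H]                     (variants iF, ihF)

with correlated individual-level random effects per role,
(nu_{1,i},...,nu_{K-1,i}) ~ MVN(0, Sigma), Sigma = D L L' D, D = diag(sigma),
expressed in the non-centered form nu_i = D L z_i with z_i ~ N(0, I) and L a
correlation Cholesky factor with an LKJ prior.  Household random effects (h)
have the same structure over households.

Priors: standard normal on intercepts and fixed effects (SDs configurable),
LKJ(shape) on each correlation Cholesky factor, and a half-normal prior on
each random-effect scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import betaln

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "Parameters",
    "VARIANTS",
    "linear_predictor",
    "category_probabilities",
    "log_likelihood_pointwise",
    "log_prior",
    "cholesky_from_corr",
    "corr_from_cholesky",
    "cpc_from_cholesky",
    "cholesky_from_cpc",
    "lkj_cholesky_logpdf",
    "sample_lkj_cholesky",
]

VARIANTS = ("i", "ih", "iF", "ihF")


@dataclass(frozen=True)
class PriorConfig:
    intercept_sd: float = 1.0
    beta_sd: float = 1.0
    lkj_shape: float = 2.0
    scale_prior: str = "half-normal"
    scale_sd: float = 1.0

    def __post_init__(self):
        for name in ("intercept_sd", "beta_sd", "lkj_shape", "scale_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scale_prior != "half-normal":
            raise ValueError("only the half-normal scale prior is implemented")


@dataclass(frozen=True)
class ModelSpec:
    """Which effects a model variant includes.

    ``variant`` is one of ``i`` (individual random effects only), ``ih``
    (adds household random effects), ``iF`` (adds fixed effects), ``ihF``
    (both).  ``n_covariates`` is the per-role fixed-effect count (default 3:
    standardized age, sex, their product).
    """

    variant: str = "ihF"
    K: int = 19
    n_covariates: int = 3
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.has_fixed and self.n_covariates < 1:
            raise ValueError("variants iF/ihF need a non-empty covariate block")

    @property
    def has_fixed(self) -> bool:
        return self.variant.endswith("F")

    @property
    def has_household(self) -> bool:
        return "h" in self.variant

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if isinstance(d.get("priors"), dict):
            d["priors"] = PriorConfig(**d["priors"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Parameters:
    """One point in parameter space (constrained scale).

    Shapes (K' = K-1, m = covariates per role, I individuals, H households):
    alpha (K',), beta_I/beta_R (K', m), beta_H (K',), z_I/z_R (I, K'),
    L_I/L_R (K', K') lower-triangular correlation Cholesky factors,
    sigma_I/sigma_R (K',) >= 0; household blocks analogous over H.
    Unused blocks for a variant may be None.
    """

    alpha: np.ndarray
    z_I: np.ndarray
    z_R: np.ndarray
    L_I: np.ndarray
    L_R: np.ndarray
    sigma_I: np.ndarray
    sigma_R: np.ndarray
    beta_I: np.ndarray | None = None
    beta_R: np.ndarray | None = None
    beta_H: np.ndarray | None = None
    z_hI: np.ndarray | None = None
    z_hR: np.ndarray | None = None
    L_hI: np.ndarray | None = None
    L_hR: np.ndarray | None = None
    sigma_hI: np.ndarray | None = None
    sigma_hR: np.ndarray | None = None

    def nu(self, role: str) -> np.ndarray:
        """Realized random-effect matrix for a role: rows are units,
        columns categories; nu = z @ (diag(sigma) L)^T."""
        z, L, s = {
            "initiator": (self.z_I, self.L_I, self.sigma_I),
            "recipient": (self.z_R, self.L_R, self.sigma_R),
            "household_initiator": (self.z_hI, self.L_hI, self.sigma_hI),
            "household_recipient": (self.z_hR, self.L_hR, self.sigma_hR),
        }[role]
        if z is None:
            raise ValueError(f"role {role!r} not present in these parameters")
        A = self.sigmaL(L, s)
        return z @ A.T

    @staticmethod
    def sigmaL(L: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        return sigma[:, None] * L


# ---------------------------------------------------------------------------
# correlation Cholesky factors and the LKJ prior
# ---------------------------------------------------------------------------

def cholesky_from_corr(R: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor of a correlation matrix."""
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError as err:
        raise ValueError("correlation matrix is not positive definite") from err


def corr_from_cholesky(L: np.ndarray) -> np.ndarray:
    """Recompose R = L L' from a correlation Cholesky factor."""
    L = np.asarray(L, dtype=float)
    return L @ L.T


def cpc_from_cholesky(L: np.ndarray) -> np.ndarray:
    """Canonical partial correlations z_ij (strictly lower) from L.

    Inverts the stick-breaking construction L[i,j] = z_ij * prod_{k<j} c_ik,
    c = sqrt(1 - z^2); the diagonal is determined by the unit-row-norm
    constraint.
    """
    L = np.asarray(L, dtype=float)
    d = L.shape[0]
    z = np.zeros((d, d))
    for i in range(1, d):
        prod = 1.0
        for j in range(i):
            z[i, j] = L[i, j] / prod
            prod *= np.sqrt(max(1.0 - z[i, j] ** 2, 0.0))
    return z


def cholesky_from_cpc(z: np.ndarray) -> np.ndarray:
    """Correlation Cholesky factor from canonical partial correlations.

    Vectorized row-wise stick-breaking; entries of ``z`` on/above the
    diagonal are ignored.
    """
    z = np.asarray(z, dtype=float)
    d = z.shape[0]
    zt = np.tril(z, k=-1)
    c = np.sqrt(1.0 - zt**2)  # ones outside the strict lower triangle
    Q = np.cumprod(np.concatenate([np.ones((d, 1)), c[:, :-1]], axis=1), axis=1)
    L = zt * Q
    L[np.diag_indices(d)] = Q[np.diag_indices(d)]
    return L


def _cpc_beta_params(d: int, shape: float) -> np.ndarray:
    """Per-column Beta(b, b) parameter of the CPCs under LKJ(shape):
    b_j = shape + (d - 2 - j)/2 for column j (0-based)."""
    j = np.arange(d)
    return shape + (d - 2 - j) / 2.0


def lkj_cholesky_logpdf(L: np.ndarray, shape: float = 2.0) -> float:
    """Normalized log-density of a correlation Cholesky factor under the
    LKJ(shape) prior, with respect to its free strictly-lower entries.

    Computed via the independent canonical-partial-correlation
    representation: z_ij ~ 2 Beta(b_j, b_j) - 1 with
    b_j = shape + (d-2-j)/2, plus the z -> L change of variables.
    """
    L = np.asarray(L, dtype=float)
    d = L.shape[0]
    if d == 1:
        return 0.0
    z = cpc_from_cholesky(L)
    b = _cpc_beta_params(d, shape)
    total = 0.0
    for i in range(1, d):
        for j in range(i):
            bj = b[j]
            log1mz2 = np.log1p(-z[i, j] ** 2)
            # log p_z(z_ij)
            total += (bj - 1.0) * log1mz2 + (1.0 - 2.0 * bj) * np.log(2.0) - betaln(bj, bj)
            # |dz/dL| from det(dL_free/dz) = prod c_ij^(i-1-j)
            total -= (i - 1 - j) * 0.5 * log1mz2
    return float(total)


def sample_lkj_cholesky(d: int, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation Cholesky factor from the LKJ(shape) prior."""
    if d == 1:
        return np.ones((1, 1))
    b = _cpc_beta_params(d, shape)
    z = np.zeros((d, d))
    for j in range(d - 1):
        u = rng.beta(b[j], b[j], size=d - 1 - j)
        z[j + 1 :, j] = 2.0 * u - 1.0
    return cholesky_from_cpc(z)


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def linear_predictor(params: Parameters, data, spec: ModelSpec) -> np.ndarray:
    """Event-level contrast matrix eta of shape (N, K-1).

    The reference category's contribution is pinned at 0 and not included.
    """
    Kp = spec.K - 1
    if params.alpha.shape != (Kp,):
        raise ValueError(f"alpha has shape {params.alpha.shape}, expected ({Kp},)")
    eta = np.tile(params.alpha, (data.n_events, 1))
    eta += params.nu("initiator")[data.i_idx]
    eta += params.nu("recipient")[data.j_idx]
    if spec.has_household:
        eta += params.nu("household_initiator")[data.hi_idx]
        eta += params.nu("household_recipient")[data.hj_idx]
    if spec.has_fixed:
        if params.beta_I is None or params.beta_R is None or params.beta_H is None:
            raise ValueError("variant with fixed effects requires beta_I/beta_R/beta_H")
        eta += data.X_I @ params.beta_I.T
        eta += data.X_R @ params.beta_R.T
        eta += data.x_H[:, None] * params.beta_H
    return eta


def category_probabilities(eta: np.ndarray) -> np.ndarray:
    """Softmax over [eta, 0]: probabilities of the K categories.

    Accepts a (K-1,) vector or an (..., K-1) array; returns (..., K).
    Computed with a log-sum-exp shift so exp(eta) is never materialized
    unnormalized.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=-1, keepdims=True)


def _log_probs(eta: np.ndarray) -> np.ndarray:
    full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    m = full.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(full - m).sum(axis=-1, keepdims=True))
    return full - lse


def log_likelihood_pointwise(params: Parameters, data, spec: ModelSpec) -> np.ndarray:
    """Per-event log p(y_n | params), an (N,) vector."""
    eta = linear_predictor(params, data, spec)
    lp = _log_probs(eta)
    return lp[np.arange(data.n_events), data.y]


def _normal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(-0.5 * np.sum((x / sd) ** 2) - x.size * (0.5 * np.log(2 * np.pi) + np.log(sd)))


def _halfnormal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        return -np.inf
    return float(
        -0.5 * np.sum((x / sd) ** 2)
        + x.size * (0.5 * np.log(2.0 / np.pi) - np.log(sd))
    )


def log_prior(params: Parameters, spec: ModelSpec) -> float:
    """Joint log prior density of all parameter blocks of a variant.

    Normal on intercepts and fixed effects, standard normal on the
    non-centered innovations z, LKJ(shape) on each correlation Cholesky
    factor (density over its free entries), half-normal on each scale.
    """
    pc = spec.priors
    total = _normal_logpdf_sum(params.alpha, pc.intercept_sd)
    total += _normal_logpdf_sum(params.z_I, 1.0)
    total += _normal_logpdf_sum(params.z_R, 1.0)
    total += lkj_cholesky_logpdf(params.L_I, pc.lkj_shape)
    total += lkj_cholesky_logpdf(params.L_R, pc.lkj_shape)
    total += _halfnormal_logpdf_sum(params.sigma_I, pc.scale_sd)
    total += _halfnormal_logpdf_sum(params.sigma_R, pc.scale_sd)
    if spec.has_fixed:
        total += _normal_logpdf_sum(params.beta_I, pc.beta_sd)
        total += _normal_logpdf_sum(params.beta_R, pc.beta_sd)
        total += _normal_logpdf_sum(params.beta_H, pc.beta_sd)
    if spec.has_household:
        total += _normal_logpdf_sum(params.z_hI, 1.0)
        total += _normal_logpdf_sum(params.z_hR, 1.0)
        total += lkj_cholesky_logpdf(params.L_hI, pc.lkj_shape)
        total += lkj_cholesky_logpdf(params.L_hR, pc.lkj_shape)
        total += _halfnormal_logpdf_sum(params.sigma_hI, pc.scale_sd)
        total += _halfnormal_logpdf_sum(params.sigma_hR, pc.scale_sd)
    return total
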