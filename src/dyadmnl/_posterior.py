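"""Unconstrained log posterior and its analytic gradient.

The sampler works on a flat real vector theta.  Constrained blocks are
transformed as follows:

* random-effect scales sigma = exp(s), half-normal prior plus the log
  Jacobian s;
* each correlation Cholesky factor L is parameterized by its canonical
  partial correlations z = tanh(y) through the row-wise stick-breaking map
  L[i,j] = z_ij * prod_{k<j} sqrt(1-z_ik^2), L[i,i] = prod_{k<i}
  sqrt(1-z_ik^2).  Under the LKJ(shape) prior the z_ij are independent with
  (z+1)/2 ~ Beta(b_j, b_j), b_j = shape + (d-2-j)/2, which makes the prior
  density in y-space simply sum b_j * log(1 - z_ij^2) + const.

All gradients are derived by hand and checked against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.special import betaln

from .model import ModelSpec, Parameters

__all__ = ["Posterior"]

_LOG2PI = np.log(2.0 * np.pi)


def _chol_forward(y_vec: np.ndarray, d: int, tril, triu):
    """Map free vector y to (L, z, Q); Q[i,j] = prod_{k<j} c[i,k]."""
    z = np.zeros((d, d))
    if y_vec.size:
        z[tril] = np.tanh(y_vec)
    c = np.sqrt(1.0 - z * z)
    c[triu] = 1.0  # only strictly-lower c values enter products
    Q = np.empty((d, d))
    Q[:, 0] = 1.0
    if d > 1:
        np.cumprod(c[:, :-1], axis=1, out=Q[:, 1:])
    L = z * Q
    idx = np.arange(d)
    L[idx, idx] = Q[idx, idx]
    return L, z, Q


def _chol_backward(dL: np.ndarray, L: np.ndarray, z: np.ndarray, Q: np.ndarray, tril, tril_mask):
    """Pull a gradient w.r.t. L (lower triangle incl. diagonal) back to y."""
    dL = dL * tril_mask
    P = dL * L
    S = P.sum(axis=1, keepdims=True) - np.cumsum(P, axis=1)  # sum over columns > j
    dY = (1.0 - z * z) * Q * dL - z * S
    return dY[tril]


class Posterior:
    """Flat-vector view of a model variant's posterior over a dataset."""

    def __init__(self, spec: ModelSpec, data, likelihood: bool = True):
        self.spec = spec
        self.data = data
        self.likelihood = likelihood
        Kp = spec.K - 1
        self.Kp = Kp
        self.m = spec.n_covariates if spec.has_fixed else 0
        self.I = data.n_individuals
        self.H = data.n_households
        self.N = data.n_events
        self.tril = np.tril_indices(Kp, -1)
        self.triu = np.triu_indices(Kp)
        self.tril_mask = np.tril(np.ones((Kp, Kp)))
        self.T = len(self.tril[0])
        # per-column Beta parameter of the CPCs under LKJ(shape)
        cols = self.tril[1]
        self.b_cols = spec.priors.lkj_shape + (Kp - 2 - cols) / 2.0
        self._lkj_const = float(
            np.sum((1.0 - 2.0 * self.b_cols) * np.log(2.0) - betaln(self.b_cols, self.b_cols))
        ) if self.T else 0.0

        self._build_slices()
        if likelihood:
            ones = np.ones(self.N)
            rng_n = np.arange(self.N)
            self.M_IT = csr_matrix((ones, (data.i_idx, rng_n)), shape=(self.I, self.N))
            self.M_RT = csr_matrix((ones, (data.j_idx, rng_n)), shape=(self.I, self.N))
            if spec.has_household:
                self.M_hIT = csr_matrix((ones, (data.hi_idx, rng_n)), shape=(self.H, self.N))
                self.M_hRT = csr_matrix((ones, (data.hj_idx, rng_n)), shape=(self.H, self.N))
            obs = data.y < Kp  # events in a non-reference category
            self.obs_rows = np.where(obs)[0]
            self.obs_cols = data.y[obs]

    # ------------------------------------------------------------------ layout
    def _build_slices(self):
        spec, Kp, m, I, H, T = self.spec, self.Kp, self.m, self.I, self.H, self.T
        names = [("alpha", Kp)]
        if spec.has_fixed:
            names += [("beta_I", Kp * m), ("beta_R", Kp * m), ("beta_H", Kp)]
        names += [
            ("z_I", I * Kp), ("z_R", I * Kp),
            ("y_LI", T), ("y_LR", T),
            ("s_I", Kp), ("s_R", Kp),
        ]
        if spec.has_household:
            names += [
                ("z_hI", H * Kp), ("z_hR", H * Kp),
                ("y_LhI", T), ("y_LhR", T),
                ("s_hI", Kp), ("s_hR", Kp),
            ]
        self.slices = {}
        off = 0
        for name, size in names:
            self.slices[name] = slice(off, off + size)
            off += size
        self.dim = off

    def _get(self, theta, name, shape=None):
        v = theta[self.slices[name]]
        return v.reshape(shape) if shape is not None else v

    # ------------------------------------------------------------ log density
    def logp_grad(self, theta: np.ndarray):
        """Log posterior density (up to no constant at all: priors are fully
        normalized) and its gradient w.r.t. theta."""
        spec, Kp, m = self.spec, self.Kp, self.m
        pc = spec.priors
        grad = np.zeros_like(theta)
        lp = 0.0

        alpha = self._get(theta, "alpha")
        Z_I = self._get(theta, "z_I", (self.I, Kp))
        Z_R = self._get(theta, "z_R", (self.I, Kp))
        y_LI = self._get(theta, "y_LI")
        y_LR = self._get(theta, "y_LR")
        s_I = self._get(theta, "s_I")
        s_R = self._get(theta, "s_R")

        L_I, zc_I, Q_I = _chol_forward(y_LI, Kp, self.tril, self.triu)
        L_R, zc_R, Q_R = _chol_forward(y_LR, Kp, self.tril, self.triu)
        sig_I = np.exp(s_I)
        sig_R = np.exp(s_R)
        A_I = sig_I[:, None] * L_I
        A_R = sig_R[:, None] * L_R

        if spec.has_fixed:
            B_I = self._get(theta, "beta_I", (Kp, m))
            B_R = self._get(theta, "beta_R", (Kp, m))
            beta_H = self._get(theta, "beta_H")
        if spec.has_household:
            Z_hI = self._get(theta, "z_hI", (self.H, Kp))
            Z_hR = self._get(theta, "z_hR", (self.H, Kp))
            y_LhI = self._get(theta, "y_LhI")
            y_LhR = self._get(theta, "y_LhR")
            s_hI = self._get(theta, "s_hI")
            s_hR = self._get(theta, "s_hR")
            L_hI, zc_hI, Q_hI = _chol_forward(y_LhI, Kp, self.tril, self.triu)
            L_hR, zc_hR, Q_hR = _chol_forward(y_LhR, Kp, self.tril, self.triu)
            sig_hI = np.exp(s_hI)
            sig_hR = np.exp(s_hR)
            A_hI = sig_hI[:, None] * L_hI
            A_hR = sig_hR[:, None] * L_hR

        # ----- likelihood
        if self.likelihood:
            data = self.data
            V_I = Z_I @ A_I.T
            V_R = Z_R @ A_R.T
            eta = alpha + V_I[data.i_idx] + V_R[data.j_idx]
            if spec.has_household:
                V_hI = Z_hI @ A_hI.T
                V_hR = Z_hR @ A_hR.T
                eta += V_hI[data.hi_idx] + V_hR[data.hj_idx]
            if spec.has_fixed:
                eta += data.X_I @ B_I.T + data.X_R @ B_R.T + data.x_H[:, None] * beta_H

            M = np.maximum(eta.max(axis=1), 0.0)
            lse = M + np.log(np.exp(-M) + np.exp(eta - M[:, None]).sum(axis=1))
            lp += float(eta[self.obs_rows, self.obs_cols].sum() - lse.sum())
            G = -np.exp(eta - lse[:, None])  # -pi_k for k < K
            G[self.obs_rows, self.obs_cols] += 1.0

            grad[self.slices["alpha"]] += G.sum(axis=0)
            if spec.has_fixed:
                grad[self.slices["beta_I"]] += (G.T @ data.X_I).ravel()
                grad[self.slices["beta_R"]] += (G.T @ data.X_R).ravel()
                grad[self.slices["beta_H"]] += G.T @ data.x_H

            for (MT, Z, A, L, zc, Q, sig, zn, yn, sn) in (
                (self.M_IT, Z_I, A_I, L_I, zc_I, Q_I, sig_I, "z_I", "y_LI", "s_I"),
                (self.M_RT, Z_R, A_R, L_R, zc_R, Q_R, sig_R, "z_R", "y_LR", "s_R"),
            ) + (
                (
                    (self.M_hIT, Z_hI, A_hI, L_hI, zc_hI, Q_hI, sig_hI, "z_hI", "y_LhI", "s_hI"),
                    (self.M_hRT, Z_hR, A_hR, L_hR, zc_hR, Q_hR, sig_hR, "z_hR", "y_LhR", "s_hR"),
                )
                if spec.has_household
                else ()
            ):
                S = np.asarray(MT @ G)  # (units, Kp) accumulated dL/dV
                grad[self.slices[zn]] += (S @ A).ravel()
                dA = S.T @ Z
                grad[self.slices[sn]] += np.sum(np.tril(dA) * L, axis=1) * sig
                dL = sig[:, None] * dA
                if self.T:
                    grad[self.slices[yn]] += _chol_backward(dL, L, zc, Q, self.tril, self.tril_mask)

        # ----- priors (fully normalized, with transform Jacobians)
        def normal_block(name, x, sd):
            lp_ = -0.5 * np.sum((x / sd) ** 2) - x.size * (0.5 * _LOG2PI + np.log(sd))
            grad[self.slices[name]] += (-x / sd**2).ravel()
            return float(lp_)

        def scale_block(name, s, sig):
            # half-normal(scale_sd) on sigma = exp(s) plus Jacobian
            tau = pc.scale_sd
            lp_ = np.sum(
                -0.5 * (sig / tau) ** 2 + 0.5 * np.log(2.0 / np.pi) - np.log(tau) + s
            )
            grad[self.slices[name]] += -((sig / tau) ** 2) + 1.0
            return float(lp_)

        def lkj_block(name, y):
            if not self.T:
                return 0.0
            zt = np.tanh(y)
            lp_ = float(np.sum(self.b_cols * np.log1p(-zt * zt))) + self._lkj_const
            grad[self.slices[name]] += -2.0 * self.b_cols * zt
            return lp_

        lp += normal_block("alpha", alpha, pc.intercept_sd)
        lp += normal_block("z_I", Z_I, 1.0)
        lp += normal_block("z_R", Z_R, 1.0)
        lp += lkj_block("y_LI", y_LI)
        lp += lkj_block("y_LR", y_LR)
        lp += scale_block("s_I", s_I, sig_I)
        lp += scale_block("s_R", s_R, sig_R)
        if spec.has_fixed:
            lp += normal_block("beta_I", B_I, pc.beta_sd)
            lp += normal_block("beta_R", B_R, pc.beta_sd)
            lp += normal_block("beta_H", beta_H, pc.beta_sd)
        if spec.has_household:
            lp += normal_block("z_hI", Z_hI, 1.0)
            lp += normal_block("z_hR", Z_hR, 1.0)
            lp += lkj_block("y_LhI", y_LhI)
            lp += lkj_block("y_LhR", y_LhR)
            lp += scale_block("s_hI", s_hI, sig_hI)
            lp += scale_block("s_hR", s_hR, sig_hR)

        return lp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    # ------------------------------------------------------------- transforms
    def constrain(self, theta: np.ndarray) -> Parameters:
        """Map a flat unconstrained vector to constrained ``Parameters``."""
        spec, Kp, m = self.spec, self.Kp, self.m
        L_I, _, _ = _chol_forward(self._get(theta, "y_LI"), Kp, self.tril, self.triu)
        L_R, _, _ = _chol_forward(self._get(theta, "y_LR"), Kp, self.tril, self.triu)
        kw = dict(
            alpha=self._get(theta, "alpha").copy(),
            z_I=self._get(theta, "z_I", (self.I, Kp)).copy(),
            z_R=self._get(theta, "z_R", (self.I, Kp)).copy(),
            L_I=L_I,
            L_R=L_R,
            sigma_I=np.exp(self._get(theta, "s_I")),
            sigma_R=np.exp(self._get(theta, "s_R")),
        )
        if spec.has_fixed:
            kw.update(
                beta_I=self._get(theta, "beta_I", (Kp, m)).copy(),
                beta_R=self._get(theta, "beta_R", (Kp, m)).copy(),
                beta_H=self._get(theta, "beta_H").copy(),
            )
        if spec.has_household:
            L_hI, _, _ = _chol_forward(self._get(theta, "y_LhI"), Kp, self.tril, self.triu)
            L_hR, _, _ = _chol_forward(self._get(theta, "y_LhR"), Kp, self.tril, self.triu)
            kw.update(
                z_hI=self._get(theta, "z_hI", (self.H, Kp)).copy(),
                z_hR=self._get(theta, "z_hR", (self.H, Kp)).copy(),
                L_hI=L_hI,
                L_hR=L_hR,
                sigma_hI=np.exp(self._get(theta, "s_hI")),
                sigma_hR=np.exp(self._get(theta, "s_hR")),
            )
        return Parameters(**kw)

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        """Jittered start: diffuse on intercepts/effects, innovations and
        correlation parameters near zero, scales moderately below 1."""
        theta = np.zeros(self.dim)
        for name, sl in self.slices.items():
            size = sl.stop - sl.start
            if name.startswith(("z_", "y_L")):
                theta[sl] = 0.1 * rng.standard_normal(size)
            elif name.startswith("s_"):
                theta[sl] = -1.0 + 0.2 * rng.standard_normal(size)
            else:
                theta[sl] = rng.uniform(-1.0, 1.0, size)
        return theta

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-event log-likelihood at one draw (used for WAIC)."""
        from .model import log_likelihood_pointwise

        return log_likelihood_pointwise(self.constrain(theta), self.data, self.spec)
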