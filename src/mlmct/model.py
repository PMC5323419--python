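"""REML estimation of the two-level linear model for intensive longitudinal data.

The model for subject i's length-L series is

    y_i = X_i gamma + Z_i u_i + e_i,      u_i ~ N(0, G),   e_i ~ N(0, R_i),

with random intercept and random slope (Z_i = [1, z_i]), fixed design
X_i = [1, z_i, c_i, c_i z_i], and a residual covariance R_i that is either
homogeneous-independent (``id``: sigma^2 I) or homogeneous AR(1)
(``ar1``: sigma^2 with correlation rho^|t-s|).  The marginal covariance is
Sigma_i = Z_i G Z_i' + R_i and estimation is by REML, with the fixed effects
profiled out via GLS and model-based standard errors taken from
C = [sum_i X_i' Sigma_i^{-1} X_i]^{-1}.

Internally the REML criterion is evaluated from per-subject cross-products
of [y | X | Z] against the tridiagonal AR(1) inverse correlation, combined
through a low-rank (Woodbury) identity in the two random effects.  One
criterion evaluation therefore costs O(1) in the series length once the
cross-products are cached, which is what makes the Monte Carlo study cheap.
The residual scale sigma^2 is profiled analytically during optimization;
``loglike_reml`` evaluates the criterion at arbitrary (G, sigma^2, rho).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, toeplitz

from .ar import RHO_CAP, StationarityError

__all__ = [
    "FixedEffects",
    "RandomEffectsCov",
    "ResidualStructure",
    "MultilevelModel",
    "MLMResults",
    "assemble_design",
    "marginal_covariance",
    "reml_fit",
    "gls_fixed_effects",
    "fixed_effect_se",
    "XNAMES",
]

XNAMES = ["Intercept", "z", "c", "z:c"]
ZNAMES = ["Intercept", "z"]


@dataclass
class FixedEffects:
    gamma: np.ndarray

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("fixed effects must be finite")


@dataclass
class RandomEffectsCov:
    """Covariance of (random intercept, random slope)."""

    var_u0: float
    var_u1: float
    cov_u0u1: float

    def __post_init__(self):
        if self.var_u0 < 0 or self.var_u1 < 0:
            raise ValueError("random-effect variances must be >= 0")
        if self.cov_u0u1**2 > self.var_u0 * self.var_u1 * (1 + 1e-10) + 1e-12:
            raise ValueError("G must be positive semidefinite")

    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.var_u0, self.cov_u0u1], [self.cov_u0u1, self.var_u1]]
        )

    @classmethod
    def from_matrix(cls, G: np.ndarray) -> "RandomEffectsCov":
        return cls(float(G[0, 0]), float(G[1, 1]), float(G[0, 1]))


@dataclass
class ResidualStructure:
    """Within-subject residual model: 'id' or 'ar1'."""

    kind: str
    sigma2: float
    rho: float = 0.0

    def __post_init__(self):
        if self.kind not in ("id", "ar1"):
            raise ValueError("kind must be 'id' or 'ar1'")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if abs(self.rho) >= 1:
            raise StationarityError("|rho| must be < 1")

    def correlation(self, n: int) -> np.ndarray:
        if self.kind == "id":
            return np.eye(n)
        return toeplitz(self.rho ** np.arange(n))

    def matrix(self, n: int) -> np.ndarray:
        return self.sigma2 * self.correlation(n)


# ---------------------------------------------------------------------------
# free functions (also used by the oracle tests)
# ---------------------------------------------------------------------------


def assemble_design(
    panel: pd.DataFrame,
    subject: str = "subject",
    occasion: str = "occasion",
    outcome: str = "y",
    time_varying: str = "z",
    level2: str = "c",
    transformed: bool = False,
):
    """Split a long panel into per-subject (y_i, X_i, Z_i) blocks.

    For a raw panel, Z_i = [1, z] and X_i = Z_i C_i = [1, z, c, c z] with the
    level-2 covariate required to be constant within subject.  For a
    transformed panel (``transformed=True``), the columns ``y_star``,
    ``x_star_*`` and ``z_star_*`` are taken verbatim: no fresh intercept is
    injected, since the whitening operator has already been applied to the
    ones column.

    Returns (subject_ids, y_blocks, X_blocks, Z_blocks).
    """
    ids = list(pd.unique(panel[subject]))
    ys, Xs, Zs = [], [], []
    for sid in ids:
        sub = panel[panel[subject] == sid].sort_values(occasion)
        if transformed:
            y = sub["y_star"].to_numpy(float)
            X = sub[[f"x_star_{c}" for c in ("intercept", "z", "c", "zc")]].to_numpy(float)
            Z = sub[[f"z_star_{c}" for c in ("intercept", "z")]].to_numpy(float)
        else:
            cvals = sub[level2].to_numpy(float)
            if not np.allclose(cvals, cvals[0]):
                raise ValueError(
                    f"level-2 covariate {level2!r} varies within subject {sid!r}"
                )
            z = sub[time_varying].to_numpy(float)
            y = sub[outcome].to_numpy(float)
            ones = np.ones_like(z)
            Z = np.column_stack([ones, z])
            X = np.column_stack([ones, z, cvals[0] * ones, cvals[0] * z])
        ys.append(y)
        Xs.append(X)
        Zs.append(Z)
    return ids, ys, Xs, Zs


def marginal_covariance(
    G: np.ndarray | RandomEffectsCov, resid: ResidualStructure, Z_i: np.ndarray
) -> np.ndarray:
    """Sigma_i = Z_i G Z_i' + R_i, checked positive definite."""
    Gm = G.matrix() if isinstance(G, RandomEffectsCov) else np.asarray(G, float)
    if np.any(np.linalg.eigvalsh(Gm) < -1e-10):
        raise ValueError("G is not positive semidefinite")
    Z_i = np.asarray(Z_i, float)
    Sigma = Z_i @ Gm @ Z_i.T + resid.matrix(Z_i.shape[0])
    if np.any(np.linalg.eigvalsh(Sigma) <= 0):
        raise ValueError("marginal covariance is not positive definite")
    return Sigma


def gls_fixed_effects(y: np.ndarray, X: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """GLS estimator (X' Sigma^-1 X)^-1 X' Sigma^-1 y."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    c = cho_factor(np.asarray(Sigma, float))
    Si_X = cho_solve(c, X)
    XtSiX = X.T @ Si_X
    if np.linalg.matrix_rank(XtSiX) < X.shape[1]:
        raise np.linalg.LinAlgError("X' Sigma^-1 X is singular")
    return np.linalg.solve(XtSiX, Si_X.T @ y)


def fixed_effect_se(X_blocks, Sigma_blocks) -> np.ndarray:
    """Model-based SEs: sqrt(diag([sum_i X_i' Sigma_i^-1 X_i]^-1))."""
    k = np.asarray(X_blocks[0]).shape[1]
    info = np.zeros((k, k))
    for X, S in zip(X_blocks, Sigma_blocks):
        X = np.asarray(X, float)
        info += X.T @ cho_solve(cho_factor(np.asarray(S, float)), X)
    if np.linalg.matrix_rank(info) < k:
        raise np.linalg.LinAlgError("singular information matrix")
    return np.sqrt(np.diag(np.linalg.inv(info)))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


def _combine_xprods(C0, B, C1s, rho):
    """M' P(rho)^{-1} M from cached cross-products (P = AR(1) correlation)."""
    if rho == 0.0:
        return C0
    return ((1.0 + rho**2) * C0 - rho**2 * B - rho * C1s) / (1.0 - rho**2)


class _Group:
    """Stacked per-subject data for one common series length."""

    def __init__(self, y, X, Z):
        # y: (N, L), X: (N, L, k), Z: (N, L, q)
        self.N, self.L = y.shape
        self.k = X.shape[2]
        self.q = Z.shape[2]
        M = np.concatenate([y[:, :, None], X, Z], axis=2)
        self.C0 = np.einsum("nlj,nlk->njk", M, M)
        ends = np.einsum("nj,nk->njk", M[:, 0], M[:, 0]) + np.einsum(
            "nj,nk->njk", M[:, -1], M[:, -1]
        )
        C1 = np.einsum("nlj,nlk->njk", M[:, :-1], M[:, 1:])
        self.B = ends
        self.C1s = C1 + np.swapaxes(C1, 1, 2)
        self.zidx = np.arange(1 + self.k, 1 + self.k + self.q)

    def crossprods(self, Lam, rho):
        """Per-group Woodbury-corrected cross-products at unit residual scale.

        Returns (Acc, sum_logdetK) where Acc = sum_i M_i' V_i^{-1} M_i over
        the (1 + k + q) columns, V_i = Z_i Lam Lam' Z_i' + P(rho), and
        sum_logdetK = sum_i log|I_q + Lam' Z_i' P^{-1} Z_i Lam|.
        """
        W = _combine_xprods(self.C0, self.B, self.C1s, rho)
        Wz = W[:, :, self.zidx]
        U = Wz @ Lam                              # (N, m, q) = M'P^{-1}Z Lam
        S = np.swapaxes(U[:, self.zidx, :], 1, 2) @ Lam  # Lam'(Z'P^-1 Z)Lam... see below
        # careful: U[:, zidx, :] = Z'P^{-1}Z Lam, so S = Lam' Z'P^{-1}Z Lam
        K = S + np.eye(self.q)
        if self.q == 2:
            det = K[:, 0, 0] * K[:, 1, 1] - K[:, 0, 1] * K[:, 1, 0]
            inv = np.empty_like(K)
            inv[:, 0, 0] = K[:, 1, 1]
            inv[:, 1, 1] = K[:, 0, 0]
            inv[:, 0, 1] = -K[:, 0, 1]
            inv[:, 1, 0] = -K[:, 1, 0]
            Kinv = inv / det[:, None, None]
            logdetK = np.log(det)
        else:
            Kinv = np.linalg.inv(K)
            logdetK = np.linalg.slogdet(K)[1]
        corr = np.einsum("nij,njk,nlk->nil", U, Kinv, U)
        Acc = (W - corr).sum(axis=0)
        return Acc, float(np.sum(logdetK))

    def logdet_P(self, rho):
        return (self.L - 1) * np.log1p(-rho**2)


class MLMResults:
    """REML fit results: estimates, uncertainties, diagnostics."""

    def __init__(self, model, gamma, bse, G, resid, llf, converged, n_iter):
        self.model = model
        self.fe_params = pd.Series(gamma, index=model.xnames, name="coef")
        self.bse = pd.Series(bse, index=model.xnames, name="se")
        self.cov_re = pd.DataFrame(G, index=ZNAMES, columns=ZNAMES)
        self.resid_struct = resid
        self.scale = resid.sigma2
        self.rho = resid.rho
        self.llf_reml = llf
        self.converged = converged
        self.n_iter = n_iter

    @property
    def params(self) -> pd.Series:
        return self.fe_params

    @property
    def random_effects_cov(self) -> RandomEffectsCov:
        return RandomEffectsCov.from_matrix(self.cov_re.to_numpy())

    def summary(self) -> str:
        lines = [
            "Two-level linear mixed model (REML)",
            f"Residual structure: {self.resid_struct.kind.upper()}"
            + (f"  rho = {self.rho:.4f}" if self.resid_struct.kind == "ar1" else ""),
            f"Subjects: {self.model.n_subjects}   Observations: {self.model.n_obs}",
            f"REML log-likelihood: {self.llf_reml:.4f}"
            f"   converged: {self.converged}  (iterations: {self.n_iter})",
            "",
            "Fixed effects:",
            f"{'':12s}{'coef':>10s}{'se':>10s}",
        ]
        for name in self.model.xnames:
            lines.append(
                f"{name:12s}{self.fe_params[name]:10.4f}{self.bse[name]:10.4f}"
            )
        lines += [
            "",
            "Random effects covariance (G):",
            f"  var(u0)     = {self.cov_re.iloc[0, 0]:.4f}",
            f"  var(u1)     = {self.cov_re.iloc[1, 1]:.4f}",
            f"  cov(u0, u1) = {self.cov_re.iloc[0, 1]:.4f}",
            f"Residual variance sigma^2 = {self.scale:.4f}",
        ]
        return "\n".join(lines)


class MultilevelModel:
    """Two-level mixed model with random intercept and slope.

    Construct from a long DataFrame (``from_dataframe``), from stacked
    balanced arrays (``from_arrays``), or from explicit per-subject blocks
    (``from_blocks``; used for whitened data, where design columns are
    consumed verbatim).  ``fit`` maximizes the REML criterion and returns an
    :class:`MLMResults`.
    """

    def __init__(self, y_blocks, X_blocks, Z_blocks, residual="id",
                 subject_ids=None, xnames=None):
        if residual not in ("id", "ar1"):
            raise ValueError("residual must be 'id' or 'ar1'")
        self.residual = residual
        self.xnames = list(xnames) if xnames is not None else list(XNAMES)
        self.subject_ids = subject_ids
        self.n_subjects = len(y_blocks)
        self.k = np.asarray(X_blocks[0]).shape[1]
        self.q = np.asarray(Z_blocks[0]).shape[1]
        self._y_blocks = [np.asarray(y, float) for y in y_blocks]
        self._X_blocks = [np.asarray(X, float) for X in X_blocks]
        self._Z_blocks = [np.asarray(Z, float) for Z in Z_blocks]
        self.n_obs = int(sum(y.shape[0] for y in self._y_blocks))
        if self.n_obs <= self.k:
            raise ValueError("need more observations than fixed effects")
        # group subjects by common series length so evaluations are batched
        by_len: dict[int, list[int]] = {}
        for i, y in enumerate(self._y_blocks):
            by_len.setdefault(y.shape[0], []).append(i)
        self._groups = []
        for L, idx in sorted(by_len.items()):
            y = np.stack([self._y_blocks[i] for i in idx])
            X = np.stack([self._X_blocks[i] for i in idx])
            Z = np.stack([self._Z_blocks[i] for i in idx])
            self._groups.append(_Group(y, X, Z))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, residual: str = "id", **cols):
        ids, ys, Xs, Zs = assemble_design(panel, **cols)
        return cls(ys, Xs, Zs, residual=residual, subject_ids=ids)

    @classmethod
    def from_arrays(cls, y: np.ndarray, z: np.ndarray, c: np.ndarray,
                    residual: str = "id"):
        """Balanced fast path: y, z of shape (N, L); c of shape (N,)."""
        y = np.asarray(y, float)
        z = np.asarray(z, float)
        c = np.asarray(c, float)
        N, L = y.shape
        ones = np.ones((N, L))
        X = np.stack([ones, z, c[:, None] * ones, c[:, None] * z], axis=2)
        Z = X[:, :, :2]
        m = cls.__new__(cls)
        m.residual = residual
        if residual not in ("id", "ar1"):
            raise ValueError("residual must be 'id' or 'ar1'")
        m.xnames = list(XNAMES)
        m.subject_ids = list(range(N))
        m.n_subjects = N
        m.k, m.q = 4, 2
        m._y_blocks = list(y)
        m._X_blocks = list(X)
        m._Z_blocks = list(Z)
        m.n_obs = N * L
        m._groups = [_Group(y, X, Z)]
        return m

    @classmethod
    def from_stacked(cls, y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                     residual: str = "id", xnames=None):
        """Balanced fast path with explicit stacked designs (N, L, k)."""
        m = cls.__new__(cls)
        if residual not in ("id", "ar1"):
            raise ValueError("residual must be 'id' or 'ar1'")
        m.residual = residual
        m.xnames = list(xnames) if xnames is not None else list(XNAMES)
        N = y.shape[0]
        m.subject_ids = list(range(N))
        m.n_subjects = N
        m.k, m.q = X.shape[2], Z.shape[2]
        m._y_blocks = list(y)
        m._X_blocks = list(X)
        m._Z_blocks = list(Z)
        m.n_obs = int(y.shape[0] * y.shape[1])
        m._groups = [_Group(np.asarray(y, float), np.asarray(X, float),
                            np.asarray(Z, float))]
        return m

    @classmethod
    def from_blocks(cls, y_blocks, X_blocks, Z_blocks, residual="id",
                    subject_ids=None, xnames=None):
        return cls(y_blocks, X_blocks, Z_blocks, residual=residual,
                   subject_ids=subject_ids, xnames=xnames)

    # -- criterion ---------------------------------------------------------

    def _profiled_neg2(self, Lam: np.ndarray, rho: float):
        """-2 REML log-likelihood with sigma^2 profiled out.

        Lam is the Cholesky-like factor of G / sigma^2.  Returns the
        criterion plus the pieces needed to reconstruct estimates.
        """
        m = 1 + self.k
        Acc = np.zeros((m + self.q, m + self.q))
        logdet = 0.0
        for g in self._groups:
            A_g, ldK = g.crossprods(Lam, rho)
            Acc += A_g
            logdet += g.N * g.logdet_P(rho) + ldK
        Bxx = Acc[1:m, 1:m]
        Bxy = Acc[1:m, 0]
        Byy = Acc[0, 0]
        sign, ld_Bxx = np.linalg.slogdet(Bxx)
        if sign <= 0:
            return np.inf, None
        gamma = np.linalg.solve(Bxx, Bxy)
        qf = Byy - Bxy @ gamma
        dof = self.n_obs - self.k
        if qf <= 0:
            return np.inf, None
        sigma2 = qf / dof
        neg2 = (
            dof * np.log(sigma2)
            + logdet
            + ld_Bxx
            + dof * (1.0 + np.log(2 * np.pi))
        )
        return neg2, (gamma, sigma2, Bxx)

    def loglike_reml(self, G, sigma2: float, rho: float = 0.0) -> float:
        """REML log-likelihood at an arbitrary parameter point.

        ``G`` may be a 2x2 array or a :class:`RandomEffectsCov`.  For the
        'id' structure ``rho`` must be 0.
        """
        Gm = G.matrix() if isinstance(G, RandomEffectsCov) else np.asarray(G, float)
        if self.residual == "id" and rho != 0.0:
            raise ValueError("rho must be 0 under the 'id' structure")
        w, V = np.linalg.eigh(Gm)
        if np.any(w < -1e-10):
            raise ValueError("G must be positive semidefinite")
        Lam = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        m = 1 + self.k
        Acc = np.zeros((m + self.q, m + self.q))
        logdet = 0.0
        for g in self._groups:
            W = _combine_xprods(g.C0, g.B, g.C1s, rho)
            Wz = W[:, :, g.zidx]
            U = Wz @ Lam
            S = np.swapaxes(U[:, g.zidx, :], 1, 2) @ Lam
            K = S + sigma2 * np.eye(self.q)
            Kinv = np.linalg.inv(K)
            corr = np.einsum("nij,njk,nlk->nil", U, Kinv, U)
            Acc += (W - corr).sum(axis=0)
            logdetK = np.linalg.slogdet(K)[1].sum()
            logdet += g.N * (
                g.L * np.log(sigma2) + g.logdet_P(rho) - self.q * np.log(sigma2)
            ) + logdetK
        Bxx = Acc[1:m, 1:m]
        Bxy = Acc[1:m, 0]
        Byy = Acc[0, 0]
        gamma = np.linalg.solve(Bxx, Bxy)
        qf = (Byy - Bxy @ gamma) / sigma2
        ld_XSiX = np.linalg.slogdet(Bxx)[1] - self.k * np.log(sigma2)
        dof = self.n_obs - self.k
        neg2 = logdet + ld_XSiX + qf + dof * np.log(2 * np.pi)
        return -0.5 * neg2

    # -- fitting -----------------------------------------------------------

    def _start_theta(self):
        """Method-of-moments starts: pooled OLS residual variance split
        between the random intercept and the residual; rho from the pooled
        lag-1 residual autocorrelation."""
        Xall = np.vstack(self._X_blocks)
        yall = np.concatenate(self._y_blocks)
        beta, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
        num = 0.0
        den = 0.0
        for y, X in zip(self._y_blocks, self._X_blocks):
            e = y - X @ beta
            num += e[1:] @ e[:-1]
            den += e @ e
        r1 = num / den if den > 0 else 0.0
        theta = np.array([0.0, 0.5 * np.log(0.5), 0.0])  # Gtilde = diag(1, 0.5)
        if self.residual == "ar1":
            r1 = float(np.clip(r1, -0.9, 0.9))
            theta = np.r_[theta, np.arctanh(r1 / RHO_CAP)]
        return theta

    def _unpack(self, theta, fix_rho=None):
        Lam = np.array([[np.exp(theta[0]), 0.0], [theta[2], np.exp(theta[1])]])
        if self.residual == "ar1":
            rho = fix_rho if fix_rho is not None else RHO_CAP * np.tanh(theta[3])
        else:
            rho = 0.0
        return Lam, rho

    def fit(self, start=None, maxiter=200, fix_rho=None) -> MLMResults:
        """Maximize the REML criterion; returns an :class:`MLMResults`.

        ``fix_rho`` holds the AR(1) parameter at a known value (the random
        components are still estimated).  Up to three jittered restarts are
        attempted if the quasi-Newton search fails.
        """
        n_free = 3 + (1 if self.residual == "ar1" and fix_rho is None else 0)
        theta0 = np.asarray(start, float) if start is not None else self._start_theta()
        if self.residual == "ar1" and fix_rho is not None:
            theta0 = theta0[:3]

        # The criterion is scaled per observation so that the quasi-Newton
        # line search sees O(1) values and gradients regardless of N*L, and
        # non-finite evaluations (extreme G, catastrophic cancellation) are
        # replaced by a smooth penalty above a reference value rather than a
        # flat plateau, which would break step-length interpolation.
        ref = {"val": None}

        def objective(theta):
            th = theta if fix_rho is None else np.r_[theta, 0.0]
            Lam, rho = self._unpack(
                th if self.residual == "ar1" else np.r_[theta[:3], 0.0],
                fix_rho=fix_rho,
            )
            val, _ = self._profiled_neg2(Lam, rho)
            val = val / self.n_obs
            if np.isfinite(val):
                if ref["val"] is None:
                    ref["val"] = val
                return val
            base = ref["val"] if ref["val"] is not None else 0.0
            return base + 100.0 + float(theta @ theta)

        bounds = [(-10.0, 10.0)] * 3 + [(-6.0, 6.0)] * (n_free - 3)
        rng = np.random.default_rng(12345)
        best = None
        n_iter = 0
        converged = False
        theta_try = theta0[:n_free].copy()
        for attempt in range(4):
            res = optimize.minimize(
                objective, theta_try, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success and np.isfinite(res.fun):
                converged = True
                best = res if res.fun <= best.fun + 1e-9 else best
                break
            theta_try = theta0[:n_free] + rng.normal(scale=0.3, size=n_free)
        theta = best.x
        th_full = theta if fix_rho is None else np.r_[theta, 0.0]
        Lam, rho = self._unpack(
            th_full if self.residual == "ar1" else np.r_[theta[:3], 0.0],
            fix_rho=fix_rho,
        )
        neg2, parts = self._profiled_neg2(Lam, rho)
        if parts is None:
            raise RuntimeError("REML criterion not finite at the optimum")
        gamma, sigma2, Bxx = parts
        G = sigma2 * (Lam @ Lam.T)
        se = np.sqrt(np.diag(np.linalg.inv(Bxx)) * sigma2)
        resid = ResidualStructure(self.residual, sigma2, rho)
        return MLMResults(self, gamma, se, G, resid, -0.5 * neg2, converged, n_iter)


def reml_fit(panel: pd.DataFrame, residual_kind: str = "id", **cols) -> MLMResults:
    """Assemble designs from a long panel and fit the MLM by REML."""
    return MultilevelModel.from_dataframe(panel, residual=residual_kind, **cols).fit()
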