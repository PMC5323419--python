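"""Per-subject regression with autoregressive errors.

This module handles step 1 of the two-step whitening estimator: for each
individual's equally spaced series, fit a regression whose errors follow a
stationary AR(p) process by exact Gaussian maximum likelihood, and build the
lower-triangular whitening operator ``A = L^{-1}`` (the inverse Cholesky
factor of the scaled residual covariance) that maps the correlated errors to
white noise with the innovation variance, ``A Sigma A' = sigma_w^2 I``.

For AR(1) the relevant objects have closed forms: the autocovariance
``gamma(h) = sigma_w^2 rho^h / (1 - rho^2)``, a tridiagonal inverse
covariance, and a two-band whitening operator whose first row is
``sqrt(1 - rho^2) e_1`` and whose later rows are ``[-rho, 1]``.  General
AR(p) is supported through the Yule-Walker autocovariances and a banded
operator with a dense p x p head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cholesky, solve_triangular, toeplitz

__all__ = [
    "RHO_CAP",
    "StationarityError",
    "CollinearityError",
    "IndividualSeries",
    "ARFit",
    "WhiteningOperator",
    "fit_ols_individual",
    "select_ar_order",
    "fit_regression_with_ar_errors",
    "ar1_autocovariance",
    "build_ar1_sigma",
    "build_ar1_sigma_inv",
    "build_whitening_ar1",
    "build_whitening_arp",
    "arp_autocovariances",
]

#: Stationarity bound for the optimized lag-1 autocorrelation.  The whitening
#: operator is undefined at |rho| = 1, so the ML search is confined to
#: [-RHO_CAP, RHO_CAP] and estimates landing on the bound are flagged.
RHO_CAP = 0.98


class StationarityError(ValueError):
    """AR parameters do not define a stationary process."""


class CollinearityError(ValueError):
    """A subject-level design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class IndividualSeries:
    """One subject's equally spaced outcome/covariate series."""

    subject_id: object
    occasions: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.occasions = np.asarray(self.occasions)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.y.shape[0]
        if self.occasions.shape[0] != n or self.z.shape[0] != n:
            raise ValueError(
                f"subject {self.subject_id!r}: occasions, y, z must have equal length"
            )
        if n < 3:
            raise ValueError(f"subject {self.subject_id!r}: need at least 3 occasions")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.z))):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values")
        d = np.diff(self.occasions.astype(float))
        if np.any(d <= 0):
            raise ValueError(
                f"subject {self.subject_id!r}: occasions must be strictly increasing"
            )
        if not np.allclose(d, d[0]):
            raise ValueError(
                f"subject {self.subject_id!r}: occasions must be equally spaced"
            )

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def design(self) -> np.ndarray:
        """Subject-level design [1, z]."""
        return np.column_stack([np.ones(self.n), self.z])


@dataclass
class ARFit:
    """ML estimates of a regression with stationary AR(p) errors."""

    order: int
    phi: np.ndarray
    sigma_w2: float
    rho: float
    beta: np.ndarray
    loglik: float
    converged: bool
    cap_hit: bool = False

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.order > 0:
            _check_stationary(self.phi)
        if not self.sigma_w2 > 0:
            raise ValueError("sigma_w2 must be positive")


@dataclass
class WhiteningOperator:
    """Lower-triangular operator A = L^{-1} with A Sigma A' = sigma_w^2 I.

    ``A`` is banded: a dense p x p head (inverse Cholesky factor of the
    leading stationary covariance scaled to unit innovation variance)
    followed by rows implementing w_t = e_t - sum_j phi_j e_{t-j}.
    ``apply`` uses the band structure, costing O(n * p) per column.
    """

    subject_id: object
    n: int
    A: np.ndarray
    sigma_w2: float
    phi: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.n, self.n):
            raise ValueError("A must be n x n")

    @property
    def order(self) -> int:
        return self.phi.shape[0]

    @property
    def rho(self) -> float:
        return float(self.phi[0]) if self.order >= 1 else 0.0

    def apply(self, M: np.ndarray) -> np.ndarray:
        """Compute A @ M via the band structure (O(n p) per column)."""
        M = np.asarray(M, dtype=float)
        if M.shape[0] != self.n:
            raise ValueError(
                f"operator for n={self.n} applied to array with {M.shape[0]} rows"
            )
        p = self.order
        if p == 0:
            return M.copy()
        out = M.copy()
        for j in range(p):
            out[p:] -= self.phi[j] * M[p - 1 - j : self.n - 1 - j]
        out[:p] = self.A[:p, :p] @ M[:p]
        return out


# ---------------------------------------------------------------------------
# AR(1) closed forms
# ---------------------------------------------------------------------------


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if abs(rho) >= 1.0:
        raise StationarityError(f"|rho| must be < 1, got {rho}")
    return rho


def _check_stationary(phi: np.ndarray) -> np.ndarray:
    """Raise unless all roots of 1 - phi_1 x - ... - phi_p x^p lie outside
    the unit circle."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.size == 0:
        return phi
    roots = np.polynomial.polynomial.polyroots(np.r_[1.0, -phi])
    if np.any(np.abs(roots) <= 1.0 + 1e-12):
        raise StationarityError(f"AR coefficients {phi} are not stationary")
    return phi


def ar1_autocovariance(rho: float, sigma_w2: float, h: int) -> float:
    """Stationary AR(1) autocovariance gamma(h) = sigma_w^2 rho^h / (1-rho^2)."""
    rho = _check_rho(rho)
    if not sigma_w2 > 0:
        raise ValueError("sigma_w2 must be positive")
    if h < 0:
        raise ValueError("lag h must be >= 0")
    return sigma_w2 * rho**h / (1.0 - rho**2)


def build_ar1_sigma(rho: float, sigma_w2: float, n: int) -> np.ndarray:
    """Dense stationary AR(1) covariance, Sigma[t, s] = gamma(|t - s|)."""
    rho = _check_rho(rho)
    if n < 1:
        raise ValueError("n must be >= 1")
    col = sigma_w2 * rho ** np.arange(n) / (1.0 - rho**2)
    return toeplitz(col)


def build_ar1_sigma_inv(rho: float, sigma_w2: float, n: int) -> np.ndarray:
    """Tridiagonal inverse of the stationary AR(1) covariance."""
    rho = _check_rho(rho)
    if n < 2:
        raise ValueError("n must be >= 2")
    S = np.zeros((n, n))
    idx = np.arange(n)
    S[idx, idx] = 1.0 + rho**2
    S[0, 0] = S[-1, -1] = 1.0
    S[idx[:-1], idx[1:]] = -rho
    S[idx[1:], idx[:-1]] = -rho
    return S / sigma_w2


def build_whitening_ar1(
    rho: float, n: int, sigma_w2: float = 1.0, subject_id: object = None
) -> WhiteningOperator:
    """AR(1) whitening operator: first row sqrt(1-rho^2) e_1, then [-rho, 1]."""
    rho = _check_rho(rho)
    if n < 1:
        raise ValueError("n must be >= 1")
    A = np.eye(n)
    A[0, 0] = np.sqrt(1.0 - rho**2)
    idx = np.arange(1, n)
    A[idx, idx - 1] = -rho
    return WhiteningOperator(subject_id, n, A, sigma_w2, phi=np.array([rho]))


# ---------------------------------------------------------------------------
# general AR(p)
# ---------------------------------------------------------------------------


def arp_autocovariances(phi: np.ndarray, nlags: int, sigma_w2: float = 1.0) -> np.ndarray:
    """Autocovariances gamma(0..nlags) of a stationary AR(p) process.

    Solves the Yule-Walker system for gamma(0..p), then extends by the
    recursion gamma(k) = sum_j phi_j gamma(k - j).
    """
    phi = _check_stationary(phi)
    p = phi.shape[0]
    if p == 0:
        g = np.zeros(nlags + 1)
        g[0] = sigma_w2
        return g
    # equations k = 0..p:  gamma(k) - sum_j phi_j gamma(|k-j|) = sigma_w2 * 1{k=0}
    A = np.eye(p + 1)
    for k in range(p + 1):
        for j in range(1, p + 1):
            A[k, abs(k - j)] -= phi[j - 1]
    b = np.zeros(p + 1)
    b[0] = sigma_w2
    g = np.linalg.solve(A, b)
    if nlags <= p:
        return g[: nlags + 1]
    out = np.empty(nlags + 1)
    out[: p + 1] = g
    for k in range(p + 1, nlags + 1):
        out[k] = phi @ out[k - p : k][::-1]
    return out


def build_whitening_arp(
    phi: np.ndarray, n: int, sigma_w2: float = 1.0, subject_id: object = None
) -> WhiteningOperator:
    """Whitening operator for stationary AR(p) errors.

    Rows t > p implement w_t = e_t - sum_j phi_j e_{t-j}; the first p rows are
    the inverse Cholesky factor of the leading p x p block of the stationary
    covariance scaled to unit innovation variance.
    """
    phi = _check_stationary(np.atleast_1d(phi))
    p = phi.shape[0]
    if p == 0:
        return WhiteningOperator(subject_id, n, np.eye(n), sigma_w2, phi=phi)
    if p == 1:
        return build_whitening_ar1(phi[0], n, sigma_w2, subject_id)
    if n <= p:
        raise ValueError("n must exceed the AR order")
    g = arp_autocovariances(phi, p - 1, sigma_w2=1.0)
    Vw_head = toeplitz(g)
    L_head = cholesky(Vw_head, lower=True)
    head = solve_triangular(L_head, np.eye(p), lower=True)
    A = np.eye(n)
    A[:p, :p] = head
    for j in range(1, p + 1):
        idx = np.arange(p, n)
        A[idx, idx - j] = -phi[j - 1]
    return WhiteningOperator(subject_id, n, A, sigma_w2, phi=phi)


def _whiten_with_phi(phi: np.ndarray, head: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Banded application of the AR(p) whitening operator to columns of M."""
    p = phi.shape[0]
    if p == 0:
        return M
    out = M.copy()
    for j in range(p):
        out[p:] -= phi[j] * M[p - 1 - j : M.shape[0] - 1 - j]
    out[:p] = head @ M[:p]
    return out


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def fit_ols_individual(series: IndividualSeries, design: np.ndarray | None = None):
    """OLS fit of one subject's series on its design; returns (beta, residuals)."""
    X = series.design() if design is None else np.asarray(design, dtype=float)
    y = series.y
    if X.shape[0] != series.n:
        raise ValueError("design row count does not match series length")
    if series.n <= X.shape[1]:
        raise ValueError(
            f"subject {series.subject_id!r}: series too short for design"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"subject {series.subject_id!r}: design matrix is rank deficient"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def _exact_arp_profile(y: np.ndarray, X: np.ndarray | None, phi: np.ndarray):
    """Exact Gaussian log-likelihood of a regression with AR(p) errors,
    profiled over (beta, sigma_w2) at fixed phi.

    Returns (loglik, beta, sigma_w2).  The first p observations contribute
    through the stationary distribution (the dense head of the operator).
    """
    n = y.shape[0]
    p = phi.shape[0]
    if p == 0:
        head = np.eye(0)
        logdet_head = 0.0
    elif p == 1:
        head = np.array([[np.sqrt(1.0 - phi[0] ** 2)]])
        logdet_head = 0.5 * np.log1p(-phi[0] ** 2)
    else:
        g = arp_autocovariances(phi, p - 1, sigma_w2=1.0)
        L_head = cholesky(toeplitz(g), lower=True)
        head = solve_triangular(L_head, np.eye(p), lower=True)
        logdet_head = -np.sum(np.log(np.diag(L_head)))
    ys = _whiten_with_phi(phi, head, y[:, None])[:, 0]
    if X is None:
        beta = np.zeros(0)
        resid = ys
    else:
        Xs = _whiten_with_phi(phi, head, X)
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
    ss = float(resid @ resid)
    sigma_w2 = ss / n
    if sigma_w2 <= 0:
        return -np.inf, beta, max(sigma_w2, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(sigma_w2)) + logdet_head
    return loglik, beta, sigma_w2


def _pacf_to_phi(r: np.ndarray) -> np.ndarray:
    """Map partial autocorrelations in (-1, 1) to stationary AR coefficients
    (Levinson-Durbin recursion)."""
    phi = np.zeros(0)
    for rk in r:
        phi = np.r_[phi - rk * phi[::-1], rk]
    return phi


def fit_regression_with_ar_errors(
    series: IndividualSeries,
    design: np.ndarray | None = None,
    p: int = 1,
) -> ARFit:
    """Joint exact ML of (beta, phi, sigma_w2) for one subject's regression
    with stationary AR(p) errors.

    The likelihood is the exact Gaussian one (stationary distribution for the
    first p observations); beta and sigma_w2 are profiled analytically, so the
    numerical search runs over phi only, constrained to the stationary region.
    """
    X = series.design() if design is None else np.asarray(design, dtype=float)
    y = series.y
    k = X.shape[1]
    if series.n < p + k + 2:
        raise ValueError(
            f"subject {series.subject_id!r}: series too short for AR({p}) fit"
        )
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError(
            f"subject {series.subject_id!r}: design matrix is rank deficient"
        )

    if p == 0:
        ll, beta, s2 = _exact_arp_profile(y, X, np.zeros(0))
        return ARFit(0, np.zeros(0), s2, 0.0, beta, ll, True)

    if p == 1:
        res = optimize.minimize_scalar(
            lambda r: -_exact_arp_profile(y, X, np.array([r]))[0],
            bounds=(-RHO_CAP, RHO_CAP),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho = float(res.x)
        ll, beta, s2 = _exact_arp_profile(y, X, np.array([rho]))
        cap = abs(rho) >= RHO_CAP - 1e-4
        return ARFit(1, np.array([rho]), s2, rho, beta, ll, bool(res.success), cap)

    # p >= 2: unconstrained search over tanh-mapped partial autocorrelations
    def negll(theta):
        r = RHO_CAP * np.tanh(theta)
        val = _exact_arp_profile(y, X, _pacf_to_phi(r))[0]
        return -val if np.isfinite(val) else 1e12

    # start from Yule-Walker partial autocorrelations of the OLS residuals
    _, e = fit_ols_individual(series, X)
    r0 = np.zeros(p)
    acf = np.array(
        [1.0] + [np.dot(e[h:], e[:-h]) / np.dot(e, e) for h in range(1, p + 1)]
    )
    for j in range(1, p + 1):
        phi_j = np.linalg.solve(toeplitz(acf[:j]), acf[1 : j + 1])
        r0[j - 1] = np.clip(phi_j[-1], -0.9, 0.9)
    res = optimize.minimize(negll, np.arctanh(r0 / RHO_CAP), method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    r = RHO_CAP * np.tanh(res.x)
    phi = _pacf_to_phi(r)
    ll, beta, s2 = _exact_arp_profile(y, X, phi)
    cap = bool(np.any(np.abs(r) >= RHO_CAP - 1e-4))
    rho = float(acf_lag1_from_phi(phi))
    return ARFit(p, phi, s2, rho, beta, ll, bool(res.success), cap)


def acf_lag1_from_phi(phi: np.ndarray) -> float:
    """Lag-1 autocorrelation implied by stationary AR coefficients."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.size == 0:
        return 0.0
    g = arp_autocovariances(phi, 1)
    return float(g[1] / g[0])


def select_ar_order(
    residuals: np.ndarray, p_max: int, criterion: str = "bic"
) -> int:
    """Choose the AR order for a residual series.

    ``fixed`` returns p_max unchanged; ``aic``/``bic`` minimize the
    information criterion of exact zero-mean AR(p) ML fits for p = 0..p_max.
    """
    e = np.asarray(residuals, dtype=float)
    if p_max < 0:
        raise ValueError("p_max must be >= 0")
    if e.shape[0] < p_max + 3:
        raise ValueError("residual series too short for requested p_max")
    if criterion == "fixed":
        return p_max
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    n = e.shape[0]
    penalty = np.log(n) if criterion == "bic" else 2.0
    best_p, best_ic = 0, np.inf
    for p in range(p_max + 1):
        if p == 0:
            ll = _exact_arp_profile(e, None, np.zeros(0))[0]
        elif p == 1:
            res = optimize.minimize_scalar(
                lambda r: -_exact_arp_profile(e, None, np.array([r]))[0],
                bounds=(-RHO_CAP, RHO_CAP), method="bounded",
            )
            ll = -res.fun
        else:
            def negll(theta, _p=p):
                v = _exact_arp_profile(e, None, _pacf_to_phi(RHO_CAP * np.tanh(theta)))[0]
                return -v if np.isfinite(v) else 1e12
            res = optimize.minimize(negll, np.zeros(p), method="Nelder-Mead")
            ll = -res.fun
        ic = -2.0 * ll + penalty * (p + 1)
        if ic < best_ic - 1e-12:
            best_p, best_ic = p, ic
    return best_p


# ---------------------------------------------------------------------------
# vectorized AR(1) ML across subjects (cross-product form)
# ---------------------------------------------------------------------------
#
# For the AR(1) whitening operator A, A'A equals the tridiagonal matrix
# T(rho) with unit corners, 1 + rho^2 on the interior diagonal and -rho off
# the diagonal.  Hence for M = [y | X] the whitened cross-product is
#   M*'M* = (1 + rho^2) C0 - rho^2 B - rho C1s,
# with C0 = M'M, B = m_1 m_1' + m_n m_n', C1s the symmetrized lag-1
# cross-product.  The profiled likelihood is then O(1) in the series length,
# which lets the per-subject ML be run on thousands of subjects cheaply.


def _ar1_xprods(M: np.ndarray):
    """Per-subject cross-products for stacked series M of shape (N, L, m)."""
    C0 = np.einsum("nlj,nlk->njk", M, M)
    ends = np.einsum("nj,nk->njk", M[:, 0], M[:, 0]) + np.einsum(
        "nj,nk->njk", M[:, -1], M[:, -1]
    )
    C1 = np.einsum("nlj,nlk->njk", M[:, :-1], M[:, 1:])
    return C0, ends, C1 + np.swapaxes(C1, 1, 2)


def _ar1_profile_negll_vec(rho: np.ndarray, C0, B, C1s, L: int):
    """Vectorized negative profiled log-likelihood, one value per subject.

    Column 0 of the cross-products is the outcome; the rest are regressors.
    """
    r = rho[:, None, None]
    W = (1.0 + r**2) * C0 - r**2 * B - rho[:, None, None] * C1s
    yy = W[:, 0, 0]
    b = W[:, 1:, 0]
    G = W[:, 1:, 1:]
    k = G.shape[1]
    if k == 2:
        det = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0]
        beta0 = (G[:, 1, 1] * b[:, 0] - G[:, 0, 1] * b[:, 1]) / det
        beta1 = (-G[:, 1, 0] * b[:, 0] + G[:, 0, 0] * b[:, 1]) / det
        ss = yy - b[:, 0] * beta0 - b[:, 1] * beta1
    else:
        beta = np.linalg.solve(G, b[:, :, None])[:, :, 0]
        ss = yy - np.einsum("nj,nj->n", b, beta)
    ss = np.maximum(ss, 1e-300)
    s2 = ss / L
    return 0.5 * L * (np.log(2 * np.pi) + 1.0 + np.log(s2)) - 0.5 * np.log1p(-rho**2)


def fit_ar1_ml_stacked(y: np.ndarray, x: np.ndarray):
    """Exact-ML AR(1) regression fits for N stacked subjects at once.

    ``y`` and ``x`` have shape (N, L); the regression design is [1, x] per
    subject.  Returns (rho, sigma_w2, beta (N, 2), loglik, cap_hit) arrays.
    The search combines a coarse grid with vectorized golden-section
    refinement, both on the O(1) cross-product form of the profiled
    likelihood.
    """
    N, L = y.shape
    M = np.concatenate(
        [y[:, :, None], np.ones((N, L, 1)), x[:, :, None]], axis=2
    )
    C0, B, C1s = _ar1_xprods(M)

    grid = RHO_CAP * np.linspace(-1.0, 1.0, 99)
    vals = np.stack([_ar1_profile_negll_vec(np.full(N, g), C0, B, C1s, L) for g in grid])
    best = np.argmin(vals, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b_ = lo.copy(), hi.copy()
    c = b_ - invphi * (b_ - a)
    d = a + invphi * (b_ - a)
    fc = _ar1_profile_negll_vec(c, C0, B, C1s, L)
    fd = _ar1_profile_negll_vec(d, C0, B, C1s, L)
    for _ in range(60):
        take_c = fc < fd
        b_ = np.where(take_c, d, b_)
        a = np.where(take_c, a, c)
        c_new = b_ - invphi * (b_ - a)
        d_new = a + invphi * (b_ - a)
        c, d = c_new, d_new
        fc = _ar1_profile_negll_vec(c, C0, B, C1s, L)
        fd = _ar1_profile_negll_vec(d, C0, B, C1s, L)
    rho = 0.5 * (a + b_)

    # recover beta, sigma_w2, loglik at the optimum
    r = rho[:, None, None]
    W = (1.0 + r**2) * C0 - r**2 * B - rho[:, None, None] * C1s
    G = W[:, 1:, 1:]
    bvec = W[:, 1:, 0]
    beta = np.linalg.solve(G, bvec[:, :, None])[:, :, 0]
    ss = np.maximum(W[:, 0, 0] - np.einsum("nj,nj->n", bvec, beta), 1e-300)
    sigma_w2 = ss / L
    loglik = (
        -0.5 * L * (np.log(2 * np.pi) + 1.0 + np.log(sigma_w2))
        + 0.5 * np.log1p(-rho**2)
    )
    cap = np.abs(rho) >= RHO_CAP - 1e-4
    return rho, sigma_w2, beta, loglik, cap
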