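"""Monte Carlo study of misspecified residual covariance in two-level models.

Panels are generated from

    y_ti = g00 + g10 z_ti + g01 c_i + g11 c_i z_ti + u0_i + u1_i z_ti + e_ti,

with z_ti, c_i iid standard normal, (u0, u1) bivariate normal with
G = [[0.5, 0.15], [0.15, 0.5]] (defaults), and subject-specific AR(1) errors
e_ti = rho_i e_(t-1)i + w_ti, w ~ N(0, 1), rho_i ~ U(rho_bar - 0.3,
rho_bar + 0.3), the first error drawn from the stationary distribution.
Every fixed effect defaults to 1.

Each generated panel is analyzed by up to three estimators — the REML model
with independent homogeneous residuals (ID), with a shared AR(1) residual
(AR1), and the two-step whitening estimator (CT: per-subject AR(1) exact ML,
whitening, then the ID model on the transformed data) — and relative biases
of parameter estimates and of the model-based standard errors are tabulated
per condition.

The default condition grid is N, L in {20, 50, 100, 200} x {20, 50, 100,
200}, rho_bar in {0.0, 0.3, 0.6}, 500 replications: 48 conditions, 24,000
datasets, 72,000 fits.  Everything is a pure function of the base seed: the
replicate-level RNG is seeded from (base_seed, N, L, rho_bar, replicate) so
any single replicate can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MultilevelModel
from .transform import transform_stacked

__all__ = [
    "TrueParameters",
    "SimulationCondition",
    "BiasReport",
    "METHODS",
    "PARAM_NAMES",
    "generate_dataset",
    "run_condition",
    "run_grid",
    "relative_bias",
    "se_relative_bias",
    "se_relative_bias_empirical",
    "true_fixed_effect_ses",
    "default_grid",
    "planned_counts",
]

METHODS = ("ID", "AR1", "CT")
PARAM_NAMES = ["gamma00", "gamma10", "gamma01", "gamma11",
               "var_u0", "var_u1", "cov_u0u1"]
SE_NAMES = ["se_gamma00", "se_gamma10", "se_gamma01", "se_gamma11"]


@dataclass
class TrueParameters:
    """Generating parameters of the two-level model."""

    gamma: np.ndarray = field(default_factory=lambda: np.ones(4))
    var_u0: float = 0.5
    var_u1: float = 0.5
    cov_u0u1: float = 0.15
    sigma_w2: float = 1.0
    rho_halfwidth: float = 0.3

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.cov_u0u1**2 > self.var_u0 * self.var_u1:
            raise ValueError("G must be positive semidefinite")

    @property
    def G(self) -> np.ndarray:
        return np.array([[self.var_u0, self.cov_u0u1],
                         [self.cov_u0u1, self.var_u1]])

    def value_of(self, param: str) -> float:
        vals = dict(
            gamma00=self.gamma[0], gamma10=self.gamma[1],
            gamma01=self.gamma[2], gamma11=self.gamma[3],
            var_u0=self.var_u0, var_u1=self.var_u1, cov_u0u1=self.cov_u0u1,
        )
        return float(vals[param])


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation grid."""

    N: int
    L: int
    rho_bar: float
    reps: int = 500
    base_seed: int = 0


def _replicate_rng(condition: SimulationCondition, replicate: int) -> np.random.Generator:
    rho_code = int(round(condition.rho_bar * 100)) + 1000
    ss = np.random.SeedSequence(
        (int(condition.base_seed), condition.N, condition.L, rho_code, replicate)
    )
    return np.random.default_rng(ss)


def _generate_arrays(condition: SimulationCondition, truth: TrueParameters,
                     replicate: int):
    """Draw one balanced panel; returns (y (N,L), z (N,L), c (N,), rho_i (N,))."""
    rng = _replicate_rng(condition, replicate)
    N, L = condition.N, condition.L
    z = rng.standard_normal((N, L))
    c = rng.standard_normal(N)
    u = rng.multivariate_normal(np.zeros(2), truth.G, size=N,
                                method="eigh")
    rho_i = rng.uniform(condition.rho_bar - truth.rho_halfwidth,
                        condition.rho_bar + truth.rho_halfwidth, size=N)
    w = rng.standard_normal((N, L)) * np.sqrt(truth.sigma_w2)
    e = np.empty((N, L))
    e[:, 0] = w[:, 0] / np.sqrt(1.0 - rho_i**2)
    for t in range(1, L):
        e[:, t] = rho_i * e[:, t - 1] + w[:, t]
    g = truth.gamma
    y = (
        g[0]
        + g[1] * z
        + g[2] * c[:, None]
        + g[3] * c[:, None] * z
        + u[:, [0]]
        + u[:, [1]] * z
        + e
    )
    return y, z, c, rho_i


def generate_dataset(condition: SimulationCondition, truth: TrueParameters,
                     replicate_index: int) -> pd.DataFrame:
    """One simulated panel as a long DataFrame (subject, occasion, y, z, c)."""
    y, z, c, _ = _generate_arrays(condition, truth, replicate_index)
    N, L = condition.N, condition.L
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(1, N + 1), L),
            "occasion": np.tile(np.arange(1, L + 1), N),
            "y": y.ravel(),
            "z": z.ravel(),
            "c": np.repeat(c, L),
        }
    )


def _fit_record(condition, replicate, method, y, z, c):
    """Fit one estimator on one panel; returns a flat result dict."""
    rec = {"replicate": replicate, "method": method}
    if method == "CT":
        y_star, X_star, Z_star, rho_hat, sw2, cap = transform_stacked(y, z, c)
        model = MultilevelModel.from_stacked(y_star, X_star, Z_star, residual="id")
        rec.update(
            rho_hat_mean=float(np.mean(rho_hat)),
            rho_hat_min=float(np.min(rho_hat)),
            rho_hat_max=float(np.max(rho_hat)),
            n_cap_hits=int(np.sum(cap)),
        )
    else:
        model = MultilevelModel.from_arrays(
            y, z, c, residual="id" if method == "ID" else "ar1"
        )
    res = model.fit()
    gam = res.fe_params.to_numpy()
    se = res.bse.to_numpy()
    G = res.cov_re.to_numpy()
    rec.update(
        converged=bool(res.converged),
        gamma00=gam[0], gamma10=gam[1], gamma01=gam[2], gamma11=gam[3],
        se_gamma00=se[0], se_gamma10=se[1], se_gamma01=se[2], se_gamma11=se[3],
        var_u0=G[0, 0], var_u1=G[1, 1], cov_u0u1=G[0, 1],
        sigma2=res.scale, rho=res.rho,
    )
    return rec


def run_condition(
    condition: SimulationCondition,
    methods=METHODS,
    truth: TrueParameters | None = None,
) -> pd.DataFrame:
    """Run all replicates of one condition; every requested method is fitted
    to the same generated dataset.  Returns the estimate table."""
    truth = truth or TrueParameters()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    records = []
    for r in range(condition.reps):
        y, z, c, rho_i = _generate_arrays(condition, truth, r)
        tse = true_fixed_effect_ses(z, c, rho_i, truth)
        for method in methods:
            rec = _fit_record(condition, r, method, y, z, c)
            rec.update(
                true_se_gamma00=tse[0], true_se_gamma10=tse[1],
                true_se_gamma01=tse[2], true_se_gamma11=tse[3],
            )
            records.append(rec)
    table = pd.DataFrame.from_records(records)
    table.insert(0, "N", condition.N)
    table.insert(1, "L", condition.L)
    table.insert(2, "rho_bar", condition.rho_bar)
    return table


def true_fixed_effect_ses(z: np.ndarray, c: np.ndarray, rho_i: np.ndarray,
                          truth: TrueParameters) -> np.ndarray:
    """True standard errors of the fixed effects for one generated design.

    These are the diagonal square roots of C = [sum_i X_i' Sigma_i^{-1}
    X_i]^{-1} evaluated at the generating parameters, with Sigma_i the true
    subject-specific covariance Z_i G Z_i' + R_i(rho_i).  They are the
    yardstick against which the fitted models' SEs are judged.
    """
    z = np.asarray(z, float)
    c = np.asarray(c, float)
    rho_i = np.asarray(rho_i, float)
    N, L = z.shape
    ones = np.ones((N, L))
    X = np.stack([ones, z, c[:, None] * ones, c[:, None] * z], axis=2)
    C0 = np.einsum("nlj,nlk->njk", X, X)
    B = np.einsum("nj,nk->njk", X[:, 0], X[:, 0]) + np.einsum(
        "nj,nk->njk", X[:, -1], X[:, -1]
    )
    C1 = np.einsum("nlj,nlk->njk", X[:, :-1], X[:, 1:])
    C1s = C1 + np.swapaxes(C1, 1, 2)
    # R_i^{-1} = T(rho_i) / sigma_w2 with T the tridiagonal AR(1) form, so
    # X' R^{-1} X is a closed-form combination of the cached cross-products
    r = rho_i[:, None, None]
    W = ((1.0 + r**2) * C0 - r**2 * B - r * C1s) / truth.sigma_w2
    Lam = np.linalg.cholesky(truth.G + 1e-14 * np.eye(2))
    U = W[:, :, :2] @ Lam                       # Z_i = X_i[:, :2]
    S = np.einsum("ij,njk,kl->nil", Lam.T, W[:, :2, :2], Lam)
    K = S + np.eye(2)
    det = K[:, 0, 0] * K[:, 1, 1] - K[:, 0, 1] * K[:, 1, 0]
    Kinv = np.empty_like(K)
    Kinv[:, 0, 0] = K[:, 1, 1]
    Kinv[:, 1, 1] = K[:, 0, 0]
    Kinv[:, 0, 1] = -K[:, 0, 1]
    Kinv[:, 1, 0] = -K[:, 1, 0]
    Kinv /= det[:, None, None]
    corr = np.einsum("nij,njk,nlk->nil", U, Kinv, U)
    info = (W - corr).sum(axis=0)
    return np.sqrt(np.diag(np.linalg.inv(info)))


def relative_bias(estimates: np.ndarray, theta: float) -> float:
    """Mean of (estimate - theta) / theta, in percent."""
    estimates = np.asarray(estimates, dtype=float)
    if theta == 0:
        raise ValueError("relative bias undefined for theta = 0")
    return float(np.mean((estimates - theta) / theta) * 100.0)


def se_relative_bias(model_ses: np.ndarray, true_ses: np.ndarray | float) -> float:
    """Relative bias (%) of model-based SEs against the true standard error.

    ``true_ses`` is either the per-replicate analytic true SE (from
    :func:`true_fixed_effect_ses`, the default yardstick in the bias report)
    or a single scalar such as a Monte Carlo SD.
    """
    model_ses = np.asarray(model_ses, dtype=float)
    true_ses = np.broadcast_to(np.asarray(true_ses, dtype=float), model_ses.shape)
    if model_ses.shape[0] < 1:
        raise ValueError("need at least 1 converged replicate")
    return float(np.mean((model_ses - true_ses) / true_ses) * 100.0)


def se_relative_bias_empirical(model_ses: np.ndarray, estimates: np.ndarray) -> float:
    """SE relative bias (%) with the Monte Carlo SD of the estimates as the
    yardstick — a truth-free diagnostic variant."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.shape[0] < 2:
        raise ValueError("need at least 2 converged replicates")
    return se_relative_bias(model_ses, float(np.std(estimates, ddof=1)))


class BiasReport:
    """Per-condition, per-method relative biases, mirroring the study tables.

    ``long`` is a DataFrame with columns N, L, rho_bar, method, parameter,
    bias (percent), n_converged.  ``parameter_table(name)`` pivots one
    parameter block into the (N, L) x (rho_bar x method) layout.
    """

    def __init__(self, long: pd.DataFrame, conv: pd.DataFrame):
        self.long = long
        self.convergence = conv

    @classmethod
    def from_estimates(cls, tables, truth: TrueParameters) -> "BiasReport":
        rows, conv_rows = [], []
        for table in tables:
            for (N, L, rho_bar, method), grp in table.groupby(
                ["N", "L", "rho_bar", "method"], sort=False
            ):
                ok = grp[grp["converged"]]
                nconv = len(ok)
                conv_rows.append(
                    dict(N=N, L=L, rho_bar=rho_bar, method=method,
                         n_converged=nconv, n_total=len(grp),
                         rate=nconv / len(grp)))
                for p in PARAM_NAMES:
                    bias = (
                        relative_bias(ok[p].to_numpy(), truth.value_of(p))
                        if nconv else np.nan
                    )
                    rows.append(dict(N=N, L=L, rho_bar=rho_bar, method=method,
                                     parameter=p, bias=bias, n_converged=nconv))
                for p, sp in zip(PARAM_NAMES[:4], SE_NAMES):
                    bias = (
                        se_relative_bias(
                            ok[sp].to_numpy(), ok[f"true_{sp}"].to_numpy()
                        )
                        if nconv >= 1 else np.nan
                    )
                    rows.append(dict(N=N, L=L, rho_bar=rho_bar, method=method,
                                     parameter=sp, bias=bias, n_converged=nconv))
        return cls(pd.DataFrame(rows), pd.DataFrame(conv_rows))

    def parameter_table(self, parameter: str) -> pd.DataFrame:
        sub = self.long[self.long["parameter"] == parameter]
        wide = sub.pivot_table(index=["N", "L"], columns=["rho_bar", "method"],
                               values="bias", sort=False)
        methods = [m for m in METHODS if m in sub["method"].unique()]
        rhos = sorted(sub["rho_bar"].unique())
        cols = [(r, m) for r in rhos for m in methods]
        return wide.reindex(columns=pd.MultiIndex.from_tuples(
            cols, names=["rho_bar", "method"]))

    def cell(self, N, L, rho_bar, method, parameter) -> float:
        sub = self.long
        m = (
            (sub["N"] == N) & (sub["L"] == L)
            & (np.isclose(sub["rho_bar"], rho_bar))
            & (sub["method"] == method) & (sub["parameter"] == parameter)
        )
        vals = sub.loc[m, "bias"]
        if len(vals) != 1:
            raise KeyError(f"no unique cell for {(N, L, rho_bar, method, parameter)}")
        return float(vals.iloc[0])


def default_grid(reps: int = 500, base_seed: int = 0):
    """The full study grid: 48 conditions."""
    return [
        SimulationCondition(N, L, rho_bar, reps=reps, base_seed=base_seed)
        for rho_bar in (0.0, 0.3, 0.6)
        for N in (20, 50, 100, 200)
        for L in (20, 50, 100, 200)
    ]


def planned_counts(grid, methods=METHODS) -> dict:
    """Planned dataset and fit counts, reported before running."""
    datasets = sum(c.reps for c in grid)
    return {
        "conditions": len(grid),
        "datasets": datasets,
        "fits": datasets * len(methods),
    }


def run_grid(
    grid,
    methods=METHODS,
    truth: TrueParameters | None = None,
    progress: bool = False,
) -> BiasReport:
    """Run every condition in the grid and tabulate relative biases."""
    truth = truth or TrueParameters()
    counts = planned_counts(grid, methods)
    if progress:  # pragma: no cover - cosmetic
        print(
            f"planned: {counts['conditions']} conditions, "
            f"{counts['datasets']} datasets, {counts['fits']} fits"
        )
    tables = []
    for cond in grid:
        tables.append(run_condition(cond, methods=methods, truth=truth))
        if progress:  # pragma: no cover
            print(f"done: N={cond.N} L={cond.L} rho_bar={cond.rho_bar}")
    report = BiasReport.from_estimates(tables, truth)
    report.planned = counts
    return report


def plot_bias(report: BiasReport, parameter: str = "var_u0", ax=None):
    """Line plot of relative bias against series length, one line per
    (rho_bar, method) — the study's figure style.  Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = report.long[report.long["parameter"] == parameter]
    for (rho_bar, method), grp in sub.groupby(["rho_bar", "method"]):
        mean_by_L = grp.groupby("L")["bias"].mean()
        ax.plot(mean_by_L.index, mean_by_L.values, marker="o",
                label=f"rho={rho_bar} {method}")
    ax.set_xlabel("series length L")
    ax.set_ylabel(f"relative bias of {parameter} (%)")
    ax.legend(fontsize=7)
    return ax
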