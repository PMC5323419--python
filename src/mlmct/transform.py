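"""The two-step Cholesky-transformation pipeline (MLM-CT, step 1).

Each subject's residual series is modeled as a stationary AR(p) process by
exact ML; the estimated coefficients define a lower-triangular whitening
operator A_i, and A_i is applied to the subject's outcome, fixed-effect
design and random-effect design.  A multilevel model with independent
homogeneous residuals fitted to the transformed data then plays the role of
the intended model under heterogeneous within-person autocorrelation.

The intercept columns of the transformed designs are A_i @ 1, not a fresh
column of ones: the step-2 model must consume the transformed columns
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ar import (
    ARFit,
    IndividualSeries,
    WhiteningOperator,
    build_whitening_arp,
    fit_ar1_ml_stacked,
    fit_ols_individual,
    fit_regression_with_ar_errors,
    select_ar_order,
)

__all__ = [
    "TransformedPanel",
    "whiten_subject",
    "mlm_ct_pipeline",
    "rescale_to_unit_variance",
    "transform_stacked",
]


@dataclass
class TransformedPanel:
    """Per-subject whitened blocks y*_i = A_i y_i, X*_i = A_i X_i, Z*_i = A_i Z_i."""

    subject_ids: list
    y_blocks: list
    X_blocks: list
    Z_blocks: list
    arfits: list = field(default_factory=list)
    occasions: list = field(default_factory=list)

    @property
    def sigma_w2(self) -> np.ndarray:
        return np.array([f.sigma_w2 for f in self.arfits])

    def to_frame(self) -> pd.DataFrame:
        """Serialize to a long DataFrame with y_star / x_star_* / z_star_* columns."""
        rows = []
        for i, sid in enumerate(self.subject_ids):
            L = self.y_blocks[i].shape[0]
            occ = (
                self.occasions[i]
                if self.occasions
                else np.arange(1, L + 1)
            )
            df = pd.DataFrame(
                {
                    "subject": sid,
                    "occasion": occ,
                    "y_star": self.y_blocks[i],
                    "x_star_intercept": self.X_blocks[i][:, 0],
                    "x_star_z": self.X_blocks[i][:, 1],
                    "x_star_c": self.X_blocks[i][:, 2],
                    "x_star_zc": self.X_blocks[i][:, 3],
                    "z_star_intercept": self.Z_blocks[i][:, 0],
                    "z_star_z": self.Z_blocks[i][:, 1],
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def whiten_subject(op: WhiteningOperator, y_i, X_i, Z_i):
    """Apply one subject's whitening operator to outcome and designs."""
    y_i = np.asarray(y_i, float)
    X_i = np.asarray(X_i, float)
    Z_i = np.asarray(Z_i, float)
    for arr, name in ((y_i, "y"), (X_i, "X"), (Z_i, "Z")):
        if arr.shape[0] != op.n:
            raise ValueError(
                f"operator dimension {op.n} does not match {name} rows {arr.shape[0]}"
            )
    ys = op.apply(y_i[:, None])[:, 0]
    return ys, op.apply(X_i), op.apply(Z_i)


def mlm_ct_pipeline(
    panel: pd.DataFrame,
    p: int = 1,
    order_selection: str | None = None,
    p_max: int = 3,
    rescale: bool = False,
    on_error: str = "raise",
    subject: str = "subject",
    occasion: str = "occasion",
    outcome: str = "y",
    time_varying: str = "z",
    level2: str = "c",
) -> TransformedPanel:
    """Estimate per-subject AR models and whiten a long panel.

    The step-1 regression uses the time-varying design [1, z] (the level-2
    covariate is constant within subject and is absorbed by the per-subject
    intercept).  ``order_selection`` of 'aic'/'bic' picks p per subject from
    OLS residuals up to ``p_max``; the default keeps ``p`` fixed.  Subjects
    whose AR fit fails abort the pipeline unless ``on_error='skip'``.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    ids = list(pd.unique(panel[subject]))
    out = TransformedPanel([], [], [], [], [], [])
    for sid in ids:
        sub = panel[panel[subject] == sid].sort_values(occasion)
        series = IndividualSeries(
            sid,
            sub[occasion].to_numpy(),
            sub[outcome].to_numpy(float),
            sub[time_varying].to_numpy(float),
        )
        cvals = sub[level2].to_numpy(float)
        if not np.allclose(cvals, cvals[0]):
            raise ValueError(f"level-2 covariate varies within subject {sid!r}")
        p_i = p
        if order_selection is not None:
            _, resid = fit_ols_individual(series)
            p_i = select_ar_order(resid, p_max, criterion=order_selection)
        if series.n < p_i + 4:
            raise ValueError(
                f"subject {sid!r}: series length {series.n} too short for AR({p_i})"
            )
        try:
            fit = fit_regression_with_ar_errors(series, p=p_i)
        except Exception:
            if on_error == "skip":
                continue
            raise RuntimeError(f"AR estimation failed for subject {sid!r}")
        op = build_whitening_arp(fit.phi, series.n, fit.sigma_w2, subject_id=sid)
        ones = np.ones(series.n)
        Z_i = np.column_stack([ones, series.z])
        X_i = np.column_stack([ones, series.z, cvals[0] * ones, cvals[0] * series.z])
        ys, Xs, Zs = whiten_subject(op, series.y, X_i, Z_i)
        out.subject_ids.append(sid)
        out.y_blocks.append(ys)
        out.X_blocks.append(Xs)
        out.Z_blocks.append(Zs)
        out.arfits.append(fit)
        out.occasions.append(series.occasions)
    if not out.subject_ids:
        raise ValueError("no subject could be transformed")
    return rescale_to_unit_variance(out) if rescale else out


def rescale_to_unit_variance(tp: TransformedPanel) -> TransformedPanel:
    """Divide each subject's whitened block by its estimated innovation SD.

    After rescaling, the transformed residual variance is ~1 for every
    subject, which makes the step-2 homogeneity assumption hold by
    construction under per-subject heteroscedasticity.
    """
    scale = np.sqrt(tp.sigma_w2)
    if np.any(~(scale > 0)):
        raise ValueError("all sigma_w2 must be positive")
    return TransformedPanel(
        list(tp.subject_ids),
        [y / s for y, s in zip(tp.y_blocks, scale)],
        [X / s for X, s in zip(tp.X_blocks, scale)],
        [Z / s for Z, s in zip(tp.Z_blocks, scale)],
        list(tp.arfits),
        list(tp.occasions),
    )


def transform_stacked(y: np.ndarray, z: np.ndarray, c: np.ndarray):
    """Vectorized AR(1) step-1 for balanced arrays (the simulation fast path).

    Fits the per-subject exact-ML AR(1) regression of y on [1, z], then
    applies each whitening operator to y, X = [1, z, c, cz] and Z = [1, z]
    in place via the band structure.  Returns
    (y_star (N,L), X_star (N,L,4), Z_star (N,L,2), rho (N,), sigma_w2 (N,),
    cap_hit (N,)).
    """
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    c = np.asarray(c, float)
    N, L = y.shape
    rho, sigma_w2, _, _, cap = fit_ar1_ml_stacked(y, z)
    ones = np.ones((N, L))
    X = np.stack([ones, z, c[:, None] * ones, c[:, None] * z], axis=2)
    M = np.concatenate([y[:, :, None], X], axis=2)  # Z = X[:, :, :2]
    Ms = M.copy()
    r = rho[:, None, None]
    Ms[:, 1:, :] = M[:, 1:, :] - r * M[:, :-1, :]
    Ms[:, 0, :] = np.sqrt(1.0 - rho[:, None] ** 2) * M[:, 0, :]
    y_star = Ms[:, :, 0]
    X_star = Ms[:, :, 1:]
    Z_star = X_star[:, :, :2]
    return y_star, X_star, Z_star, rho, sigma_w2, cap
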