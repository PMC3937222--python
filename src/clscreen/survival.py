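"""Survival-coefficient estimation, batch normalization, and lifespan units.

Under constant exponential death of both co-cultured populations, the
interpolated log-ratio ln(R/C) at the fixed outgrowth time t* is linear in
stationary-phase age T with slope s = r_wt - r_x, the apparent survival
coefficient (per day). The slope is estimated per strain-well by iteratively
reweighted least squares with Tukey bisquare weights (tuning constant 4.685)
so that single aberrant ages - low signal, adaptive regrowth - are
down-weighted rather than dominating the fit; plain OLS is retained as an
option for oracle comparisons.

Raw slopes are then centered per batch on the wild-type controls (median by
default), giving the corrected coefficient whose WT distribution is zero by
construction; the relative lifespan is L = 1 + s_corr and an absolute
half-life follows from the WT reference half-life where s_corr < r_wt.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outgrowth import QC_OK

log = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: conventional 95%-efficiency tuning constant for the bisquare estimator
BISQUARE_C = 4.685

FLAG_TOO_FEW = "too_few_points"
FLAG_EXCEEDS_BOUND = "exceeds_bound"
FLAG_OUTLIER = "outlier_downweighted"


@dataclass
class SurvivalFit:
    """Per-well slope of ln(R/C)^t* vs age, before and after batch centering."""

    strain_id: str
    s_raw: float
    s_se: float
    intercept: float
    n_ages: int
    s_corr: float = np.nan
    flags: set = field(default_factory=set)
    batch_id: str = ""
    role: str = "mutant"


def irls_line(x, y, c: float = BISQUARE_C, max_iter: int = 50, tol: float = 1e-10):
    """Robust straight-line fit by IRLS with Tukey bisquare weights.

    The scale is re-estimated each iteration as MAD/0.6745 of the residuals.
    Standard errors use the Street-Carroll-Ruppert sandwich estimate
    (the convention of MATLAB's robustfit). On data with zero residual scale
    (a perfect line) the fit reduces exactly to OLS.

    Returns ``(slope, intercept, se_slope, se_intercept, weights)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >=3 points for a robust line fit")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(n)
    yscale = max(1.0, float(np.max(np.abs(y))))
    for _ in range(max_iter):
        r = y - X @ beta
        s = float(np.median(np.abs(r))) / 0.6745
        if s <= 1e-12 * yscale:
            # scale collapsed: points on the line keep full weight, any
            # remaining gross outliers none; the fit cannot improve further
            w = (np.abs(r) <= 1e-9 * yscale).astype(float)
            if w.sum() < 2:
                w = np.ones(n)
            break
        u = r / (c * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        if w.sum() < 2:  # pathological: nearly all points rejected
            w = np.ones(n)
            break
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        if np.max(np.abs(beta_new - beta)) <= tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new

    r = y - X @ beta
    s = float(np.median(np.abs(r))) / 0.6745
    XtX_inv = np.linalg.inv(X.T @ X)
    if s <= 1e-12 * yscale:
        # degenerate (perfect) fit: classical OLS error over the retained points
        sigma2 = float(np.sum(w * r * r)) / max(w.sum() - 2, 1)
        cov = sigma2 * XtX_inv
    else:
        u = r / s
        au = np.abs(u)
        psi = np.where(au < c, u * (1.0 - (u / c) ** 2) ** 2, 0.0)
        dpsi = np.where(au < c, (1.0 - (u / c) ** 2) * (1.0 - 5.0 * (u / c) ** 2), 0.0)
        mean_dpsi = float(np.mean(dpsi))
        if mean_dpsi <= 0:
            mean_dpsi = 1.0  # degenerate; fall back to unscaled sandwich
        sigma2 = s * s * float(np.sum(psi * psi)) / (n - 2) / (mean_dpsi ** 2)
        cov = sigma2 * XtX_inv
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return float(beta[1]), float(beta[0]), float(se[1]), float(se[0]), w


def ols_line(x, y):
    """Plain OLS line fit; returns ``(slope, intercept, se_slope, se_intercept)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >=3 points for a line fit with SE")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sigma2 = float(np.sum(r * r)) / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return float(beta[1]), float(beta[0]), float(se[1]), float(se[0])


def fit_survival(ages, ln_ratios, method: str = "robust",
                 strain_id: str = "", min_ages: int = 3) -> SurvivalFit | None:
    """Fit the survival coefficient for one strain-well.

    Only QC-passing points should be supplied. Strains with fewer than
    ``min_ages`` distinct usable ages yield ``None`` (they mirror the screen's
    exclusion of low-signal or slow-growing strains).
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(ln_ratios, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(y)
    ages, y = ages[ok], y[ok]
    if np.unique(ages).size < min_ages:
        return None
    flags: set = set()
    if method == "robust":
        slope, intercept, se_s, _, w = irls_line(ages, y)
        if np.min(w) < 0.5:
            flags.add(FLAG_OUTLIER)
    elif method == "ols":
        slope, intercept, se_s, _ = ols_line(ages, y)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return SurvivalFit(strain_id=strain_id, s_raw=slope, s_se=se_s,
                       intercept=intercept, n_ages=int(np.unique(ages).size),
                       flags=flags)


def fit_survival_table(points: pd.DataFrame, method: str = "robust",
                       min_ages: int = 3) -> pd.DataFrame:
    """Fit one survival coefficient per well from a ratio-point table.

    ``points`` is the output of :func:`clscreen.outgrowth.ratio_points`; rows
    with ``qc != ok`` are excluded before fitting. Wells that fail the minimum
    distinct-age requirement are dropped (reported via the returned frame's
    ``attrs['n_excluded']``).
    """
    usable = points[points["qc"] == QC_OK]
    rows = []
    n_excluded = 0
    for (plate, well), grp in usable.groupby(["plate_id", "well"], sort=False):
        fit = fit_survival(grp["age_days"].to_numpy(), grp["ln_ratio"].to_numpy(),
                           method=method, strain_id=str(grp["strain_id"].iloc[0]),
                           min_ages=min_ages)
        if fit is None:
            n_excluded += 1
            continue
        rows.append((plate, well, fit.strain_id, grp["role"].iloc[0],
                     grp["batch_id"].iloc[0], fit.s_raw, fit.s_se,
                     fit.intercept, fit.n_ages, ";".join(sorted(fit.flags))))
    out = pd.DataFrame(rows, columns=["plate_id", "well", "strain_id", "role",
                                      "batch_id", "s_raw", "s_se", "intercept",
                                      "n_ages", "flags"])
    out.attrs["n_excluded"] = n_excluded
    return out


def normalize_batch(fits: pd.DataFrame, center: str = "median") -> pd.DataFrame:
    """Per-batch centering of raw slopes on the wild-type controls.

    ``s_corr = s_raw - center(s_raw over the batch's wt_control wells)``; by
    definition the corrected WT survival coefficient is centered on zero in
    every batch, which removes plate/batch effects. A batch without any
    wild-type fit is an error.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    wt = fits[fits["role"] == "wt_control"]
    centers = wt.groupby("batch_id")["s_raw"].agg(center)
    missing = sorted(set(fits["batch_id"]) - set(centers.index))
    if missing:
        raise ValueError(f"batches without a fitted wt_control well: {missing}")
    out = fits.copy()
    out["s_corr"] = out["s_raw"] - out["batch_id"].map(centers).to_numpy()
    return out


def half_life(s_corr: float, lambda_wt: float) -> float:
    """Mutant half-life (days) from its corrected survival coefficient.

    r_wt = ln2/lambda_wt, r_x = r_wt - s_corr, lambda_x = ln2/r_x. The WT
    death rate bounds s at s <= r_wt; at or beyond the bound the implied death
    rate is nonpositive and the half-life is undefined (NaN).
    """
    if lambda_wt <= 0:
        raise ValueError("lambda_wt must be positive")
    if not np.isfinite(s_corr):
        return float("nan")
    if s_corr == 0.0:  # no survival effect: the WT half-life, exactly
        return float(lambda_wt)
    r_x = LN2 / lambda_wt - s_corr
    if r_x <= 0:
        return float("nan")
    return LN2 / r_x


def to_lifespan(fits: pd.DataFrame, lambda_wt: float = 21.7,
                growth: pd.DataFrame | None = None,
                condition: str = "SDC") -> pd.DataFrame:
    """Convert batch-normalized fits to relative-lifespan records.

    L = 1 + s_corr with se_L = se_s (the regression error, unchanged). The
    half-life column is NA wherever s_corr >= r_wt (flagged exceeds_bound).
    ``growth`` optionally supplies a per-strain relative growth rate G
    (columns strain_id, G); per-well G tables are averaged per strain.
    """
    if "s_corr" not in fits.columns:
        raise ValueError("fits must be batch-normalized first (missing s_corr)")
    out = fits.copy()
    out["L"] = 1.0 + out["s_corr"]
    out["se_L"] = out["s_se"]
    out["half_life_days"] = [half_life(s, lambda_wt) for s in out["s_corr"]]
    r_wt = LN2 / lambda_wt
    exceeded = out["s_corr"] >= r_wt
    out["flags"] = [
        ";".join(sorted(set(filter(None, str(f).split(";"))) | ({FLAG_EXCEEDS_BOUND} if ex else set())))
        for f, ex in zip(out.get("flags", [""] * len(out)), exceeded)
    ]
    if growth is not None and len(growth):
        g_per_strain = growth.groupby("strain_id")["G"].mean()
        out["G"] = out["strain_id"].map(g_per_strain).to_numpy()
    else:
        out["G"] = np.nan
    out["condition"] = condition
    return out
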