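"""Outgrowth-curve processing: background correction, log-ratios, interpolation.

A competitive chronological-lifespan assay tracks a fluorophore-tagged mutant
co-cultured with a reference strain. At each stationary-phase age an aliquot is
regrown in fresh medium and read every few hours for two fluorescence channels
(RFP, CFP) and OD600. Because both populations grow exponentially during
outgrowth, the log of the background-corrected channel ratio, ln(R/C), is a
linear function of outgrowth time; evaluating it at a fixed time t* (10 h by
default) yields one number per age whose change across ages reflects only the
difference in stationary-phase death rates, not any difference in growth rate.

This module turns raw per-well time series into those per-age interpolated
log-ratios, with quality flags, plus absolute growth-rate fits from OD curves.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default interpolation time (hours post inoculation)
T_STAR = 10.0
#: conservative dynamic-range limits on ln(R/C) at t*
LN_RATIO_FLOOR = -3.5
LN_RATIO_CEILING = 2.5
#: how far (hours) past the last/first read linear extrapolation is allowed
MAX_EXTRAPOLATION_H = 1.5

QC_OK = "ok"
QC_BELOW_FLOOR = "below_floor"
QC_ABOVE_CEILING = "above_ceiling"
QC_TOO_FEW_POINTS = "too_few_points"
QC_NONPOSITIVE = "nonpositive_signal"


@dataclass
class OutgrowthCurve:
    """One well's outgrowth time series at one stationary-phase age.

    ``age_days`` counts days since age zero (day 5 post-inoculation).
    Arrays are parallel and ordered by strictly increasing ``time_h``.
    """

    plate_id: str
    well: str
    strain_id: str
    role: str
    batch_id: str
    age_days: float
    time_h: np.ndarray
    rfp_raw: np.ndarray
    cfp_raw: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.rfp_raw = np.asarray(self.rfp_raw, dtype=float)
        self.cfp_raw = np.asarray(self.cfp_raw, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if not (self.time_h.size == self.rfp_raw.size == self.cfp_raw.size == self.od600.size):
            raise ValueError("curve arrays must have equal length")
        if self.time_h.size >= 2 and not np.all(np.diff(self.time_h) > 0):
            raise ValueError(
                f"times not strictly increasing for {self.plate_id}/{self.well} age {self.age_days}"
            )

    @property
    def n_points(self) -> int:
        return int(self.time_h.size)


@dataclass
class BackgroundModel:
    """Affine background signal vs OD600 for one fluorescence channel.

    Fitted from single-color control wells that *lack* the channel's
    fluorophore, so their raw signal in that channel is pure background
    (medium autofluorescence plus cell-density-dependent crosstalk).
    """

    channel: str
    intercept: float
    slope: float
    od_range: tuple[float, float]
    n_points: int

    #: set once the model has been applied outside its fitted OD range
    extrapolated: bool = False

    def predict(self, od600):
        od = np.asarray(od600, dtype=float)
        lo, hi = self.od_range
        if np.any((od < lo - 1e-12) | (od > hi + 1e-12)) and not self.extrapolated:
            self.extrapolated = True
            log.info(
                "background model for %s extrapolated outside fitted OD range [%g, %g]",
                self.channel, lo, hi,
            )
        return self.intercept + self.slope * od


@dataclass
class RatioPoint:
    """Interpolated ln(R/C) at t* for one (strain-well, age)."""

    strain_id: str
    age_days: float
    ln_ratio: float
    qc: str


@dataclass
class GrowthFit:
    """Exponential growth rate from ln(OD600) vs time over a fit window."""

    strain_id: str
    rate_per_h: float
    se: float
    window_h: tuple[float, float]
    n_points: int
    relative_G: float | None = None


@dataclass
class DynamicRangeResult:
    """Outcome of a dilution-series calibration of the ln(R/C) dynamic range."""

    linear_range: tuple[float, float] | None
    floor: float
    ceiling: float
    calibrated: bool
    n_linear_points: int = 0


_CONTROL_FOR_CHANNEL = {"RFP": "cfp_only", "CFP": "rfp_only"}


def fit_background(control_curves, channel: str) -> BackgroundModel:
    """Least-squares affine fit of raw channel signal vs OD600.

    ``control_curves`` are wells lacking the channel's fluorophore (CFP-only
    wells for the RFP channel and vice versa); all their timepoints are pooled.
    A negative slope is permitted but logged, since crosstalk should grow with
    cell density.
    """
    if channel not in ("RFP", "CFP"):
        raise ValueError(f"unknown channel {channel!r}")
    expected_role = _CONTROL_FOR_CHANNEL[channel]
    od_parts, sig_parts = [], []
    for c in control_curves:
        if c.role != expected_role:
            raise ValueError(
                f"background controls for channel {channel} must be {expected_role} wells, "
                f"got role {c.role!r} for {c.plate_id}/{c.well}"
            )
        od_parts.append(c.od600)
        sig_parts.append(c.rfp_raw if channel == "RFP" else c.cfp_raw)
    if not od_parts:
        raise ValueError(f"no control wells supplied for channel {channel}")
    od = np.concatenate(od_parts)
    sig = np.concatenate(sig_parts)
    return fit_background_arrays(od, sig, channel)


def fit_background_arrays(od600, signal, channel: str) -> BackgroundModel:
    """Affine OLS of ``signal`` on ``od600``; core used by :func:`fit_background`."""
    od = np.asarray(od600, dtype=float)
    sig = np.asarray(signal, dtype=float)
    ok = np.isfinite(od) & np.isfinite(sig)
    od, sig = od[ok], sig[ok]
    if od.size < 3:
        raise ValueError(f"need >=3 control points to fit {channel} background, got {od.size}")
    if np.ptp(od) < 1e-12:
        # degenerate design: constant OD -> constant background
        intercept, slope = float(np.mean(sig)), 0.0
    else:
        slope, intercept = np.polyfit(od, sig, 1)
    if slope < 0:
        log.info("fitted negative background slope (%g) for channel %s", slope, channel)
    return BackgroundModel(
        channel=channel,
        intercept=float(intercept),
        slope=float(slope),
        od_range=(float(od.min()), float(od.max())),
        n_points=int(od.size),
    )


def correct_and_logratio(curve: OutgrowthCurve, bg_rfp: BackgroundModel,
                         bg_cfp: BackgroundModel):
    """Background-correct both channels and return usable (t, ln(R/C)) points.

    RFP = RFPraw - RFPbg(OD) and CFP = CFPraw - CFPbg(OD); timepoints where
    either corrected signal is nonpositive carry no ratio information and are
    dropped (and counted).

    Returns ``(t, ln_rc, n_dropped)``.
    """
    rfp = curve.rfp_raw - bg_rfp.predict(curve.od600)
    cfp = curve.cfp_raw - bg_cfp.predict(curve.od600)
    usable = (rfp > 0) & (cfp > 0)
    n_dropped = int((~usable).sum())
    t = curve.time_h[usable]
    ln_rc = np.log(rfp[usable]) - np.log(cfp[usable])
    return t, ln_rc, n_dropped


def interpolate_at_tstar(t, ln_rc, t_star: float = T_STAR, *,
                         floor: float = LN_RATIO_FLOOR,
                         ceiling: float = LN_RATIO_CEILING,
                         max_extrapolation_h: float = MAX_EXTRAPOLATION_H,
                         strain_id: str = "", age_days: float = np.nan) -> RatioPoint:
    """Linearly interpolate ln(R/C) at ``t_star``.

    Both populations grow exponentially during outgrowth, so ln(R/C) is linear
    in time in-model and linear interpolation between the two flanking reads is
    exact. If t* falls outside the observed span, the nearest segment is
    extended up to ``max_extrapolation_h`` (covering one missing read);
    otherwise the age is unusable. Values outside [floor, ceiling] are outside
    the assay's calibrated dynamic range and flagged for downstream exclusion.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(ln_rc, dtype=float)
    if t.size < 2:
        return RatioPoint(strain_id, age_days, np.nan, QC_TOO_FEW_POINTS)
    if t_star < t[0] - max_extrapolation_h or t_star > t[-1] + max_extrapolation_h:
        return RatioPoint(strain_id, age_days, np.nan, QC_TOO_FEW_POINTS)
    if t_star <= t[0]:
        i0, i1 = 0, 1               # extrapolate from first segment
    elif t_star >= t[-1]:
        i0, i1 = t.size - 2, t.size - 1  # extrapolate from last segment
    else:
        i1 = int(np.searchsorted(t, t_star, side="right"))
        i0 = i1 - 1
    slope = (y[i1] - y[i0]) / (t[i1] - t[i0])
    value = float(y[i0] + slope * (t_star - t[i0]))
    if value < floor:
        qc = QC_BELOW_FLOOR
    elif value > ceiling:
        qc = QC_ABOVE_CEILING
    else:
        qc = QC_OK
    return RatioPoint(strain_id, age_days, value, qc)


def ratio_points(curves, bg_rfp: BackgroundModel, bg_cfp: BackgroundModel, *,
                 t_star: float = T_STAR, floor: float = LN_RATIO_FLOOR,
                 ceiling: float = LN_RATIO_CEILING,
                 max_extrapolation_h: float = MAX_EXTRAPOLATION_H) -> pd.DataFrame:
    """Process every mutant/WT-control curve into one interpolated RatioPoint row.

    Returns a DataFrame with columns plate_id, well, strain_id, role, batch_id,
    age_days, ln_ratio, qc. Single-color and blank wells are skipped (they
    carry no strain-level result).
    """
    rows = []
    for c in curves:
        if c.role not in ("mutant", "wt_control"):
            continue
        t, y, _ = correct_and_logratio(c, bg_rfp, bg_cfp)
        if t.size == 0:
            rp = RatioPoint(c.strain_id, c.age_days, np.nan, QC_NONPOSITIVE)
        else:
            rp = interpolate_at_tstar(
                t, y, t_star, floor=floor, ceiling=ceiling,
                max_extrapolation_h=max_extrapolation_h,
                strain_id=c.strain_id, age_days=c.age_days,
            )
        rows.append((c.plate_id, c.well, c.strain_id, c.role, c.batch_id,
                     c.age_days, rp.ln_ratio, rp.qc))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "well", "strain_id", "role", "batch_id",
                 "age_days", "ln_ratio", "qc"],
    )


def calibrate_dynamic_range(expected, observed, *, slope_tol: float = 0.2,
                            default_floor: float = LN_RATIO_FLOOR,
                            default_ceiling: float = LN_RATIO_CEILING) -> DynamicRangeResult:
    """Estimate the linear dynamic range from a defined-mixture dilution series.

    ``expected`` are the ln(R/C) values implied by known mixture ratios of the
    two labelled reference populations; ``observed`` the interpolated readout.
    The largest contiguous stretch (sorted by expected value) over which every
    local segment slope d(observed)/d(expected) lies within ``slope_tol`` of 1
    is reported; its endpoints are the suggested floor/ceiling. With no
    stretch of at least 3 points the defaults are retained and a warning logged.
    """
    exp = np.asarray(expected, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if exp.size != obs.size:
        raise ValueError("expected/observed must have equal length")
    if exp.size < 4:
        raise ValueError("need >=4 defined mixture ratios to calibrate")
    order = np.argsort(exp)
    exp, obs = exp[order], obs[order]
    seg_ok = np.abs(np.diff(obs) / np.diff(exp) - 1.0) <= slope_tol
    # longest run of consecutive True segments
    best_start = best_len = 0
    start = 0
    run = 0
    for i, ok in enumerate(seg_ok):
        if ok:
            if run == 0:
                start = i
            run += 1
            if run > best_len:
                best_start, best_len = start, run
        else:
            run = 0
    if best_len < 2:  # fewer than 3 points
        log.warning("no contiguous linear stretch of >=3 points; keeping default thresholds")
        return DynamicRangeResult(None, default_floor, default_ceiling, False)
    lo = float(exp[best_start])
    hi = float(exp[best_start + best_len])
    return DynamicRangeResult((lo, hi), lo, hi, True, best_len + 1)


def fit_growth_rate(time_h, od600, *, window: tuple[float, float] = (2.0, 10.0),
                    blank: float = 0.0, strain_id: str = "") -> GrowthFit | None:
    """OLS slope of ln(OD600 - blank) vs time over the exponential window.

    Returns ``None`` when fewer than 3 positive blank-subtracted OD points fall
    inside the window (no fit possible).
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float) - blank
    sel = (t >= window[0]) & (t <= window[1]) & (od > 0)
    if sel.sum() < 3:
        return None
    t, y = t[sel], np.log(od[sel])
    n = t.size
    X = np.column_stack([np.ones(n), t])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    sigma2 = rss / (n - 2) if n > 2 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    rate = float(beta[1])
    if rate <= 0:
        return None
    return GrowthFit(strain_id, rate, float(np.sqrt(cov[1, 1])), window, n)


def growth_table(curves, *, age_days: float = 0.0,
                 window: tuple[float, float] = (2.0, 10.0),
                 blank: float = 0.0) -> pd.DataFrame:
    """Fit absolute growth rates for every mutant/WT well at one age and derive
    G = gr_x / gr_wt against the per-batch mean of WT-control rates.
    """
    rows = []
    for c in curves:
        if c.role not in ("mutant", "wt_control") or c.age_days != age_days:
            continue
        fit = fit_growth_rate(c.time_h, c.od600, window=window, blank=blank,
                              strain_id=c.strain_id)
        if fit is None:
            continue
        rows.append((c.plate_id, c.well, c.strain_id, c.role, c.batch_id,
                     fit.rate_per_h, fit.se, fit.n_points))
    df = pd.DataFrame(rows, columns=["plate_id", "well", "strain_id", "role",
                                     "batch_id", "gr", "gr_se", "n_points"])
    if df.empty:
        df["G"] = []
        return df
    wt = df[df["role"] == "wt_control"]
    wt_mean = wt.groupby("batch_id")["gr"].mean()
    df["G"] = df["gr"] / df["batch_id"].map(wt_mean).to_numpy()
    return df
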