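"""Synthetic competitive-aging experiments with known ground truth.

The generator emulates the study conditions of an automated co-culture CLS
assay: mixed RFP-tagged mutant / CFP-tagged reference populations that die at
constant exponential rates in stationary phase, are sampled at age zero (day 5
post-inoculation) and every 2-3 days up to day 23, and regrow exponentially
after a 5/700 dilution into fresh medium, read every 3 h for 15 h. Raw channel
signals carry an affine OD600-dependent background (autofluorescence plus
crosstalk), multiplicative log-normal measurement noise, per-batch slope
offsets, and the control wells (scattered WT, single-color, blank) that the
downstream pipeline needs for background fitting and batch normalization.

Every scenario emits the exact ``plate_io`` schemas plus the ground truth, so
each downstream stage is testable by parameter recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

LN2 = math.log(2.0)


@dataclass
class SimStrainTruth:
    """Ground-truth parameters for one simulated strain.

    ``death_rate_r`` is the per-day exponential death rate in stationary
    phase; ``growth_rate_g`` the per-hour outgrowth rate. Optional adaptive
    regrowth switches the viable population to exponential *increase* at
    ``regrowth_rate`` from ``regrowth_age_days`` on, the artifact that turns
    apparent survival nonlinear.
    """

    strain_id: str
    death_rate_r: float
    growth_rate_g: float
    lag_h: float = 0.0
    regrowth_age_days: float | None = None
    regrowth_rate: float | None = None
    true_class: str = "neutral"

    def __post_init__(self) -> None:
        if not np.isfinite(self.death_rate_r):
            raise ValueError("death_rate_r must be finite")
        if self.growth_rate_g <= 0:
            raise ValueError("growth_rate_g must be positive")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        if (self.regrowth_age_days is None) != (self.regrowth_rate is None):
            raise ValueError("regrowth_age_days and regrowth_rate must be set together")


@dataclass
class SimConfig:
    """Study-condition parameters of a simulated plate set.

    Defaults mirror the assay's published sampling design (ages, read times,
    inoculum) and a WT reference with a 21.7-day half-life; noise magnitudes
    are calibration choices documented in the methods note.
    """

    r_wt: float = LN2 / 21.7          # per day
    g_wt: float = 0.4                 # per hour
    lag_wt_h: float = 0.0
    ages: tuple = (0, 2, 5, 7, 9, 12, 14, 16, 19, 21, 23)
    read_times_h: tuple = (3, 6, 9, 12, 15)
    mix_fraction: float = 0.5
    dilution: float = 5.0 / 700.0
    n0_cells: float = 1e7
    alpha_rfp: float = 1e-3           # fluorescence a.u. per cell
    alpha_cfp: float = 8e-4
    bg_rfp: tuple = (20.0, 60.0)      # intercept, slope vs OD600
    bg_cfp: tuple = (28.0, 45.0)
    od_per_cell: float = 1e-7
    od_blank: float = 0.04
    carrying_capacity: float = 2e8
    cv_fluor: float = 0.05
    cv_od: float = 0.05
    batch_offset_sd: float = 0.005    # per-day SD of delta_b
    batch_offsets: dict | None = None  # explicit per-batch delta_b, overrides sd
    strains_per_batch: int = 35
    n_wt_controls: int = 8            # per batch
    n_rfp_only: int = 2
    n_cfp_only: int = 2
    n_blank: int = 1
    poisson_inoculum: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_wt < 0 or self.g_wt <= 0:
            raise ValueError("reference rates must be positive")
        ages = np.asarray(self.ages, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        for name in ("alpha_rfp", "alpha_cfp", "od_per_cell", "dilution", "n0_cells"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Everything needed to score a simulated scenario against the truth."""

    truths: pd.DataFrame              # strain_id, r, g, lag, class, batch_id
    batch_offsets: dict
    seed: int
    config: SimConfig

    def truth_table(self) -> pd.DataFrame:
        df = self.truths.copy()
        df["delta_b"] = df["batch_id"].map(self.batch_offsets)
        return df


_ROWS = "ABCDEFGH"


def _well_label(i: int) -> str:
    return f"{_ROWS[i // 12]}{i % 12 + 1:02d}"


def build_layout(truths: list[SimStrainTruth], cfg: SimConfig) -> pd.DataFrame:
    """Arrange strains and control wells into plates, one batch per plate
    (a batch never spans plates; plates hold at most 96 wells)."""
    per_batch = cfg.strains_per_batch
    overhead = cfg.n_wt_controls + cfg.n_rfp_only + cfg.n_cfp_only + cfg.n_blank
    if per_batch + overhead > 96:
        raise ValueError("batch does not fit on a 96-well plate")
    if cfg.n_wt_controls < 1:
        raise ValueError("each batch needs at least one wt_control well")
    rows = []
    n_batches = max(1, math.ceil(len(truths) / per_batch))
    for b in range(n_batches):
        batch_id = f"B{b + 1:02d}"
        plate_id = f"P{b + 1:02d}"
        batch_strains = truths[b * per_batch:(b + 1) * per_batch]
        i = 0
        for st in batch_strains:
            rows.append((plate_id, _well_label(i), st.strain_id, "RFP", "mutant", batch_id))
            i += 1
        for _ in range(cfg.n_wt_controls):
            rows.append((plate_id, _well_label(i), "WT", "RFP", "wt_control", batch_id))
            i += 1
        for _ in range(cfg.n_rfp_only):
            rows.append((plate_id, _well_label(i), "", "RFP", "rfp_only", batch_id))
            i += 1
        for _ in range(cfg.n_cfp_only):
            rows.append((plate_id, _well_label(i), "", "CFP", "cfp_only", batch_id))
            i += 1
        for _ in range(cfg.n_blank):
            rows.append((plate_id, _well_label(i), "", "", "blank", batch_id))
            i += 1
    return pd.DataFrame(rows, columns=["plate_id", "well", "strain_id",
                                       "fluorophore", "role", "batch_id"])


def _viable(n0: np.ndarray, r: np.ndarray, ages: np.ndarray,
            regrowth_age: np.ndarray, regrowth_rate: np.ndarray) -> np.ndarray:
    """Viable cells per well (rows) at each age (cols): exponential decay,
    switching to exponential regrowth at ``regrowth_age`` where set."""
    T = ages[None, :]
    N = n0[:, None] * np.exp(-r[:, None] * T)
    has_rg = np.isfinite(regrowth_age)
    if has_rg.any():
        T0 = regrowth_age[:, None]
        N_at_switch = n0[:, None] * np.exp(-r[:, None] * T0)
        rg = N_at_switch * np.exp(regrowth_rate[:, None] * (T - T0))
        N = np.where(has_rg[:, None] & (T > T0), rg, N)
    return N


def simulate_plate_set(truths: list[SimStrainTruth], cfg: SimConfig,
                       seed: int | None = None):
    """Simulate a full plate set.

    Returns ``(readings, layout, sim_truth)`` in the ``plate_io`` schemas.
    Wells whose inoculum underflows below one cell are clamped to zero viable
    cells and flagged in ``sim_truth`` (their ratio points become unusable,
    exercising the QC path downstream).
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    layout = build_layout(truths, cfg)
    truth_map = {t.strain_id: t for t in truths}

    batches = sorted(layout["batch_id"].unique())
    if cfg.batch_offsets is not None:
        offsets = {b: float(cfg.batch_offsets.get(b, 0.0)) for b in batches}
    elif cfg.batch_offset_sd > 0:
        offsets = {b: float(d) for b, d in
                   zip(batches, rng.normal(0.0, cfg.batch_offset_sd, len(batches)))}
    else:
        offsets = {b: 0.0 for b in batches}

    wells = layout.reset_index(drop=True)
    nw = len(wells)
    ages = np.asarray(cfg.ages, dtype=float)
    times = np.asarray(cfg.read_times_h, dtype=float)
    na, nt = ages.size, times.size

    # per-well parameters of the RFP-side and CFP-side populations
    r_rfp = np.zeros(nw); g_rfp = np.zeros(nw); lag_rfp = np.zeros(nw)
    rg_age = np.full(nw, np.nan); rg_rate = np.full(nw, np.nan)
    n0_rfp = np.zeros(nw); n0_cfp = np.zeros(nw)
    for i, row in enumerate(wells.itertuples()):
        role = row.role
        if role == "blank":
            continue
        delta = offsets[row.batch_id]
        if role == "mutant":
            st = truth_map[row.strain_id]
            r_rfp[i] = st.death_rate_r + delta
            g_rfp[i] = st.growth_rate_g
            lag_rfp[i] = st.lag_h
            if st.regrowth_age_days is not None:
                rg_age[i] = st.regrowth_age_days
                rg_rate[i] = st.regrowth_rate
            n0_rfp[i] = cfg.n0_cells * cfg.mix_fraction
            n0_cfp[i] = cfg.n0_cells * (1.0 - cfg.mix_fraction)
        elif role == "wt_control":
            r_rfp[i] = cfg.r_wt + delta
            g_rfp[i] = cfg.g_wt
            lag_rfp[i] = cfg.lag_wt_h
            n0_rfp[i] = cfg.n0_cells * cfg.mix_fraction
            n0_cfp[i] = cfg.n0_cells * (1.0 - cfg.mix_fraction)
        elif role == "rfp_only":
            r_rfp[i] = cfg.r_wt + delta
            g_rfp[i] = cfg.g_wt
            lag_rfp[i] = cfg.lag_wt_h
            n0_rfp[i] = cfg.n0_cells
        elif role == "cfp_only":
            n0_cfp[i] = cfg.n0_cells

    # viable cells at each age, then inoculum into outgrowth
    Nx = _viable(n0_rfp, r_rfp, ages, rg_age, rg_rate)              # (nw, na)
    Nwt = _viable(n0_cfp, np.full(nw, cfg.r_wt), ages,
                  np.full(nw, np.nan), np.full(nw, np.nan))
    inoc_x = cfg.dilution * Nx
    inoc_wt = cfg.dilution * Nwt
    if cfg.poisson_inoculum:
        inoc_x = rng.poisson(inoc_x).astype(float)
        inoc_wt = rng.poisson(inoc_wt).astype(float)
    underflow = ((inoc_x < 1.0) & (n0_rfp[:, None] > 0)) | \
                ((inoc_wt < 1.0) & (n0_cfp[:, None] > 0))
    inoc_x = np.where(inoc_x < 1.0, 0.0, inoc_x)
    inoc_wt = np.where(inoc_wt < 1.0, 0.0, inoc_wt)

    # exponential outgrowth, shared hard carrying capacity
    tg = times[None, None, :]
    grow_x = np.exp(np.clip(tg - lag_rfp[:, None, None], 0.0, None)
                    * g_rfp[:, None, None])
    grow_wt = np.exp(np.clip(tg - cfg.lag_wt_h, 0.0, None) * cfg.g_wt)
    Ox = inoc_x[:, :, None] * grow_x                                 # (nw, na, nt)
    Owt = inoc_wt[:, :, None] * grow_wt
    total = Ox + Owt
    over = total > cfg.carrying_capacity
    if over.any():
        scale = np.where(over, cfg.carrying_capacity / np.where(total > 0, total, 1.0), 1.0)
        Ox = Ox * scale
        Owt = Owt * scale
        total = Ox + Owt

    od_true = cfg.od_per_cell * total + cfg.od_blank
    rfp_true = cfg.alpha_rfp * Ox + cfg.bg_rfp[0] + cfg.bg_rfp[1] * od_true
    cfp_true = cfg.alpha_cfp * Owt + cfg.bg_cfp[0] + cfg.bg_cfp[1] * od_true

    def _lognoise(cv, shape):
        if cv <= 0:
            return 1.0
        sigma = math.sqrt(math.log1p(cv * cv))
        return np.exp(rng.normal(0.0, sigma, shape) - 0.5 * sigma * sigma)

    od_obs = od_true * _lognoise(cfg.cv_od, od_true.shape)
    rfp_obs = rfp_true * _lognoise(cfg.cv_fluor, rfp_true.shape)
    cfp_obs = cfp_true * _lognoise(cfg.cv_fluor, cfp_true.shape)

    readings = pd.DataFrame({
        "plate_id": np.repeat(wells["plate_id"].to_numpy(), na * nt),
        "well": np.repeat(wells["well"].to_numpy(), na * nt),
        "age_days": np.tile(np.repeat(ages, nt), nw),
        "time_h": np.tile(times, nw * na),
        "rfp_raw": rfp_obs.ravel(),
        "cfp_raw": cfp_obs.ravel(),
        "od600": od_obs.ravel(),
    })

    strain_batch = wells.loc[wells["role"] == "mutant", ["strain_id", "batch_id"]]
    batch_of = dict(zip(strain_batch["strain_id"], strain_batch["batch_id"]))
    truth_df = pd.DataFrame([{
        "strain_id": t.strain_id,
        "death_rate_r": t.death_rate_r,
        "growth_rate_g": t.growth_rate_g,
        "lag_h": t.lag_h,
        "true_class": t.true_class,
        "true_s": cfg.r_wt - t.death_rate_r,
        "batch_id": batch_of.get(t.strain_id, ""),
    } for t in truths])
    sim_truth = SimTruth(truths=truth_df, batch_offsets=offsets, seed=int(seed), config=cfg)
    sim_truth.underflow_wells = wells.loc[underflow.any(axis=1), "well"].tolist()
    return readings, layout, sim_truth


def make_screen_scenario(n_strains: int, fraction_short: float = 0.0,
                         fraction_long: float = 0.0, effect_size_sd: float = 0.01,
                         seed: int = 0, **cfg_overrides):
    """Reproducible screen scenario with labelled true classes.

    Short-lived strains get a death rate r_wt + |effect|, long-lived strains
    r_wt - |effect| (capped to stay positive), with |effect| half-normal of
    scale ``effect_size_sd`` (per day). Growth rates scatter a few percent
    around the WT rate, which the fixed-t* readout must not confound.
    """
    if not (0 <= fraction_short <= 1 and 0 <= fraction_long <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if fraction_short + fraction_long > 1:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed, **cfg_overrides)
    n_short = int(round(n_strains * fraction_short))
    n_long = int(round(n_strains * fraction_long))
    classes = (["short"] * n_short + ["long"] * n_long
               + ["neutral"] * (n_strains - n_short - n_long))
    rng.shuffle(classes)
    truths = []
    for i, cls in enumerate(classes):
        if cls == "neutral":
            r = cfg.r_wt
        else:
            eff = abs(rng.normal(0.0, effect_size_sd))
            r = cfg.r_wt + eff if cls == "short" else max(cfg.r_wt - eff, 0.1 * cfg.r_wt)
        g = cfg.g_wt * float(np.clip(rng.normal(1.0, 0.03), 0.85, 1.15))
        truths.append(SimStrainTruth(
            strain_id=f"S{i + 1:04d}", death_rate_r=float(r),
            growth_rate_g=g, true_class=cls,
        ))
    return truths, cfg


def make_epistasis_scenario(n_genes: int = 12, n_modules: int = 2, seed: int = 0,
                            sigma: float = 0.01, n_reps: int = 2,
                            single_mean: float = 0.9, single_sd: float = 0.04):
    """Replicate-level scenario for the epistasis/network layers.

    Gene single-knockout lifespans scatter below 1 (mildly deleterious, as for
    autophagy genes). Pairs within a module combine by the min rule (the
    same-pathway pattern, positive epistasis under the multiplicative model);
    pairs across modules combine multiplicatively (truly neutral). Emits a
    replicate table in the epistasis-input schema plus the truth (module
    labels and true pooled values).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    modules = {g: f"M{i % n_modules + 1}" for i, g in enumerate(genes)}
    # singles are mildly deleterious (L < 1): the same-pathway min rule then
    # always yields positive epistasis under the multiplicative expectation
    true_L = {g: float(np.clip(rng.normal(single_mean, single_sd), 0.75, 0.97))
              for g in genes}
    rows = []
    for g in genes:
        for rep in range(n_reps):
            rows.append({"gene_x": g, "gene_y": "", "L": true_L[g] + rng.normal(0, sigma),
                         "se": sigma, "tag": f"rep{rep + 1}"})
    for i, gx in enumerate(genes):
        for gy in genes[i + 1:]:
            if modules[gx] == modules[gy]:
                lxy = min(true_L[gx], true_L[gy])
            else:
                lxy = true_L[gx] * true_L[gy]
            for rep in range(n_reps):
                rows.append({"gene_x": gx, "gene_y": gy,
                             "L": lxy + rng.normal(0, sigma), "se": sigma,
                             "tag": f"rep{rep + 1}"})
    replicates = pd.DataFrame(rows)
    truth = {"modules": modules, "true_L": true_L, "seed": int(seed)}
    return replicates, truth
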