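"""End-to-end orchestration: readings -> ratio points -> survival -> calls.

The heavy lifting lives in the stage modules; this module wires them together
on long-format tables (fast enough for whole simulated screens), carries the
run configuration, and writes a reproducible run directory with a SHA-256
manifest of every output.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plate_io, outgrowth, survival, screen_stats, synthetic_data, epistasis, gi_network

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables, serialized verbatim into every run directory."""

    outdir: str = "clscreen_run"
    seed: int = 0
    t_star: float = 10.0
    floor: float = -3.5
    ceiling: float = 2.5
    min_ages: int = 3
    method: str = "robust"
    batch_center: str = "median"
    lambda_wt: float = 21.7
    q_threshold: float = 0.05
    g_threshold_calls: float = 0.95
    g_threshold_enrich: float = 0.9
    ci: float = 0.95
    term_min: int = 5
    term_max: int = 60
    epistasis_model: str = "multiplicative"
    log_level: str = "INFO"
    # inputs; when readings/layout are absent a scenario is simulated
    readings: str | None = None
    layout: str | None = None
    go_mapping: str | None = None
    epistasis_replicates: str | None = None
    sim: dict = field(default_factory=lambda: {
        "n_strains": 140, "fraction_short": 0.072, "fraction_long": 0.068,
        "effect_size_sd": 0.01,
    })
    sim_epistasis: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ------------------------------------------------------- table-based stages

def fit_backgrounds_from_table(readings: pd.DataFrame, layout: pd.DataFrame):
    """Fit both channels' background models from the single-color control wells."""
    merged = readings.merge(layout[["plate_id", "well", "role"]],
                            on=["plate_id", "well"], how="left")
    rfp_only = merged[merged["role"] == "rfp_only"]
    cfp_only = merged[merged["role"] == "cfp_only"]
    bg_cfp = outgrowth.fit_background_arrays(rfp_only["od600"], rfp_only["cfp_raw"], "CFP")
    bg_rfp = outgrowth.fit_background_arrays(cfp_only["od600"], cfp_only["rfp_raw"], "RFP")
    return bg_rfp, bg_cfp


def ratio_points_table(readings: pd.DataFrame, layout: pd.DataFrame,
                       bg_rfp: outgrowth.BackgroundModel,
                       bg_cfp: outgrowth.BackgroundModel, *,
                       t_star: float = 10.0, floor: float = -3.5,
                       ceiling: float = 2.5,
                       max_extrapolation_h: float = 1.5) -> pd.DataFrame:
    """Vectorized equivalent of :func:`clscreen.outgrowth.ratio_points`.

    Corrects both channels in bulk, drops nonpositive-signal timepoints, and
    interpolates ln(R/C) at t* for every (well, age) of every mutant or
    WT-control well.
    """
    lay = layout[["plate_id", "well", "strain_id", "role", "batch_id"]]
    df = readings.merge(lay, on=["plate_id", "well"], how="left")
    df = df[df["role"].isin(["mutant", "wt_control"])].copy()
    df = df.sort_values(["plate_id", "well", "age_days", "time_h"], kind="mergesort")
    rfp = df["rfp_raw"].to_numpy() - bg_rfp.predict(df["od600"].to_numpy())
    cfp = df["cfp_raw"].to_numpy() - bg_cfp.predict(df["od600"].to_numpy())
    usable = (rfp > 0) & (cfp > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lnrc = np.where(usable, np.log(np.where(usable, rfp, 1.0))
                        - np.log(np.where(usable, cfp, 1.0)), np.nan)
    t = df["time_h"].to_numpy(dtype=float)
    keys = df[["plate_id", "well", "age_days"]].to_numpy(dtype=object)
    change = np.ones(len(df), dtype=bool)
    change[1:] = np.any(keys[1:] != keys[:-1], axis=1)
    starts = np.flatnonzero(change)
    bounds = np.append(starts, len(df))
    meta = df[["plate_id", "well", "strain_id", "role", "batch_id", "age_days"]].to_numpy(dtype=object)
    rows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        m = usable[s:e]
        plate, well, strain, role, batch, age = meta[s]
        if not m.any():
            rows.append((plate, well, strain, role, batch, age, np.nan,
                         outgrowth.QC_NONPOSITIVE))
            continue
        rp = outgrowth.interpolate_at_tstar(
            t[s:e][m], lnrc[s:e][m], t_star, floor=floor, ceiling=ceiling,
            max_extrapolation_h=max_extrapolation_h, strain_id=strain, age_days=age,
        )
        rows.append((plate, well, strain, role, batch, age, rp.ln_ratio, rp.qc))
    return pd.DataFrame(rows, columns=["plate_id", "well", "strain_id", "role",
                                       "batch_id", "age_days", "ln_ratio", "qc"])


def growth_table_from_readings(readings: pd.DataFrame, layout: pd.DataFrame, *,
                               age_days: float = 0.0,
                               window: tuple[float, float] = (2.0, 10.0)) -> pd.DataFrame:
    """Absolute and relative growth rates from the age-``age_days`` OD curves.

    The OD blank is estimated from blank wells where present; relative G is
    computed against the per-batch mean WT-control rate.
    """
    lay = layout[["plate_id", "well", "strain_id", "role", "batch_id"]]
    df = readings.merge(lay, on=["plate_id", "well"], how="left")
    df = df[df["age_days"] == age_days]
    blanks = df[df["role"] == "blank"]
    blank = float(blanks["od600"].mean()) if len(blanks) else 0.0
    rows = []
    for (plate, well), grp in df[df["role"].isin(["mutant", "wt_control"])].groupby(
            ["plate_id", "well"], sort=False):
        fit = outgrowth.fit_growth_rate(grp["time_h"], grp["od600"], window=window,
                                        blank=blank, strain_id=str(grp["strain_id"].iloc[0]))
        if fit is None:
            continue
        rows.append((plate, well, fit.strain_id, grp["role"].iloc[0],
                     grp["batch_id"].iloc[0], fit.rate_per_h, fit.se, fit.n_points))
    out = pd.DataFrame(rows, columns=["plate_id", "well", "strain_id", "role",
                                      "batch_id", "gr", "gr_se", "n_points"])
    if out.empty:
        out["G"] = []
        return out
    wt_mean = out[out["role"] == "wt_control"].groupby("batch_id")["gr"].mean()
    out["G"] = out["gr"] / out["batch_id"].map(wt_mean).to_numpy()
    return out


def analyze_screen(readings: pd.DataFrame, layout: pd.DataFrame, *,
                   t_star: float = 10.0, floor: float = -3.5, ceiling: float = 2.5,
                   min_ages: int = 3, method: str = "robust",
                   batch_center: str = "median", lambda_wt: float = 21.7,
                   q_threshold: float = 0.05, g_threshold: float = 0.95,
                   growth: pd.DataFrame | None = None,
                   estimate_growth: bool = False, call: bool = True) -> dict:
    """Run the full single-screen analysis on in-memory tables.

    Returns a dict with ratio_points, fits (batch-normalized), records
    (mutants), wt_records, calls (when ``call``), the background models, and
    the growth table used for G (externally supplied or OD-estimated).
    """
    bg_rfp, bg_cfp = fit_backgrounds_from_table(readings, layout)
    points = ratio_points_table(readings, layout, bg_rfp, bg_cfp,
                                t_star=t_star, floor=floor, ceiling=ceiling)
    fits = survival.fit_survival_table(points, method=method, min_ages=min_ages)
    fits = survival.normalize_batch(fits, center=batch_center)
    if growth is None and estimate_growth:
        growth = growth_table_from_readings(readings, layout)
    records_all = survival.to_lifespan(fits, lambda_wt=lambda_wt, growth=growth)
    records = records_all[records_all["role"] == "mutant"].reset_index(drop=True)
    wt_records = records_all[records_all["role"] == "wt_control"].reset_index(drop=True)
    out = {"ratio_points": points, "fits": fits, "records": records,
           "wt_records": wt_records, "bg_rfp": bg_rfp, "bg_cfp": bg_cfp,
           "growth": growth}
    if call:
        out["calls"] = screen_stats.call_phenotypes(
            records, wt_records, q_threshold=q_threshold, g_threshold=g_threshold)
    return out


# ------------------------------------------------------------- full pipeline

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every applicable stage, writing all outputs plus a manifest.

    Identical config + seed give byte-identical result tables. Any stage
    failure propagates with the stage name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    outputs: list[Path] = [outdir / "config.yaml"]

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- inputs: load or simulate
    if config.readings and config.layout:
        layout = _stage("load-layout", lambda: plate_io.read_layout(config.layout))
        readings = _stage("load-readings",
                          lambda: plate_io.read_readings_table(config.readings))
    else:
        def _simulate():
            truths, cfg = synthetic_data.make_screen_scenario(
                seed=config.seed, **config.sim)
            readings, layout, truth = synthetic_data.simulate_plate_set(
                truths, cfg, seed=config.seed)
            plate_io.write_frame(truth.truth_table(), outdir / "truth.tsv")
            outputs.append(outdir / "truth.tsv")
            return readings, layout
        readings, layout = _stage("simulate", _simulate)
    plate_io.write_readings(readings, outdir / "readings.tsv")
    plate_io.write_layout(layout, outdir / "layout.tsv")
    outputs += [outdir / "readings.tsv", outdir / "layout.tsv"]

    # --- outgrowth + survival + calls
    result = _stage("analyze", lambda: analyze_screen(
        readings, layout, t_star=config.t_star, floor=config.floor,
        ceiling=config.ceiling, min_ages=config.min_ages, method=config.method,
        batch_center=config.batch_center, lambda_wt=config.lambda_wt,
        q_threshold=config.q_threshold, g_threshold=config.g_threshold_calls,
        estimate_growth=True))
    plate_io.write_frame(result["ratio_points"], outdir / "ratio_points.tsv")
    outputs.append(outdir / "ratio_points.tsv")

    calls = result["calls"]
    res_table = calls.rename(columns={"half_life_days": "half_life_days"})
    plate_io.write_results(res_table, outdir / "survival.tsv")
    outputs.append(outdir / "survival.tsv")

    # --- enrichment (needs a gene->GO mapping)
    if config.go_mapping:
        def _enrich():
            mapping = pd.read_csv(config.go_mapping, sep="\t",
                                  names=["gene_id", "term_id"], comment="#")
            enr = screen_stats.go_enrichment(
                calls.rename(columns={"strain_id": "strain_id"}), mapping,
                min_n=config.term_min, max_n=config.term_max,
                g_min=config.g_threshold_enrich)
            plate_io.write_frame(enr, outdir / "enrichment.tsv")
            outputs.append(outdir / "enrichment.tsv")
        _stage("enrich", _enrich)

    # --- epistasis + network (from a replicate table, real or simulated)
    replicates = None
    if config.epistasis_replicates:
        replicates = _stage("load-replicates",
                            lambda: pd.read_csv(config.epistasis_replicates, sep="\t",
                                                comment="#"))
    elif config.sim_epistasis is not None:
        replicates, _ = synthetic_data.make_epistasis_scenario(
            seed=config.seed, **config.sim_epistasis)
    if replicates is not None:
        def _epistasis():
            scored = epistasis.score_table(replicates, model=config.epistasis_model,
                                           ci=config.ci)
            plate_io.write_epistasis(scored, outdir / "epistasis.tsv")
            outputs.append(outdir / "epistasis.tsv")
            mat = gi_network.epsilon_matrix(scored)
            clustering = gi_network.cluster_profiles(mat)
            labels_df = pd.DataFrame(
                sorted(clustering["labels"].items()), columns=["gene", "cluster"])
            plate_io.write_frame(labels_df, outdir / "clusters.tsv")
            outputs.append(outdir / "clusters.tsv")
            singles, _doubles = epistasis.pool_table(replicates)
            net = gi_network.build_network(
                scored, clustering["labels"],
                {g: wl.L for g, wl in singles.items()})
            gi_network.write_graphml(net, outdir / "network.graphml")
            gi_network.write_edgelist(net, outdir / "network_edges.tsv")
            outputs.extend([outdir / "network.graphml", outdir / "network_edges.tsv"])
        _stage("epistasis", _epistasis)

    manifest = {
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
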