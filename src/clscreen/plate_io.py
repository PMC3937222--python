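"""Tabular I/O with strict schemas for plate-reader CLS experiments.

All artifacts are tidy (long-format) delimited text: one reading per row,
delimiter auto-detected between tab and comma on read, always written as TSV
with a documented comment header. Ages are days since age zero (the day-5
post-inoculation origin of stationary phase), outgrowth times are hours post
inoculation, fluorescence is in arbitrary reader units.
"""
from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .outgrowth import OutgrowthCurve

log = logging.getLogger(__name__)

LAYOUT_COLUMNS = ["plate_id", "well", "strain_id", "fluorophore", "role", "batch_id"]
READING_COLUMNS = ["plate_id", "well", "age_days", "time_h", "rfp_raw", "cfp_raw", "od600"]
RESULT_COLUMNS = ["strain_id", "s_raw", "s_corr", "s_se", "n_ages", "L", "Z", "p",
                  "q", "class", "half_life_days", "G", "flags"]
EPISTASIS_COLUMNS = ["gene_x", "gene_y", "L_x", "se_x", "L_y", "se_y", "L_xy",
                     "se_xy", "eps", "se_eps", "model", "call", "direction"]

ROLES = {"mutant", "wt_control", "rfp_only", "cfp_only", "blank"}
FLUOROPHORES = {"RFP", "CFP"}
#: roles whose wells never produce strain-level results
NON_RESULT_ROLES = {"rfp_only", "cfp_only", "blank"}

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")

_HEADER_NOTE = (
    "# clscreen table; ages are days since age zero (day 5 post-inoculation); "
    "times are hours post outgrowth inoculation; missing values encoded as NA\n"
)


def normalize_well(well: str) -> str:
    """Normalize well labels to zero-padded form, e.g. ``a1`` -> ``A01``."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"malformed well label {well!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    raise ValueError(f"{path}: empty file")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_sep(path), comment="#",
                       na_values=["NA"], keep_default_na=True)


def _write_table(df: pd.DataFrame, path, columns) -> None:
    out = df.reindex(columns=columns)
    with open(path, "w") as fh:
        fh.write(_HEADER_NOTE)
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------- layouts

def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    """Check the layout schema and its invariants; returns a normalized copy."""
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout missing columns: {missing}")
    df = layout.loc[:, LAYOUT_COLUMNS].copy()
    df["well"] = df["well"].map(normalize_well)
    for col in ("plate_id", "batch_id", "role"):
        df[col] = df[col].astype(str)
    df["strain_id"] = df["strain_id"].fillna("").astype(str)
    df["fluorophore"] = df["fluorophore"].fillna("").astype(str)
    bad_roles = set(df["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"unknown roles in layout: {sorted(bad_roles)}")
    # blanks may leave the fluorophore unset; everything else must declare one
    fl = df["fluorophore"].fillna("")
    bad_fl = df.loc[(df["role"] != "blank") & ~fl.isin(FLUOROPHORES)]
    if len(bad_fl):
        raise ValueError(f"invalid fluorophore entries:\n{bad_fl.head()}")
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        raise ValueError(f"duplicate wells within plate:\n{df[dup].head()}")
    batches = df.groupby("batch_id")["role"].apply(lambda r: (r == "wt_control").sum())
    no_wt = batches[batches == 0]
    if len(no_wt):
        raise ValueError(f"batches without any wt_control well: {list(no_wt.index)}")
    return df


def read_layout(path) -> pd.DataFrame:
    return validate_layout(_read_table(path))


def write_layout(layout: pd.DataFrame, path) -> None:
    _write_table(validate_layout(layout), path, LAYOUT_COLUMNS)


# ---------------------------------------------------------------- readings

def validate_readings(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"readings missing columns: {missing}")
    out = df.loc[:, READING_COLUMNS].copy()
    out["plate_id"] = out["plate_id"].astype(str)
    out["well"] = out["well"].map(normalize_well)
    for col in ("age_days", "time_h", "rfp_raw", "cfp_raw", "od600"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    if (out["age_days"] < 0).any():
        raise ValueError("negative age_days in readings")
    if (out["time_h"] <= 0).any():
        raise ValueError("non-positive time_h in readings")
    dup = out.duplicated(subset=["plate_id", "well", "age_days", "time_h"])
    if dup.any():
        first = out[dup].iloc[0]
        raise ValueError(
            "duplicate reading for (plate, well, age, time) = "
            f"({first.plate_id}, {first.well}, {first.age_days}, {first.time_h})"
        )
    return out


def curves_from_readings(readings: pd.DataFrame, layout: pd.DataFrame):
    """Group validated reading rows into one :class:`OutgrowthCurve` per
    (plate, well, age).

    Returns ``(curves, report)`` where the report accounts for every input row:
    ``n_input == n_accepted + n_rejected``. Unknown wells are a hard error;
    curves whose times are not strictly increasing (duplicate times after
    sorting) are rejected with a logged reason.
    """
    readings = validate_readings(readings)
    layout = validate_layout(layout)
    lay = layout.set_index(["plate_id", "well"])
    known = set(lay.index)
    keys = set(zip(readings["plate_id"], readings["well"]))
    unknown = keys - known
    if unknown:
        raise ValueError(f"readings reference wells absent from layout: {sorted(unknown)[:5]}")

    curves, rejected = [], []
    n_accepted = 0
    readings = readings.sort_values(["plate_id", "well", "age_days", "time_h"])
    for (plate, well, age), grp in readings.groupby(["plate_id", "well", "age_days"], sort=False):
        t = grp["time_h"].to_numpy(dtype=float)
        meta = lay.loc[(plate, well)]
        if np.any(np.diff(t) <= 0):
            rejected.append({"plate_id": plate, "well": well, "age_days": age,
                             "reason": "non-monotone times"})
            log.warning("rejected curve %s/%s age %s: non-monotone times", plate, well, age)
            continue
        if grp[["rfp_raw", "cfp_raw", "od600"]].isna().any().any():
            rejected.append({"plate_id": plate, "well": well, "age_days": age,
                             "reason": "malformed numeric values"})
            continue
        curves.append(OutgrowthCurve(
            plate_id=plate, well=well, strain_id=meta["strain_id"],
            role=meta["role"], batch_id=meta["batch_id"], age_days=float(age),
            time_h=t, rfp_raw=grp["rfp_raw"].to_numpy(dtype=float),
            cfp_raw=grp["cfp_raw"].to_numpy(dtype=float),
            od600=grp["od600"].to_numpy(dtype=float),
        ))
        n_accepted += len(grp)
    n_rejected = len(readings) - n_accepted
    report = {"n_input": int(len(readings)), "n_accepted": int(n_accepted),
              "n_rejected": int(n_rejected), "rejected": rejected}
    return curves, report


def read_readings(path, layout: pd.DataFrame):
    """Read a readings table and group it into outgrowth curves (see
    :func:`curves_from_readings`)."""
    return curves_from_readings(_read_table(path), layout)


def write_readings(readings: pd.DataFrame, path) -> None:
    _write_table(validate_readings(readings), path, READING_COLUMNS)


def read_readings_table(path) -> pd.DataFrame:
    """Read a readings table without grouping (validated, long format)."""
    return validate_readings(_read_table(path))


# ---------------------------------------------------------------- results

def write_results(records: pd.DataFrame, path) -> None:
    """Write per-strain lifespan results with a deterministic column order.

    Missing values (e.g. an undefined half-life when s >= r_wt) are ``NA``.
    An empty collection yields a header-only file.
    """
    _write_table(records, path, RESULT_COLUMNS)


def read_results(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results missing columns: {missing}")
    out = df.loc[:, RESULT_COLUMNS]
    out["flags"] = out["flags"].fillna("").astype(str)  # empty flag set, not NA
    return out


def write_epistasis(records: pd.DataFrame, path) -> None:
    _write_table(records, path, EPISTASIS_COLUMNS)


def read_epistasis(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in EPISTASIS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epistasis table missing columns: {missing}")
    out = df.loc[:, EPISTASIS_COLUMNS]
    out["direction"] = out["direction"].fillna("").astype(str)
    return out


def write_frame(df: pd.DataFrame, path) -> None:
    """Write an arbitrary intermediate table (e.g. ratio points) as TSV."""
    _write_table(df, path, list(df.columns))


def read_frame(path) -> pd.DataFrame:
    return _read_table(path)
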