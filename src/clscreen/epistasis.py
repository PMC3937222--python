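"""Lifespan epistasis: replicate pooling, interaction scoring, orientation.

Replicate lifespans (L, sigma) are pooled by inverse-variance weighting.
Genetic interaction between genes x and y is the deviation of the pooled
double-knockout lifespan from a neutral expectation built from the singles:

* multiplicative (default): eps = L_xy - L_x * L_y
* additive:                 eps = L_xy - (L_x + L_y - 1)

with first-order (delta-method) error propagation; a pair is called positive
or negative when |eps| exceeds the normal critical value at the configured
confidence level times sigma_eps. The two models differ identically by
(L_x - 1)(L_y - 1), which is why an additive definition biases deleterious
pairs toward positive epistasis. Significant positive interactions may be
oriented from the larger to the smaller single-knockout effect when the two
singles differ significantly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screen_stats import rank_sum_p

log = logging.getLogger(__name__)

MODEL_MULTIPLICATIVE = "multiplicative"
MODEL_ADDITIVE = "additive"

CALL_POSITIVE = "positive"
CALL_NEGATIVE = "negative"
CALL_NEUTRAL = "neutral"


@dataclass
class WeightedLifespan:
    """Inverse-variance pooled lifespan for a gene or gene pair."""

    ident: str
    L: float
    sigma: float
    n_replicates: int
    replicates: list = field(default_factory=list)  # (L_i, sigma_i, weight_i)


@dataclass
class EpistasisRecord:
    gene_x: str
    gene_y: str
    L_x: float
    sigma_x: float
    L_y: float
    sigma_y: float
    L_xy: float
    sigma_xy: float
    epsilon: float
    sigma_eps: float
    model: str
    call: str
    direction: str | None = None   # gene the arrow points *to* (smaller effect)


def pool_replicates(replicates, ident: str = "") -> WeightedLifespan:
    """Error-weighted average of replicate (L, sigma) pairs.

    Weights are w_i = 1/sigma_i^2; the pooled error is (sum w_i)^(-1/2), so
    pooling k identical replicates shrinks sigma by sqrt(k). Any nonpositive
    sigma is an error (a replicate without an error estimate cannot be
    weighted).
    """
    reps = [(float(L), float(s)) for L, s in replicates]
    if not reps:
        raise ValueError("no replicates to pool")
    if any(s <= 0 for _, s in reps):
        raise ValueError(f"nonpositive replicate error for {ident!r}")
    w = np.array([1.0 / (s * s) for _, s in reps])
    L = np.array([L for L, _ in reps])
    wsum = float(w.sum())
    pooled_L = float((w * L).sum() / wsum)
    pooled_sigma = wsum ** -0.5
    return WeightedLifespan(ident=ident, L=pooled_L, sigma=pooled_sigma,
                            n_replicates=len(reps),
                            replicates=[(li, si, wi / wsum) for (li, si), wi in zip(reps, w)])


def pool_table(replicates: pd.DataFrame) -> tuple[dict, dict]:
    """Pool a replicate table into per-gene singles and per-pair doubles.

    The table has columns gene_x, gene_y, L, se (and optionally tag); rows
    with an empty/missing gene_y are single knockouts. Marker-swap and
    single-knockout replicates are treated identically. Returns
    ``(singles, doubles)`` keyed by gene and by the sorted (x, y) tuple.
    """
    df = replicates.copy()
    df["gene_y"] = df["gene_y"].fillna("").astype(str)
    df["gene_x"] = df["gene_x"].astype(str)
    singles: dict[str, WeightedLifespan] = {}
    doubles: dict[tuple, WeightedLifespan] = {}
    single_rows = df[df["gene_y"].str.strip() == ""]
    for gene, grp in single_rows.groupby("gene_x"):
        singles[gene] = pool_replicates(zip(grp["L"], grp["se"]), ident=gene)
    double_rows = df[df["gene_y"].str.strip() != ""]
    if len(double_rows):
        key = [tuple(sorted(p)) for p in zip(double_rows["gene_x"], double_rows["gene_y"])]
        for pair, grp in double_rows.groupby(pd.Series(key, index=double_rows.index)):
            doubles[pair] = pool_replicates(zip(grp["L"], grp["se"]),
                                            ident="|".join(pair))
    return singles, doubles


def score_epistasis(x: WeightedLifespan, y: WeightedLifespan, xy: WeightedLifespan,
                    model: str = MODEL_MULTIPLICATIVE, ci: float = 0.95,
                    use_t: bool = False) -> EpistasisRecord:
    """Score one pair against the chosen neutral model.

    sigma_eps is first-order propagation:
    multiplicative  sqrt(sigma_xy^2 + (L_y sigma_x)^2 + (L_x sigma_y)^2)
    additive        sqrt(sigma_xy^2 + sigma_x^2 + sigma_y^2)
    The call is positive/negative when |eps| > z * sigma_eps at the ``ci``
    level (normal z by default; a t quantile on the pooled replicate count is
    available via ``use_t``).
    """
    if model == MODEL_MULTIPLICATIVE:
        eps = xy.L - x.L * y.L
        sigma_eps = float(np.sqrt(xy.sigma ** 2 + (y.L * x.sigma) ** 2
                                  + (x.L * y.sigma) ** 2))
    elif model == MODEL_ADDITIVE:
        eps = xy.L - (x.L + y.L - 1.0)
        sigma_eps = float(np.sqrt(xy.sigma ** 2 + x.sigma ** 2 + y.sigma ** 2))
    else:
        raise ValueError(f"unknown neutral model {model!r}")
    if use_t:
        dof = max(x.n_replicates + y.n_replicates + xy.n_replicates - 3, 1)
        crit = float(stats.t.ppf(0.5 + ci / 2.0, dof))
    else:
        crit = float(stats.norm.ppf(0.5 + ci / 2.0))
    if sigma_eps > 0 and abs(eps) > crit * sigma_eps:
        call = CALL_POSITIVE if eps > 0 else CALL_NEGATIVE
    else:
        call = CALL_NEUTRAL
    return EpistasisRecord(
        gene_x=x.ident, gene_y=y.ident, L_x=x.L, sigma_x=x.sigma,
        L_y=y.L, sigma_y=y.sigma, L_xy=xy.L, sigma_xy=xy.sigma,
        epsilon=float(eps), sigma_eps=sigma_eps, model=model, call=call,
    )


def orient_interaction(record: EpistasisRecord, z: float = 1.96) -> str | None:
    """Direction for a significant positive interaction.

    The single-knockout effect is |L - 1|. When the two singles differ
    significantly (|L_x - L_y| > z * sqrt(sigma_x^2 + sigma_y^2); both
    deviations are near-linear in L), the arrow points from the larger-effect
    gene to the smaller-effect gene. Returns the *target* gene, or None when
    undirected. Calling on a non-positive record yields None and a log entry.
    """
    if record.call != CALL_POSITIVE:
        log.info("orientation requested for non-positive pair %s-%s",
                 record.gene_x, record.gene_y)
        return None
    se = np.sqrt(record.sigma_x ** 2 + record.sigma_y ** 2)
    if se <= 0 or abs(record.L_x - record.L_y) <= z * se:
        return None
    e_x, e_y = abs(record.L_x - 1.0), abs(record.L_y - 1.0)
    target = record.gene_y if e_x > e_y else record.gene_x
    record.direction = target
    return target


def score_table(replicates: pd.DataFrame, model: str = MODEL_MULTIPLICATIVE,
                ci: float = 0.95, orient: bool = True,
                use_t: bool = False) -> pd.DataFrame:
    """Pool a replicate table and score every double-knockout pair.

    Pairs whose singles were not measured are skipped with a warning. Output
    columns follow the ``plate_io`` epistasis schema.
    """
    singles, doubles = pool_table(replicates)
    rows = []
    for (gx, gy), xy in sorted(doubles.items()):
        if gx not in singles or gy not in singles:
            log.warning("pair (%s, %s) lacks a pooled single knockout; skipped", gx, gy)
            continue
        rec = score_epistasis(singles[gx], singles[gy], xy, model=model,
                              ci=ci, use_t=use_t)
        direction = orient_interaction(rec) if (orient and rec.call == CALL_POSITIVE) else None
        rows.append({"gene_x": gx, "gene_y": gy, "L_x": rec.L_x, "se_x": rec.sigma_x,
                     "L_y": rec.L_y, "se_y": rec.sigma_y, "L_xy": rec.L_xy,
                     "se_xy": rec.sigma_xy, "eps": rec.epsilon,
                     "se_eps": rec.sigma_eps, "model": rec.model, "call": rec.call,
                     "direction": direction if direction else ""})
    return pd.DataFrame(rows, columns=["gene_x", "gene_y", "L_x", "se_x", "L_y",
                                       "se_y", "L_xy", "se_xy", "eps", "se_eps",
                                       "model", "call", "direction"])


def epistasis_spectrum(records: pd.DataFrame, subsets: dict | None = None) -> dict:
    """Summarize the interaction spectrum.

    Returns counts and fractions by call, overall and per named subset of
    pairs (each subset a set of sorted (gene_x, gene_y) tuples, e.g.
    core-autophagy pairs or physically interacting pairs). Each subset is also
    compared to its complement by a rank-sum test on eps (does the subset sit
    higher on the epistasis scale?).
    """
    if not len(records):
        raise ValueError("no epistasis records")
    def _fractions(df):
        n = len(df)
        counts = df["call"].value_counts()
        return {
            "n": int(n),
            "n_positive": int(counts.get(CALL_POSITIVE, 0)),
            "n_negative": int(counts.get(CALL_NEGATIVE, 0)),
            "n_neutral": int(counts.get(CALL_NEUTRAL, 0)),
            "frac_positive": float(counts.get(CALL_POSITIVE, 0)) / n,
            "frac_negative": float(counts.get(CALL_NEGATIVE, 0)) / n,
            "frac_neutral": float(counts.get(CALL_NEUTRAL, 0)) / n,
            "median_eps": float(np.median(records_eps(df))),
        }
    def records_eps(df):
        return np.asarray(df["eps"], dtype=float)

    summary = {"overall": _fractions(records)}
    if subsets:
        pair_key = [tuple(sorted(p)) for p in zip(records["gene_x"], records["gene_y"])]
        keys = pd.Series(pair_key, index=records.index)
        for name, pairs in subsets.items():
            inside = records[keys.isin({tuple(sorted(p)) for p in pairs})]
            outside = records[~keys.isin({tuple(sorted(p)) for p in pairs})]
            entry = _fractions(inside) if len(inside) else {"n": 0}
            if len(inside) and len(outside):
                entry["ranksum_p_vs_rest"] = rank_sum_p(records_eps(inside),
                                                        records_eps(outside))
            summary[name] = entry
    return summary
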