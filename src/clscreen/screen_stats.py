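"""Screen-level statistics: phenotype calls, comparisons, GO enrichment, CFU.

Hit calling follows the screen's recipe: each knockout's relative lifespan L
gets a Z-score against the spread of the wild-type replicate L values, a
two-tailed normal p-value, and a Benjamini-Hochberg q-value; significant
phenotypes use q < 0.05, and short-lived calls with a marked growth defect
(G below threshold) are flagged as non-specific. Functional enrichment tests
each GO term's L values against the entire filtered data set with a two-sided
Wilcoxon rank-sum test (exact enumeration for small samples, asymptotic with
tie correction otherwise).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CLASS_SHORT = "short"
CLASS_LONG = "long"
CLASS_NEUTRAL = "neutral"

#: exact rank-sum enumeration limits (beyond these the normal approximation
#: with tie correction is used)
EXACT_MAX_POOLED = 50
EXACT_MAX_SMALLER = 25


# ------------------------------------------------------------- rank-sum test

def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p for samples ``x`` vs ``y``.

    Small samples (pooled size <= 50, smaller sample <= 25) use exact
    enumeration of the permutation distribution of the rank sum, computed by
    dynamic programming over doubled midranks so that ties are handled
    exactly. Larger samples use the asymptotic Mann-Whitney test with tie
    correction. The two-sided p is 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    if n + m <= EXACT_MAX_POOLED and min(n, m) <= EXACT_MAX_SMALLER:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum_p(x, y) -> float:
    pooled = np.concatenate([x, y])
    n = x.size
    ranks = stats.rankdata(pooled)          # midranks; ties -> half-integers
    d = np.rint(2.0 * ranks).astype(np.int64)  # doubled midranks are integers
    obs = int(d[:n].sum())
    # distribution of the doubled rank sum over all C(N, n) subsets
    max_sum = int(np.sort(d)[-n:].sum())
    dp = np.zeros((n + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for val in d:
        for j in range(n, 0, -1):
            dp[j, val:] += dp[j - 1, : max_sum + 1 - val]
    dist = dp[n]
    total = dist.sum()
    p_le = dist[: obs + 1].sum() / total
    p_ge = dist[obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ------------------------------------------------------------- hit calling

def call_phenotypes(records: pd.DataFrame, wt_records: pd.DataFrame,
                    q_threshold: float = 0.05, g_threshold: float = 0.95) -> pd.DataFrame:
    """Assign Z, p, q and a lifespan class to every measured knockout.

    Z = (L - 1) / sd(WT L), with the WT standard deviation taken about the WT
    pool's own mean (robust to residual miscentering after batch
    normalization). Two-tailed normal p-values feed Benjamini-Hochberg FDR;
    class follows the sign of L - 1 among q < ``q_threshold``. Short-lived
    calls with G < ``g_threshold`` are flagged ``growth_filtered`` (their
    short survival may be a general growth defect); long-lived calls are never
    growth-filtered. ``specific`` marks significant calls surviving the filter.
    """
    wt_L = np.asarray(wt_records["L"], dtype=float)
    wt_L = wt_L[np.isfinite(wt_L)]
    if wt_L.size < 30:
        raise ValueError(f"need >=30 WT replicate L values, got {wt_L.size}")
    sd = float(np.std(wt_L, ddof=1))
    if sd <= 0:
        raise ValueError("degenerate WT pool (zero spread)")
    out = records.copy()
    L = np.asarray(out["L"], dtype=float)
    out["Z"] = (L - 1.0) / sd
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["Z"]))
    finite = np.isfinite(out["p"].to_numpy())
    q = np.full(len(out), np.nan)
    if finite.sum():
        q[finite] = multipletests(out.loc[finite, "p"], method="fdr_bh")[1]
    out["q"] = q
    significant = out["q"] < q_threshold
    out["class"] = np.where(~significant, CLASS_NEUTRAL,
                            np.where(L < 1.0, CLASS_SHORT, CLASS_LONG))
    G = np.asarray(out["G"], dtype=float) if "G" in out.columns else np.full(len(out), np.nan)
    out["growth_filtered"] = (out["class"] == CLASS_SHORT) & np.isfinite(G) & (G < g_threshold)
    out["specific"] = significant & ~out["growth_filtered"]
    out.attrs["wt_sd"] = sd
    out.attrs["n_wt"] = int(wt_L.size)
    return out


def check_wt_normality(wt_L, min_expected: int = 5) -> float:
    """Chi-square goodness-of-fit p-value of the WT L pool against a normal.

    Equal-probability bins under the fitted normal (sample mean/SD) with at
    least ``min_expected`` expected counts per bin; degrees of freedom are
    reduced by the two estimated parameters. A diagnostic gate only - a small
    p warns that the Z-score machinery's normality assumption is shaky.
    """
    x = np.asarray(wt_L, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 20:
        raise ValueError("need >=20 WT values for the normality check")
    k = int(max(4, min(n // min_expected, 30)))
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, k + 1), loc=mean, scale=sd)
    obs, _ = np.histogram(x, bins=edges)
    expected = n / k
    statistic = float(((obs - expected) ** 2 / expected).sum())
    dof = k - 1 - 2
    return float(stats.chi2.sf(statistic, dof))


def compare_screens(a: pd.DataFrame, b: pd.DataFrame,
                    method: str = "pearson"):
    """Correlate L between two screens over their shared strains.

    Supports replicate, dye-swap, aeration and reference-strain comparisons;
    Spearman is the rank-based choice for reference-strain sensitivity.
    Returns ``(r, paired)`` where ``paired`` has columns strain_id, L_a, L_b.
    """
    pa = a.groupby("strain_id")["L"].mean()
    pb = b.groupby("strain_id")["L"].mean()
    shared = pa.index.intersection(pb.index)
    if len(shared) < 10:
        raise ValueError(f"need >=10 shared strains, got {len(shared)}")
    paired = pd.DataFrame({"strain_id": shared, "L_a": pa[shared].to_numpy(),
                           "L_b": pb[shared].to_numpy()})
    if method == "pearson":
        r = stats.pearsonr(paired["L_a"], paired["L_b"]).statistic
    elif method == "spearman":
        r = stats.spearmanr(paired["L_a"], paired["L_b"]).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), paired


def confirm_in_condition(primary_calls: pd.DataFrame, second: pd.DataFrame,
                         second_wt: pd.DataFrame, ci: float = 0.95):
    """Confirm primary short/long calls in a second aging condition.

    A call is confirmed when its second-condition L escapes the central
    ``ci`` interval of the second condition's WT replicate distribution on the
    matching side (below for short, above for long). Returns the per-strain
    table, per-class confirmation fractions, and the rank-sum p comparing the
    second-condition L distributions of the primary short vs long sets.
    """
    wt_L = np.asarray(second_wt["L"], dtype=float)
    wt_L = wt_L[np.isfinite(wt_L)]
    if wt_L.size < 10:
        raise ValueError("need >=10 WT replicates in the second condition")
    alpha = 1.0 - ci
    lo, hi = np.quantile(wt_L, [alpha / 2.0, 1.0 - alpha / 2.0])
    hits = primary_calls[primary_calls["class"].isin([CLASS_SHORT, CLASS_LONG])]
    second_L = second.groupby("strain_id")["L"].mean()
    rows = []
    for row in hits[["strain_id", "class"]].to_dict("records"):
        L2 = second_L.get(row["strain_id"], np.nan)
        if not np.isfinite(L2):
            continue
        confirmed = (L2 < lo) if row["class"] == CLASS_SHORT else (L2 > hi)
        rows.append({"strain_id": row["strain_id"], "class": row["class"],
                     "L_second": float(L2), "confirmed": bool(confirmed)})
    table = pd.DataFrame(rows)
    fractions = {}
    for cls in (CLASS_SHORT, CLASS_LONG):
        sub = table[table["class"] == cls] if len(table) else table
        fractions[cls] = float(sub["confirmed"].mean()) if len(sub) else np.nan
    p_classes = np.nan
    if len(table):
        s = table.loc[table["class"] == CLASS_SHORT, "L_second"]
        l = table.loc[table["class"] == CLASS_LONG, "L_second"]
        if len(s) and len(l):
            p_classes = rank_sum_p(s.to_numpy(), l.to_numpy())
    return table, fractions, float(p_classes)


# ------------------------------------------------------------- GO enrichment

def go_enrichment(records: pd.DataFrame, mapping: pd.DataFrame,
                  min_n: int = 5, max_n: int = 60, g_min: float = 0.9,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-GO-term skew of relative lifespan vs the whole data set.

    Genes require a measured L and relative growth G > ``g_min`` (so general
    growth defects do not masquerade as survival biology). Each qualifying
    term's L values are rank-sum tested two-sided against the *entire*
    filtered data set (term genes included in the background, matching the
    screen's definition). Terms outside [min_n, max_n] measured genes are
    skipped and counted in ``attrs['n_skipped_size']``.
    """
    if not len(mapping):
        raise ValueError("empty gene->term mapping")
    rec = records.copy()
    G = np.asarray(rec["G"], dtype=float) if "G" in rec.columns else np.full(len(rec), np.nan)
    keep = np.isfinite(np.asarray(rec["L"], dtype=float))
    keep &= np.where(np.isfinite(G), G > g_min, True)
    rec = rec[keep]
    L_of = rec.groupby("strain_id")["L"].mean()
    background = L_of.to_numpy()
    bg_median = float(np.median(background))
    rows, n_skipped = [], 0
    for term, genes in mapping.groupby("term_id")["gene_id"]:
        vals = L_of.reindex(genes.unique()).dropna()
        if not (min_n <= len(vals) <= max_n):
            n_skipped += 1
            continue
        med = float(np.median(vals))
        p = rank_sum_p(vals.to_numpy(), background)
        rows.append({"term_id": term, "n_genes": int(len(vals)), "median_L": med,
                     "p": p, "direction": CLASS_LONG if med > bg_median else CLASS_SHORT,
                     "significant": p < alpha})
    out = pd.DataFrame(rows, columns=["term_id", "n_genes", "median_L", "p",
                                      "direction", "significant"])
    out.attrs["n_skipped_size"] = n_skipped
    out.attrs["n_background"] = int(background.size)
    return out


# ------------------------------------------------------------- CFU curves

def cfu_survival_curve(counts: pd.DataFrame, t0_day: float = 4.0) -> pd.DataFrame:
    """Percent-survival curve from colony-forming-unit counts.

    ``counts`` has columns day, replicate, cfu. Each replicate is normalized
    to 100% at ``t0_day``; the summary reports the across-replicate mean and
    SEM (sd/sqrt(n)) per day.
    """
    required = {"day", "replicate", "cfu"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    pieces = []
    for rep, grp in counts.groupby("replicate"):
        base = grp.loc[grp["day"] == t0_day, "cfu"]
        if base.empty:
            raise ValueError(f"replicate {rep!r} has no count at day {t0_day}")
        b = float(base.iloc[0])
        if b <= 0:
            raise ValueError(f"replicate {rep!r} has nonpositive count at day {t0_day}")
        g = grp.copy()
        g["percent"] = 100.0 * g["cfu"] / b
        pieces.append(g)
    per_rep = pd.concat(pieces, ignore_index=True)
    summary = (per_rep.groupby("day")["percent"]
               .agg(mean="mean", sd="std", n="count").reset_index())
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    return summary[["day", "mean", "sem", "n"]]
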