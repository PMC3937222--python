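"""Genetic-interaction profiles, hierarchical clustering, and the GI network.

Genes sharing a pathway show similar quantitative interaction patterns across
partners, so genes are clustered by the correlation of their raw epsilon
profiles: the distance between two genes is 1 - Spearman rho over the
partners both profiles share (self and mutual entries excluded; rank
correlation is robust to the strong outliers at both ends of the epsilon
scale). Complete-linkage merging and a height or k cut give module labels.
Significant interactions plus the labels form a network whose edges carry the
epsilon value, its sign, and optional directionality; module-level enrichment
of positive interactions is assessed with Fisher's exact test.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .epistasis import CALL_NEUTRAL, CALL_POSITIVE

log = logging.getLogger(__name__)

#: default dendrogram cut, as a fraction of the maximum merge height
DEFAULT_CUT_FRACTION = 0.7
#: minimum shared partners for a defined profile correlation
MIN_SHARED_PARTNERS = 3


def epsilon_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Symmetric gene x gene matrix of raw epsilon values.

    Missing (untested) pairs stay NaN; the diagonal is masked (a gene has no
    interaction with itself).
    """
    genes = sorted(set(records["gene_x"]) | set(records["gene_y"]))
    mat = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    for gx, gy, eps in zip(records["gene_x"], records["gene_y"], records["eps"]):
        mat.loc[gx, gy] = eps
        mat.loc[gy, gx] = eps
    np.fill_diagonal(mat.values, np.nan)
    return mat


def profile_distances(matrix: pd.DataFrame,
                      min_shared: int = MIN_SHARED_PARTNERS) -> np.ndarray:
    """Condensed pairwise-complete Spearman distance between gene profiles.

    For genes i and j the profiles are compared over partners where both have
    a measured epsilon, excluding i and j themselves (the self column is
    undefined and the mutual entry would let a single pair dominate). Fewer
    than ``min_shared`` common partners make the distance undefined - an
    error naming the pair, since imputing would fabricate rank structure.
    """
    genes = list(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    n = len(genes)
    if n < 3:
        raise ValueError("need >=3 genes to cluster profiles")
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(vals[i]) & np.isfinite(vals[j])
            mask[i] = mask[j] = False
            if mask.sum() < min_shared:
                raise ValueError(
                    f"profiles of {genes[i]} and {genes[j]} share only "
                    f"{int(mask.sum())} partners (< {min_shared})"
                )
            rho = stats.spearmanr(vals[i, mask], vals[j, mask]).statistic
            if not np.isfinite(rho):  # constant profile: no rank structure
                rho = 0.0
            out.append(1.0 - rho)
    return np.asarray(out)


def cluster_profiles(matrix: pd.DataFrame, linkage: str = "complete",
                     cut_height: float | None = None, k: int | None = None,
                     min_shared: int = MIN_SHARED_PARTNERS) -> dict:
    """Hierarchically cluster genes by their epsilon profiles.

    Returns a dict with the gene order, the condensed distances, the linkage
    matrix ``Z``, and integer cluster ``labels`` from the requested cut
    (``k`` clusters, or a distance ``cut_height``; default is a height cut at
    0.7 x the maximum merge height).
    """
    genes = list(matrix.index)
    dist = profile_distances(matrix, min_shared=min_shared)
    Z = hierarchy.linkage(dist, method=linkage)
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        height = cut_height if cut_height is not None \
            else DEFAULT_CUT_FRACTION * float(Z[:, 2].max())
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    return {"genes": genes, "distances": dist, "linkage": Z,
            "labels": {g: int(l) for g, l in zip(genes, labels)}}


def build_network(records: pd.DataFrame, labels: dict | None = None,
                  singles: dict | None = None) -> nx.Graph:
    """Build the GI network from scored records.

    Nodes carry cluster labels (and single-knockout L where supplied); edges
    exist only for significant calls and carry epsilon, its error, the call
    sign, and - for oriented positive interactions - the target gene. Edge
    count equals the count of significant records; (x, y)/(y, x) duplicates
    collapse onto one undirected edge.
    """
    G = nx.Graph()
    genes = sorted(set(records["gene_x"]) | set(records["gene_y"]))
    labels = labels or {}
    singles = singles or {}
    for g in genes:
        if labels and g not in labels:
            log.warning("gene %s has no cluster label", g)
        attrs = {"cluster": int(labels.get(g, -1))}
        if g in singles:
            attrs["L"] = float(singles[g])
        G.add_node(g, **attrs)
    sig = records[records["call"] != CALL_NEUTRAL]
    for row in sig.to_dict("records"):
        u, v = sorted((row["gene_x"], row["gene_y"]))
        direction = row.get("direction", "") or ""
        G.add_edge(u, v, eps=float(row["eps"]), se_eps=float(row["se_eps"]),
                   call=row["call"], sign=1 if row["call"] == CALL_POSITIVE else -1,
                   directed=bool(direction), target=str(direction))
    return G


def module_positive_enrichment(records: pd.DataFrame, labels: dict,
                               module: int) -> float:
    """One-sided Fisher exact p for excess positive interactions inside a module.

    Contingency over all scored pairs: (within-module vs not) x (positive call
    vs not). Tests whether genes of one cluster interact positively with each
    other more often than the rest of the map does.
    """
    inside = np.array([
        labels.get(x) == module and labels.get(y) == module
        for x, y in zip(records["gene_x"], records["gene_y"])
    ])
    positive = (records["call"] == CALL_POSITIVE).to_numpy()
    a = int(np.sum(inside & positive))
    b = int(np.sum(inside & ~positive))
    c = int(np.sum(~inside & positive))
    d = int(np.sum(~inside & ~positive))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def write_edgelist(G: nx.Graph, path) -> None:
    rows = [{"gene_x": u, "gene_y": v, **data} for u, v, data in G.edges(data=True)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
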