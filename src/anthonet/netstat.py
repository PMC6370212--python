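"""Transcript-metabolite correlation networks and node-strength statistics.

All feature pairs (gene-gene, metabolite-metabolite, gene-metabolite) are
correlated across samples with Pearson's rho; two-sided p-values come from
the exact t transform t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of
freedom.  Pairs with p <= alpha form the significant set from which the
network statistics derive:

* node strength ns(i): the mean of |rho| over node i's significant partners
  (nodes with no significant partner get ns = 0);
* network strength NS: the arithmetic mean of all node strengths.

The display threshold (|rho| >= 0.65 by default) only filters the *drawn*
edge list; ns and NS always use the full significant set.  The |rho|
convention makes both statistics live in [0, 1]; a flag switches to signed
rho, and another disables the significance filter (then ns estimates the
unconditional mean |rho| of a node).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "NetworkSummary",
    "correlation_matrix",
    "node_strength",
    "network_strength",
    "build_network",
    "significance_threshold",
]


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with a significance mask."""

    features: list[str]
    rho: pd.DataFrame  # symmetric, diagonal 1
    pval: pd.DataFrame  # symmetric, diagonal 0
    significant: pd.DataFrame  # boolean, diagonal False, p <= alpha
    n_samples: int
    alpha: float
    feature_types: pd.Series | None = None  # e.g. "transcript" / "metabolite"


@dataclass
class NetworkSummary:
    """Edge list above the display threshold plus ns/NS statistics."""

    edges: pd.DataFrame  # columns: source, target, rho
    ns: pd.Series  # per-node strength
    NS: float
    display_threshold: float


def correlation_matrix(
    data: pd.DataFrame,
    alpha: float = 0.05,
    feature_types: pd.Series | None = None,
) -> CorrelationResult:
    """Pearson rho/p matrices for a feature x sample data frame.

    Needs at least 3 samples (the t test has n-2 df).  Constant features are
    dropped with a warning — their correlation is undefined.
    """
    n = data.shape[1]
    if n < 3:
        raise ValueError(f"correlation needs >= 3 samples, got {n}")
    values = data.astype(float)
    constant = values.std(axis=1, ddof=0) == 0
    if constant.any():
        dropped = sorted(values.index[constant])
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        values = values.loc[~constant]
    if len(values) < 2:
        raise ValueError("need at least 2 non-constant features")
    features = list(values.index)

    rho = np.corrcoef(values.to_numpy())
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pval[np.isnan(pval)] = 0.0  # |rho| == 1 -> t == inf -> p == 0
    np.fill_diagonal(pval, 0.0)
    significant = pval <= alpha
    np.fill_diagonal(significant, False)

    if feature_types is not None:
        feature_types = feature_types.reindex(features)
    return CorrelationResult(
        features=features,
        rho=pd.DataFrame(rho, index=features, columns=features),
        pval=pd.DataFrame(pval, index=features, columns=features),
        significant=pd.DataFrame(significant, index=features, columns=features),
        n_samples=n,
        alpha=alpha,
        feature_types=feature_types,
    )


def node_strength(
    cr: CorrelationResult,
    significant_only: bool = True,
    absolute: bool = True,
) -> pd.Series:
    """Per-node mean correlation over off-diagonal partners.

    Default: mean |rho| over the node's significant pairs (0 when it has
    none).  ``significant_only=False`` averages over all partners, which is
    the unbiased estimator of a node's unconditional mean |rho|;
    ``absolute=False`` averages signed rho.
    """
    rho = cr.rho.to_numpy().copy()
    if absolute:
        rho = np.abs(rho)
    mask = (
        cr.significant.to_numpy()
        if significant_only
        else ~np.eye(len(cr.features), dtype=bool)
    )
    counts = mask.sum(axis=1)
    sums = np.where(mask, rho, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ns = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return pd.Series(ns, index=cr.features, name="ns")


def network_strength(ns: pd.Series | np.ndarray | list[float]) -> float:
    """Arithmetic mean of the node strengths."""
    arr = np.asarray(ns, dtype=float)
    if arr.size == 0:
        raise ValueError("network strength of an empty node set is undefined")
    return float(arr.mean())


def build_network(
    cr: CorrelationResult,
    display_threshold: float = 0.65,
    significant_only: bool = True,
    absolute: bool = True,
) -> NetworkSummary:
    """Edge list at the display threshold plus ns/NS.

    Edges are the significant pairs with |rho| >= threshold, each carrying
    the signed rho (anticorrelations draw as negative edges); ns/NS are
    computed from *all* significant pairs regardless of the threshold.
    Edge order is deterministic: lexicographic by (source, target).
    """
    ns = node_strength(cr, significant_only=significant_only, absolute=absolute)
    rows = []
    feats = cr.features
    rho = cr.rho.to_numpy()
    sig = cr.significant.to_numpy()
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if sig[i, j] and abs(rho[i, j]) >= display_threshold:
                rows.append((feats[i], feats[j], float(rho[i, j])))
    rows.sort(key=lambda r: (r[0], r[1]))
    edges = pd.DataFrame(rows, columns=["source", "target", "rho"])
    return NetworkSummary(
        edges=edges,
        ns=ns,
        NS=network_strength(ns),
        display_threshold=display_threshold,
    )


def to_graphml(cr: CorrelationResult, net: NetworkSummary) -> nx.Graph:
    """NetworkX graph with ns and feature-type node attributes."""
    g = nx.Graph()
    for feat in cr.features:
        attrs = {"ns": float(net.ns[feat])}
        if cr.feature_types is not None and feat in cr.feature_types.index:
            ftype = cr.feature_types[feat]
            if pd.notna(ftype):
                attrs["feature_type"] = str(ftype)
        g.add_node(feat, **attrs)
    for row in net.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, rho=float(row.rho))
    return g


def significance_threshold(n_samples: int, alpha: float = 0.05) -> float:
    """Closed-form |rho| boundary of two-sided significance at alpha.

    Inverts the t transform: rho_crit = t_crit / sqrt(n - 2 + t_crit^2).
    With n = 9 and alpha = 0.05 this is about 0.666 — only strong
    correlations survive a 9-sample design.
    """
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n_samples - 2)
    return float(t_crit / np.sqrt(n_samples - 2 + t_crit**2))
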