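"""Weighted gene coexpression network construction.

The pipeline is: Pearson correlation -> soft-power adjacency |cor|^beta ->
topological overlap -> average-linkage clustering of 1 - TOM -> modules ->
module eigengenes (first principal component) -> memberships/connectivities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "ScaleFreeFit",
    "MODULE_PALETTE",
    "correlation_matrix",
    "adjacency",
    "whole_network_connectivity",
    "scale_free_fit",
    "soft_power_table",
    "pick_soft_power",
    "topological_overlap",
    "detect_modules",
    "modules_from_dissimilarity",
    "module_eigengene",
    "module_membership",
    "intramodular_connectivity",
    "gene_significance",
]

#: Module label vocabulary, assigned to detected clusters by decreasing size.
#: "grey" is reserved for unassigned genes.
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

GREY = "grey"


@dataclass
class Network:
    """Symmetric gene-by-gene connection strengths in [0, 1]."""

    gene_ids: list
    weights: np.ndarray
    power_beta: int
    kind: str  # "adjacency" or "TOM"

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ScaleFreeFit:
    power_beta: int
    r2: float  # signed fit index, truncated at 0 for positive slopes
    slope: float
    n_bins: int
    r2_unsigned: float = field(default=np.nan)


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation across samples.

    Zero-variance genes get correlation 0 with everything (diagonal stays 1),
    with a logged warning.
    """
    X = expr.to_numpy(float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite expression values")
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance genes; correlations set to 0", int(degenerate.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def adjacency(corr: pd.DataFrame, beta: int) -> Network:
    """Unsigned soft-power adjacency a_ij = |cor_ij|^beta, unit diagonal."""
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    a = np.abs(corr.to_numpy(float)) ** int(beta)
    np.fill_diagonal(a, 1.0)
    return Network(list(corr.index), a, int(beta), "adjacency")


def whole_network_connectivity(net: Network) -> pd.Series:
    """k_i = sum of connection strengths to all other genes."""
    k = net.weights.sum(axis=1) - np.diag(net.weights)
    return pd.Series(k, index=net.gene_ids, name="k")


def scale_free_fit(net: Network, n_bins: int = 10) -> ScaleFreeFit:
    """Goodness of a power-law fit to the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; log10 relative
    frequency is regressed on log10 mean connectivity over non-empty bins.
    The signed index is -sign(slope) * R^2, truncated below at 0 when the
    slope is positive (a rising p(k) never passes).
    """
    k = whole_network_connectivity(net).to_numpy()
    if np.unique(k).size < 2:
        raise ValueError("all connectivities identical; fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 2:
        raise ValueError("fewer than 2 usable bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    r2 = r * r
    signed = r2 if slope < 0 else 0.0
    return ScaleFreeFit(net.power_beta, signed, slope, n_bins, r2_unsigned=r2)


def soft_power_table(
    corr: pd.DataFrame, candidates=range(1, 21), n_bins: int = 10
) -> pd.DataFrame:
    rows = []
    for beta in candidates:
        fit = scale_free_fit(adjacency(corr, beta), n_bins=n_bins)
        rows.append((beta, fit.r2, fit.slope))
    return pd.DataFrame(rows, columns=["beta", "r2", "slope"])


def pick_soft_power(
    corr: pd.DataFrame,
    candidates=range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest candidate power whose signed fit index reaches ``target_r2``;
    falls back to the argmax power with a warning when none qualifies."""
    table = soft_power_table(corr, candidates, n_bins=n_bins)
    ok = table[table["r2"] >= target_r2]
    if len(ok):
        return int(ok["beta"].iloc[0])
    best = int(table.loc[table["r2"].idxmax(), "beta"])
    logger.warning(
        "no candidate power reaches r2 >= %.3g; using argmax beta=%d", target_r2, best
    )
    return best


def topological_overlap(adj: Network) -> Network:
    """Unsigned topological overlap matrix.

    omega_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j with k_i = sum_{u != i} a_iu; omega_ii = 1.
    """
    if adj.kind != "adjacency":
        raise ValueError("topological_overlap expects an adjacency network")
    a = adj.weights
    k = a.sum(axis=1) - np.diag(a)
    # (A@A)_ij includes u=i and u=j terms a_ii*a_ij + a_ij*a_jj = 2*a_ij
    shared = a @ a - 2.0 * a * np.diag(a)[None, :]
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten below
    if (denom <= 0).any():
        raise AssertionError("non-positive TOM denominator; adjacency out of range")
    omega = numer / denom
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    return Network(adj.gene_ids, omega, adj.power_beta, "TOM")


def modules_from_dissimilarity(
    diss: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.7,
) -> pd.Series:
    """Average-linkage clustering of a dissimilarity matrix into modules.

    The dendrogram is cut at the given quantile of its merge heights; clusters
    of at least ``min_module_size`` genes become modules labelled from
    ``MODULE_PALETTE`` by decreasing size (ties broken by the lexicographically
    smallest member gene id); everything else is "grey".
    """
    gene_ids = list(diss.index)
    n = len(gene_ids)
    if n < min_module_size:
        return pd.Series(GREY, index=diss.index, name="module")
    d = diss.to_numpy(float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    cut = float(np.quantile(link[:, 2], cut_height_quantile))
    assign = hierarchy.fcluster(link, t=cut, criterion="distance")
    labels = pd.Series(GREY, index=diss.index, name="module")
    clusters = []
    for c in np.unique(assign):
        members = [gene_ids[i] for i in np.flatnonzero(assign == c)]
        if len(members) >= min_module_size:
            clusters.append((len(members), min(str(m) for m in members), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, members) in enumerate(clusters):
        name = (
            MODULE_PALETTE[rank]
            if rank < len(MODULE_PALETTE)
            else f"module{rank + 1}"
        )
        labels.loc[members] = name
    return labels


def detect_modules(
    tom: Network,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.7,
) -> pd.Series:
    """Detect modules from a TOM network via 1 - omega dissimilarity."""
    if tom.kind != "TOM":
        raise ValueError("detect_modules expects a TOM network")
    diss = pd.DataFrame(1.0 - tom.weights, index=tom.gene_ids, columns=tom.gene_ids)
    return modules_from_dissimilarity(diss, min_module_size, cut_height_quantile)


def _standardize(X: np.ndarray, axis: int = 1) -> np.ndarray:
    mu = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance profile; cannot standardize")
    return (X - mu) / sd


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component summary of each module (modules x samples).

    Genes are standardized across samples; the leading left singular vector of
    the samples-by-genes matrix is the eigengene. Its sign is fixed so it
    correlates positively with the module's mean standardized expression, and
    it is scaled to unit sample variance.
    """
    labels = labels.loc[expr.index.intersection(labels.index)]
    modules = [m for m in labels.unique() if m != GREY]
    # deterministic order: by decreasing size then name
    modules.sort(key=lambda m: (-int((labels == m).sum()), str(m)))
    rows = {}
    for m in modules:
        genes = labels.index[labels == m]
        if len(genes) < 2:
            raise ValueError(f"module {m!r} has fewer than 2 genes")
        Z = _standardize(expr.loc[genes].to_numpy(float), axis=1)  # genes x samples
        U, s, Vt = np.linalg.svd(Z.T, full_matrices=False)
        e = U[:, 0]
        mean_profile = Z.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        e = (e - e.mean()) / e.std(ddof=1)
        rows[m] = e
    return pd.DataFrame(rows, index=expr.columns).T


def module_membership(
    expr: pd.DataFrame, eigengenes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed correlation of every gene with every module eigengene.

    Returns (MM, MM p-values); p from the t distribution with n - 2 df.
    """
    X = expr.to_numpy(float)
    E = eigengenes[expr.columns].to_numpy(float)
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    es = np.sqrt((Ec**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        mm = (Xc @ Ec.T) / np.outer(xs, es)
    mm[np.isnan(mm)] = 0.0
    mm = np.clip(mm, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mm * np.sqrt((n - 2) / np.maximum(1.0 - mm**2, 1e-300))
    pv = 2.0 * stats.t.sf(np.abs(t), n - 2)
    mm_df = pd.DataFrame(mm, index=expr.index, columns=eigengenes.index)
    p_df = pd.DataFrame(pv, index=expr.index, columns=eigengenes.index)
    return mm_df, p_df


def intramodular_connectivity(mm: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """|MM| of each gene with its own module eigengene (NaN for grey genes)."""
    out = pd.Series(np.nan, index=mm.index, name="k_im")
    for g in mm.index:
        m = labels.get(g, GREY)
        if m != GREY and m in mm.columns:
            out.loc[g] = abs(mm.loc[g, m])
    return out


def gene_significance(pvals, cap: float = 300.0) -> np.ndarray:
    """GS = -log10(p); p = 0 capped at ``cap`` with a warning."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("p = 0 encountered; gene significance capped at %g", cap)
    with np.errstate(divide="ignore"):
        gs = -np.log10(p)
    return np.minimum(gs, cap)
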