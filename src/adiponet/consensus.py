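"""Consensus modules across two tissues and eigengene-network preservation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Network, modules_from_dissimilarity

__all__ = [
    "EigengeneNetwork",
    "PreservationResult",
    "consensus_dissimilarity",
    "detect_consensus_modules",
    "eigengene_network",
    "preservation",
]


@dataclass
class EigengeneNetwork:
    """Module-level network with A_IJ = (1 + cor(E_I, E_J)) / 2."""

    module_ids: list
    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency, float)
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("eigengene adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("eigengene adjacency must lie in [0, 1]")
        self.adjacency = np.clip(a, 0.0, 1.0)


@dataclass
class PreservationResult:
    module_ids: list
    preserv: np.ndarray  # 1 - |A1 - A2|
    density_d: float
    per_module_density: pd.Series


def consensus_dissimilarity(
    tom1: Network,
    tom2: Network,
    align: bool = True,
    align_quantile: float = 0.95,
) -> pd.DataFrame:
    """d_ij = 1 - min(omega1_ij, omega2_ij), after optional quantile alignment.

    Alignment rescales the second TOM multiplicatively so that its
    ``align_quantile`` off-diagonal quantile matches the first TOM's (values
    clipped back to [0, 1]); it compensates for overall density differences
    between tissues.
    """
    if list(tom1.gene_ids) != list(tom2.gene_ids):
        raise ValueError("TOMs must share the same gene set in the same order")
    if tom1.kind != "TOM" or tom2.kind != "TOM":
        raise ValueError("inputs must be TOM networks")
    w1 = tom1.weights.copy()
    w2 = tom2.weights.copy()
    if align:
        off = ~np.eye(w1.shape[0], dtype=bool)
        q1 = np.quantile(w1[off], align_quantile)
        q2 = np.quantile(w2[off], align_quantile)
        if q2 > 0:
            w2 = np.clip(w2 * (q1 / q2), 0.0, 1.0)
    d = 1.0 - np.minimum(w1, w2)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=tom1.gene_ids, columns=tom1.gene_ids)


def detect_consensus_modules(
    diss: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.7,
) -> pd.Series:
    """Modules from a consensus dissimilarity (same clustering as detect_modules)."""
    return modules_from_dissimilarity(diss, min_module_size, cut_height_quantile)


def eigengene_network(eigengenes: pd.DataFrame) -> EigengeneNetwork:
    """A_IJ = (1 + cor(E_I, E_J)) / 2 over module eigengenes (modules x samples)."""
    if eigengenes.shape[0] < 2:
        raise ValueError("need at least 2 module eigengenes")
    corr = np.corrcoef(eigengenes.to_numpy(float))
    corr = np.clip(corr, -1.0, 1.0)
    a = (1.0 + corr) / 2.0
    np.fill_diagonal(a, 1.0)
    return EigengeneNetwork(list(eigengenes.index), a)


def preservation(net1: EigengeneNetwork, net2: EigengeneNetwork) -> PreservationResult:
    """Preservation network and its density.

    preserv_IJ = 1 - |A1_IJ - A2_IJ|; the density D averages the off-diagonal
    preservation entries (the diagonal is identically 1 and is excluded).
    """
    if list(net1.module_ids) != list(net2.module_ids):
        raise ValueError("networks must share the same modules")
    m = len(net1.module_ids)
    if m < 2:
        raise ValueError("density undefined for a single module")
    pres = 1.0 - np.abs(net1.adjacency - net2.adjacency)
    off = ~np.eye(m, dtype=bool)
    density = float(pres[off].mean())
    per_module = pd.Series(
        (pres.sum(axis=1) - np.diag(pres)) / (m - 1),
        index=net1.module_ids,
        name="density",
    )
    return PreservationResult(list(net1.module_ids), pres, density, per_module)
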