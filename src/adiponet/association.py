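"""Eigengene-trait association, gene-set enrichment, eSNP prioritization,
and exact binomial/Bonferroni arithmetic."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import _design_matrix, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "eigengene_trait_association",
    "fisher_exact_greater",
    "fisher_enrichment",
    "prioritize_esnps",
    "binomial_enrichment",
    "bonferroni_threshold",
]


def eigengene_trait_association(
    eigengenes: pd.DataFrame,
    annotation: pd.DataFrame,
    traits,
    covariates=("plate", "gender"),
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Linear regression of each module eigengene on each trait + covariates.

    ``eigengenes`` is modules x samples. BH FDR is applied within each trait
    across modules; rows with ``fdr_q`` below ``q_threshold`` are flagged
    significant. ``direction`` is the sign of the trait coefficient (for a
    case/control trait, the sign of the case-minus-control difference).
    """
    annot = annotation.set_index("sample_id").loc[list(eigengenes.columns)]
    rows = []
    for trait in traits:
        X, samples, _ = _design_matrix(annot, trait, covariates)
        Y = eigengenes[samples].to_numpy(float).T  # samples x modules
        n, p = X.shape
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = XtX_inv @ (X.T @ Y)
        resid = Y - X @ beta
        df = n - p
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[1] / se, np.inf * np.sign(beta[1]))
        pv = 2.0 * stats.t.sf(np.abs(t), df)
        q = bh_fdr(pv)
        for i, module in enumerate(eigengenes.index):
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "effect": beta[1, i],
                    "p": pv[i],
                    "fdr_q": q[i],
                    "direction": int(np.sign(beta[1, i])),
                    "significant": bool(q[i] < q_threshold),
                }
            )
    return pd.DataFrame(rows)


def fisher_exact_greater(
    count: int, module_size: int, set_size: int, background_size: int
) -> float:
    """One-sided (greater) Fisher exact p for a module/set overlap table."""
    table = [
        [count, module_size - count],
        [set_size - count, background_size - module_size - set_size + count],
    ]
    if min(min(row) for row in table) < 0:
        raise ValueError("inconsistent 2x2 table")
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def fisher_enrichment(
    module_genes,
    gene_sets: dict,
    background_genes,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """One-sided (greater) Fisher's exact enrichment of each gene set.

    The 2x2 table compares module membership against set membership within the
    background universe; fold enrichment FE = (count/module)/(set/background).
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    module = set(module_genes) & background
    if not module <= background:  # pragma: no cover - intersected above
        raise ValueError("module must be contained in background")
    n_bg = len(background)
    n_mod = len(module)
    rows = []
    for name, genes in gene_sets.items():
        in_set = set(genes) & background
        count = len(module & in_set)
        p = fisher_exact_greater(count, n_mod, len(in_set), n_bg)
        fe = (
            (count / n_mod) / (len(in_set) / n_bg)
            if n_mod > 0 and len(in_set) > 0
            else 0.0
        )
        rows.append(
            {
                "gene_set": name,
                "count": count,
                "percent": 100.0 * count / n_mod if n_mod else 0.0,
                "fold_enrichment": fe,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr_q"] < q_threshold
    return out


def prioritize_esnps(
    mets_de: pd.DataFrame,
    mm_results: pd.DataFrame,
    interdepot_de: pd.DataFrame,
    eqtl_results: pd.DataFrame,
    consensus_labels: pd.Series,
    focus_modules: dict,
    consensus_module: str,
    de_q: float = 0.01,
    mm_p: float = 0.01,
    interdepot_q: float = 0.01,
) -> pd.DataFrame:
    """Assemble the follow-up eSNP panel from two selection criteria.

    Criterion i: the probeset is MetS-differentially expressed (``fdr_q`` <
    ``de_q`` in ``mets_de``) AND has high module membership (``mm_p_value`` <
    ``mm_p``) in the designated top module of its tissue (``focus_modules``,
    e.g. ``{"ABD": "brown", "GLU": "darkgreen"}``).

    Criterion ii: the probeset belongs to the designated consensus module OR
    is MetS-DE in the single-gene analysis, AND is inter-depot differentially
    expressed at ``fdr_q`` < ``interdepot_q``.

    For each qualifying probeset the best (smallest-p) eQTL record supplies
    the eSNP; probesets without any eQTL are skipped with a log message. The
    result carries per-criterion provenance flags and is invariant to input
    row order.
    """
    mets_hits = set(mets_de.loc[mets_de["fdr_q"] < de_q, "probeset_id"])
    inter_hits = set(interdepot_de.loc[interdepot_de["fdr_q"] < interdepot_q, "probeset_id"])

    mm_hits: set = set()
    for _, row in mm_results.iterrows():
        target = focus_modules.get(row.get("tissue"))
        if target is not None and row["module"] == target and row["mm_p_value"] < mm_p:
            mm_hits.add(row["probeset_id"])

    consensus_members = set(consensus_labels.index[consensus_labels == consensus_module])

    crit_i = mets_hits & mm_hits
    crit_ii = (consensus_members | mets_hits) & inter_hits
    qualifying = sorted(str(p) for p in (crit_i | crit_ii))

    best = (
        eqtl_results.sort_values(["p", "snp_id"], kind="mergesort")
        .drop_duplicates("probeset_id")
        .set_index("probeset_id")
    )
    rows = []
    for ps in qualifying:
        if ps not in best.index:
            logger.info("probeset %s qualifies but has no eQTL; skipped", ps)
            continue
        rec = best.loc[ps]
        rows.append(
            {
                "probeset_id": ps,
                "snp_id": rec["snp_id"],
                "eqtl_p": rec["p"],
                "criterion_i": ps in crit_i,
                "criterion_ii": ps in crit_ii,
            }
        )
    return pd.DataFrame(
        rows, columns=["probeset_id", "snp_id", "eqtl_p", "criterion_i", "criterion_ii"]
    )


def binomial_enrichment(
    n_tests: int, per_test_alpha: float, n_observed: int
) -> tuple[float, float]:
    """Exact binomial probabilities by direct summation of the mass function.

    Returns (P(X = n_observed), P(X >= n_observed)) for
    X ~ Binomial(n_tests, per_test_alpha).
    """
    if not 0 <= n_observed <= n_tests:
        raise ValueError("n_observed must lie in [0, n_tests]")
    if not 0 < per_test_alpha < 1:
        raise ValueError("per_test_alpha must lie in (0, 1)")
    p = per_test_alpha

    def pmf(k: int) -> float:
        return math.comb(n_tests, k) * p**k * (1.0 - p) ** (n_tests - k)

    point = pmf(n_observed)
    tail = sum(pmf(k) for k in range(n_observed, n_tests + 1))
    return point, min(tail, 1.0)


def _round_sig(x: float, sig_figs: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig_figs - 1)


def bonferroni_threshold(
    alpha: float, n_tests: int, sig_figs: int | None = None
) -> float:
    """Per-test threshold alpha / n_tests, optionally rounded to significant figures."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    return _round_sig(thr, sig_figs) if sig_figs is not None else thr
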