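"""Expression filtering, replicate averaging, and differential expression.

Expression matrices are pandas DataFrames with probeset ids as the index and
sample ids as columns, holding finite log2 intensities. Sample annotation is a
DataFrame with one row per sample (``sample_id`` column plus design columns).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "average_technical_replicates",
    "filter_expressed",
    "de_single_gene",
    "de_between_depots",
    "bh_fdr",
    "overlap_summary",
    "percent_of",
    "OverlapSummary",
]


def _check_expression(expr: pd.DataFrame) -> None:
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if expr.index.duplicated().any():
        raise ValueError("duplicate probeset ids")
    if expr.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("non-finite expression values")


def average_technical_replicates(
    expr: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates into one column per subject x tissue x visit.

    Returns the collapsed expression matrix and a matching one-row-per-column
    annotation table. Non-replicated samples pass through unchanged (their
    values, not their sample ids: output columns are named
    ``<subject>|<tissue>|v<visit>``).
    """
    _check_expression(expr)
    annot = annotation.set_index("sample_id").loc[list(expr.columns)]
    if "replicate_id" in annot.columns:
        # a replicate group must not span tissues or subjects
        rep = annot.dropna(subset=["replicate_id"])
        for rid, grp in rep.groupby("replicate_id"):
            if grp["tissue"].nunique() > 1:
                raise ValueError(f"replicate group {rid!r} spans tissues")
            if grp["subject_id"].nunique() > 1:
                raise ValueError(f"replicate group {rid!r} spans subjects")
    visit = annot["visit"] if "visit" in annot.columns else pd.Series(1, index=annot.index)
    keys = [
        f"{s}|{t}|v{v}"
        for s, t, v in zip(annot["subject_id"], annot["tissue"], visit)
    ]
    grouped = expr.T.groupby(pd.Index(keys, name="unit_id")).mean().T
    first_rows = (
        annot.assign(unit_id=keys)
        .reset_index()
        .drop_duplicates("unit_id")
        .set_index("unit_id")
        .loc[grouped.columns]
        .reset_index()
        .rename(columns={"unit_id": "sample_id"})
        .drop(columns=["replicate_id"], errors="ignore")
    )
    if "sample_id" in first_rows.columns and first_rows.columns.duplicated().any():
        first_rows = first_rows.loc[:, ~first_rows.columns.duplicated()]
    return grouped, first_rows


def filter_expressed(
    expr: pd.DataFrame,
    threshold: float = 4.0,
    min_fraction: float = 0.10,
    autosomal_ids=None,
    mode: str = "per_individual",
) -> pd.Index:
    """Return probesets detectably expressed under the intensity filter.

    ``mode="per_individual"`` (default) keeps a probeset when the fraction of
    individuals with intensity strictly above ``threshold`` is at least
    ``min_fraction`` (boundary inclusive). ``mode="mean"`` is the alternative
    reading where the probeset's mean intensity must exceed ``threshold``
    (``min_fraction`` is ignored). Probesets not in ``autosomal_ids`` (when
    given) are dropped first.
    """
    _check_expression(expr)
    if autosomal_ids is not None:
        expr = expr.loc[expr.index.isin(set(autosomal_ids))]
    if mode == "per_individual":
        frac = (expr > threshold).sum(axis=1) / expr.shape[1]
        keep = frac >= min_fraction
    elif mode == "mean":
        keep = expr.mean(axis=1) > threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return expr.index[keep]


def _encode_response(values: pd.Series) -> pd.Series:
    if values.dtype == object or str(values.dtype) == "category":
        mapping = {"case": 1.0, "control": 0.0}
        out = values.map(mapping)
        if out.isna().any() and not values.isna().all():
            bad = set(values.dropna()) - set(mapping)
            if bad:
                raise ValueError(f"cannot encode response levels {bad}")
        return out
    return values.astype(float)


def _design_matrix(
    annot: pd.DataFrame, response: str, covariates
) -> tuple[np.ndarray, pd.Index, list[str]]:
    """Build [intercept | response | covariate dummies]; drop rank-deficient
    covariates with a warning. Returns (X, complete-case sample ids, names)."""
    resp = _encode_response(annot[response])
    cols = {"_resp": resp}
    for cov in covariates:
        cols[cov] = annot[cov]
    frame = pd.DataFrame(cols, index=annot.index).dropna()
    if frame.empty:
        raise ValueError("no complete cases")
    if frame["_resp"].nunique() < 2:
        raise ValueError(f"response {response!r} is constant on complete cases")
    blocks = [np.ones((len(frame), 1)), frame[["_resp"]].to_numpy(float)]
    names = ["intercept", response]
    for cov in covariates:
        col = frame[cov]
        if col.dtype == object or str(col.dtype) == "category" or col.nunique() < 8:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True).to_numpy(float)
        else:
            dummies = col.to_numpy(float)[:, None]
        cand = np.hstack(blocks + [dummies])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            logger.warning("dropping rank-deficient covariate %r", cov)
            continue
        blocks.append(dummies)
        names.append(cov)
    X = np.hstack(blocks)
    return X, frame.index, names


def de_single_gene(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    response: str,
    covariates=("gender", "plate"),
) -> pd.DataFrame:
    """Per-probeset OLS of expression on a response plus nuisance covariates.

    The returned frame has one row per probeset with the response coefficient,
    its two-sided t-test p-value, and BH-adjusted q-value.
    """
    _check_expression(expr)
    annot = annotation.set_index("sample_id").loc[list(expr.columns)]
    X, samples, _ = _design_matrix(annot, response, covariates)
    Y = expr[samples].to_numpy(float).T  # samples x probesets
    n, p = X.shape
    if n <= p:
        raise ValueError("fewer samples than design columns")
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # p x genes
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, np.inf * np.sign(beta[1]))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(np.isfinite(beta[1]) & (se == 0) & (beta[1] == 0), 1.0, pvals)
    return pd.DataFrame(
        {
            "probeset_id": expr.index,
            "effect": beta[1],
            "p": pvals,
            "fdr_q": bh_fdr(pvals),
            "contrast": response,
        }
    )


def de_between_depots(
    expr_abd: pd.DataFrame,
    expr_glu: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Between-depot differential expression with a subject random intercept.

    Fixed effects: tissue, case/control status, gender, plate (whichever are
    present in the annotation); random intercept per subject; ML fit. The
    reported p is the Wald test on the tissue coefficient.
    """
    import statsmodels.formula.api as smf

    shared = expr_abd.index.intersection(expr_glu.index)
    if len(shared) == 0:
        raise ValueError("no shared probesets between depots")
    annot = annotation.set_index("sample_id")
    samples = [s for s in list(expr_abd.columns) + list(expr_glu.columns) if s in annot.index]
    meta = annot.loc[samples].copy()
    tissue = pd.Series(
        ["ABD"] * expr_abd.shape[1] + ["GLU"] * expr_glu.shape[1],
        index=list(expr_abd.columns) + list(expr_glu.columns),
    )
    meta["tissue"] = tissue.loc[meta.index]
    paired = meta.groupby("subject_id")["tissue"].nunique()
    if (paired >= 2).sum() == 0:
        raise ValueError("no subject contributes both depots")

    covs = [c for c in ("case_status", "gender", "plate") if c in meta.columns]
    usable = [c for c in covs if meta[c].nunique() > 1]
    rhs = " + ".join(["C(tissue)"] + [f"C({c})" for c in usable])
    rows = []
    stacked = pd.concat([expr_abd.loc[shared], expr_glu.loc[shared]], axis=1)
    for ps in shared:
        data = meta.copy()
        data["y"] = stacked.loc[ps, data.index].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(f"y ~ {rhs}", data, groups=data["subject_id"])
            fit = None
            for method in ("lbfgs", "bfgs", None):
                try:
                    fit = (
                        model.fit(reml=False, method=method)
                        if method
                        else model.fit(reml=False)
                    )
                    break
                except Exception:  # singular fits at a variance boundary
                    continue
            if fit is None:
                rows.append((ps, np.nan, np.nan))
                continue
        term = [n for n in fit.params.index if n.startswith("C(tissue)")][0]
        rows.append((ps, fit.params[term], fit.pvalues[term]))
    out = pd.DataFrame(rows, columns=["probeset_id", "effect", "p"])
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    out["contrast"] = "depot"
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1; NaN entries propagate
    and are excluded from m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qm = np.empty(m)
    qm[order] = q
    out[mask] = qm
    return out


@dataclass(frozen=True)
class OverlapSummary:
    a_only: int
    b_only: int
    both: int
    union: int
    pct_a_only: float
    pct_b_only: float
    pct_both: float


def percent_of(count: int, total: int, ndigits: int | None = None) -> float:
    """100*count/total, optionally rounded to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    return round(pct, ndigits) if ndigits is not None else pct


def overlap_summary(set_a, set_b) -> OverlapSummary:
    """Counts and union-denominated percentages for a two-set Venn diagram."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("both sets empty")
    a_only = len(a - b)
    b_only = len(b - a)
    both = len(a & b)
    n = len(union)
    return OverlapSummary(
        a_only=a_only,
        b_only=b_only,
        both=both,
        union=n,
        pct_a_only=100.0 * a_only / n,
        pct_b_only=100.0 * b_only / n,
        pct_both=100.0 * both / n,
    )
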