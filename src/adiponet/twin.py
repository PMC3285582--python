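"""Twin variance decomposition by maximum likelihood.

The model for an observation (aliquot l, visit k, twin j, pair i) is

    y = mu + batch + pair + zyg + ind_env + common_visit + ind_visit + resid

with six independent zero-mean random effects. ``pair`` is shared by co-twins
regardless of zygosity (variance A/2 + C under the classical twin model);
``zyg`` is shared by MZ co-twins but independent between DZ co-twins
(variance A/2); ``ind_env`` is per twin; ``common_visit`` is shared by
co-twins measured at the same visit; ``ind_visit`` is per twin-visit; the
residual is per aliquot. Familiality F = (s2_pair + s2_zyg) / total = A + C
over total; heritability h2 = 2 * s2_zyg / total.

The likelihood factorizes over twin pairs; pairs with identical design
signatures share the same block covariance, which keeps the evaluation cheap.
Fitting is plain ML (not REML) over nonnegatively-bounded variances with
multiple seeded starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "TwinVarianceComponents",
    "HeritabilitySummary",
    "fit_twin_model",
    "familiality",
    "heritability",
    "summarize",
    "decompose_eigengenes",
    "compare_familiality",
]

COMPONENTS = (
    "sigma2_pair",
    "sigma2_zyg",
    "sigma2_ind_env",
    "sigma2_common_visit",
    "sigma2_ind_visit",
    "sigma2_residual",
)


@dataclass
class TwinVarianceComponents:
    sigma2_pair: float
    sigma2_zyg: float
    sigma2_ind_env: float
    sigma2_common_visit: float
    sigma2_ind_visit: float
    sigma2_residual: float
    loglik: float
    converged: bool
    n_obs: int
    fixed_effects: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COMPONENTS)

    def as_dict(self) -> dict:
        d = {c: getattr(self, c) for c in COMPONENTS}
        d["loglik"] = self.loglik
        d["converged"] = self.converged
        return d


@dataclass
class HeritabilitySummary:
    familiality: float
    heritability: float
    proportions: dict


def _pair_structures(design: pd.DataFrame):
    """Group pairs by design signature.

    Returns a list of (observation-index array of shape (n_pairs, k),
    structure tensor M of shape (6, k, k)) — one entry per unique signature.
    """
    req = {"pair_id", "twin_index", "zygosity", "visit", "aliquot"}
    missing = req - set(design.columns)
    if missing:
        raise ValueError(f"design missing columns {sorted(missing)}")
    groups: dict = {}
    for pid, grp in design.groupby("pair_id", sort=True):
        grp = grp.sort_values(["twin_index", "visit", "aliquot"], kind="mergesort")
        zyg = str(grp["zygosity"].iloc[0]).upper()
        if grp["zygosity"].nunique() > 1:
            raise ValueError(f"pair {pid} has inconsistent zygosity")
        sig = (zyg, tuple(zip(grp["twin_index"], grp["visit"], grp["aliquot"])))
        groups.setdefault(sig, []).append(grp.index.to_numpy())

    pos = {ix: i for i, ix in enumerate(design.index)}
    out = []
    for (zyg, rows), members in groups.items():
        k = len(rows)
        twin = np.array([r[0] for r in rows])
        visit = np.array([r[1] for r in rows])
        same_twin = (twin[:, None] == twin[None, :]).astype(float)
        same_visit = (visit[:, None] == visit[None, :]).astype(float)
        M = np.empty((6, k, k))
        M[0] = 1.0  # pair
        M[1] = np.ones((k, k)) if zyg == "MZ" else same_twin  # zygosity
        M[2] = same_twin  # individual environment
        M[3] = same_visit  # common visit
        M[4] = same_twin * same_visit  # individual visit
        M[5] = np.eye(k)  # residual (per aliquot)
        idx = np.array([[pos[i] for i in m] for m in members])
        out.append((idx, M))
    return out


def _profiled_negloglik(theta, groups, y, X, jitter):
    """-2 loglik (up to constant) with GLS-profiled fixed effects.

    Also returns (beta, cov_beta) for Wald inference at this theta.
    """
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    n_total = 0
    for idx, M in groups:
        k = M.shape[1]
        V = np.tensordot(theta, M, axes=1) + jitter * np.eye(k)
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            V = V + (jitter * 1e4 + 1e-8) * np.eye(k)
            c = cho_factor(V, lower=True)
        Vinv = cho_solve(c, np.eye(k))
        ld = 2.0 * np.log(np.diag(c[0])).sum()
        npairs = idx.shape[0]
        logdet += npairs * ld
        n_total += npairs * k
        yg = y[idx]  # (npairs, k)
        Xg = X[idx]  # (npairs, k, p)
        Vy = yg @ Vinv  # (npairs, k)
        ytvy += float((Vy * yg).sum())
        VX = np.einsum("ij,njp->nip", Vinv, Xg)
        xtvx += np.einsum("nip,niq->pq", Xg, VX)
        xtvy += np.einsum("nip,ni->p", VX, yg)
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - float(beta @ xtvy)
    nll = 0.5 * (n_total * np.log(2 * np.pi) + logdet + quad)
    return nll, beta, np.linalg.inv(xtvx)


def _build_fixed(design: pd.DataFrame, covariates, extra_fixed: pd.DataFrame | None):
    n = len(design)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in design.columns:
            continue
        col = design[cov]
        if col.nunique() < 2:
            logger.warning("fixed covariate %r has < 2 levels; dropped", cov)
            continue
        dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
        blocks.append(dummies.to_numpy(float))
        names.extend(dummies.columns)
    if extra_fixed is not None:
        blocks.append(np.asarray(extra_fixed, float).reshape(n, -1))
        names.extend(
            extra_fixed.columns
            if hasattr(extra_fixed, "columns")
            else [f"x{i}" for i in range(blocks[-1].shape[1])]
        )
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    return X, names


def fit_twin_model(
    y,
    design: pd.DataFrame,
    covariates=("batch",),
    extra_fixed: pd.DataFrame | None = None,
    n_starts: int = 5,
    n_polish: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    min_pairs: int = 10,
    fix_zero: tuple = (),
) -> TwinVarianceComponents:
    """Constrained ML fit of the six-component twin model.

    ``y`` is aligned with the rows of ``design`` (array, or Series indexed by
    ``design``'s ``sample_id``). ``n_starts`` seeded starting points are
    screened; full optimization runs from the best ``n_polish`` of them. The
    response is standardized internally, which makes the derived variance
    ratios invariant to affine transformations of ``y`` up to optimizer
    tolerance. ``fix_zero`` names components pinned at zero — e.g. fix the
    visit variances in a single-visit design, where they are not identifiable
    from the pair and residual components.
    """
    design = design.reset_index(drop=True)
    if isinstance(y, pd.Series) and "sample_id" in design.columns:
        y = y.loc[design["sample_id"]].to_numpy(float)
    else:
        y = np.asarray(y, float)
    if y.shape[0] != len(design):
        raise ValueError("y and design length mismatch")
    if design["pair_id"].nunique() < min_pairs:
        raise ValueError(f"need at least {min_pairs} twin pairs")
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")

    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("constant response")
    scale = np.sqrt(vary)
    ystd = (y - y.mean()) / scale

    groups = _pair_structures(design)
    X, names = _build_fixed(design, covariates, extra_fixed)
    jitter = 1e-9

    unknown = set(fix_zero) - set(COMPONENTS)
    if unknown:
        raise ValueError(f"unknown components {sorted(unknown)}")
    zero_mask = np.array([c in fix_zero for c in COMPONENTS])

    rng = np.random.default_rng(seed)
    starts = [np.full(6, 1.0 / 6.0)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.dirichlet(np.ones(6)) * rng.uniform(0.5, 1.5))
    starts = [np.where(zero_mask, 0.0, s) for s in starts]

    def obj(theta):
        return _profiled_negloglik(theta, groups, ystd, X, jitter)[0]

    scored = sorted(starts, key=obj)
    best = None
    bounds = [(0.0, 0.0) if z else (0.0, None) for z in zero_mask]
    for s in scored[: max(n_polish, 1)]:
        res = optimize.minimize(
            obj, s, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.maximum(best.x, 0.0)
    nll, beta, cov_beta = _profiled_negloglik(theta, groups, ystd, X, jitter)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    fixed = pd.DataFrame(
        {
            "name": names,
            "beta": beta * scale,
            "se": se * scale,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        }
    )
    return TwinVarianceComponents(
        *(theta * vary),
        loglik=-nll - len(y) * np.log(scale),
        converged=bool(best.success),
        n_obs=len(y),
        fixed_effects=fixed,
    )


def familiality(vc: TwinVarianceComponents) -> float:
    """F = (s2_pair + s2_zyg) / total — additive genetics plus shared environment."""
    total = vc.total
    if total == 0:
        raise ValueError("total variance is zero; familiality undefined")
    return (vc.sigma2_pair + vc.sigma2_zyg) / total


def heritability(vc: TwinVarianceComponents, clip: bool = False) -> float:
    """h2 = 2 * s2_zyg / total (twice the MZ-extra component)."""
    total = vc.total
    if total == 0:
        raise ValueError("total variance is zero; heritability undefined")
    h2 = 2.0 * vc.sigma2_zyg / total
    if h2 > 1:
        logger.warning("h2 = %.3f exceeds 1 (degenerate fit)", h2)
        if clip:
            h2 = 1.0
    return h2


def summarize(vc: TwinVarianceComponents) -> HeritabilitySummary:
    total = vc.total
    if total == 0:
        raise ValueError("total variance is zero")
    props = {c: getattr(vc, c) / total for c in COMPONENTS}
    return HeritabilitySummary(familiality(vc), heritability(vc), props)


def decompose_eigengenes(
    labels: pd.Series,
    twin_expr: pd.DataFrame,
    design: pd.DataFrame,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the twin model to each module eigengene computed on twin samples.

    Module labels may come from another cohort; eigengenes are computed on the
    genes shared with ``twin_expr``. Modules with fewer than 2 shared genes
    are skipped with a log message.
    """
    from .network import GREY, module_eigengene

    shared = labels.index.intersection(twin_expr.index)
    labels = labels.loc[shared]
    usable = [
        m
        for m in labels.unique()
        if m != GREY and (labels == m).sum() >= 2
    ]
    skipped = set(labels.unique()) - set(usable) - {GREY}
    for m in skipped:
        logger.info("module %s has < 2 shared genes; skipped", m)
    eig = module_eigengene(twin_expr, labels[labels.isin(usable)])
    rows = []
    for m in eig.index:
        vc = fit_twin_model(
            pd.Series(eig.loc[m].to_numpy(), index=eig.columns),
            design,
            **fit_kwargs,
        )
        row = {"module": m, **vc.as_dict()}
        row["familiality"] = familiality(vc)
        row["heritability"] = heritability(vc)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_familiality(group_a, group_b, paired: bool = False) -> dict:
    """Wilcoxon comparison of two familiality distributions.

    Paired -> signed-rank test; unpaired -> rank-sum (Mann-Whitney). Returns
    the statistic, two-sided p, and group medians/IQRs.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison requires equal lengths")
        if np.all(a == b):
            logger.info("all paired differences zero; p = 1 by convention")
            statistic, p = 0.0, 1.0
        else:
            statistic, p = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        statistic, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return {
        "statistic": float(statistic),
        "p": float(p),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "iqr_a": (float(q1a), float(q3a)),
        "iqr_b": (float(q1b), float(q3b)),
    }
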