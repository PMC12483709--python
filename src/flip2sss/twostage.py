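"""Two-stage summary-statistics inference with sign-flip score tests (flip2sss).

Stage 1 reduces each cluster (e.g., each subject of a longitudinal study) to
the coefficients of a within-cluster GLM — the "summary statistics".  Stage 2
models the N x h matrix of these estimates with a linear model in the
between-cluster covariates, masked so that each between term only enters the
within-columns it is declared to model.  Inference on the stage-2 coefficients
uses the standardized sign-flip score test, applying one shared flip ensemble
(indexed by cluster) across all h second-stage models; its robustness to
variance misspecification is what lets the random-effect structure stay
unmodeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm_core
from .flipscores import (
    STANDARDIZATION_FORMULA,
    FlipEnsemble,
    ScoreDecomposition,
    effective_score,
    make_flips,
    mahalanobis_combine,
    standardized_flip_stats,
)
from .glm_core import GlmSpec, fit_firth_logistic, fit_glm

__all__ = [
    "ModelSpec2SSS",
    "ClusterSummaryMatrix",
    "Flip2sssResult",
    "stage1_summaries",
    "stage2_test",
    "fit_flip2sss",
]

logger = logging.getLogger("flip2sss")

INTERCEPT = "(Intercept)"


@dataclass
class ModelSpec2SSS:
    """Specification of a two-stage model.

    ``within`` lists the covariates that vary within clusters (the stage-1
    design is intercept + these).  ``between`` lists the cluster-constant
    covariates (stage-2 main effects).  ``mask`` maps each within-coefficient
    column to the between terms allowed to model it; the between intercept is
    always included.  By default every between main effect models the
    within-intercept column only — interactions in the originating formula
    unmask further columns (see :func:`flip2sss.io.parse_model`).
    """

    response: str
    cluster_id: str
    within: list[str] = field(default_factory=list)
    between: list[str] = field(default_factory=list)
    mask: dict[str, list[str]] | None = None
    family: str = "binomial"
    stage1_estimator: str = "auto"  # "ml" | "firth" | "auto"
    B: int = 5000
    seed: int = 0
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = {INTERCEPT: [INTERCEPT] + list(self.between)}
            for w in self.within:
                self.mask[w] = [INTERCEPT]
        for col, terms in self.mask.items():
            if INTERCEPT not in terms:
                terms.insert(0, INTERCEPT)
        if self.stage1_estimator == "auto":
            self.stage1_estimator = "firth" if self.family == "binomial" else "ml"
        if self.stage1_estimator not in ("ml", "firth"):
            raise ValueError("stage1_estimator must be 'ml', 'firth' or 'auto'")

    @property
    def within_columns(self) -> list[str]:
        return [INTERCEPT] + list(self.within)


@dataclass
class ClusterSummaryMatrix:
    """Stage-1 output: the N x h matrix of per-cluster coefficient estimates."""

    cluster_ids: np.ndarray
    within_names: list[str]
    estimates: np.ndarray  # N x h, NaN where inestimable
    estimable: np.ndarray  # N x h bool
    cluster_sizes: np.ndarray
    separated: np.ndarray  # per-cluster bool (ML would diverge)
    converged: np.ndarray  # per-cluster bool
    between_data: pd.DataFrame  # one row per cluster, aligned with cluster_ids

    @property
    def n_clusters(self) -> int:
        return self.cluster_ids.shape[0]

    def diagnostics_summary(self) -> dict:
        return {
            "n_clusters": int(self.n_clusters),
            "n_separated": int(self.separated.sum()),
            "n_nonconverged": int((~self.converged).sum()),
            "n_inestimable_cells": int((~self.estimable).sum()),
        }


@dataclass
class Flip2sssResult:
    """Per-coefficient sign-flip tests and per-covariate combined tests."""

    coefficient_table: pd.DataFrame
    anova_table: pd.DataFrame
    summaries: ClusterSummaryMatrix
    runlog: dict


def _expand_between(between_data: pd.DataFrame, terms: list[str]):
    """Build the stage-2 design: intercept plus dummies/numerics per term.

    Returns (Z, column_names, term_of_column).  Factors get treatment coding
    with the alphabetically first level as reference.
    """
    n = between_data.shape[0]
    cols = [np.ones(n)]
    names = [INTERCEPT]
    terms_of = [INTERCEPT]
    for t in terms:
        s = between_data[t]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            if len(levels) < 2:
                raise ValueError(f"between covariate {t!r} is constant across clusters (aliased)")
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{t}[{lev}]")
                terms_of.append(t)
        else:
            v = s.to_numpy(float)
            if np.ptp(v) == 0:
                raise ValueError(f"between covariate {t!r} is constant across clusters (aliased)")
            cols.append(v)
            names.append(t)
            terms_of.append(t)
    return np.column_stack(cols), names, terms_of


def stage1_summaries(data: pd.DataFrame, spec: ModelSpec2SSS) -> ClusterSummaryMatrix:
    """Fit the within-cluster GLM separately per cluster.

    Clusters with rank-deficient within designs get partial rows (aliased
    cells flagged inestimable); clusters with fewer than two observations
    contribute only to the within-intercept.  Binomial ML fits that diverge
    (complete separation) are flagged but their capped estimates are kept.
    """
    df = data.df if hasattr(data, "df") else data
    codes, cluster_ids = pd.factorize(df[spec.cluster_id], sort=True)
    cluster_ids = np.asarray(cluster_ids)
    N = cluster_ids.size
    if N < 2:
        raise ValueError("need at least 2 clusters")
    h = 1 + len(spec.within)
    order = np.argsort(codes, kind="stable")
    y_all = df[spec.response].to_numpy(float)[order]
    W_all = (
        df[list(spec.within)].to_numpy(float)[order] if spec.within else np.empty((len(df), 0))
    )
    sizes = np.bincount(codes, minlength=N)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    first_rows = order[bounds[:-1]]
    estimates = np.full((N, h), np.nan)
    estimable = np.zeros((N, h), dtype=bool)
    separated = np.zeros(N, dtype=bool)
    converged = np.ones(N, dtype=bool)
    firth = spec.stage1_estimator == "firth" and spec.family == "binomial"
    in_batch = np.zeros(N, dtype=bool)
    if spec.family == "binomial" and N > 1:
        in_batch = _stage1_batched(
            y_all, W_all, bounds, sizes, h, firth, estimates, estimable, separated, converged
        )
    for idx in np.flatnonzero(~in_batch):
        lo, hi = bounds[idx], bounds[idx + 1]
        nj = hi - lo
        use_cols = list(range(h)) if (nj >= 2 or h == 1) else [0]  # minimum-data rule
        X = np.column_stack([np.ones(nj), W_all[lo:hi, [j - 1 for j in use_cols if j > 0]]])
        gspec = GlmSpec(spec.family, X, y_all[lo:hi])
        fit = fit_firth_logistic(gspec) if firth else fit_glm(gspec)
        coefs = fit.coefficients
        for local_j, j in enumerate(use_cols):
            if np.isfinite(coefs[local_j]):
                estimates[idx, j] = coefs[local_j]
                estimable[idx, j] = True
        separated[idx] = fit.separation_flag
        converged[idx] = fit.converged
    for j, name in enumerate(spec.within_columns):
        if not estimable[:, j].any():
            raise ValueError(f"within coefficient {name!r} is inestimable in every cluster")
    between_data = (
        df.iloc[first_rows][list(spec.between)].set_axis(cluster_ids, axis=0)
        if spec.between
        else pd.DataFrame(index=cluster_ids)
    )
    return ClusterSummaryMatrix(
        cluster_ids=cluster_ids,
        within_names=spec.within_columns,
        estimates=estimates,
        estimable=estimable,
        cluster_sizes=sizes,
        separated=separated,
        converged=converged,
        between_data=between_data,
    )


def _stage1_batched(
    y_all, W_all, bounds, sizes, h, firth, estimates, estimable, separated, converged
) -> np.ndarray:
    """Vectorized stage-1 logistic fits for full-rank clusters; returns the
    mask of clusters handled.  Irregular clusters (too small or rank
    deficient) fall back to the scalar per-cluster path."""
    N = sizes.shape[0]
    cand = sizes >= max(h, 2)
    if not cand.any():
        return np.zeros(N, dtype=bool)
    idxs = np.flatnonzero(cand)
    m = int(sizes[idxs].max())
    Xp = np.zeros((idxs.size, m, h))
    yp = np.zeros((idxs.size, m))
    real = np.zeros((idxs.size, m), dtype=bool)
    for i, idx in enumerate(idxs):
        lo, hi = bounds[idx], bounds[idx + 1]
        nj = hi - lo
        Xp[i, :nj, 0] = 1.0
        Xp[i, :nj, 1:] = W_all[lo:hi]
        yp[i, :nj] = y_all[lo:hi]
        real[i, :nj] = True
    # same relative tolerance as detect_aliased, via singular values
    sv = np.linalg.svd(Xp, compute_uv=False)
    full_rank = sv[:, -1] > glm_core.ALIAS_RTOL * sv[:, 0]
    if not full_rank.all():
        keep = np.flatnonzero(full_rank)
        idxs, Xp, yp, real = idxs[keep], Xp[keep], yp[keep], real[keep]
        if idxs.size == 0:
            return np.zeros(N, dtype=bool)
    max_iter = 200 if firth else 100
    beta, conv, _, sep = glm_core.batched_logistic(
        Xp, yp, real, firth=firth, max_iter=max_iter
    )
    if firth:
        # diagnostics: would plain ML have separated?
        _, _, _, sep = glm_core.batched_logistic(Xp, yp, real, firth=False, max_iter=100)
    estimates[idxs] = beta
    estimable[idxs] = True
    separated[idxs] = sep
    converged[idxs] = conv
    handled = np.zeros(N, dtype=bool)
    handled[idxs] = True
    return handled


def stage2_test(summaries: ClusterSummaryMatrix, spec: ModelSpec2SSS) -> Flip2sssResult:
    """Masked stage-2 linear models with shared-flip score inference.

    For each within-coefficient column k the available cluster estimates are
    regressed on the unmasked between terms; every stage-2 coefficient gets a
    standardized sign-flip test (all other unmasked terms as nuisance), and
    each between covariate additionally gets an ANOVA-like combined test that
    pools its dummy columns across all within-columns via the Mahalanobis
    quadratic form.  One flip ensemble, indexed by sorted cluster id, is
    shared by every test; clusters inestimable for a column contribute zero
    to that column's flipped sums.
    """
    N = summaries.n_clusters
    flips = make_flips(N, spec.B, spec.seed)
    Z, colnames, term_of = _expand_between(summaries.between_data, list(spec.between))
    coef_rows = []
    anova_nus: dict[str, list[np.ndarray]] = {}
    anova_cols: dict[str, list[tuple[str, str]]] = {}
    for k, wname in enumerate(summaries.within_names):
        allowed = spec.mask.get(wname, [INTERCEPT])
        cols_k = [i for i, t in enumerate(term_of) if t in allowed]
        avail = summaries.estimable[:, k] & np.isfinite(summaries.estimates[:, k])
        yk = summaries.estimates[avail, k]
        Zk = Z[avail][:, cols_k]
        if int(avail.sum()) < len(cols_k):
            raise ValueError(
                f"within column {wname!r}: {int(avail.sum())} estimable clusters "
                f"< {len(cols_k)} stage-2 terms"
            )
        kept, dropped = glm_core.detect_aliased(Zk)
        if dropped.size:
            bad = [colnames[cols_k[j]] for j in dropped]
            raise ValueError(f"stage-2 design rank-deficient in column {wname!r}: aliased {bad}")
        ols = np.linalg.lstsq(Zk, yk, rcond=None)[0]
        for local_c, c in enumerate(cols_k):
            nuis = [j for j in range(len(cols_k)) if j != local_c]
            spn = GlmSpec("gaussian", Zk[:, nuis] if nuis else np.empty((len(yk), 0)), yk)
            fitn = fit_glm(spn)
            sd_k = effective_score(fitn, spn, Zk, [local_c])
            nu_full = np.zeros(N)
            nu_full[avail] = sd_k.contributions[:, 0]
            proj_full = np.zeros((N, 1))
            proj_full[avail] = sd_k.nuisance_projection
            sd_full = ScoreDecomposition(nu_full[:, None], np.array([c]), proj_full)
            res = standardized_flip_stats(sd_full, flips)
            coef_rows.append(
                {
                    "term": colnames[c],
                    "within_column": wname,
                    "estimate": float(ols[local_c]),
                    "score_stat": res.observed,
                    "p_value": res.p_two_sided,
                }
            )
            t = term_of[c]
            anova_nus.setdefault(t, []).append(nu_full)
            anova_cols.setdefault(t, []).append((colnames[c], wname))
    anova_rows = []
    for t, nus in anova_nus.items():
        mat = np.column_stack(nus)
        sd_t = ScoreDecomposition(mat, np.arange(mat.shape[1]), mat)
        res = mahalanobis_combine(sd_t, flips)
        anova_rows.append(
            {
                "term": t,
                "n_components": mat.shape[1],
                "score_stat": res.observed,
                "p_value": res.p_two_sided,
            }
        )
    runlog = {
        "seed": spec.seed,
        "B": flips.B,
        "flip_mode": flips.mode,
        "stage1_estimator": spec.stage1_estimator,
        "family": spec.family,
        "standardization": STANDARDIZATION_FORMULA,
        "stage1_diagnostics": summaries.diagnostics_summary(),
    }
    return Flip2sssResult(
        coefficient_table=pd.DataFrame(coef_rows),
        anova_table=pd.DataFrame(anova_rows),
        summaries=summaries,
        runlog=runlog,
    )


def fit_flip2sss(data, spec: ModelSpec2SSS) -> Flip2sssResult:
    """Run both stages; the user-facing entry point of the method."""
    df = data.df if hasattr(data, "df") else data
    _validate_between_constant(df, spec)
    summaries = stage1_summaries(df, spec)
    diag = summaries.diagnostics_summary()
    logger.info(
        "stage 1: %(n_clusters)d clusters, %(n_separated)d separated, "
        "%(n_nonconverged)d non-converged, %(n_inestimable_cells)d inestimable cells",
        diag,
    )
    return stage2_test(summaries, spec)


def _validate_between_constant(df: pd.DataFrame, spec: ModelSpec2SSS) -> None:
    for b in spec.between:
        nun = df.groupby(spec.cluster_id, observed=True)[b].nunique(dropna=False)
        bad = nun[nun > 1]
        if len(bad):
            raise ValueError(
                f"between covariate {b!r} varies within clusters: {list(bad.index[:10])}"
            )
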