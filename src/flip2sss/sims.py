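"""Simulation study: type-I error and power for clustered binary data.

The generative model is a random-intercept random-slope logistic mixed model:
per cluster j draw b0_j ~ N(0, sd0^2) and b1_j ~ N(0, sd1^2); per observation
draw the tested covariate X ~ N(0,1) and the correlated nuisance covariate
Z = X + N(0,1); then

    logit P(Y = 1) = beta * X + eta * Z + b0_j + b1_j * X

Rejection rates over replicated datasets are compared between the flip2sss
method (ML or Firth first stage) and the standard comparators: a naive GLM
Wald test ignoring clustering and GEE with independence working correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .twostage import INTERCEPT, ModelSpec2SSS, fit_flip2sss

__all__ = ["SimScenario", "SimReport", "generate_dataset", "run_scenario", "run_grid"]

METHODS = ("flip2sss_ml", "flip2sss_firth", "glm_wald", "gee_independence")


@dataclass
class SimScenario:
    """One cell of the simulation grid.

    ``cluster_sizes`` is either a constant n_j (balanced) or the string
    ``"unbalanced"`` for n_j drawn uniformly on {2, ..., 2*n_bar} with mean
    size ``n_bar``.  ``beta_tested = 0`` gives a type-I error study.
    """

    N: int = 25
    cluster_sizes: int = 8
    unbalanced: bool = False
    beta_tested: float = 0.0
    beta_nuisance: float = 1.0
    re_sd: tuple[float, float] = (1.0, 1.0)
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 0
    B: int = 1000
    methods: tuple[str, ...] = ("flip2sss_firth",)
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(s < 0 for s in self.re_sd):
            raise ValueError("random-effect sds must be non-negative")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")


@dataclass
class SimReport:
    """Rejection-rate estimates with 95% Monte-Carlo half-widths."""

    scenario: SimScenario
    rejection_rate: dict[str, float]
    mc_halfwidth: dict[str, float]
    n_errors: dict[str, int]
    diagnostics: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        s = self.scenario
        rows = []
        for m in s.methods:
            rows.append(
                {
                    "scenario": s.label or f"N{s.N}_nj{s.cluster_sizes}"
                    + ("_unbal" if s.unbalanced else ""),
                    "N": s.N,
                    "n_j": s.cluster_sizes,
                    "unbalanced": s.unbalanced,
                    "beta": s.beta_tested,
                    "method": m,
                    "rejection_rate": self.rejection_rate[m],
                    "mc_halfwidth": self.mc_halfwidth[m],
                    "n_errors": self.n_errors[m],
                    **{f"diag_{k}": v for k, v in self.diagnostics.items()},
                }
            )
        return pd.DataFrame(rows)


def generate_dataset(scn: SimScenario, rep_seed: int) -> pd.DataFrame:
    """Draw one long-format dataset (columns y, cluster, x, z) from the model."""
    rng = np.random.default_rng(rep_seed)
    if scn.unbalanced:
        sizes = rng.integers(2, 2 * scn.cluster_sizes + 1, size=scn.N)
    else:
        sizes = np.full(scn.N, scn.cluster_sizes)
    n = int(sizes.sum())
    cluster = np.repeat(np.arange(scn.N), sizes)
    b0 = rng.normal(0.0, scn.re_sd[0], size=scn.N)
    b1 = rng.normal(0.0, scn.re_sd[1], size=scn.N)
    x = rng.normal(size=n)
    z = x + rng.normal(size=n)
    eta = scn.beta_tested * x + scn.beta_nuisance * z + b0[cluster] + b1[cluster] * x
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({"y": y, "cluster": cluster, "x": x, "z": z})


def _p_flip2sss(df: pd.DataFrame, estimator: str, B: int, seed: int):
    """flip2sss p-value for the X effect: the within-X slope column's mean
    (stage-2 intercept) tested by the shared-flip standardized score test."""
    spec = ModelSpec2SSS(
        response="y",
        cluster_id="cluster",
        within=["x", "z"],
        between=[],
        family="binomial",
        stage1_estimator=estimator,
        B=B,
        seed=seed,
    )
    res = fit_flip2sss(df, spec)
    tab = res.coefficient_table
    row = tab[(tab.within_column == "x") & (tab.term == INTERCEPT)]
    return float(row.p_value.iloc[0]), res.runlog["stage1_diagnostics"]


def _p_glm_wald(df: pd.DataFrame) -> float:
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(df)), df.x, df.z])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(df.y.to_numpy(), X, family=sm.families.Binomial()).fit()
    return float(fit.pvalues[1])


def _p_gee_independence(df: pd.DataFrame) -> float:
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(df)), df.x, df.z])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GEE(
            df.y.to_numpy(),
            X,
            groups=df.cluster.to_numpy(),
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
    return float(fit.pvalues[1])


def run_scenario(scn: SimScenario) -> SimReport:
    """Monte-Carlo estimate of each method's rejection rate under ``scn``.

    A replicate whose flip2sss run raises is counted in ``n_errors`` and kept
    in the denominator (never silently dropped).
    """
    rng = np.random.default_rng(scn.seed)
    rejects = {m: 0 for m in scn.methods}
    errors = {m: 0 for m in scn.methods}
    diagnostics = {"n_separated": 0, "n_inestimable_cells": 0, "n_nonconverged": 0}
    any_ok = False
    for _ in range(scn.n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        df = generate_dataset(scn, rep_seed)
        diag_counted = False
        for m in scn.methods:
            try:
                if m in ("flip2sss_ml", "flip2sss_firth"):
                    est = "firth" if m.endswith("firth") else "ml"
                    p, diag = _p_flip2sss(df, est, scn.B, rep_seed + 1)
                    if not diag_counted:  # same stage-1 diagnostics per rep
                        for k in diagnostics:
                            diagnostics[k] += diag.get(k, 0)
                        diag_counted = True
                    any_ok = True
                elif m == "glm_wald":
                    p = _p_glm_wald(df)
                else:
                    p = _p_gee_independence(df)
            except Exception:
                errors[m] += 1
                continue
            if p <= scn.alpha:
                rejects[m] += 1
    if not any_ok and any(m.startswith("flip2sss") for m in scn.methods):
        if all(errors[m] == scn.n_reps for m in scn.methods if m.startswith("flip2sss")):
            raise RuntimeError("flip2sss stage 1 infeasible in every replicate of the scenario")
    rate = {m: rejects[m] / scn.n_reps for m in scn.methods}
    half = {m: 1.96 * np.sqrt(r * (1 - r) / scn.n_reps) for m, r in rate.items()}
    return SimReport(scn, rate, half, errors, diagnostics)


def run_grid(base: SimScenario, *, Ns=None, n_js=None, betas=None, unbalanced=(False,)) -> pd.DataFrame:
    """Run a grid of scenarios varying N, n_j, beta and balance; stack reports."""
    frames = []
    for N in Ns or [base.N]:
        for nj in n_js or [base.cluster_sizes]:
            for beta in betas if betas is not None else [base.beta_tested]:
                for unbal in unbalanced:
                    scn = replace(
                        base, N=N, cluster_sizes=nj, beta_tested=beta, unbalanced=unbal
                    )
                    frames.append(run_scenario(scn).to_frame())
    return pd.concat(frames, ignore_index=True)
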