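"""Reading long-format tables and parsing the single-formula model interface.

The user writes one formula over the long table, e.g.::

    unhealth ~ 1 + country + age + sex + time + sex:time

Terms that vary within clusters (here ``time``) define the stage-1
within-cluster design; cluster-constant terms are stage-2 between covariates.
A between main effect models the within-intercept column; a between:within
interaction additionally lets that between term model the corresponding
within-slope column.  The resulting mask is stored on the
:class:`~flip2sss.twostage.ModelSpec2SSS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .twostage import INTERCEPT, ModelSpec2SSS

__all__ = ["ObservationTable", "read_table", "parse_model", "write_results"]

logger = logging.getLogger("flip2sss")


@dataclass
class ObservationTable:
    """A validated long-format 2-level dataset plus its column-role map."""

    df: pd.DataFrame
    response: str
    cluster_id: str
    within: list[str]
    between: list[str]
    n_dropped: int = 0

    @property
    def n_clusters(self) -> int:
        return self.df[self.cluster_id].nunique()

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.df.groupby(self.cluster_id, observed=True).size()


def read_table(path, role_config: dict) -> ObservationTable:
    """Read a CSV/TSV file and validate column roles.

    ``role_config`` needs keys ``response``, ``cluster`` and lists ``within``
    and ``between``.  Rows with missing values in any used column are dropped
    (count logged); a between covariate varying within a cluster is an error
    naming the offending clusters.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return validate_table(
        df,
        response=role_config["response"],
        cluster_id=role_config["cluster"],
        within=list(role_config.get("within", [])),
        between=list(role_config.get("between", [])),
    )


def validate_table(df, response, cluster_id, within, between) -> ObservationTable:
    used = [response, cluster_id, *within, *between]
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise ValueError(f"role columns not found in table: {missing}")
    n0 = len(df)
    df = df.dropna(subset=used).reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing values in used columns", n_dropped)
    for b in between:
        nun = df.groupby(cluster_id, observed=True)[b].nunique(dropna=False)
        bad = nun[nun > 1]
        if len(bad):
            raise ValueError(
                f"between covariate {b!r} varies within clusters {list(bad.index[:10])}"
            )
    return ObservationTable(df, response, cluster_id, within, between, n_dropped)


def _split_terms(rhs: str) -> list[str]:
    return [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]


def parse_model(
    formula_text: str,
    data: pd.DataFrame | ObservationTable,
    cluster_id: str | None = None,
    *,
    family: str = "binomial",
    stage1_estimator: str = "auto",
    B: int = 5000,
    seed: int = 0,
    within: list[str] | None = None,
    between: list[str] | None = None,
) -> ModelSpec2SSS:
    """Turn a single formula into a masked two-stage model specification.

    Within/between classification is taken from ``data``'s ObservationTable
    roles, from the keyword lists, or (fallback) inferred from within-cluster
    variation of each term.
    """
    if isinstance(data, ObservationTable):
        cluster_id = cluster_id or data.cluster_id
        within = within if within is not None else (data.within or None)
        between = between if between is not None else (data.between or None)
        df = data.df
    else:
        df = data
    if cluster_id is None:
        raise ValueError("cluster_id is required")
    if "~" not in formula_text:
        raise ValueError("formula must contain '~'")
    lhs, rhs = (s.strip() for s in formula_text.split("~", 1))
    if lhs not in df.columns:
        raise ValueError(f"response column {lhs!r} not found")
    terms = _split_terms(rhs)
    mains = [t for t in terms if ":" not in t]
    inters = [tuple(p.strip() for p in t.split(":")) for t in terms if ":" in t]
    for t in mains:
        if t not in df.columns:
            raise ValueError(f"formula term {t!r} is not a column of the data")
    for pair in inters:
        if len(pair) != 2:
            raise ValueError(f"only two-way between:within interactions are supported: {pair}")
        for p in pair:
            if p not in df.columns:
                raise ValueError(f"interaction names unknown term {p!r}")

    def is_within(col: str) -> bool:
        if within is not None and col in within:
            return True
        if between is not None and col in between:
            return False
        return df.groupby(cluster_id, observed=True)[col].nunique(dropna=False).gt(1).any()

    within_terms = [t for t in mains if is_within(t)]
    between_terms = [t for t in mains if t not in within_terms]
    mask: dict[str, list[str]] = {INTERCEPT: [INTERCEPT] + between_terms}
    for w in within_terms:
        mask[w] = [INTERCEPT]
    for pair in inters:
        w_part = [p for p in pair if is_within(p)]
        b_part = [p for p in pair if not is_within(p)]
        if len(w_part) != 1 or len(b_part) != 1:
            raise ValueError(f"interaction {':'.join(pair)} must pair one between with one within term")
        if w_part[0] not in within_terms:
            raise ValueError(
                f"within term {w_part[0]!r} appears only inside an interaction; "
                "add it as a main effect so the stage-1 design contains it"
            )
        if b_part[0] not in between_terms:
            raise ValueError(f"between term {b_part[0]!r} appears only inside an interaction")
        if b_part[0] not in mask[w_part[0]]:
            mask[w_part[0]].append(b_part[0])
    return ModelSpec2SSS(
        response=lhs,
        cluster_id=cluster_id,
        within=within_terms,
        between=between_terms,
        mask=mask,
        family=family,
        stage1_estimator=stage1_estimator,
        B=B,
        seed=seed,
        formula=formula_text,
    )


def write_results(result, out_dir) -> dict:
    """Write coefficients.csv, anova.csv and runlog.json to ``out_dir``."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coef_path = out / "coefficients.csv"
    anova_path = out / "anova.csv"
    log_path = out / "runlog.json"
    result.coefficient_table.to_csv(coef_path, index=False, float_format="%.12g")
    result.anova_table.to_csv(anova_path, index=False, float_format="%.12g")
    with open(log_path, "w") as fh:
        json.dump(result.runlog, fh, indent=2)
    return {"coefficients": coef_path, "anova": anova_path, "runlog": log_path}
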