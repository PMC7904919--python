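"""Deterministic data preparation.

Gene-level QC filtering of read counts, summarization of gene expression
into module-level scores, square-root transformation of regional pathology
burdens, and per-subject OLS slopes of longitudinal cognition.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from modtrait.synthetic import BRAIN_REGIONS

logger = logging.getLogger(__name__)

__all__ = [
    "build_analysis_table",
    "estimate_slopes",
    "filter_low_expression",
    "summarize_modules",
    "transform_pathology",
]


def filter_low_expression(
    counts: pd.DataFrame, min_reads: int = 4, min_subjects: int = 100
) -> list:
    """Keep genes expressed at >= ``min_reads`` in >= ``min_subjects`` subjects.

    This is the prevalence-style QC rule "genes with less than ``min_reads``
    reads in ``min_subjects`` individuals are removed". Row (gene) order is
    preserved; returns the retained gene ids.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if min_reads < 0:
        raise ValueError(f"min_reads must be >= 0, got {min_reads!r}")
    if min_subjects > counts.shape[1]:
        raise ValueError(
            f"min_subjects ({min_subjects}) exceeds the number of subjects "
            f"({counts.shape[1]})"
        )
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    prevalent = (counts.to_numpy() >= min_reads).sum(axis=1) >= min_subjects
    return counts.index[prevalent].tolist()


def summarize_modules(
    expr: pd.DataFrame, assignment: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a genes-by-subjects matrix to subjects-by-modules summaries.

    The module score for a subject is the mean across member genes of each
    gene's z-score (standardized across subjects, ddof=1). Genes in the
    assignment but absent from ``expr`` are ignored; modules left with no
    retained genes are dropped with a logged warning, as are zero-variance
    genes (whose z-score is undefined). The summarization method is
    recorded in ``result.attrs['method']`` (``mean_z``).
    """
    assignment = assignment[["gene_id", "module_id"]]
    present = assignment[assignment["gene_id"].isin(expr.index)]
    if present.empty:
        raise ValueError("module assignment references no gene present in expr")

    mat = expr.loc[present["gene_id"]].to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "dropping %d zero-variance genes from module summaries", constant.sum()
        )
    z = np.where(
        constant[:, None], np.nan, (mat - mat.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    )
    zdf = pd.DataFrame(z, index=present["gene_id"].to_numpy(), columns=expr.columns)
    zdf["__module__"] = present["module_id"].to_numpy()
    summary = zdf.groupby("__module__", sort=False).mean()
    empty = summary.index[summary.isna().all(axis=1)]
    if len(empty):
        logger.warning("dropping modules with no retained genes: %s", list(empty))
        summary = summary.drop(index=empty)
    dropped = set(assignment["module_id"]) - set(summary.index)
    if dropped:
        logger.warning("modules with no genes in expr dropped: %s", sorted(dropped))

    def _module_key(m: str):
        tail = m.lstrip("m")
        return (0, int(tail)) if tail.isdigit() else (1, m)

    summary = summary.T.loc[:, sorted(summary.index, key=_module_key)]
    summary.index.name = "subject_id"
    summary.attrs["method"] = "mean_z"
    return summary


def transform_pathology(
    pathology: pd.DataFrame, global_method: str = "sqrt_of_mean"
) -> pd.DataFrame:
    """Square-root transform regional pathology and derive global burdens.

    ``pathology`` is long-form with columns ``subject_id, region, mark,
    value`` (raw, non-negative). Returns a wide per-subject table with one
    ``{mark}_sqrt_{region}`` column per region and a ``{mark}_sqrt_global``
    column. The default global value is the square root of the mean of the
    raw regional values (transform applied last); ``global_method=
    'mean_of_sqrt'`` averages the transformed regional values instead.
    """
    required = {"subject_id", "region", "mark", "value"}
    missing = required - set(pathology.columns)
    if missing:
        raise ValueError(f"pathology table missing columns: {sorted(missing)}")
    if (pathology["value"] < 0).any():
        bad = pathology.loc[pathology["value"] < 0, "subject_id"].unique()
        raise ValueError(f"negative raw pathology values for subjects {bad[:5]}")
    if global_method not in ("sqrt_of_mean", "mean_of_sqrt"):
        raise ValueError(f"unknown global_method {global_method!r}")

    wide = pathology.pivot_table(
        index="subject_id", columns=["mark", "region"], values="value"
    )
    out = {}
    for mark in wide.columns.get_level_values("mark").unique():
        raw = wide[mark]
        regions = [r for r in BRAIN_REGIONS if r in raw.columns] or list(raw.columns)
        raw = raw[regions]
        for region in regions:
            out[f"{mark}_sqrt_{region}"] = np.sqrt(raw[region])
        if global_method == "sqrt_of_mean":
            out[f"{mark}_sqrt_global"] = np.sqrt(raw.mean(axis=1))
        else:
            out[f"{mark}_sqrt_global"] = np.sqrt(raw).mean(axis=1)
    panel = pd.DataFrame(out)
    panel.index.name = "subject_id"
    panel.attrs["global_method"] = global_method
    return panel


def estimate_slopes(cognition: pd.DataFrame) -> pd.DataFrame:
    """Per-subject OLS slope of cognition score on visit year.

    ``cognition`` is long-form with columns ``subject_id, visit_year,
    score``. Subjects with fewer than two visits get a missing slope (they
    are excluded from downstream models by complete-case handling).
    Duplicate visit years within a subject are an error.
    """
    required = {"subject_id", "visit_year", "score"}
    missing = required - set(cognition.columns)
    if missing:
        raise ValueError(f"cognition table missing columns: {sorted(missing)}")
    dup = cognition.duplicated(subset=["subject_id", "visit_year"])
    if dup.any():
        offenders = cognition.loc[dup, "subject_id"].unique()
        raise ValueError(f"duplicate visit_year for subjects {offenders[:5]}")

    def _slope(group: pd.DataFrame) -> float:
        if len(group) < 2:
            return np.nan
        x = group["visit_year"].to_numpy(dtype=float)
        y = group["score"].to_numpy(dtype=float)
        xc = x - x.mean()
        return float(xc @ (y - y.mean()) / (xc @ xc))

    grouped = cognition.groupby("subject_id", sort=False)
    slopes = grouped.apply(_slope, include_groups=False)
    out = pd.DataFrame({"slope": slopes, "n_visits": grouped.size()})
    out.index.name = "subject_id"
    return out


def build_analysis_table(
    cohort: pd.DataFrame,
    module_expr: pd.DataFrame | None = None,
    pathology_panel: pd.DataFrame | None = None,
    slopes: pd.DataFrame | None = None,
    ad: pd.Series | None = None,
    extra: Iterable[pd.DataFrame] = (),
) -> pd.DataFrame:
    """Join the per-subject layers on subject id into one modelling table."""
    table = cohort.copy()
    pieces = [module_expr, pathology_panel, slopes, ad, *extra]
    for piece in pieces:
        if piece is None:
            continue
        table = table.join(piece, how="left")
    return table
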