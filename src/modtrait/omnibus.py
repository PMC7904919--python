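"""Permutation omnibus test and empirical QQ envelopes for module scans.

The scan of a trait against M module summaries yields M p-values. To ask
whether that whole collection deviates from the uniform null, the trait is
permuted across subjects B times (covariates and expression stay attached
to their subjects, so the permutation preserves everything except the
trait-subject link), the scan is rerun each time, and a summary statistic
of the p-value collection (default: the count of modules with nominal
P < 0.05) is compared against its permutation distribution with the
add-one estimator p = (1 + #{stat_b >= stat_obs}) / (B + 1). The same
null matrix yields pointwise empirical confidence envelopes for the QQ
plot of observed vs expected -log10 p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from modtrait.association import (
    BASE_RNA_COVARIATES,
    AssociationResult,
    CovariateSet,
    _aligned_complete,
    _module_sort_key,
    _scan_engine,
)

__all__ = [
    "OmnibusResult",
    "PermutationNull",
    "QQ_STATISTICS",
    "build_permutation_null",
    "omnibus_p",
    "order_statistic_quantiles",
    "qq_envelope",
]


@dataclass
class PermutationNull:
    """B x M matrix of module p-values under trait relabeling."""

    pvalues: np.ndarray  # shape (B, M), entries in (0, 1]
    module_ids: tuple[str, ...]
    B: int
    seed: int | None = None

    def __post_init__(self):
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B!r}")
        if self.pvalues.shape != (self.B, len(self.module_ids)):
            raise ValueError("pvalues shape does not match (B, M)")


def _count_stat(p: np.ndarray, alpha: float) -> np.ndarray:
    return (p < alpha).sum(axis=-1)


def _sumlog_stat(p: np.ndarray, alpha: float) -> np.ndarray:
    return (-np.log10(p)).sum(axis=-1)


QQ_STATISTICS = {"count": _count_stat, "sumlog": _sumlog_stat}


def build_permutation_null(
    cohort: pd.DataFrame,
    module_expr: pd.DataFrame,
    trait: str,
    covariates: CovariateSet = BASE_RNA_COVARIATES,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Rerun the trait-module scan on B trait relabelings.

    Only the trait vector is shuffled across (complete-case) subjects; the
    observed data are never included in the null matrix.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B!r}")
    order = sorted(module_expr.columns, key=_module_sort_key)
    module_expr = module_expr.loc[:, order]
    Y, x, C, _, _ = _aligned_complete(cohort, module_expr, trait, covariates)
    if np.ptp(x) == 0:
        raise ValueError(f"trait {trait!r} is constant; cannot permute")
    if rng is None:
        rng = np.random.default_rng(seed)
    pmat = np.empty((B, Y.shape[1]))
    for b in range(B):
        _, _, p = _scan_engine(Y, rng.permutation(x), C)
        pmat[b] = p
    return PermutationNull(
        pvalues=pmat, module_ids=tuple(map(str, order)), B=B, seed=seed
    )


@dataclass
class OmnibusResult:
    statistic: str
    observed: float
    p: float
    B: int
    alpha: float = 0.05


def omnibus_p(
    observed: Sequence[AssociationResult] | Sequence[float],
    null: PermutationNull,
    statistic: str = "count",
    alpha: float = 0.05,
) -> OmnibusResult:
    """Empirical omnibus p-value for the observed module p-value collection.

    ``statistic='count'`` counts modules with nominal P < ``alpha``;
    ``'sumlog'`` sums -log10 p. Exceedance uses >= (ties count against the
    observed data), and the add-one estimator keeps p in (1/(B+1), 1].
    """
    if statistic not in QQ_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {sorted(QQ_STATISTICS)}"
        )
    obs_p = np.asarray(
        [r.p if isinstance(r, AssociationResult) else float(r) for r in observed]
    )
    if obs_p.shape[0] != len(null.module_ids):
        raise ValueError(
            f"observed has {obs_p.shape[0]} p-values but the null holds "
            f"{len(null.module_ids)} modules"
        )
    fn = QQ_STATISTICS[statistic]
    stat_obs = float(fn(obs_p, alpha))
    stat_null = fn(null.pvalues, alpha)
    p_emp = (1.0 + float((stat_null >= stat_obs).sum())) / (null.B + 1.0)
    return OmnibusResult(
        statistic=statistic, observed=stat_obs, p=p_emp, B=null.B, alpha=alpha
    )


def order_statistic_quantiles(null: PermutationNull, q: float) -> np.ndarray:
    """Per-rank quantile (over permutations) of sorted -log10 null p-values.

    Rank r (1-based) is the r-th smallest p-value, i.e. the r-th largest
    -log10 p; returns an array of length M ordered by rank.
    """
    neglog = -np.log10(np.sort(null.pvalues, axis=1))
    return np.quantile(neglog, q, axis=0)


def qq_envelope(
    null: PermutationNull, levels: Sequence[float] = (0.90, 0.95)
) -> pd.DataFrame:
    """Pointwise empirical confidence envelopes for the QQ plot.

    For each rank r in 1..M, the level-l band spans the empirical
    (1-l)/2 and (1+l)/2 quantiles of the r-th order statistic of
    -log10 p across permutations; the expected value is
    -log10(r / (M + 1)). Columns: rank, expected, lo/hi per level.
    """
    for level in levels:
        if not 0.0 < level < 1.0:
            raise ValueError(f"envelope level must lie in (0, 1), got {level!r}")
    if null.B < 40 and any(lv >= 0.95 for lv in levels):
        warnings.warn(
            f"B={null.B} permutations is too few to resolve a 95% envelope",
            stacklevel=2,
        )
    M = len(null.module_ids)
    ranks = np.arange(1, M + 1)
    out = pd.DataFrame(
        {"rank": ranks, "expected": -np.log10(ranks / (M + 1.0))}
    )
    for level in levels:
        tag = f"{level * 100:g}"
        out[f"lo{tag}"] = order_statistic_quantiles(null, (1 - level) / 2)
        out[f"hi{tag}"] = order_statistic_quantiles(null, (1 + level) / 2)
    return out
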