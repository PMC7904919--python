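"""Covariate-adjusted linear association scans.

One atomic record, :class:`AssociationResult`, serves every scan: a
single-predictor OLS fit with an intercept and a named covariate set,
reporting the predictor's beta, SE and two-sided t-test P on the
complete-case sample. Scans over many outcomes (modules, genes, SNPs)
share a vectorized residualization path that is numerically identical to
the per-model statsmodels fit (checked by the test suite to 1e-10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "CovariateSet",
    "bh_adjust",
    "build_design",
    "fit_linear_association",
    "gene_scan_with_fdr",
    "results_to_frame",
    "snp_scan",
    "trait_module_scan",
    "trait_outcome_models",
]

logger = logging.getLogger(__name__)

_P_FLOOR = np.finfo(float).tiny  # perfect fits report this instead of 0


@dataclass(frozen=True)
class CovariateSet:
    """Named, ordered covariate list; ``id`` tags results for comparison."""

    id: str
    columns: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"duplicate covariate names in set {self.id!r}")


#: Demographic covariates used by the trait-outcome models.
BASE_COVARIATES = CovariateSet(
    "base", ("age_death", "sex", "education", "race_white", "study", "pmi")
)
#: Demographics plus RNA technical covariates, used by expression scans.
BASE_RNA_COVARIATES = CovariateSet(
    "base_rna",
    ("age_death", "sex", "education", "race_white", "study", "pmi", "batch", "rin"),
)


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    beta: float
    se: float
    p: float
    n_used: int
    covariate_set: str = "none"
    q: float | None = None
    degenerate: bool = False


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Tabulate results with columns outcome, predictor, beta, se, p, q, ..."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "predictor": r.predictor,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "q": r.q,
                "n_used": r.n_used,
                "covariate_set": r.covariate_set,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )


def build_design(data: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns; categorical/object columns one-hot encoded.

    The first level of each categorical is the reference (dropped).
    """
    pieces = []
    for col in columns:
        if col not in data.columns:
            raise ValueError(f"unknown covariate column {col!r}")
        s = data[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(s.astype(float).to_frame(col))
    if not pieces:
        return pd.DataFrame(index=data.index)
    return pd.concat(pieces, axis=1)


def _drop_constant_covariates(frame: pd.DataFrame, n_lead: int) -> pd.DataFrame:
    """Drop covariate columns that are constant in the analysis sample.

    A constant covariate is indistinguishable from the intercept and would
    spuriously trip the collinearity check; the first ``n_lead`` columns
    (outcome/predictor slots) are never dropped.
    """
    cov = frame.iloc[:, n_lead:]
    constant = [c for c in cov.columns if cov[c].nunique(dropna=False) <= 1]
    if constant:
        logger.warning("dropping constant covariate column(s): %s", constant)
        frame = frame.drop(columns=constant)
    return frame


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the collinear columns when the design is rank deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    offenders = []
    running = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([running, X[:, j : j + 1]])
        if np.linalg.matrix_rank(cand) > running.shape[1]:
            running = cand
        else:
            offenders.append(name)
    raise ValueError(f"rank-deficient design; collinear columns: {offenders}")


def fit_linear_association(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: CovariateSet | None = None,
    *,
    predictor_values: pd.Series | None = None,
) -> AssociationResult:
    """OLS of ``outcome`` on ``predictor`` + covariates with an intercept.

    Complete-case analysis; ``n_used`` records the rows actually fit. A
    constant predictor or outcome after complete-case restriction yields a
    degenerate result (``p`` is NaN) rather than an exception; a
    rank-deficient covariate design raises, naming the collinear columns.
    """
    covariates = covariates or CovariateSet("none")
    cols = {outcome: data[outcome].astype(float)}
    if predictor_values is not None:
        cols[predictor] = predictor_values.astype(float)
    else:
        cols[predictor] = data[predictor].astype(float)
    frame = pd.DataFrame(cols)
    design = build_design(data, covariates.columns)
    frame = pd.concat([frame, design], axis=1).dropna()
    frame = _drop_constant_covariates(frame, n_lead=2)
    n_used = len(frame)
    n_params = frame.shape[1]
    if n_used < n_params + 1:
        raise ValueError(
            f"only {n_used} complete cases for {n_params} parameters "
            f"({outcome} ~ {predictor} + {covariates.id})"
        )

    y = frame[outcome].to_numpy()
    x = frame[predictor].to_numpy()
    base = AssociationResult(
        outcome=outcome,
        predictor=predictor,
        beta=np.nan,
        se=np.nan,
        p=np.nan,
        n_used=n_used,
        covariate_set=covariates.id,
    )
    if np.ptp(x) == 0:
        return replace(base, degenerate=True)
    if np.ptp(y) == 0:
        return replace(base, beta=0.0, se=np.nan, degenerate=True)

    X = np.column_stack(
        [np.ones(n_used), x, frame.iloc[:, 2:].to_numpy(dtype=float)]
    )
    _check_rank(X, ["intercept", predictor, *frame.columns[2:]])
    fit = sm.OLS(y, X).fit()
    p = float(fit.pvalues[1])
    if not np.isfinite(p) or p <= 0:  # zero residual variance: perfect fit
        p = _P_FLOOR
    return replace(
        base, beta=float(fit.params[1]), se=float(fit.bse[1]), p=float(p)
    )


def _scan_engine(
    Y: np.ndarray, x: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized single-predictor OLS across many outcomes.

    ``Y`` is n x M outcomes, ``x`` the shared predictor, ``C`` the n x k
    covariate design (without intercept). Residualizes both sides on
    [1, C] (Frisch-Waugh-Lovell), so beta/SE/P equal the full OLS fit with
    residual df = n - k - 2. Returns (beta, se, p); outcomes or predictors
    with no residual variance produce NaNs (degenerate fits).
    """
    n = Y.shape[0]
    X = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(X)
    Yr = Y - Q @ (Q.T @ Y)
    xr = x - Q @ (Q.T @ x)
    sxx = float(xr @ xr)
    df = n - X.shape[1] - 1
    if sxx <= n * np.finfo(float).eps * max(1.0, float(x @ x)) or df <= 0:
        nan = np.full(Y.shape[1], np.nan)
        return nan, nan.copy(), nan.copy()
    beta = (xr @ Yr) / sxx
    rss = np.einsum("ij,ij->j", Yr, Yr) - beta**2 * sxx
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(np.isfinite(p), np.maximum(p, _P_FLOOR), p)
    syy = np.einsum("ij,ij->j", Yr, Yr)
    degenerate = syy <= n * np.finfo(float).eps
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    p = np.where(degenerate, np.nan, p)
    p = np.where(np.isnan(se) & ~degenerate, _P_FLOOR, p)  # perfect fit
    return beta, se, p


def _module_sort_key(name: str):
    tail = str(name).lstrip("m")
    return (0, int(tail)) if tail.isdigit() else (1, str(name))


def _aligned_complete(
    cohort: pd.DataFrame,
    outcome_mat: pd.DataFrame,
    trait: str,
    covariates: CovariateSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index, int]:
    """Align subjects, drop incomplete rows, and build the scan inputs."""
    if trait not in cohort.columns:
        raise ValueError(f"trait column {trait!r} absent from cohort")
    shared = cohort.index.intersection(outcome_mat.index)
    if len(shared) == 0:
        raise ValueError("no shared subjects between cohort and outcome matrix")
    design = build_design(cohort.loc[shared], covariates.columns)
    frame = pd.concat(
        [cohort.loc[shared, [trait]].astype(float), design], axis=1
    )
    keep = frame.notna().all(axis=1) & outcome_mat.loc[shared].notna().all(axis=1)
    frame = _drop_constant_covariates(frame[keep], n_lead=1)
    Y = outcome_mat.loc[frame.index].to_numpy(dtype=float)
    x = frame[trait].to_numpy()
    C = frame.iloc[:, 1:].to_numpy(dtype=float)
    return Y, x, C, frame.index, len(frame)


def trait_module_scan(
    cohort: pd.DataFrame,
    module_expr: pd.DataFrame,
    trait: str,
    covariates: CovariateSet = BASE_RNA_COVARIATES,
) -> list[AssociationResult]:
    """Regress each module summary on the trait, adjusting for covariates.

    One result per module column, ordered by module id.
    """
    if module_expr.shape[1] < 1:
        raise ValueError("module_expr has no module columns")
    order = sorted(module_expr.columns, key=_module_sort_key)
    module_expr = module_expr.loc[:, order]
    Y, x, C, _, n_used = _aligned_complete(cohort, module_expr, trait, covariates)
    beta, se, p = _scan_engine(Y, x, C)
    return [
        AssociationResult(
            outcome=str(mod),
            predictor=trait,
            beta=float(beta[j]),
            se=float(se[j]),
            p=float(p[j]),
            n_used=n_used,
            covariate_set=covariates.id,
            degenerate=bool(np.isnan(p[j])),
        )
        for j, mod in enumerate(order)
    ]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_scan_with_fdr(
    cohort: pd.DataFrame,
    expr: pd.DataFrame,
    trait: str,
    covariates: CovariateSet = BASE_RNA_COVARIATES,
) -> list[AssociationResult]:
    """Per-gene trait association with BH-FDR across exactly these genes.

    ``expr`` is genes x subjects, already restricted to the gene family of
    interest (e.g. the genes of the modules under study); the BH family is
    that set and nothing else. Degenerate (zero-variance) genes are
    excluded from the adjustment and carry ``q=None``.
    """
    if expr.shape[0] == 0:
        raise ValueError("gene set is empty")
    Y_mat = expr.T
    Y, x, C, _, n_used = _aligned_complete(cohort, Y_mat, trait, covariates)
    beta, se, p = _scan_engine(Y, x, C)
    results = [
        AssociationResult(
            outcome=str(g),
            predictor=trait,
            beta=float(beta[j]),
            se=float(se[j]),
            p=float(p[j]),
            n_used=n_used,
            covariate_set=covariates.id,
            degenerate=bool(np.isnan(p[j])),
        )
        for j, g in enumerate(Y_mat.columns)
    ]
    ok = [r for r in results if not r.degenerate]
    if ok:
        q = bh_adjust([r.p for r in ok])
        for r, qv in zip(ok, q):
            r.q = float(qv)
    return results


def snp_scan(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    outcome: str,
    covariates: CovariateSet = BASE_COVARIATES,
) -> list[AssociationResult]:
    """Additive-coding association of an outcome with each SNP dosage.

    Monomorphic SNPs are flagged degenerate, never dropped silently.
    """
    values = genotypes.to_numpy()
    if not np.isin(values[~pd.isna(values)], [0, 1, 2]).all():
        raise ValueError("dosages must lie in {0, 1, 2}")
    results = []
    shared = cohort.index.intersection(genotypes.index)
    data = cohort.loc[shared]
    geno = genotypes.loc[shared]
    for snp in genotypes.columns:
        frame = pd.concat(
            [
                data[[outcome]].astype(float),
                geno[snp].astype(float).rename("dosage"),
                build_design(data, covariates.columns),
            ],
            axis=1,
        ).dropna()
        x = frame["dosage"].to_numpy()
        if np.ptp(x) == 0:
            results.append(
                AssociationResult(
                    outcome=outcome,
                    predictor=str(snp),
                    beta=np.nan,
                    se=np.nan,
                    p=np.nan,
                    n_used=len(frame),
                    covariate_set=covariates.id,
                    degenerate=True,
                )
            )
            continue
        res = fit_linear_association(
            data.assign(**{str(snp): geno[snp].astype(float)}),
            outcome,
            str(snp),
            covariates,
        )
        results.append(res)
    return results


def trait_outcome_models(
    data: pd.DataFrame,
    trait: str,
    outcome: str = "slope",
    covariate_sets: Sequence[CovariateSet] = (),
) -> list[AssociationResult]:
    """Refit the trait-outcome association under each covariate set.

    The canonical use attenuates the trait -> cognitive-decline slope
    association by adding pathology burdens (amyloid, tau, all indices) to
    the base covariates, one row per covariate set.
    """
    if not covariate_sets:
        raise ValueError("covariate_sets must be nonempty")
    return [
        fit_linear_association(data, outcome, trait, cs) for cs in covariate_sets
    ]
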