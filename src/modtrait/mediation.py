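"""Linear structural-equation causal mediation and instrument screening.

For a treatment T, mediator M and outcome Y (with covariates X) the engine
fits the mediator model ``M ~ T + X``, the outcome model ``Y ~ T + M + X``
and the total-effect model ``Y ~ T + X``, then draws coefficient vectors
from their asymptotic normal distributions (quasi-Bayesian Monte Carlo).
Per draw, the average causal mediation effect (ACME) is the product of the
T -> M and M -> Y coefficients, the average direct effect (ADE) the T
coefficient of the outcome model, and the total effect the T coefficient
of the total model; point estimates are draw means and intervals are
percentile intervals. Under the no-interaction linear model
ACME + ADE = total within Monte-Carlo error.

A binary outcome is handled with a logistic outcome model; its effects are
reported on the latent (log-odds) scale.

The instrumental-variable screen asks whether a SNP that predicts the
treatment still predicts the mediator after adjusting for the treatment;
if so the SNP is pleiotropic and unusable as an instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from modtrait.association import (
    BASE_COVARIATES,
    CovariateSet,
    _drop_constant_covariates,
    build_design,
    fit_linear_association,
)

__all__ = [
    "ChainSpec",
    "DirectionComparison",
    "IVCheckResult",
    "MediationResult",
    "chain_mediation",
    "classify_instrument",
    "direction_test",
    "fit_mediation",
    "iv_pleiotropy_check",
]


@dataclass
class MediationResult:
    treatment: str
    mediator: str
    outcome: str
    acme: float
    acme_ci: tuple[float, float]
    p_acme: float
    ade: float
    ade_ci: tuple[float, float]
    p_ade: float
    total: float
    total_ci: tuple[float, float]
    p_total: float
    prop_mediated: float
    n_used: int
    n_sims: int
    seed: int | None
    outcome_model: str = "linear"
    degenerate: bool = False


@dataclass
class ChainSpec:
    """Ordered causal chain; consecutive triples define mediation fits."""

    variables: tuple[str, ...]
    covariates: CovariateSet = BASE_COVARIATES

    def __post_init__(self):
        if len(self.variables) < 3:
            raise ValueError("a chain needs at least three variables")


def _mc_p(draws: np.ndarray) -> float:
    """Two-sided Monte-Carlo tail probability with add-one correction."""
    n = draws.size
    lo = (1.0 + float((draws <= 0).sum())) / (n + 1.0)
    hi = (1.0 + float((draws >= 0).sum())) / (n + 1.0)
    return min(1.0, 2.0 * min(lo, hi))


def _param_draws(fit, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    mean = np.asarray(fit.params, dtype=float)
    cov = np.asarray(fit.cov_params(), dtype=float)
    cov = (cov + cov.T) / 2.0  # symmetrize numerical asymmetry
    return rng.multivariate_normal(
        mean, cov, size=n_sims, method="svd", check_valid="ignore"
    )


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.isin(u, [0.0, 1.0]).all()


def fit_mediation(
    data: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    covariates: CovariateSet | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
    outcome_family: str = "auto",
) -> MediationResult:
    """Quasi-Bayesian mediation analysis for one (T, M, Y) triple.

    ``outcome_family`` is ``'linear'``, ``'logistic'`` or ``'auto'``
    (logistic when the outcome is 0/1 binary). A deterministic
    treatment-mediator relationship makes the outcome design collinear;
    that case returns a degenerate flagged result with NaN effects rather
    than raising, so direction comparisons can report it.
    """
    if n_sims < 100:
        raise ValueError(f"n_sims must be >= 100, got {n_sims!r}")
    covariates = covariates or CovariateSet("none")
    design = build_design(data, covariates.columns)
    frame = pd.concat(
        [data[[treatment, mediator, outcome]].astype(float), design], axis=1
    ).dropna()
    frame = _drop_constant_covariates(frame, n_lead=3)
    n_used = len(frame)
    n_params = frame.shape[1]
    if n_used < n_params + 2:
        raise ValueError(
            f"only {n_used} complete cases for the mediation models"
        )
    t = frame[treatment].to_numpy()
    m = frame[mediator].to_numpy()
    y = frame[outcome].to_numpy()
    if np.ptp(m) == 0:
        raise ValueError(f"mediator {mediator!r} is constant")
    C = frame.iloc[:, 3:].to_numpy(dtype=float)
    ones = np.ones(n_used)

    X_med = np.column_stack([ones, t, C])  # M ~ T + X, T at index 1
    X_out = np.column_stack([ones, t, m, C])  # Y ~ T + M + X
    X_tot = np.column_stack([ones, t, C])  # Y ~ T + X

    family = outcome_family
    if family == "auto":
        family = "logistic" if _is_binary(y) else "linear"
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown outcome_family {outcome_family!r}")

    base = MediationResult(
        treatment=treatment,
        mediator=mediator,
        outcome=outcome,
        acme=np.nan,
        acme_ci=(np.nan, np.nan),
        p_acme=np.nan,
        ade=np.nan,
        ade_ci=(np.nan, np.nan),
        p_ade=np.nan,
        total=np.nan,
        total_ci=(np.nan, np.nan),
        p_total=np.nan,
        prop_mediated=np.nan,
        n_used=n_used,
        n_sims=n_sims,
        seed=seed,
        outcome_model=family,
    )
    if np.linalg.matrix_rank(X_out) < X_out.shape[1]:
        base.degenerate = True
        return base

    rng = np.random.default_rng(seed)
    try:
        med_fit = sm.OLS(m, X_med).fit()
        if family == "logistic":
            out_fit = sm.Logit(y, X_out).fit(disp=False)
            tot_fit = sm.Logit(y, X_tot).fit(disp=False)
        else:
            out_fit = sm.OLS(y, X_out).fit()
            tot_fit = sm.OLS(y, X_tot).fit()
        a = _param_draws(med_fit, n_sims, rng)[:, 1]
        out_draws = _param_draws(out_fit, n_sims, rng)
        b = out_draws[:, 2]
        c_prime = out_draws[:, 1]
        total_draws = _param_draws(tot_fit, n_sims, rng)[:, 1]
    except (np.linalg.LinAlgError, ValueError):
        base.degenerate = True
        return base

    acme_draws = a * b

    def _summ(draws: np.ndarray) -> tuple[float, tuple[float, float], float]:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return float(draws.mean()), (float(lo), float(hi)), _mc_p(draws)

    acme, acme_ci, p_acme = _summ(acme_draws)
    ade, ade_ci, p_ade = _summ(c_prime)
    total, total_ci, p_total = _summ(total_draws)
    prop = acme / total if total != 0 else np.nan

    base.acme, base.acme_ci, base.p_acme = acme, acme_ci, p_acme
    base.ade, base.ade_ci, base.p_ade = ade, ade_ci, p_ade
    base.total, base.total_ci, base.p_total = total, total_ci, p_total
    base.prop_mediated = float(prop)
    return base


def chain_mediation(
    data: pd.DataFrame,
    chain: ChainSpec | Sequence[str],
    covariates: CovariateSet | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
) -> list[MediationResult]:
    """Mediation fit for every consecutive triple of an ordered chain.

    A five-variable chain such as trait -> module -> tau -> slope -> AD
    yields three fits; a binary terminal variable (AD status) gets a
    logistic outcome model automatically.
    """
    if isinstance(chain, ChainSpec):
        names = chain.variables
        covariates = covariates or chain.covariates
    else:
        names = tuple(chain)
        if len(names) < 3:
            raise ValueError("a chain needs at least three variables")
    missing = [v for v in names if v not in data.columns]
    if missing:
        raise ValueError(f"chain variables not found in data: {missing}")
    seeds = np.random.SeedSequence(seed).spawn(len(names) - 2)
    results = []
    for i in range(len(names) - 2):
        sub_seed = int(seeds[i].generate_state(1)[0] % (2**31))
        results.append(
            fit_mediation(
                data,
                names[i],
                names[i + 1],
                names[i + 2],
                covariates,
                n_sims=n_sims,
                seed=sub_seed,
            )
        )
    return results


@dataclass
class DirectionComparison:
    """Forward vs reverse mediation; a heuristic consistency check only.

    Comparing ACME p-values between the orderings T -> M -> Y and
    M -> T -> Y indicates which ordering the data are more consistent
    with; it is not a proof of causal direction.
    """

    forward: MediationResult
    reverse: MediationResult
    preferred: str  # "forward", "reverse" or "indeterminate"


def direction_test(
    data: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    covariates: CovariateSet | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
) -> DirectionComparison:
    """Fit mediation in both orderings and compare the mediated signal."""
    ss = np.random.SeedSequence(seed).spawn(2)
    fwd = fit_mediation(
        data,
        treatment,
        mediator,
        outcome,
        covariates,
        n_sims=n_sims,
        seed=int(ss[0].generate_state(1)[0] % (2**31)),
    )
    rev = fit_mediation(
        data,
        mediator,
        treatment,
        outcome,
        covariates,
        n_sims=n_sims,
        seed=int(ss[1].generate_state(1)[0] % (2**31)),
    )
    if fwd.degenerate or rev.degenerate or np.isnan(fwd.p_acme) or np.isnan(rev.p_acme):
        preferred = "indeterminate"
    elif fwd.p_acme < rev.p_acme:
        preferred = "forward"
    elif rev.p_acme < fwd.p_acme:
        preferred = "reverse"
    else:
        preferred = "indeterminate"
    return DirectionComparison(forward=fwd, reverse=rev, preferred=preferred)


@dataclass
class IVCheckResult:
    snp: str
    p_snp_trait: float
    p_snp_module_unadjusted: float
    p_snp_module_adjusted: float
    alpha: float
    verdict: str  # instrument_candidate | pleiotropic | uninformative


def classify_instrument(
    p_snp_trait: float,
    p_snp_module_unadjusted: float,
    p_snp_module_adjusted: float,
    alpha: float = 0.05,
    snp: str = "snp",
) -> IVCheckResult:
    """Apply the instrument decision rule to three association p-values.

    A SNP is an ``instrument_candidate`` when it predicts the trait
    (p < alpha) and its effect on the module vanishes after adjusting for
    the trait (p >= alpha); it is ``pleiotropic`` when the adjusted module
    effect persists (p < alpha), because the SNP then reaches the module
    through a path that bypasses the trait; otherwise ``uninformative``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if p_snp_trait < alpha and p_snp_module_adjusted >= alpha:
        verdict = "instrument_candidate"
    elif p_snp_trait < alpha and p_snp_module_adjusted < alpha:
        verdict = "pleiotropic"
    else:
        verdict = "uninformative"
    return IVCheckResult(
        snp=snp,
        p_snp_trait=p_snp_trait,
        p_snp_module_unadjusted=p_snp_module_unadjusted,
        p_snp_module_adjusted=p_snp_module_adjusted,
        alpha=alpha,
        verdict=verdict,
    )


def iv_pleiotropy_check(
    data: pd.DataFrame,
    snp: str,
    trait: str,
    module: str,
    covariates: CovariateSet | None = None,
    alpha: float = 0.05,
) -> IVCheckResult:
    """Screen one SNP as a candidate instrument for the trait-module link.

    Fits trait ~ SNP + X, module ~ SNP + X, and module ~ SNP + trait + X
    (``data`` must hold the dosage column, coded 0/1/2), then applies
    :func:`classify_instrument`.
    """
    dosage = data[snp].dropna().to_numpy()
    if not np.isin(dosage, [0, 1, 2]).all():
        raise ValueError("dosages must lie in {0, 1, 2}")
    covariates = covariates or CovariateSet("none")
    adj = CovariateSet(f"{covariates.id}+{trait}", (*covariates.columns, trait))
    p_trait = fit_linear_association(data, trait, snp, covariates).p
    p_mod = fit_linear_association(data, module, snp, covariates).p
    p_mod_adj = fit_linear_association(data, module, snp, adj).p
    return classify_instrument(p_trait, p_mod, p_mod_adj, alpha=alpha, snp=snp)
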