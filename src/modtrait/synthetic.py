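"""Synthetic ROSMAP-like cohort generator with known planted effects.

Emulates the data structure of a joint ROS/MAP-style ageing cohort: five
NEO-FFI personality scores on a bounded integer scale, demographic and
RNA-technical covariates, a genes-by-subjects expression matrix organised
into co-expression modules, biallelic SNP dosages, amyloid-beta and tau
measured in eight brain regions, longitudinal cognition, and a dementia
indicator. Effects along the causal chain

    trait -> module expression -> tau -> cognitive-decline slope -> AD

are planted explicitly through :class:`EffectSpec`, so every downstream
statistical stage can be tested for recovery of known truth.

All quantitative layers work on standardized scales: planted effects are
per standard deviation of the upstream variable on a unit-variance (before
noise) downstream variable, except SNP effects which are per effect allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "BRAIN_REGIONS",
    "TRAITS",
    "CohortConfig",
    "ConfigError",
    "EffectSpec",
    "ExpressionData",
    "SimulatedOutcomes",
    "SimulatedStudy",
    "generate_cohort",
    "generate_downstream",
    "generate_expression",
    "generate_genotypes",
    "simulate_mediation_trio",
    "simulate_study",
]

#: The eight regions in which amyloid and tau are quantified.
BRAIN_REGIONS = ("MF", "EC", "SF", "CG", "CALC", "HIP", "IT", "AG")

#: NEO Five-Factor Inventory trait names.
TRAITS = (
    "neuroticism",
    "conscientiousness",
    "extraversion",
    "openness",
    "agreeableness",
)

_DEFAULT_TRAIT_MEANS = {
    "neuroticism": 17.0,
    "conscientiousness": 34.0,
    "extraversion": 30.0,
    "openness": 25.0,
    "agreeableness": 34.0,
}
_DEFAULT_TRAIT_SDS = {
    "neuroticism": 6.5,
    "conscientiousness": 5.0,
    "extraversion": 6.0,
    "openness": 5.3,
    "agreeableness": 3.9,
}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class CohortConfig:
    """Demographic and trait-scale parameters of the simulated cohort.

    Defaults mirror the published demographics of the 466-subject
    ROSMAP-style analysis sample: mean age at death 88 (SD 6.8) years,
    62% female, 99% white, 16.7 (3.5) years of education, and NEO-FFI
    trait scores on a 0-48 composite scale (12 items scored 0-4 each).
    A 0-36 scale variant is supported via ``trait_max_score=36``.
    """

    n_subjects: int = 466
    female_frac: float = 287 / 466
    age_mean: float = 88.0
    age_sd: float = 6.8
    edu_mean: float = 16.7
    edu_sd: float = 3.5
    white_frac: float = 461 / 466
    study_frac: float = 0.5  # ROS vs MAP split
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRAIT_MEANS)
    )
    trait_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRAIT_SDS)
    )
    trait_max_score: int = 48
    pmi_mean: float = 7.0  # hours
    pmi_sd: float = 3.5
    n_batches: int = 8
    rin_mean: float = 7.0
    rin_sd: float = 1.0
    visits_mean: float = 8.0  # mean number of annual cognitive assessments
    seed: int = 0

    def validate(self) -> None:
        for name in ("female_frac", "white_frac", "study_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("age_sd", "edu_sd", "pmi_sd", "rin_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v!r}")
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects!r}")
        if self.n_batches < 1:
            raise ConfigError(f"n_batches must be >= 1, got {self.n_batches!r}")
        if self.trait_max_score < 1:
            raise ConfigError(
                f"trait_max_score must be >= 1, got {self.trait_max_score!r}"
            )
        if self.visits_mean < 2:
            raise ConfigError(f"visits_mean must be >= 2, got {self.visits_mean!r}")
        for trait in TRAITS:
            if trait not in self.trait_means:
                raise ConfigError(f"trait_means missing entry for {trait!r}")
            if trait not in self.trait_sds:
                raise ConfigError(f"trait_sds missing entry for {trait!r}")
            if self.trait_sds[trait] < 0:
                raise ConfigError(f"trait_sds[{trait!r}] must be >= 0")


@dataclass
class EffectSpec:
    """Planted effects along the trait -> module -> pathology -> decline chain.

    ``trait_to_module`` maps a module id to the effect (per SD of
    ``expression_trait``) on that module's latent factor. ``module_to_tau``
    and ``module_to_amyloid`` map module ids to effects (per SD of the
    module summary) on the latent sqrt-scale pathology burden.
    ``tau_to_slope`` acts per SD of latent tau on the cognitive slope and
    ``slope_to_ad`` is a logistic coefficient per SD of the latent slope.
    SNP effects are additive per effect allele: ``snp_to_trait`` on the raw
    trait score (applied before clipping), ``snp_to_module`` as
    ``{snp: (module, effect)}`` on the module factor, ``snp_to_pathology``
    as ``{snp: (mark, effect)}`` on the latent sqrt-scale burden.
    """

    trait_to_module: Mapping[str, float] = field(default_factory=dict)
    expression_trait: str = "neuroticism"
    module_to_tau: Mapping[str, float] = field(default_factory=dict)
    module_to_amyloid: Mapping[str, float] = field(default_factory=dict)
    tau_to_slope: float = 0.0
    slope_to_ad: float = 0.0
    snp_to_trait: Mapping[str, float] = field(default_factory=dict)
    snp_to_trait_target: str = "neuroticism"
    snp_to_module: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    snp_to_pathology: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    noise_sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "module": 1.0,
            "gene": 1.0,
            "tau": 1.0,
            "amyloid": 1.0,
            "region": 0.3,
            "slope": 1.0,
            "cognition": 0.25,
        }
    )

    def noise(self, layer: str) -> float:
        sd = self.noise_sds.get(layer, 0.0)
        if sd < 0:
            raise ConfigError(f"noise_sds[{layer!r}] must be >= 0, got {sd!r}")
        return float(sd)

    def validate_references(
        self,
        module_ids: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> None:
        """Check every referenced module/SNP id exists in the generated data."""
        if module_ids is not None:
            known = set(module_ids)
            referenced = (
                set(self.trait_to_module)
                | set(self.module_to_tau)
                | set(self.module_to_amyloid)
                | {m for m, _ in self.snp_to_module.values()}
            )
            missing = sorted(referenced - known)
            if missing:
                raise ConfigError(f"EffectSpec references unknown modules: {missing}")
        if snp_ids is not None:
            known = set(snp_ids)
            referenced = (
                set(self.snp_to_trait)
                | set(self.snp_to_module)
                | set(self.snp_to_pathology)
            )
            missing = sorted(referenced - known)
            if missing:
                raise ConfigError(f"EffectSpec references unknown SNPs: {missing}")


def _zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-score (ddof=1); a zero-variance vector maps to zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a cohort table: one row per subject, traits plus covariates.

    Sex is coded female=1, race white=1, study is a binary ROS/MAP
    indicator, batch a categorical string label. Trait scores are rounded,
    clipped Gaussians on ``[0, trait_max_score]``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in range(n)],
            "sex": rng.binomial(1, config.female_frac, n).astype(int),
            "age_death": config.age_mean + config.age_sd * rng.standard_normal(n),
            "education": np.clip(
                np.round(config.edu_mean + config.edu_sd * rng.standard_normal(n)),
                0,
                None,
            ),
            "race_white": rng.binomial(1, config.white_frac, n).astype(int),
            "study": rng.binomial(1, config.study_frac, n).astype(int),
            "pmi": np.clip(
                config.pmi_mean + config.pmi_sd * rng.standard_normal(n), 0.5, None
            ),
            "batch": pd.Categorical(
                [f"b{b + 1}" for b in rng.integers(0, config.n_batches, n)]
            ),
            "rin": np.clip(
                config.rin_mean + config.rin_sd * rng.standard_normal(n), 2.0, 10.0
            ),
        }
    )
    for trait in TRAITS:
        raw = config.trait_means[trait] + config.trait_sds[trait] * rng.standard_normal(n)
        cohort[trait] = np.clip(np.round(raw), 0, config.trait_max_score).astype(int)
    return cohort.set_index("subject_id", drop=False)


@dataclass
class ExpressionData:
    """Latent expression, optional counts, module map and gene loadings."""

    latent: pd.DataFrame  # genes x subjects, normalized scale
    counts: pd.DataFrame | None  # genes x subjects, NB read counts
    assignment: pd.DataFrame  # columns gene_id, module_id
    loadings: pd.Series  # per-gene factor loading


def generate_expression(
    cohort: pd.DataFrame,
    n_genes: int,
    n_modules: int,
    effects: EffectSpec,
    rng: np.random.Generator,
    *,
    background_frac: float = 0.0,
    genotypes: pd.DataFrame | None = None,
    with_counts: bool = True,
    nb_dispersion: float = 10.0,
) -> ExpressionData:
    """Generate a genes-by-subjects matrix with module co-expression structure.

    Each module has one latent factor per subject; member genes load on it
    with loadings drawn uniform on [0.4, 0.9] plus independent noise, so
    within-module correlation exceeds between-module correlation. Planted
    trait and SNP effects enter at the factor level. Counts, when
    requested, come from a negative-binomial (gamma-Poisson) link on the
    latent level.
    """
    if n_modules > n_genes:
        raise ConfigError(
            f"n_modules ({n_modules}) may not exceed n_genes ({n_genes})"
        )
    if not 0.0 <= background_frac < 1.0:
        raise ConfigError(f"background_frac must lie in [0, 1), got {background_frac!r}")
    n = len(cohort)
    module_ids = [f"m{k + 1}" for k in range(n_modules)]
    effects.validate_references(module_ids=module_ids)

    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    n_background = int(round(background_frac * n_genes))
    # every non-background gene joins a uniformly chosen module; each module
    # is guaranteed at least one member by seeding one gene per module first
    membership = np.empty(n_genes, dtype=object)
    membership[:n_background] = None
    assignable = n_genes - n_background
    if assignable < n_modules:
        raise ConfigError(
            "background_frac leaves fewer assignable genes than modules"
        )
    draws = np.concatenate(
        [np.arange(n_modules), rng.integers(0, n_modules, assignable - n_modules)]
    )
    rng.shuffle(draws)
    membership[n_background:] = [module_ids[k] for k in draws]
    rng.shuffle(membership)

    trait_z = _zscore(cohort[effects.expression_trait].to_numpy())
    sd_module = effects.noise("module")
    factors = sd_module * rng.standard_normal((n, n_modules))
    for mod, eff in effects.trait_to_module.items():
        factors[:, module_ids.index(mod)] += eff * trait_z
    if effects.snp_to_module:
        if genotypes is None:
            raise ConfigError(
                "snp_to_module effects configured but no genotypes supplied"
            )
        geno = genotypes.loc[cohort.index]
        for snp, (mod, eff) in effects.snp_to_module.items():
            factors[:, module_ids.index(mod)] += eff * geno[snp].to_numpy(dtype=float)

    loadings = pd.Series(rng.uniform(0.4, 0.9, n_genes), index=gene_ids, name="loading")
    sd_gene = effects.noise("gene")
    latent = sd_gene * rng.standard_normal((n_genes, n))
    for i, mod in enumerate(membership):
        if mod is not None:
            latent[i] += loadings.iloc[i] * factors[:, module_ids.index(mod)]
    latent_df = pd.DataFrame(latent, index=gene_ids, columns=cohort.index)

    counts_df = None
    if with_counts:
        # NB link: per-gene baseline depth, modest fold-change per latent unit
        log_base = rng.normal(math.log(50.0), 1.0, n_genes)
        mu = np.exp(log_base[:, None] + 0.3 * latent)
        lam = rng.gamma(nb_dispersion, mu / nb_dispersion)
        counts_df = pd.DataFrame(
            rng.poisson(lam), index=gene_ids, columns=cohort.index
        )

    assignment = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "module_id": [m if m is not None else "background" for m in membership],
        }
    )
    return ExpressionData(
        latent=latent_df, counts=counts_df, assignment=assignment, loadings=loadings
    )


def generate_genotypes(
    cohort: pd.DataFrame,
    n_snps: int,
    maf: float | Sequence[float],
    effects: EffectSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw Hardy-Weinberg dosages and apply planted SNP-on-trait effects.

    Returns ``(genotypes, cohort)`` where the cohort is a copy with trait
    scores re-derived when ``snp_to_trait`` effects are configured (the
    additive allele effect is added to the raw score, then rounded and
    clipped back to the trait scale).
    """
    maf_arr = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,)).copy()
    if np.any((maf_arr <= 0.0) | (maf_arr >= 0.5)):
        raise ConfigError(f"maf must lie strictly in (0, 0.5), got {maf!r}")
    snp_ids = [f"snp{j + 1:03d}" for j in range(n_snps)]
    effects.validate_references(snp_ids=snp_ids)
    n = len(cohort)
    dosages = rng.binomial(2, maf_arr, size=(n, n_snps)).astype(np.int8)
    genotypes = pd.DataFrame(dosages, index=cohort.index, columns=snp_ids)
    genotypes.attrs["maf"] = dict(zip(snp_ids, maf_arr))

    cohort = cohort.copy()
    if effects.snp_to_trait:
        trait = effects.snp_to_trait_target
        raw = cohort[trait].to_numpy(dtype=float)
        for snp, eff in effects.snp_to_trait.items():
            raw = raw + eff * genotypes[snp].to_numpy(dtype=float)
        # clip back to the configured trait scale (0-48 unless overridden)
        max_score = cohort.attrs.get("trait_max_score", 48)
        cohort[trait] = np.clip(np.round(raw), 0, max_score).astype(int)
    return genotypes, cohort


@dataclass
class SimulatedOutcomes:
    """Raw downstream layers plus the latent truth used to generate them."""

    pathology: pd.DataFrame  # long: subject_id, region, mark, value (raw, >=0)
    cognition: pd.DataFrame  # long: subject_id, visit_year, score
    ad: pd.Series  # binary AD status per subject
    truth: pd.DataFrame  # latent tau/amyloid sqrt-scale, slope per subject


def generate_downstream(
    cohort: pd.DataFrame,
    module_expr: pd.DataFrame,
    effects: EffectSpec,
    rng: np.random.Generator,
    *,
    genotypes: pd.DataFrame | None = None,
    tau_mean: float = 2.0,
    amyloid_mean: float = 1.5,
    ad_base_rate: float = 0.4,
) -> SimulatedOutcomes:
    """Generate pathology, longitudinal cognition and AD status.

    The latent sqrt-scale tau burden responds to planted module effects;
    the per-subject cognitive slope responds to latent tau; AD status is a
    Bernoulli draw from a logistic model on the latent slope. Regional raw
    values are the square of the latent sqrt-scale value plus regional
    noise (clipped at zero), so with zero regional noise the sqrt of the
    cross-region mean recovers the latent value exactly.
    """
    missing = module_expr.index.difference(cohort.index)
    extra = cohort.index.difference(module_expr.index)
    if len(missing) or len(extra):
        offenders = sorted(set(missing.tolist()) | set(extra.tolist()))
        raise ConfigError(
            f"module_expr subjects misaligned with cohort: {offenders[:10]}"
        )
    module_expr = module_expr.loc[cohort.index]
    n = len(cohort)

    def _latent(mark_mean: float, planted: Mapping[str, float], layer: str) -> np.ndarray:
        lat = mark_mean + effects.noise(layer) * rng.standard_normal(n)
        for mod, eff in planted.items():
            if mod not in module_expr.columns:
                raise ConfigError(f"EffectSpec references unknown module {mod!r}")
            lat = lat + eff * _zscore(module_expr[mod].to_numpy())
        return lat  # clipped at zero after SNP effects are applied

    tau = _latent(tau_mean, effects.module_to_tau, "tau")
    amyloid = _latent(amyloid_mean, effects.module_to_amyloid, "amyloid")
    if effects.snp_to_pathology:
        if genotypes is None:
            raise ConfigError(
                "snp_to_pathology effects configured but no genotypes supplied"
            )
        geno = genotypes.loc[cohort.index]
        for snp, (mark, eff) in effects.snp_to_pathology.items():
            dose = geno[snp].to_numpy(dtype=float)
            if mark == "tau":
                tau = tau + eff * dose
            elif mark == "amyloid":
                amyloid = amyloid + eff * dose
            else:
                raise ConfigError(
                    f"snp_to_pathology mark must be 'tau' or 'amyloid', got {mark!r}"
                )
    # a burden cannot be negative on the sqrt scale; clipping here keeps the
    # latent value identical to the measured global when regional noise is 0
    tau = np.clip(tau, 0.0, None)
    amyloid = np.clip(amyloid, 0.0, None)

    sd_region = effects.noise("region")
    records = []
    for mark, lat in (("amyloid", amyloid), ("tau", tau)):
        for region in BRAIN_REGIONS:
            sqrt_val = np.clip(lat + sd_region * rng.standard_normal(n), 0.0, None)
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": cohort.index,
                        "region": region,
                        "mark": mark,
                        "value": sqrt_val**2,
                    }
                )
            )
    pathology = pd.concat(records, ignore_index=True)

    slope = effects.tau_to_slope * _zscore(tau) + effects.noise(
        "slope"
    ) * rng.standard_normal(n)

    lam = max(cohort.attrs.get("visits_mean", 8.0) - 2.0, 0.0)
    n_visits = 2 + rng.poisson(lam, n)
    sd_cog = effects.noise("cognition")
    baseline = rng.standard_normal(n)
    cog_records = []
    for i, sid in enumerate(cohort.index):
        years = np.arange(n_visits[i], dtype=float)
        scores = baseline[i] + slope[i] * years + sd_cog * rng.standard_normal(
            n_visits[i]
        )
        cog_records.append(
            pd.DataFrame({"subject_id": sid, "visit_year": years, "score": scores})
        )
    cognition = pd.concat(cog_records, ignore_index=True)

    logit_p = math.log(ad_base_rate / (1 - ad_base_rate)) + effects.slope_to_ad * _zscore(
        slope
    )
    ad = pd.Series(
        rng.binomial(1, expit(logit_p)), index=cohort.index, name="ad"
    )

    truth = pd.DataFrame(
        {"tau_sqrt": tau, "amyloid_sqrt": amyloid, "slope": slope},
        index=cohort.index,
    )
    return SimulatedOutcomes(
        pathology=pathology, cognition=cognition, ad=ad, truth=truth
    )


@dataclass
class SimulatedStudy:
    """All layers of one simulated study, plus the truth behind them."""

    config: CohortConfig
    effects: EffectSpec
    cohort: pd.DataFrame
    genotypes: pd.DataFrame | None
    expression: ExpressionData
    module_expr: pd.DataFrame
    outcomes: SimulatedOutcomes


def simulate_study(
    config: CohortConfig,
    effects: EffectSpec,
    *,
    n_genes: int = 13484,
    n_modules: int = 47,
    n_snps: int | None = 69,
    maf: float | Sequence[float] = 0.3,
    background_frac: float = 0.0,
    with_counts: bool = False,
    seed: int | None = None,
) -> SimulatedStudy:
    """Run the full generator chain under one seed.

    A single :class:`numpy.random.Generator` is seeded once and threaded
    through cohort, genotype, expression and downstream generation in a
    fixed order, so identical ``(config, effects, seed)`` reproduce the
    study exactly. The module summary matrix is the mean of z-scored
    member genes (see :func:`modtrait.preprocess.summarize_modules`).
    """
    from modtrait.preprocess import summarize_modules

    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort = generate_cohort(config, rng)
    cohort.attrs["trait_max_score"] = config.trait_max_score
    cohort.attrs["visits_mean"] = config.visits_mean
    genotypes = None
    if n_snps:
        genotypes, cohort = generate_genotypes(cohort, n_snps, maf, effects, rng)
    expression = generate_expression(
        cohort,
        n_genes,
        n_modules,
        effects,
        rng,
        background_frac=background_frac,
        genotypes=genotypes,
        with_counts=with_counts,
    )
    module_expr = summarize_modules(
        expression.latent,
        expression.assignment[expression.assignment["module_id"] != "background"],
    )
    outcomes = generate_downstream(
        cohort, module_expr, effects, rng, genotypes=genotypes
    )
    return SimulatedStudy(
        config=config,
        effects=effects,
        cohort=cohort,
        genotypes=genotypes,
        expression=expression,
        module_expr=module_expr,
        outcomes=outcomes,
    )


def simulate_mediation_trio(
    n: int,
    a: float,
    b: float,
    c_prime: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Minimal treatment/mediator/outcome triple from a linear chain.

    ``m = a*t + e1`` and ``y = b*m + c_prime*t + e2`` with standard-normal
    treatment and independent ``N(0, noise_sd)`` residuals; the true ACME
    is ``a*b`` and the true direct effect ``c_prime``. Used as the oracle
    data-generating process for mediation-recovery checks.
    """
    t = rng.standard_normal(n)
    m = a * t + noise_sd * rng.standard_normal(n)
    y = b * m + c_prime * t + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"t": t, "m": m, "y": y})
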