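"""Shared demo-study definition for the numbered analysis drivers.

One ROSMAP-like cohort at the study's design scale (466 subjects, 47
modules, five NEO-FFI traits, 69 SNPs at MAF 0.3, amyloid/tau in 8
regions, annual cognition) with a planted causal chain through module m7:

    neuroticism --0.3--> m7 --0.4--> tau --0.4--> slope --1.2--> AD

plus a handful of weaker neuroticism effects on other modules (so the
omnibus test has a genuine excess of suggestive associations to find), a
pleiotropic SNP influencing both the trait and m7 directly, and a SNP
with a direct tau effect. Every driver regenerates the study from
``SEED``, so the scripts are standalone and mutually consistent.
"""

from modtrait.association import CovariateSet
from modtrait.preprocess import (
    build_analysis_table,
    estimate_slopes,
    transform_pathology,
)
from modtrait.synthetic import CohortConfig, EffectSpec, simulate_study

SEED = 20260920
N_SUBJECTS = 466
N_MODULES = 47
GENES_PER_MODULE = 50  # module summaries depend only weakly on this
N_SNPS = 69
TRAIT = "neuroticism"
CHAIN_MODULE = "m7"
B_PERMUTATIONS = 999
ALPHA = 0.05

# scans adjust for demographics + RNA technical covariates; pathology and
# mediation models use the demographic set
SCAN_COVARIATES = CovariateSet(
    "base_rna",
    ("age_death", "sex", "education", "race_white", "study", "pmi", "batch", "rin"),
)
BASE_COVARIATES = CovariateSet(
    "base", ("age_death", "sex", "education", "race_white", "study", "pmi")
)

EFFECTS = EffectSpec(
    trait_to_module={
        CHAIN_MODULE: 0.30,
        **{f"m{k}": 0.15 for k in (3, 6, 11, 19, 24, 30, 38, 44)},
    },
    module_to_tau={CHAIN_MODULE: 0.4},
    tau_to_slope=0.4,
    slope_to_ad=1.2,
    snp_to_trait={"snp007": 1.5},
    snp_to_module={"snp007": (CHAIN_MODULE, 0.25)},  # pleiotropic path
    snp_to_pathology={"snp021": ("tau", 0.2)},
)


def make_demo_study():
    config = CohortConfig(n_subjects=N_SUBJECTS, seed=SEED)
    return simulate_study(
        config,
        EFFECTS,
        n_genes=N_MODULES * GENES_PER_MODULE,
        n_modules=N_MODULES,
        n_snps=N_SNPS,
        maf=0.3,
        seed=SEED,
    )


def make_analysis_table(study):
    return build_analysis_table(
        study.cohort,
        study.module_expr,
        transform_pathology(study.outcomes.pathology),
        estimate_slopes(study.outcomes.cognition),
        study.outcomes.ad,
    )
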