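"""OLS engine, scans, BH-FDR: oracle equivalence and calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import analysis_table, make_study
from modtrait.association import (
    BASE_COVARIATES,
    CovariateSet,
    _scan_engine,
    bh_adjust,
    fit_linear_association,
    gene_scan_with_fdr,
    results_to_frame,
    snp_scan,
    trait_module_scan,
    trait_outcome_models,
)
from modtrait.synthetic import EffectSpec


def ols_oracle(y, X):
    """Closed-form normal equations: beta, se vector, two-sided t-test p."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    p = 2 * stats.t.sf(np.abs(beta / se), df)
    return beta, se, p


class TestFitLinearAssociation:
    def test_simple_slope_by_hand(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 2.0, 3.0], "x": [0.0, 1.0, 2.0, 3.0]})
        res = fit_linear_association(data, "y", "x")
        assert res.beta == pytest.approx(0.6)  # Sxy/Sxx = 3/5
        assert res.n_used == 4

    def test_constant_outcome_degenerate(self, rng):
        data = pd.DataFrame({"y": np.ones(20), "x": rng.normal(size=20)})
        res = fit_linear_association(data, "y", "x")
        assert res.degenerate
        assert res.beta == 0.0
        assert np.isnan(res.p)

    def test_constant_predictor_degenerate(self, rng):
        data = pd.DataFrame({"y": rng.normal(size=20), "x": np.ones(20)})
        res = fit_linear_association(data, "y", "x")
        assert res.degenerate and np.isnan(res.p)

    def test_covariate_equal_to_predictor_raises(self, rng):
        x = rng.normal(size=30)
        data = pd.DataFrame({"y": rng.normal(size=30), "x": x, "twin": x})
        with pytest.raises(ValueError, match="twin"):
            fit_linear_association(data, "y", "x", CovariateSet("c", ("twin",)))

    def test_complete_case_n_used(self, rng):
        y = rng.normal(size=30)
        y[:5] = np.nan
        data = pd.DataFrame({"y": y, "x": rng.normal(size=30)})
        assert fit_linear_association(data, "y", "x").n_used == 25

    def test_matches_normal_equations_with_covariates(self, rng):
        """Beta/SE/P equal the closed-form oracle on random 50x5 designs."""
        for _ in range(20):
            n = 50
            data = pd.DataFrame(
                rng.normal(size=(n, 5)), columns=["y", "x", "c1", "c2", "c3"]
            )
            res = fit_linear_association(
                data, "y", "x", CovariateSet("c", ("c1", "c2", "c3"))
            )
            X = np.column_stack(
                [np.ones(n), data["x"], data[["c1", "c2", "c3"]].to_numpy()]
            )
            beta, se, p = ols_oracle(data["y"].to_numpy(), X)
            assert res.beta == pytest.approx(beta[1], abs=1e-10)
            assert res.se == pytest.approx(se[1], abs=1e-10)
            assert res.p == pytest.approx(p[1], abs=1e-10)

    def test_categorical_covariate_one_hot(self, rng):
        n = 40
        data = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "x": rng.normal(size=n),
                "batch": pd.Categorical(rng.choice(["b1", "b2", "b3"], n)),
            }
        )
        res = fit_linear_association(data, "y", "x", CovariateSet("c", ("batch",)))
        X = np.column_stack(
            [
                np.ones(n),
                data["x"],
                (data["batch"] == "b2").astype(float),
                (data["batch"] == "b3").astype(float),
            ]
        )
        beta, se, _ = ols_oracle(data["y"].to_numpy(), X)
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se[1], abs=1e-10)


class TestScanEngine:
    def test_engine_matches_per_model_fit(self, rng):
        """The vectorized residualization path equals statsmodels OLS."""
        n, M = 60, 7
        Y = rng.normal(size=(n, M))
        x = rng.normal(size=n)
        C = rng.normal(size=(n, 3))
        beta, se, p = _scan_engine(Y, x, C)
        data = pd.DataFrame(C, columns=["c1", "c2", "c3"])
        data["x"] = x
        for j in range(M):
            data["y"] = Y[:, j]
            res = fit_linear_association(
                data, "y", "x", CovariateSet("c", ("c1", "c2", "c3"))
            )
            assert beta[j] == pytest.approx(res.beta, abs=1e-10)
            assert se[j] == pytest.approx(res.se, abs=1e-10)
            assert p[j] == pytest.approx(res.p, abs=1e-10)

    def test_residual_degrees_of_freedom(self, rng):
        """P values follow the t distribution with n - k - 2 residual df."""
        n, k = 25, 4
        Y = rng.normal(size=(n, 1))
        x = rng.normal(size=n)
        C = rng.normal(size=(n, k))
        beta, se, p = _scan_engine(Y, x, C)
        t = beta[0] / se[0]
        assert p[0] == pytest.approx(2 * stats.t.sf(abs(t), n - k - 2), rel=1e-12)


class TestTraitModuleScan:
    def test_one_result_per_module_ordered(self, null_study, null_analysis):
        results = trait_module_scan(
            null_analysis, null_study.module_expr, "neuroticism"
        )
        assert [r.outcome for r in results] == ["m1", "m2", "m3", "m4", "m5"]
        assert all(r.covariate_set == "base_rna" for r in results)

    def test_row_order_invariance(self, null_study, null_analysis):
        shuffled = null_analysis.sample(frac=1, random_state=0)
        r1 = trait_module_scan(null_analysis, null_study.module_expr, "neuroticism")
        r2 = trait_module_scan(shuffled, null_study.module_expr, "neuroticism")
        np.testing.assert_allclose(
            [r.beta for r in r1], [r.beta for r in r2], atol=1e-12
        )

    def test_missing_trait_rejected(self, null_study, null_analysis):
        with pytest.raises(ValueError, match="nope"):
            trait_module_scan(null_analysis, null_study.module_expr, "nope")

    def test_null_significant_count_binomial(self):
        """Under the null ~5% of 47 modules reach P<0.05: mean ~= 2.35.

        The tolerance is 3 binomial standard errors of the replicate mean.
        """
        reps, total = 200, 0
        for rep in range(reps):
            study = make_study(
                n_subjects=150, n_genes=94, n_modules=47, n_snps=None, seed=5000 + rep
            )
            scan = trait_module_scan(
                study.cohort, study.module_expr, "neuroticism", CovariateSet("none")
            )
            total += sum(r.p < 0.05 for r in scan)
        mean = total / reps
        tol = 3 * np.sqrt(47 * 0.05 * 0.95 / reps)
        assert abs(mean - 2.35) < tol

    def test_planted_module_attains_minimum_p(self):
        """A 0.3-per-SD planted effect wins the scan in >=90% of replicates."""
        reps, wins = 100, 0
        for rep in range(reps):
            study = make_study(
                n_subjects=466,
                n_genes=100,
                n_modules=10,
                n_snps=None,
                seed=6000 + rep,
                effects=EffectSpec(trait_to_module={"m7": 0.3}),
            )
            scan = trait_module_scan(
                study.cohort, study.module_expr, "neuroticism", CovariateSet("none")
            )
            best = min(scan, key=lambda r: r.p)
            wins += best.outcome == "m7"
        assert wins / reps >= 0.90


def brute_force_bh(pvals):
    """q_i = min over j with p_j >= p_i of p_(j) * m / rank_j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    adjusted = p[order] * m / np.arange(1, m + 1)
    running = np.minimum.accumulate(adjusted[::-1])[::-1]
    q[order] = np.minimum(running, 1.0)
    return q


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_three_value_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.03, 0.5]), [0.015, 0.045, 0.5]
        )

    def test_flat_ladder_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_brute_force_on_permutations(self):
        base = [0.001, 0.011, 0.03, 0.04, 0.2, 0.9]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(
                bh_adjust(list(perm)), brute_force_bh(perm), atol=1e-12
            )

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestGeneScan:
    def test_single_gene_q_equals_p(self, null_study, null_analysis):
        expr = null_study.expression.latent.iloc[:1]
        (res,) = gene_scan_with_fdr(
            null_analysis, expr, "neuroticism", CovariateSet("none")
        )
        assert res.q == pytest.approx(res.p)

    def test_null_family_rarely_discovers(self):
        """BH at q<0.05 on 499 null genes: any-discovery rate ~< 5%.

        Allows 3 binomial SE on the replicate fraction.
        """
        reps, any_hit = 60, 0
        for rep in range(reps):
            study = make_study(
                n_subjects=150, n_genes=499, n_modules=4, n_snps=None, seed=7000 + rep
            )
            results = gene_scan_with_fdr(
                study.cohort,
                study.expression.latent,
                "neuroticism",
                CovariateSet("none"),
            )
            any_hit += any(r.q is not None and r.q < 0.05 for r in results)
        assert any_hit / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_planted_gene_reaches_q05(self):
        """One gene with a 0.4-per-SD effect reaches q<0.05 in >=80%."""
        reps, hits = 50, 0
        for rep in range(reps):
            study = make_study(
                n_subjects=466, n_genes=80, n_modules=4, n_snps=None, seed=7500 + rep
            )
            trait = study.cohort["neuroticism"]
            z = ((trait - trait.mean()) / trait.std(ddof=1)).to_numpy()
            expr = study.expression.latent.copy()
            expr.iloc[0] = expr.iloc[0] + 0.4 * z
            results = gene_scan_with_fdr(
                study.cohort, expr, "neuroticism", CovariateSet("none")
            )
            target = results[0]
            assert target.outcome == expr.index[0]
            hits += target.q < 0.05
        assert hits / reps >= 0.80

    def test_fdr_family_is_exactly_the_scanned_set(self, null_study, null_analysis):
        expr = null_study.expression.latent
        full = gene_scan_with_fdr(null_analysis, expr, "neuroticism", CovariateSet("none"))
        sub = gene_scan_with_fdr(
            null_analysis, expr.iloc[:10], "neuroticism", CovariateSet("none")
        )
        # same p for the shared genes, different q because the family differs
        assert sub[0].p == pytest.approx(full[0].p, abs=1e-12)
        frame = results_to_frame(full)
        assert frame["q"].notna().all()


class TestSnpScan:
    def test_outcome_equal_to_dosage_perfect_fit(self, rng):
        dosage = rng.integers(0, 3, 50).astype(float)
        cohort = pd.DataFrame(
            {"y": dosage}, index=[f"s{i}" for i in range(50)]
        )
        geno = pd.DataFrame({"snp1": dosage}, index=cohort.index)
        (res,) = snp_scan(cohort, geno, "y", CovariateSet("none"))
        assert res.beta == pytest.approx(1.0)
        assert 0 < res.p <= 1e-290  # capped at machine minimum, never zero

    def test_monomorphic_snp_flagged_not_dropped(self, rng):
        cohort = pd.DataFrame(
            {"y": rng.normal(size=30)}, index=[f"s{i}" for i in range(30)]
        )
        geno = pd.DataFrame(
            {"mono": np.zeros(30), "poly": rng.integers(0, 3, 30)}, index=cohort.index
        )
        results = snp_scan(cohort, geno, "y", CovariateSet("none"))
        by_name = {r.predictor: r for r in results}
        assert by_name["mono"].degenerate and np.isnan(by_name["mono"].p)
        assert not by_name["poly"].degenerate

    def test_fractional_dosage_rejected(self, rng):
        cohort = pd.DataFrame(
            {"y": rng.normal(size=10)}, index=[f"s{i}" for i in range(10)]
        )
        geno = pd.DataFrame({"snp1": np.linspace(0, 2, 10)}, index=cohort.index)
        with pytest.raises(ValueError, match="dosage"):
            snp_scan(cohort, geno, "y", CovariateSet("none"))

    def test_planted_pathology_effect_sign_recovery(self):
        """Per-allele tau effect of 0.2 at n=398: sign recovered >=95%."""
        reps, hits = 200, 0
        eff = EffectSpec(snp_to_pathology={"snp001": ("tau", 0.2)})
        for rep in range(reps):
            study = make_study(
                n_subjects=398,
                n_genes=20,
                n_modules=2,
                n_snps=3,
                seed=8000 + rep,
                effects=eff,
            )
            an = analysis_table(study)
            results = snp_scan(
                an, study.genotypes, "tau_sqrt_global", CovariateSet("none")
            )
            hits += {r.predictor: r.beta for r in results}["snp001"] > 0
        assert hits / reps >= 0.95


class TestTraitOutcomeModels:
    def covariate_sets(self):
        return [
            BASE_COVARIATES,
            CovariateSet("base+amyloid", (*BASE_COVARIATES.columns, "amyloid_sqrt_global")),
            CovariateSet("base+tau", (*BASE_COVARIATES.columns, "tau_sqrt_global")),
            CovariateSet(
                "base+allpath",
                (*BASE_COVARIATES.columns, "amyloid_sqrt_global", "tau_sqrt_global"),
            ),
        ]

    def test_one_row_per_covariate_set(self, chain_analysis):
        results = trait_outcome_models(
            chain_analysis, "neuroticism", "slope", self.covariate_sets()
        )
        assert [r.covariate_set for r in results] == [
            "base",
            "base+amyloid",
            "base+tau",
            "base+allpath",
        ]

    def test_empty_covariate_sets_rejected(self, chain_analysis):
        with pytest.raises(ValueError):
            trait_outcome_models(chain_analysis, "neuroticism", "slope", [])

    def test_tau_adjustment_attenuates_mediated_association(self):
        """When tau fully mediates trait->slope, |beta| shrinks under +TAU."""
        reps, shrunk = 100, 0
        eff = EffectSpec(
            trait_to_module={"m1": 0.8},
            module_to_tau={"m1": 0.8},
            tau_to_slope=0.8,
        )
        sets = [
            CovariateSet("base", ()),
            CovariateSet("base+tau", ("tau_sqrt_global",)),
        ]
        for rep in range(reps):
            study = make_study(
                n_subjects=300,
                n_genes=40,
                n_modules=2,
                n_snps=None,
                seed=9000 + rep,
                effects=eff,
            )
            an = analysis_table(study)
            base, adj = trait_outcome_models(an, "neuroticism", "slope", sets)
            shrunk += abs(adj.beta) < abs(base.beta)
        assert shrunk / reps >= 0.95

    def test_noiseless_full_mediation_conditional_zero(self):
        eff = EffectSpec(
            trait_to_module={"m1": 0.5},
            module_to_tau={"m1": 0.5},
            tau_to_slope=0.7,
            noise_sds={
                "module": 1.0,
                "gene": 1.0,
                "tau": 1.0,
                "region": 0.0,
                "slope": 0.0,
                "cognition": 0.0,
            },
        )
        study = make_study(
            n_subjects=200, n_genes=30, n_modules=2, n_snps=None, seed=17, effects=eff
        )
        an = analysis_table(study)
        res = trait_outcome_models(
            an,
            "neuroticism",
            "slope",
            [CovariateSet("base+tau", ("tau_sqrt_global",))],
        )[0]
        assert res.beta == pytest.approx(0.0, abs=1e-10)
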