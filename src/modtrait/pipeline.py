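"""Pipeline orchestration: config, stage execution, manifest, TSV/JSON IO.

``run_pipeline`` chains simulate/ingest -> preprocess -> trait-module scan
-> permutation omnibus -> gene-level FDR scan -> pathology scans -> IV
screens -> mediation chain, writing one tab-delimited or JSON artifact per
stage plus a manifest with seeds, thresholds and file checksums, so a run
is reproducible and self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from modtrait import association as assoc
from modtrait import mediation as med
from modtrait import omnibus as omni
from modtrait import preprocess as prep
from modtrait import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_table",
    "run_pipeline",
    "write_study",
    "write_table",
]


def write_table(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def write_study(study: syn.SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every simulated layer as the standard TSV formats."""
    out = Path(out_dir)
    files = {
        "phenotype": write_table(
            study.cohort.reset_index(drop=True), out / "phenotype.tsv"
        ),
        "expression": write_table(
            study.expression.latent, out / "expression.tsv", index=True
        ),
        "modules": write_table(study.expression.assignment, out / "modules.tsv"),
        "pathology": write_table(study.outcomes.pathology, out / "pathology.tsv"),
        "cognition": write_table(study.outcomes.cognition, out / "cognition.tsv"),
        "ad_status": write_table(
            study.outcomes.ad.rename("ad").reset_index(), out / "ad_status.tsv"
        ),
    }
    if study.expression.counts is not None:
        files["counts"] = write_table(
            study.expression.counts, out / "counts.tsv", index=True
        )
    if study.genotypes is not None:
        files["genotypes"] = write_table(
            study.genotypes, out / "genotypes.tsv", index=True
        )
    return files


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one YAML/JSON document).

    Exactly one of ``inputs`` (paths to existing TSVs) or ``simulate``
    (generator settings) must be present.
    """

    out_dir: str = "results/run"
    trait: str = "neuroticism"
    seed: int = 0
    B: int = 1000
    n_sims: int = 1000
    alpha: float = 0.05
    statistic: str = "count"
    envelope_levels: tuple[float, ...] = (0.90, 0.95)
    chain: tuple[str, ...] | None = None
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, str] | None = None
    scan_covariates: tuple[str, ...] = assoc.BASE_RNA_COVARIATES.columns
    pathology_covariates: tuple[str, ...] = assoc.BASE_COVARIATES.columns

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must contain exactly one of 'simulate' or 'inputs'"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kwargs = dict(raw)
        for key in ("chain", "scan_covariates", "pathology_covariates", "envelope_levels"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _effects_from_config(block: Mapping[str, Any]) -> syn.EffectSpec:
    eff = dict(block.get("effects", {}))
    for key in ("snp_to_module", "snp_to_pathology"):
        if key in eff:
            eff[key] = {k: tuple(v) for k, v in eff[key].items()}
    return syn.EffectSpec(**eff)


def _simulate_stage(config: PipelineConfig) -> syn.SimulatedStudy:
    block = dict(config.simulate or {})
    effects = _effects_from_config(block)
    cohort_kwargs = dict(block.get("cohort", {}))
    cohort_kwargs.setdefault("n_subjects", block.get("n_subjects", 466))
    cc = syn.CohortConfig(seed=config.seed, **cohort_kwargs)
    return syn.simulate_study(
        cc,
        effects,
        n_genes=block.get("n_genes", 13484),
        n_modules=block.get("n_modules", 47),
        n_snps=block.get("n_snps", 69),
        maf=block.get("maf", 0.3),
        with_counts=block.get("with_counts", False),
        seed=config.seed,
    )


def _signed_neglog10(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    with np.errstate(divide="ignore"):
        frame["signed_neglog10_p"] = np.sign(frame["beta"]) * -np.log10(frame["p"])
    return frame


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name: str, *paths: Path) -> None:
        stages.append(
            {
                "name": name,
                "files": [
                    {
                        "path": str(p.relative_to(out)),
                        "sha256": _sha256(p),
                        "bytes": p.stat().st_size,
                    }
                    for p in paths
                ],
            }
        )
        logger.info("stage %s: wrote %d file(s)", name, len(paths))

    # -- stage 1: simulate or ingest ------------------------------------
    if config.simulate is not None:
        study = _simulate_stage(config)
        files = write_study(study, out / "data")
        record("simulate", *files.values())
        cohort = study.cohort
        expression = study.expression.latent
        assignment = study.expression.assignment
        genotypes = study.genotypes
        pathology = study.outcomes.pathology
        cognition = study.outcomes.cognition
        ad = study.outcomes.ad
    else:
        paths = dict(config.inputs or {})
        cohort = read_table(paths["phenotype"]).set_index("subject_id", drop=False)
        expression = read_table(paths["expression"], index_col=0)
        assignment = read_table(paths["modules"])
        genotypes = (
            read_table(paths["genotypes"], index_col=0)
            if "genotypes" in paths
            else None
        )
        pathology = read_table(paths["pathology"])
        cognition = read_table(paths["cognition"])
        ad = (
            read_table(paths["ad_status"]).set_index("subject_id")["ad"]
            if "ad_status" in paths
            else None
        )
        if "counts" in paths:
            counts = read_table(paths["counts"], index_col=0)
            kept = prep.filter_low_expression(counts)
            expression = expression.loc[expression.index.intersection(kept)]
        record("ingest")

    # -- stage 2: preprocess --------------------------------------------
    assignment_fg = assignment[assignment["module_id"] != "background"]
    module_expr = prep.summarize_modules(expression, assignment_fg)
    panel = prep.transform_pathology(pathology)
    slopes = prep.estimate_slopes(cognition)
    analysis = prep.build_analysis_table(cohort, module_expr, panel, slopes, ad)
    record(
        "preprocess",
        write_table(module_expr, out / "module_expression.tsv", index=True),
        write_table(panel, out / "pathology_panel.tsv", index=True),
        write_table(slopes, out / "decline_slopes.tsv", index=True),
    )

    scan_cov = assoc.CovariateSet("base_rna", config.scan_covariates)
    path_cov = assoc.CovariateSet("base", config.pathology_covariates)

    # -- stage 3: trait-module scan -------------------------------------
    scan = assoc.trait_module_scan(analysis, module_expr, config.trait, scan_cov)
    scan_frame = assoc.results_to_frame(scan)
    record("trait_module_scan", write_table(scan_frame, out / "trait_module_scan.tsv"))

    # -- stage 4: permutation omnibus + QQ envelope ---------------------
    null = omni.build_permutation_null(
        analysis, module_expr, config.trait, scan_cov, B=config.B, seed=config.seed
    )
    result = omni.omnibus_p(scan, null, statistic=config.statistic, alpha=config.alpha)
    envelope = omni.qq_envelope(null, levels=config.envelope_levels)
    observed_sorted = np.sort([r.p for r in scan])
    envelope["observed"] = -np.log10(observed_sorted)
    omnibus_path = out / "omnibus.json"
    omnibus_path.write_text(
        json.dumps(
            {
                "statistic": result.statistic,
                "observed": result.observed,
                "p": result.p,
                "B": result.B,
                "alpha": result.alpha,
            },
            indent=2,
        )
    )
    record(
        "omnibus",
        omnibus_path,
        write_table(envelope, out / "qq_envelope.tsv"),
    )

    # -- stage 5: gene-level scan with FDR ------------------------------
    hits = [r.outcome for r in scan if r.p < config.alpha]
    if not hits:  # fall back to the top modules so the stage always runs
        hits = scan_frame.nsmallest(4, "p")["outcome"].tolist()
    genes = assignment_fg.loc[
        assignment_fg["module_id"].isin(hits), "gene_id"
    ].tolist()
    gene_results = assoc.gene_scan_with_fdr(
        analysis, expression.loc[expression.index.intersection(genes)],
        config.trait, scan_cov,
    )
    gene_frame = assoc.results_to_frame(gene_results)
    record("gene_scan", write_table(gene_frame, out / "gene_scan.tsv"))

    # -- stage 6: pathology scans (trait, modules, SNPs) ----------------
    path_results = []
    marks = sorted({c.rsplit("_sqrt_", 1)[0] for c in panel.columns})
    for mark in marks:
        path_results.append(
            assoc.fit_linear_association(
                analysis, f"{mark}_sqrt_global", config.trait, path_cov
            )
        )
    region_cols = [c for c in panel.columns if not c.endswith("_global")]
    target_modules = hits[:4]
    for mod in target_modules:
        for col in region_cols:
            path_results.append(
                assoc.fit_linear_association(analysis, col, mod, scan_cov)
            )
    if genotypes is not None:
        for mark in marks:
            path_results.extend(
                assoc.snp_scan(analysis, genotypes, f"{mark}_sqrt_global", path_cov)
            )
    path_frame = _signed_neglog10(assoc.results_to_frame(path_results))
    record("pathology_scan", write_table(path_frame, out / "pathology_scan.tsv"))

    # -- stage 7: instrumental-variable screens -------------------------
    iv_records = []
    if genotypes is not None and target_modules:
        module = target_modules[0]
        screen_data = analysis.join(genotypes.astype(float))
        for snp in genotypes.columns:
            try:
                check = med.iv_pleiotropy_check(
                    screen_data, snp, config.trait, module, path_cov, config.alpha
                )
            except ValueError:
                continue  # monomorphic dosage in the complete cases
            iv_records.append(vars(check))
    iv_path = out / "iv_checks.json"
    iv_path.write_text(json.dumps(iv_records, indent=2, default=float))
    record("iv_checks", iv_path)

    # -- stage 8: mediation chain ---------------------------------------
    chain = config.chain
    if chain is None:
        module = target_modules[0] if target_modules else module_expr.columns[0]
        chain = (config.trait, module, "tau_sqrt_global", "slope")
        if ad is not None:
            chain = (*chain, "ad")
    med_results = med.chain_mediation(
        analysis, chain, path_cov, n_sims=config.n_sims, seed=config.seed
    )
    med_path = out / "mediation.json"
    med_path.write_text(
        json.dumps([vars(r) for r in med_results], indent=2, default=float)
    )
    record("mediation", med_path)

    manifest = {
        "seed": config.seed,
        "trait": config.trait,
        "B": config.B,
        "n_sims": config.n_sims,
        "alpha": config.alpha,
        "statistic": config.statistic,
        "chain": list(chain),
        "omnibus_p": result.p,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
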