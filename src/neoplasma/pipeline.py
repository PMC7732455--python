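"""End-to-end orchestration of the analysis stages.

Stage order: read -> flag filter -> two branches:

* PCA branch (optional): union valid-value filter -> left-censored
  imputation -> PCA.  The imputed matrix exists only inside this branch.
* Testing branch: per-arm valid-value filter -> batch correction ->
  paired mixed-model differential abundance -> BH -> significance gate,
  with the Fisher missingness analysis run on the pre-filter matrix.

Then trajectories (changes, correlation matrix, optional target screen),
the immunoglobulin panel with half-life estimates for decaying species,
and protein-mRNA concordance when RNA counts are supplied.  A manifest
records the configuration hash, derived stage seeds, package versions and
per-stage row counts.  All randomness flows from one root seed through
named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    FOLLOWUP_DOLS,
    ProteinQuantMatrix,
    RnaCountMatrix,
    read_protein_groups,
    read_rna_counts,
    read_sample_meta,
    write_results_table,
)
from .diffabund import fisher_missingness, fit_paired_lmm
from .immunoglobulin import compute_ig_ratios, estimate_half_life
from .integration import concordance, normalize_counts, rna_changes
from .ordination import ImputationParams, impute_left_censored, run_pca
from .preprocess import (
    correct_batch,
    filter_flags,
    filter_valid_values,
    filter_valid_values_union,
    test_global_distributions,
)
from .trajectories import compute_changes, correlation_matrix, screen_against

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (int(root_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    # input paths (ignored when in-memory objects are passed to run_all)
    protein_groups: str | None = None
    sample_map: dict | None = None
    sample_meta: str | None = None
    rna_counts: str | None = None
    # stage parameters
    min_fraction: float = 0.5
    q: float = 0.01
    tune_sigma: float = 0.3
    n_components: int = 5
    fdr: float = 0.05
    lfc: float = 0.2
    covariates: tuple = ("sex", "batch")
    batch_covariates: tuple = ("dol", "sex")
    n_perm: int = 10000
    bootstrap_n: int = 2000
    concordance_threshold: float = 0.3
    screen_target: str | None = None
    half_life_proteins: tuple = ()
    ig_ref: str = "IGHG2"
    # stage toggles
    run_pca: bool = True
    run_global_test: bool = True
    run_batch_correction: bool = True
    run_diffabund: bool = True
    run_trajectories: bool = True
    run_ig: bool = True
    run_integration: bool = True
    seed: int = 0
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(
    config: PipelineConfig,
    matrix: ProteinQuantMatrix | None = None,
    rna: RnaCountMatrix | None = None,
    meta: pd.DataFrame | None = None,
) -> dict:
    """Run the configured stages; returns a results bundle with a manifest.

    In-memory inputs take precedence over configured paths.
    """
    cfg = config
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "root_seed": cfg.seed,
        "stage_seeds": {},
        "counts": {},
    }
    bundle: dict = {"manifest": manifest}

    if meta is None:
        if cfg.sample_meta is None:
            raise ValueError("no sample metadata configured")
        meta = read_sample_meta(cfg.sample_meta)
    if matrix is None:
        if cfg.protein_groups is None:
            raise ValueError("no protein matrix: set protein_groups")
        sample_map = cfg.sample_map or {s: s for s in meta["sample_id"]}
        matrix = read_protein_groups(cfg.protein_groups, sample_map)
    if rna is None and cfg.rna_counts is not None:
        rna = read_rna_counts(cfg.rna_counts)

    manifest["counts"]["input_proteins"] = matrix.n_proteins
    manifest["counts"]["samples"] = len(matrix.samples)

    flagged, flag_report = filter_flags(matrix)
    bundle["flag_report"] = flag_report
    manifest["counts"]["after_flag_filter"] = flagged.n_proteins

    if cfg.run_global_test:
        seed = stage_seed(cfg.seed, "global_test")
        manifest["stage_seeds"]["global_test"] = seed
        bundle["global_test"] = test_global_distributions(
            flagged, meta, n_perm=cfg.n_perm, seed=seed
        )

    if cfg.run_pca:
        union, union_report = filter_valid_values_union(flagged, meta, cfg.min_fraction)
        seed = stage_seed(cfg.seed, "imputation")
        manifest["stage_seeds"]["imputation"] = seed
        imputed = impute_left_censored(
            union, ImputationParams(q=cfg.q, tune_sigma=cfg.tune_sigma, seed=seed)
        )
        bundle["pca"] = run_pca(imputed, n_components=cfg.n_components)
        manifest["counts"]["pca_proteins"] = union.n_proteins
        del imputed  # quarantine: the imputed matrix never leaves this branch

    corrected_arms: dict[int, ProteinQuantMatrix] = {}
    if cfg.run_diffabund:
        diff_results = {}
        missingness = {}
        batch_models = {}
        for dol in FOLLOWUP_DOLS:
            if not (meta["dol"] == dol).any():
                continue
            arm_matrix, vv_report = filter_valid_values(flagged, meta, dol, cfg.min_fraction)
            flag_report.n_removed_valid_value[dol] = vv_report.n_removed_valid_value[dol]
            if cfg.run_batch_correction and meta["batch"].nunique() > 1:
                arm_matrix, batch_models[dol] = correct_batch(
                    arm_matrix, meta, covariates=cfg.batch_covariates
                )
            corrected_arms[dol] = arm_matrix
            diff_results[dol] = fit_paired_lmm(
                arm_matrix, meta, dol, covariates=cfg.covariates,
                fdr=cfg.fdr, lfc=cfg.lfc
            )
            missingness[dol] = fisher_missingness(flagged, meta, dol)
            manifest["counts"][f"tested_dol{dol}"] = int(
                (~diff_results[dol].frame["not_testable"]).sum()
            )
            manifest["counts"][f"significant_dol{dol}"] = diff_results[dol].n_significant
        bundle["diffabund"] = diff_results
        bundle["missingness"] = missingness
        bundle["batch_models"] = batch_models

    corrected_full = flagged
    if cfg.run_batch_correction and meta["batch"].nunique() > 1:
        corrected_full, _ = correct_batch(flagged, meta, covariates=cfg.batch_covariates)

    traj = None
    if cfg.run_trajectories or cfg.run_ig or (cfg.run_integration and rna is not None):
        traj = compute_changes(corrected_full, meta)
        bundle["trajectories"] = traj
    if cfg.run_trajectories and traj is not None:
        bundle["correlation_matrix"] = correlation_matrix(traj)
        if cfg.screen_target is not None:
            bundle["screen"] = screen_against(traj, cfg.screen_target)

    if cfg.run_ig and corrected_full.ibaq is not None and traj is not None:
        try:
            bundle["ig_panel"] = compute_ig_ratios(corrected_full, meta, ref=cfg.ig_ref)
        except KeyError as exc:
            logger.warning("Ig panel skipped: %s", exc)
        half_lives = {}
        targets = cfg.half_life_proteins or [
            pid for pid, gene in corrected_full.records["gene_name"].items()
            if gene in ("IGHG1", "IGHG2", "IGHG3", "IGHG4")
        ]
        for pid in targets:
            if pid not in traj.delta.index:
                continue
            seed = stage_seed(cfg.seed, f"halflife:{pid}")
            manifest["stage_seeds"][f"halflife:{pid}"] = seed
            half_lives[pid] = estimate_half_life(
                traj, pid, bootstrap_n=cfg.bootstrap_n, seed=seed
            )
        bundle["half_lives"] = half_lives

    if cfg.run_integration and rna is not None and traj is not None:
        norm = normalize_counts(rna)
        gene_traj = rna_changes(norm, meta)
        gene_set = set(gene_traj.delta.index)
        pairs = pd.DataFrame(
            [
                {"gene": gene, "protein": pid}
                for pid, gene in corrected_full.records["gene_name"].items()
                if gene in gene_set
            ]
        )
        if len(pairs):
            bundle["concordance"] = concordance(
                traj, gene_traj, pairs, threshold=cfg.concordance_threshold
            )
            manifest["counts"]["concordant_pairs"] = bundle["concordance"].n_concordant

    if cfg.outdir:
        _write_bundle(bundle, Path(cfg.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = bundle["manifest"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if "flag_report" in bundle:
        write_results_table(bundle["flag_report"], outdir / "filter_report.tsv")
    if "pca" in bundle:
        write_results_table(bundle["pca"], outdir / "pca_scores.tsv")
    for dol, res in bundle.get("diffabund", {}).items():
        write_results_table(res, outdir / f"diffabund_dol{dol}.tsv")
    for dol, res in bundle.get("missingness", {}).items():
        write_results_table(res, outdir / f"missingness_dol{dol}.tsv")
    if "correlation_matrix" in bundle:
        bundle["correlation_matrix"].corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t")
    if "screen" in bundle:
        write_results_table(bundle["screen"], outdir / "correlation_screen.tsv")
    if "ig_panel" in bundle:
        write_results_table(bundle["ig_panel"], outdir / "ig_panel.tsv")
    if bundle.get("half_lives"):
        frames = [r.to_frame() for r in bundle["half_lives"].values()]
        write_results_table(pd.concat(frames, ignore_index=True), outdir / "half_lives.tsv")
    if "concordance" in bundle:
        write_results_table(bundle["concordance"], outdir / "concordance.tsv")
    if "global_test" in bundle:
        gt = bundle["global_test"]
        write_results_table(
            pd.DataFrame([{"statistic": gt.statistic, "p_value": gt.p_value,
                           "n_perm": gt.n_perm, "group": gt.group}]),
            outdir / "global_distribution_test.tsv",
        )
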