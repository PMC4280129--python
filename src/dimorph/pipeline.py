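"""End-to-end orchestration: load or simulate, call, aggregate, report.

`run_pipeline` executes io -> SDE calling -> cross-tissue taxonomy ->
sharing enrichment -> validation -> clustering/MA figures, writing
every table as TSV plus a JSON manifest (version, seed, criteria,
per-stage row counts). The manifest contains no timestamps, so two
runs with the same config and seed produce identical manifests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dimorph.clustering_viz import (
    build_ratio_matrix,
    linkage_to_newick,
    ma_points,
    plot_ma,
    plot_ratio_heatmap,
    ward_cluster_2way,
)
from dimorph.concordance import (
    cross_tissue_concordance,
    pairwise_sample_correlations,
    sample_cluster_check,
    sex_separation_test,
)
from dimorph.cross_tissue import (
    breadth_statistics,
    build_profiles,
    distribution_summary,
    expression_summary,
    identify_ubiquitous_sde,
    per_tissue_incidence,
    tissue_count_distribution,
)
from dimorph.io_formats import (
    join_and_validate,
    read_exclude_list,
    read_expression_matrix,
    read_sample_annotation,
    write_expression_matrix,
    write_stats_table,
)
from dimorph.sde_calling import SdeCriteria, call_sde_all
from dimorph.sharing_enrichment import (
    enrichment_null_mc,
    enrichment_table,
    render_table2_matrix,
)
from dimorph.synthetic import SimulationConfig, generate_dataset, recovery_metrics

log = logging.getLogger("dimorph")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of real input or simulation.

    Real input: matrix_path + samples_path (+ optional exclude_path).
    Simulation: a SimulationConfig (seeded from ``seed``).
    """

    out_dir: str | Path = "dimorph_out"
    matrix_path: str | Path | None = None
    samples_path: str | Path | None = None
    exclude_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    criteria: SdeCriteria = field(default_factory=SdeCriteria)
    bh_scope: str = "all"
    ubiquitous_majority: float = 0.5
    seed: int = 0
    do_enrichment: bool = True
    do_clustering: bool = True
    do_validation: bool = True
    figures: bool = False
    write_inputs: bool = False
    mc_reps: int = 0

    def validate(self) -> None:
        real = self.matrix_path is not None or self.samples_path is not None
        sim = self.simulation is not None
        if real == sim:
            raise ValueError("specify exactly one of (matrix+samples) or simulation")
        if real and (self.matrix_path is None or self.samples_path is None):
            raise ValueError("both matrix_path and samples_path are required")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from dimorph import __version__

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "criteria": {
            "expr_threshold": config.criteria.expr_threshold,
            "min_abs_log2_diff": config.criteria.min_abs_log2_diff,
            "max_q": config.criteria.max_q,
        },
        "bh_scope": config.bh_scope,
        "stages": {},
        "outputs": [],
        "warnings": [],
    }

    def _record(name: str, **info) -> None:
        manifest["stages"][name] = info
        log.info("stage %s: %s", name, info)

    def _emit(df: pd.DataFrame, name: str, index: bool = True) -> None:
        _write_tsv(df, out / name, index=index)
        manifest["outputs"].append(name)

    # --- io ------------------------------------------------------------
    truth = None
    if config.simulation is not None:
        matrix, annotation, truth = generate_dataset(config.simulation, seed=config.seed)
        manifest["input"] = {"mode": "simulation", "n_probesets": int(matrix.shape[0])}
        if config.write_inputs:
            write_expression_matrix(matrix, out / "matrix.tsv")
            annotation.to_csv(out / "samples.tsv", sep="\t", index=False)
            _emit(truth.effects, "truth_effects.tsv")
            truth.labels.to_frame().to_csv(out / "truth_labels.tsv", sep="\t")
            manifest["outputs"] += ["matrix.tsv", "samples.tsv", "truth_labels.tsv"]
    else:
        matrix = read_expression_matrix(config.matrix_path)
        annotation = read_sample_annotation(config.samples_path)
        manifest["input"] = {"mode": "files", "matrix": str(config.matrix_path)}
    exclude = read_exclude_list(config.exclude_path) if config.exclude_path else None
    dataset = join_and_validate(matrix, annotation, exclude=exclude)
    _record(
        "io",
        n_probesets=int(dataset.matrix.shape[0]),
        n_samples=int(dataset.matrix.shape[1]),
        n_tissues=len(dataset.tissues),
        small_groups=[list(g) for g in dataset.small_groups],
    )

    # --- sde calling ----------------------------------------------------
    all_stats = call_sde_all(dataset, config.criteria, bh_scope=config.bh_scope)
    write_stats_table(all_stats, out / "sde_stats.tsv")
    manifest["outputs"].append("sde_stats.tsv")
    n_degenerate = int(sum(df["degenerate_variance"].sum() for df in all_stats.values()))
    if n_degenerate:
        manifest["warnings"].append(f"{n_degenerate} degenerate-variance tests (p set to 0)")
    _record(
        "sde_calling",
        n_tests=int(sum(len(df) for df in all_stats.values())),
        n_sde_calls=int(sum(df["sde"].sum() for df in all_stats.values())),
    )

    # --- cross-tissue ----------------------------------------------------
    profiles = build_profiles(all_stats)
    ubiq = identify_ubiquitous_sde(profiles, config.ubiquitous_majority)
    exclude_ids = list(ubiq.index)
    dist = tissue_count_distribution(profiles)
    _emit(dist, "tissue_count_distribution.tsv")
    _emit(ubiq, "ubiquitous_sde.tsv")
    incidence = per_tissue_incidence(profiles, exclude=exclude_ids)
    _emit(incidence, "per_tissue_incidence.tsv")
    summary = {
        "distribution": distribution_summary(dist),
        "breadth": breadth_statistics(profiles),
        "expression": expression_summary(profiles),
    }
    (out / "cross_tissue_summary.json").write_text(json.dumps(summary, indent=2))
    manifest["outputs"].append("cross_tissue_summary.json")
    _record(
        "cross_tissue",
        n_sde_probesets=summary["distribution"]["n_sde_total"],
        n_ubiquitous=len(exclude_ids),
    )

    n_multi = int((profiles.n_sde[~profiles.probesets.isin(exclude_ids)] >= 2).sum())

    # --- sharing enrichment ----------------------------------------------
    if config.do_enrichment and n_multi > 0:
        table = enrichment_table(profiles, exclude=exclude_ids)
        _emit(table, "pair_sharing.tsv", index=False)
        _emit(render_table2_matrix(profiles, exclude=exclude_ids), "pair_sharing_matrix.tsv")
        info = {"n_pairs": len(table), "n_multi_tissue_sde": n_multi}
        if config.mc_reps > 0:
            null = enrichment_null_mc(
                profiles, config.mc_reps, seed=config.seed + 1, exclude=exclude_ids
            )
            info["mc_mean_enrichment"] = null.mean_enrichment
            info["mc_reps"] = config.mc_reps
        _record("sharing_enrichment", **info)
    elif config.do_enrichment:
        manifest["warnings"].append("no multi-tissue SDE probesets; sharing stage skipped")

    # --- validation -------------------------------------------------------
    if config.do_validation:
        totals = incidence["n_sde_total"]
        focus = totals.idxmax() if (totals > 0).any() else None
        if focus is not None:
            subset = list(profiles.probesets[profiles.sde[focus]])
            if len(subset) >= 3:
                corr = pairwise_sample_correlations(dataset, focus, subset)
                _emit(corr, "sample_correlations.tsv", index=False)
                sep = sex_separation_test(corr)
                linkage, segregated = sample_cluster_check(dataset, focus, subset)
                rows = []
                for other in dataset.tissues:
                    r, sign = cross_tissue_concordance(all_stats[focus], all_stats[other])
                    rows.append({"tissue": other, "pearson_r": r, "sign_agreement": sign})
                _emit(pd.DataFrame(rows), "concordance.tsv", index=False)
                report = {
                    "focus_tissue": focus,
                    "mean_r_same_sex": sep.mean_same,
                    "sd_r_same_sex": sep.sd_same,
                    "mean_r_cross_sex": sep.mean_cross,
                    "sd_r_cross_sex": sep.sd_cross,
                    "separation_p_value": sep.p_value,
                    "sexes_segregate_in_dendrogram": segregated,
                }
                (out / "validation.json").write_text(json.dumps(report, indent=2))
                manifest["outputs"].append("validation.json")
                _record("validation", focus_tissue=focus, n_sde_subset=len(subset))
            else:
                manifest["warnings"].append("too few SDE probesets for validation stage")
        else:
            manifest["warnings"].append("no SDE calls; validation stage skipped")

    # --- clustering / figures ---------------------------------------------
    if config.do_clustering and summary["distribution"]["n_sde_total"] > len(exclude_ids):
        try:
            ratio = build_ratio_matrix(all_stats, profiles, exclude=exclude_ids)
        except ValueError as err:
            manifest["warnings"].append(f"clustering skipped: {err}")
            ratio = None
        if ratio is not None and ratio.values.shape[0] >= 2:
            clust = ward_cluster_2way(ratio)
            _emit(ratio.values.loc[clust.row_order, clust.col_order], "ratio_matrix_clustered.tsv")
            (out / "tissue_tree.nwk").write_text(
                linkage_to_newick(clust.col_linkage, list(ratio.values.columns)) + "\n"
            )
            manifest["outputs"].append("tissue_tree.nwk")
            _record(
                "clustering",
                n_rows=int(ratio.values.shape[0]),
                color_bound=float(ratio.color_bound),
            )
            if config.figures:
                plot_ratio_heatmap(ratio, clust, out / "heatmap.png")
                manifest["outputs"].append("heatmap.png")
    if config.figures:
        wide = profiles.probesets[profiles.n_sde > 10]
        for tissue in list(dataset.tissues)[:4]:
            pts = ma_points(all_stats[tissue], wide)
            name = f"ma_{tissue.replace(' ', '_').lower()}.png"
            plot_ma(pts, out / name, title=tissue)
            manifest["outputs"].append(name)

    # --- recovery metrics (simulation only) --------------------------------
    if truth is not None:
        rec = recovery_metrics(truth, all_stats, config.criteria.min_abs_log2_diff)
        _emit(rec.per_tissue, "recovery_per_tissue.tsv")
        manifest["recovery"] = {
            "recall": rec.recall,
            "precision": rec.precision,
            "observed_fdr": rec.observed_fdr,
            "bias_sign_accuracy": rec.bias_sign_accuracy,
            "n_true": rec.n_true,
            "n_called": rec.n_called,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
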