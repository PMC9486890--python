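"""End-to-end pipeline driver: simulate -> serology -> ROC -> ratios ->
repertoire -> enrichment, with per-stage CSV/JSON outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from . import __version__
from .enrichment import knn_tissue_score, label_transfer_confidence, permutation_enrichment
from .ratios import ratio_trajectories, window_summary
from .repertoire import (compare_mutation_rates, constant_region_proportions,
                         dominant_isotypes, expansion_or, mutation_rates)
from .serology import contingency_from_calls, derive_cutoff, fisher_exact
from .synthetic import CohortConfig, RepertoireConfig, simulate_repertoire, simulate_serology_cohort
from .temporal_roc import compare_windows, time_thresholded_auc

log = logging.getLogger("seroclone")

STAGES = ("simulate", "serology", "time_roc", "ratios", "repertoire", "enrichment")


@dataclass
class RunConfig:
    out_dir: str = "seroclone_out"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    serology_path: str | None = None   # read instead of simulating
    repertoire_path: str | None = None
    grid_step: int = 10
    max_day: int = 370
    split_day: int = 30
    n_perm: int = 10_000
    n_downsamples: int = 1000
    knn_k: int = 200
    cohort: dict = field(default_factory=dict)       # CohortConfig overrides
    repertoire: dict = field(default_factory=dict)   # RepertoireConfig overrides

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.stages = tuple(cfg.stages)
        return cfg


def _check_dependencies(config: RunConfig) -> None:
    stages = set(config.stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    simulating = "simulate" in stages
    needs_serology = stages & {"serology", "time_roc", "ratios"}
    if needs_serology and not simulating and config.serology_path is None:
        raise ValueError("serology stages need either the simulate stage "
                         "or a serology input path")
    needs_rep = stages & {"repertoire", "enrichment"}
    if needs_rep and not simulating and config.repertoire_path is None:
        raise ValueError("repertoire/enrichment stages need either the simulate "
                         "stage or a repertoire input path")


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run the selected stages in order and write outputs under ``out_dir``.

    Dependencies are checked up front: a stage whose input is neither
    simulated nor provided as a path fails before any computation starts.
    Returns a summary dict (also written to ``summary.json``).
    """
    if isinstance(config, dict):
        config = RunConfig.from_mapping(config)
    _check_dependencies(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "package_version": __version__,
                     "stages": list(config.stages)}
    stages = set(config.stages)

    samples = controls = None
    cells = scores = None
    if "simulate" in stages:
        cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
        samples, controls = simulate_serology_cohort(cohort_cfg)
        rep_cfg = RepertoireConfig(**{"seed": config.seed + 1, **config.repertoire})
        rep = simulate_repertoire(rep_cfg)
        cells, scores = rep.cells, rep.scores
        sio.write_serology(samples, out / "serology_samples.csv", seed=config.seed)
        sio.write_serology(controls.drop(columns=["assay_signal"]),
                           out / "serology_controls.csv", seed=config.seed)
        sio.write_repertoire(cells, out / "repertoire_cells.tsv", seed=config.seed + 1)
        log.info("simulated %d samples, %d controls, %d cells",
                 len(samples), len(controls), len(cells))
    if config.serology_path is not None:
        samples = sio.read_serology(config.serology_path)
        controls = samples[samples["ot_status"] == "control"]
        samples = samples[samples["ot_status"] != "control"]
    if config.repertoire_path is not None:
        cells = sio.read_repertoire(config.repertoire_path)

    if "serology" in stages:
        calls = pd.concat([samples, controls], ignore_index=True)
        stage: dict = {}
        if "assay_signal" in controls.columns:
            stage["cutoff_from_controls"] = derive_cutoff(controls["assay_signal"])
        for isotype in ("IgA", "IgM"):
            for grouping in ("case_control", "ot"):
                table = contingency_from_calls(calls, isotype, grouping=grouping)
                res = fisher_exact(table)
                stage[f"{isotype}_{grouping}"] = {
                    "table": table.counts.tolist(),
                    "p": res.p_two_sided, "odds_ratio": res.odds_ratio,
                    "ci95": [res.ci95_low, res.ci95_high],
                    "sample_odds_ratio": res.sample_odds_ratio,
                }
        summary["serology"] = stage

    if "time_roc" in stages:
        profile = time_thresholded_auc(samples, "IgA", grid_step=config.grid_step,
                                       max_day=config.max_day)
        profile.table.to_csv(out / "time_roc_IgA.csv", index=False)
        contrast = compare_windows(profile, split_day=config.split_day)
        summary["time_roc"] = {"isotype": "IgA", **contrast}

    if "ratios" in stages:
        traj = ratio_trajectories(samples)
        summ = window_summary(traj, by_stratum=True)
        traj.to_csv(out / "ratio_trajectories.csv", index=False)
        summ.to_csv(out / "ratio_window_summary.csv", index=False)
        summary["ratios"] = {"n_trajectories": len(traj)}

    if "repertoire" in stages:
        if "dominant_isotype" not in cells.columns:
            if any(g in cells.columns for g in ("IGHM", "IGHG1", "IGHA1")):
                cells = cells.assign(dominant_isotype=dominant_isotypes(cells))
            else:
                cells = cells.assign(dominant_isotype=cells["c_call"])
        cells = cells.join(mutation_rates(cells))
        props = constant_region_proportions(cells)
        props.to_csv(out / "constant_region_proportions.csv", index=False)
        mut = compare_mutation_rates(cells, pairs=[("IGHA1", "IGHG1"), ("IGHA2", "IGHG1")])
        mut.to_csv(out / "mutation_rate_comparisons.csv", index=False)
        tum = cells.loc[cells["tissue"] == "tumour", "clone_id"]
        blood = cells.loc[cells["tissue"] == "blood", "clone_id"]
        exp = expansion_or(tum, blood, n_downsamples=config.n_downsamples,
                           seed=config.seed + 2)
        summary["repertoire"] = {
            "expansion_or": exp.or_point, "expansion_ci95": list(exp.ci95),
            "target_size": exp.target_size,
            "n_pairs_mutation": len(mut),
        }

    if "enrichment" in stages:
        if "dominant_isotype" not in cells.columns:
            cells = cells.assign(dominant_isotype=cells["c_call"])
        top_cluster = int(cells["cluster"].max())
        enr = permutation_enrichment(cells, top_cluster, "IGHA1",
                                     n_perm=config.n_perm, seed=config.seed + 3)
        knn = knn_tissue_score(cells[["umap_1", "umap_2"]].to_numpy(),
                               cells["tissue"].to_numpy(), "tumour",
                               k=min(config.knn_k, len(cells) - 1))
        np.savetxt(out / "knn_tissue_score.csv", knn, delimiter=",", header="score",
                   comments="")
        stage = {"cluster": enr.cluster, "attribute": enr.attribute,
                 "fold": enr.observed_fold, "log2_fold": enr.log2_fold,
                 "p": enr.p_empirical, "mean_knn_score": float(knn.mean())}
        if scores is not None:
            conf = label_transfer_confidence(
                scores.drop(columns=["cell_id"]).to_numpy(),
                labels=list(scores.columns[1:]))
            stage["n_top_quartile"] = int(conf["keep_top_quartile"].sum())
        summary["enrichment"] = stage

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return summary
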