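"""End-to-end orchestration of the synthetic-study analysis.

``run_pipeline`` chains every stage — simulate, FC assembly, leverage
selection, similarity, cohort stability, cross-atlas concordance and
age-invariance — into one reproducible run directory, and records a
manifest (config snapshot, per-stage seeds, package version, output file
digests) so a run can be reproduced bit-for-bit.

Seed fan-out: a single master seed is expanded into per-stage sub-seeds by
hashing ``"{master}:{stage_name}"`` with SHA-256 and reducing modulo 2^31.
The rule is deterministic and documented so every stage can also be re-run
in isolation with its own seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .age import cv_age_prediction, per_feature_age_regression, random_set_mae_distribution
from .atlas import (
    match_regions_across_atlases,
    overlap_coefficient,
    region_frequencies,
    top_frequent_regions,
    voxel_overlap_percentage,
)
from .cohorts import (
    consensus_features,
    intersection_matrix,
    mean_offdiagonal,
    partition_cohorts,
    per_cohort_selection,
)
from .io import write_feature_set, write_metadata_tsv
from .leverage import FeatureSet, leverage_scores, sample_random_features, select_top_k
from .similarity import inter_subject_similarity, random_feature_null, within_subject_similarity
from .synthetic import SimulationConfig, generate_study, make_toy_atlas_pair

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "derive_seed", "load_config", "run_pipeline"]

STAGES = ("simulate", "fc", "select", "similarity", "stability", "atlas_overlap", "age_invariance")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: SHA-256 of "master:stage" mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration of one full run."""

    simulation: SimulationConfig
    seed: int = 0
    cohort_size: int = 20
    k: int = 80
    null_trials: int = 1000
    folds: int = 10
    n_random_sets: int = 20
    alpha: float = 0.001
    top_region_fraction: float = 0.5
    atlas_grid: tuple = (8, 8, 8)
    atlas_b_regions: int = 30

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown configuration keys: {sorted(bad)}")
        sim_raw = dict(raw.pop("simulation", {}))
        sim_known = set(SimulationConfig.__dataclass_fields__)
        sim_bad = set(sim_raw) - sim_known
        if sim_bad:
            raise ValueError(f"unknown simulation keys: {sorted(sim_bad)}")
        if "tasks" in sim_raw:
            sim_raw["tasks"] = tuple(sim_raw["tasks"])
        if "age_range" in sim_raw:
            sim_raw["age_range"] = tuple(sim_raw["age_range"])
        cfg = cls(simulation=SimulationConfig(**sim_raw), **raw)
        if "atlas_grid" in raw:
            cfg.atlas_grid = tuple(raw["atlas_grid"])
        cfg.simulation.validate()
        if cfg.k < 1:
            raise ValueError("k must be >= 1")
        if cfg.null_trials < 100:
            raise ValueError("null_trials must be >= 100")
        return cfg


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    return PipelineConfig.from_dict(raw)


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict
    version: str
    file_digests: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonable))


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    return str(value)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_jsonable))


def run_pipeline(config: PipelineConfig, out_dir, heatmaps: bool = True) -> RunManifest:
    """Execute every stage on a synthetic study and write a run directory.

    Stage order: simulate -> fc -> select -> similarity -> stability ->
    atlas-overlap -> age-invariance.  Any stage failure raises with the
    stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: derive_seed(config.seed, stage) for stage in STAGES}
    written = []

    stage = "simulate"
    try:
        sim = SimulationConfig(
            **{**asdict(config.simulation), "seed": seeds[stage]}
        )
        study = generate_study(sim)
        meta_path = out / "metadata.tsv"
        write_metadata_tsv(study.metadata, meta_path)
        truth_path = out / "truth.json"
        _write_json(
            {
                "signature_edges": study.truth["signature_edges"],
                "drift_edges": study.truth["drift_edges"],
            },
            truth_path,
        )
        written += [meta_path, truth_path]

        stage = "fc"
        matrices = {task: study.population_matrix(task) for task in sim.tasks}
        fc_summary = {
            task: {"m": M.m, "n": M.n, "r": M.r} for task, M in matrices.items()
        }
        fc_path = out / "fc_summary.json"
        _write_json(fc_summary, fc_path)
        written.append(fc_path)

        stage = "select"
        rest_task = sim.tasks[0]
        M_rest = matrices[rest_task]
        rest_result = leverage_scores(M_rest)
        rest_set = select_top_k(rest_result, config.k)
        set_path = out / "features_rest.tsv"
        write_feature_set(rest_set, sim.n_regions, set_path, scores=rest_result)
        written += [set_path, set_path.with_suffix(".tsv.json")]

        stage = "similarity"
        all_features = FeatureSet(indices=np.arange(M_rest.m), m=M_rest.m, provenance="all")
        sim_report: dict = {"tasks": {}, "task_pairs": {}}
        for task, M in matrices.items():
            on_selected = inter_subject_similarity(M, rest_set)
            on_all = inter_subject_similarity(M, all_features)
            null = random_feature_null(
                M,
                k=config.k,
                n_trials=config.null_trials,
                seed=seeds[stage],
                observed=on_selected.mean,
                side="lower",
            )
            sim_report["tasks"][task] = {
                "selected_mean": on_selected.mean,
                "selected_sd": on_selected.sd,
                "all_mean": on_all.mean,
                "all_sd": on_all.sd,
                "n_pairs": on_selected.n_pairs,
                "null": {
                    "mean": null.null_mean,
                    "sd": null.null_sd,
                    "empirical_p": null.empirical_p,
                    "z_p": null.z_p,
                },
            }
        for other in sim.tasks[1:]:
            summary = within_subject_similarity(M_rest, matrices[other], rest_set)
            sim_report["task_pairs"][f"{rest_task}-{other}"] = {
                "mean": summary.mean,
                "sd": summary.sd,
                "n_pairs": summary.n_pairs,
            }
        sim_path = out / "similarity.json"
        _write_json(sim_report, sim_path)
        written.append(sim_path)

        stage = "stability"
        cohorts = partition_cohorts(study.metadata, cohort_size=config.cohort_size)
        stability_report = {}
        consensus_by_task = {}
        for task, M in matrices.items():
            sets = per_cohort_selection(M, cohorts, config.k)
            mat = intersection_matrix(sets, [c.label for c in cohorts], task=task)
            mat_path = out / f"intersection_{task}.tsv"
            np.savetxt(mat_path, mat.values, delimiter="\t", fmt="%.4f")
            written.append(mat_path)
            if heatmaps:
                png = out / f"intersection_{task}.png"
                _save_heatmap(mat.values, [c.label for c in cohorts], task, png)
            consensus = consensus_features(sets)
            consensus_by_task[task] = consensus
            stability_report[task] = {
                "consecutive_mean": mean_offdiagonal(mat, "consecutive"),
                "all_pairs_mean": mean_offdiagonal(mat, "all_pairs"),
                "consensus_size": consensus.k,
            }
        stab_path = out / "stability.json"
        _write_json(stability_report, stab_path)
        written.append(stab_path)
        cohort_sets_rest = per_cohort_selection(M_rest, cohorts, config.k)

        stage = "atlas_overlap"
        atlas_a, atlas_b = make_toy_atlas_pair(
            grid_shape=config.atlas_grid,
            n_regions_a=sim.n_regions,
            n_regions_b=config.atlas_b_regions,
            seed=seeds[stage],
        )
        freq_a = region_frequencies(cohort_sets_rest, sim.n_regions, atlas_a.name, rest_task)
        top_a = top_frequent_regions(freq_a, config.top_region_fraction)
        # independent selection in atlas B's own region space
        sim_b = SimulationConfig(
            **{
                **asdict(config.simulation),
                "n_regions": config.atlas_b_regions,
                "n_signature_edges": min(
                    sim.n_signature_edges,
                    config.atlas_b_regions * (config.atlas_b_regions - 1) // 4,
                ),
                "n_drift_edges": 0,
                "seed": seeds[stage] + 1,
            }
        )
        study_b = generate_study(sim_b)
        M_b = study_b.population_matrix(rest_task)
        cohorts_b = partition_cohorts(study_b.metadata, cohort_size=config.cohort_size)
        k_b = min(config.k, M_b.m)
        sets_b = per_cohort_selection(M_b, cohorts_b, k_b)
        freq_b = region_frequencies(sets_b, sim_b.n_regions, atlas_b.name, rest_task)
        top_b = top_frequent_regions(freq_b, config.top_region_fraction)
        matches_ab = match_regions_across_atlases(top_a, atlas_a, top_b, atlas_b)
        matches_ba = match_regions_across_atlases(top_b, atlas_b, top_a, atlas_a)
        rng_null = np.random.default_rng(seeds[stage] + 2)
        null_coefs = []
        for _ in range(50):
            rand_a = set(rng_null.choice(atlas_a.region_ids, size=len(top_a), replace=False).tolist())
            rand_b = set(rng_null.choice(atlas_b.region_ids, size=len(top_b), replace=False).tolist())
            null_coefs.append(
                overlap_coefficient(
                    rand_a, rand_b, match_regions_across_atlases(rand_a, atlas_a, rand_b, atlas_b)
                )
            )
        atlas_report = {
            "n_a": len(top_a),
            "n_b": len(top_b),
            "n_matched_ab": len(matches_ab),
            "n_matched_ba": len(matches_ba),
            "overlap_coefficient_ab": overlap_coefficient(top_a, top_b, matches_ab),
            "overlap_coefficient_ba": overlap_coefficient(top_b, top_a, matches_ba),
            "voxel_overlap_pct": voxel_overlap_percentage(atlas_a, atlas_b),
            "random_region_overlap_mean": float(np.mean(null_coefs)),
        }
        atlas_path = out / "atlas_overlap.json"
        _write_json(atlas_report, atlas_path)
        written.append(atlas_path)

        stage = "age_invariance"
        consensus = consensus_by_task[rest_task]
        ages = study.ages
        age_report: dict = {}
        if consensus.k >= 1:
            regression = per_feature_age_regression(M_rest, ages, features=consensus)
            adjusted = regression.with_fdr(alpha=config.alpha)
            stable_mae = cv_age_prediction(
                M_rest, ages, consensus, folds=config.folds, seed=seeds[stage]
            )
            random_mae = random_set_mae_distribution(
                M_rest,
                ages,
                k=consensus.k,
                n_sets=config.n_random_sets,
                folds=config.folds,
                seed=seeds[stage],
            )
            age_report = {
                "n_features": adjusted.n_features,
                "n_nonsignificant": adjusted.n_nonsignificant,
                "frac_nonsignificant": adjusted.n_nonsignificant / adjusted.n_features,
                "stable_mae_mean": stable_mae.mean,
                "stable_mae_sd": stable_mae.sd,
                "random_mae_mean": random_mae.mean,
                "random_mae_sd": random_mae.sd,
            }
        else:
            age_report = {"n_features": 0, "note": "empty consensus; age analyses skipped"}
        age_path = out / "age_invariance.json"
        _write_json(age_report, age_path)
        written.append(age_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config={**asdict(config), "simulation": asdict(config.simulation)},
        stage_seeds=seeds,
        version=__version__,
        file_digests={p.name: _sha256(p) for p in written if p.exists()},
    )
    manifest.write(out / "manifest.json")
    return manifest


def _save_heatmap(values, labels, task, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.set_title(f"feature-set intersection ({task})")
    fig.colorbar(im, ax=ax, label="% shared features")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
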