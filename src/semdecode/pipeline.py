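"""End-to-end synthetic experiment: simulate, decode, compare, localize.

Composes the other modules into the full analysis: generate a multi-subject
synthetic dataset, run single-trial leave-two-out decoding under all six
coordinate models and averaged-data decoding with stability selection,
calibrate chance by training-label permutation, compare models across
subjects with Bonferroni-corrected paired t-tests, decode from an ROI, and
run the searchlight RSA with sign-flip group inference.

Seeds are split hierarchically (master -> stage -> subject) with
``numpy.random.SeedSequence`` so every stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .semantic_space import CoordinateModel, design_matrix
from .synthetic import GenerationConfig, SyntheticDataset, generate_dataset
from .zeroshot import (
    compare_models,
    leave_two_out_averaged,
    leave_two_out_single_trial,
    permutation_null,
    roi_decode,
)
from .rsa import (
    cluster_table,
    group_pseudo_t,
    model_rdm,
    searchlight_rsa,
    smooth_within_mask,
)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "render_report"]

logger = logging.getLogger("semdecode")

ALL_MODELS = tuple(CoordinateModel)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one synthetic experiment."""

    generation: GenerationConfig = field(default_factory=GenerationConfig)
    n_subjects: int = 17
    k_stable: int = 500
    lam: float | str = "gcv"
    n_permutations: int = 200
    single_trial_pair_subsample: int | None = None
    rsa_radius_mm: float = 7.0
    rsa_smooth_fwhm_mm: float = 6.0
    rsa_n_perm: int = 1000
    run_rsa: bool = True
    run_roi: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        # keep one master seed: the generator inherits it
        self.generation = GenerationConfig(
            **{**self.generation.to_dict(), "seed": self.seed}
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generation"] = self.generation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["generation"] = GenerationConfig.from_dict(d["generation"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def tiny_experiment_config(seed: int = 0) -> ExperimentConfig:
    """Smoke-scale configuration (8 targets, 2 subjects, 50 permutations)."""
    return ExperimentConfig(
        generation=GenerationConfig(
            items_per_category=2,
            dim=20,
            grid_shape=(8, 8, 8),
            n_informative=40,
            nonclue_features_per_target=4,
        ),
        n_subjects=2,
        k_stable=60,
        n_permutations=50,
        rsa_n_perm=50,
        seed=seed,
    )


@dataclass
class ExperimentReport:
    """All experiment-level results plus provenance."""

    single_trial_accuracy: pd.DataFrame  # subjects x models (percent)
    averaged_accuracy: pd.DataFrame  # subjects x columns: all_features, roi
    model_comparison: pd.DataFrame
    null_accuracies: np.ndarray
    null_threshold: float
    rsa_clusters: pd.DataFrame | None
    rsa_threshold: float | None
    provenance: dict


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> ExperimentReport:
    """Run every stage deterministically under the master seed.

    When ``outdir`` is given each stage's artifacts are checkpointed there
    as TSV/JSON as soon as the stage finishes.
    """
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    null_seed, rsa_seed, subsample_seed = seeds[1], seeds[2], seeds[3]

    t0 = _stage("simulate")
    dataset = generate_dataset(config.generation, n_subjects=config.n_subjects)
    trials = dataset.trials
    gen = config.generation
    mask = gen.build_mask()
    logger.info("simulated %d subjects in %.1fs", config.n_subjects, time.perf_counter() - t0)

    # trial- and target-level design matrices under every model
    Y_single = {
        m: design_matrix(
            trials, m, dataset.norms, dataset.keyword_map, dataset.space
        )
        for m in ALL_MODELS
    }
    Y_avg = design_matrix(
        trials,
        CoordinateModel.ALL_FEATURES,
        dataset.norms,
        dataset.keyword_map,
        dataset.space,
        averaged=True,
    )
    targets = dataset.norms.targets
    categories = [
        dataset.norms.table.loc[dataset.norms.table["target"] == t, "category"].iloc[0]
        for t in targets
    ]
    n_reps = len(trials) // len(targets)

    def reps_view(stack):
        """[targets x reps x voxels] view ordered to match ``targets``."""
        order = np.concatenate(
            [np.flatnonzero((trials["target"] == t).to_numpy()) for t in targets]
        )
        return stack.betas[order].reshape(len(targets), n_reps, -1)

    t0 = _stage("single_trial_decode")
    subsample_rngs = np.random.default_rng(subsample_seed).spawn(config.n_subjects)
    st_rows = []
    for s, stack in enumerate(dataset.beta_stacks):
        row = {}
        for m in ALL_MODELS:
            res = leave_two_out_single_trial(
                stack.betas,
                trials,
                Y_single[m],
                lam=config.lam,
                n_pair_subsample=config.single_trial_pair_subsample,
                rng=subsample_rngs[s],
            )
            row[m.value] = res.overall_accuracy
        st_rows.append(row)
        logger.info("subject %d single-trial done (%.1fs)", s, time.perf_counter() - t0)
    single_trial = pd.DataFrame(st_rows)
    _checkpoint(outdir_path, "single_trial_accuracy.tsv", single_trial)

    t0 = _stage("averaged_decode")
    avg_rows = []
    for s, stack in enumerate(dataset.beta_stacks):
        reps = reps_view(stack)
        res = leave_two_out_averaged(
            reps,
            Y_avg,
            categories=categories,
            targets=targets,
            k=config.k_stable,
            lam=config.lam,
        )
        row = {"all_features": res.overall_accuracy}
        if config.run_roi:
            roi = dataset.ground_truths[s].informative
            row["roi_informative"] = roi_decode(
                reps, roi, Y_avg, categories=categories, targets=targets,
                lam=config.lam,
            ).overall_accuracy
        avg_rows.append(row)
    averaged = pd.DataFrame(avg_rows)
    _checkpoint(outdir_path, "averaged_accuracy.tsv", averaged)
    logger.info("averaged decode done (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("permutation_null")
    # permutations distributed across subjects, accuracies pooled
    per_subject = np.array_split(np.arange(config.n_permutations), config.n_subjects)
    null_rngs = np.random.default_rng(null_seed).spawn(config.n_subjects)
    null_accs = []
    for s, (stack, chunk) in enumerate(zip(dataset.beta_stacks, per_subject)):
        if len(chunk) == 0:
            continue
        null = permutation_null(
            reps_view(stack),
            Y_avg,
            n_iter=len(chunk),
            seed=null_rngs[s],
            analysis="averaged",
            categories=categories,
            k=config.k_stable,
            lam=config.lam,
        )
        null_accs.append(null.accuracies)
    null_accs = np.concatenate(null_accs)
    null_threshold = float(np.percentile(null_accs, 95))
    _checkpoint_json(
        outdir_path,
        "permutation_null.json",
        {"accuracies": null_accs.tolist(), "threshold_pct": null_threshold},
    )
    logger.info("permutation null done (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("compare_models")
    comparison = compare_models(single_trial)
    _checkpoint(outdir_path, "model_comparison.tsv", comparison)

    rsa_clusters = None
    rsa_threshold = None
    if config.run_rsa:
        t0 = _stage("rsa")
        rdm = model_rdm(Y_single[CoordinateModel.ALL_FEATURES])
        z_maps = []
        for stack in dataset.beta_stacks:
            sl = searchlight_rsa(
                stack.betas, mask, gen.voxel_size_mm, rdm, config.rsa_radius_mm
            )
            z_maps.append(
                smooth_within_mask(
                    sl.values, mask, gen.voxel_size_mm, config.rsa_smooth_fwhm_mm
                )
            )
        group = group_pseudo_t(
            np.vstack(z_maps),
            mask,
            gen.voxel_size_mm,
            variance_fwhm_mm=config.rsa_smooth_fwhm_mm,
            n_perm=config.rsa_n_perm,
            seed=np.random.default_rng(rsa_seed),
        )
        rsa_threshold = group.threshold
        rsa_clusters = cluster_table(group, mask, gen.voxel_size_mm)
        _checkpoint(outdir_path, "rsa_clusters.tsv", rsa_clusters)
        logger.info("rsa done (%.1fs)", time.perf_counter() - t0)

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "semdecode_version": __version__,
        "numpy_version": np.__version__,
    }
    report = ExperimentReport(
        single_trial_accuracy=single_trial,
        averaged_accuracy=averaged,
        model_comparison=comparison,
        null_accuracies=null_accs,
        null_threshold=null_threshold,
        rsa_clusters=rsa_clusters,
        rsa_threshold=rsa_threshold,
        provenance=provenance,
    )
    if outdir_path is not None:
        render_report(report, outdir_path)
        config.to_yaml(outdir_path / "config.yaml")
    return report


def _checkpoint(outdir: Path | None, name: str, df: pd.DataFrame) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, sep="\t", index=False)


def _checkpoint_json(outdir: Path | None, name: str, payload: dict) -> None:
    if outdir is not None:
        (outdir / name).write_text(json.dumps(payload, indent=2))


def render_report(report: ExperimentReport, outdir: str | Path) -> dict[str, Path]:
    """Write summary tables: per-model accuracy distributions with
    significance markers, and the RSA peak table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    acc = report.single_trial_accuracy
    summary = pd.DataFrame(
        {
            "model": acc.columns,
            "mean_accuracy_pct": acc.mean().to_numpy(),
            "sd_pct": acc.std(ddof=1).to_numpy(),
            "min_pct": acc.min().to_numpy(),
            "max_pct": acc.max().to_numpy(),
            "above_null_threshold": (
                acc.mean() > report.null_threshold
            ).to_numpy(),
        }
    ).sort_values("mean_accuracy_pct", ascending=False, ignore_index=True)
    paths["accuracy_summary"] = outdir / "accuracy_summary.tsv"
    summary.to_csv(paths["accuracy_summary"], sep="\t", index=False)

    comp = report.model_comparison.copy()
    comp["significance"] = [
        "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"
        for p in comp["p_bonferroni"]
    ]
    paths["model_comparison"] = outdir / "model_comparison.tsv"
    comp.to_csv(paths["model_comparison"], sep="\t", index=False)

    payload = {
        "null_threshold_pct": report.null_threshold,
        "averaged_accuracy_mean_pct": float(
            report.averaged_accuracy["all_features"].mean()
        ),
        "provenance": report.provenance,
    }
    if report.rsa_threshold is not None:
        payload["rsa_pseudo_t_threshold"] = report.rsa_threshold
        paths["rsa_clusters"] = outdir / "rsa_clusters.tsv"
        report.rsa_clusters.to_csv(paths["rsa_clusters"], sep="\t", index=False)
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(payload, indent=2))
    return paths
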