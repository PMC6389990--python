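"""Forward-model synthetic data: semantic space, stimulus design, beta maps.

The generator emulates a clue-triplet guessing-game experiment: 60 target
objects in 4 semantic categories (15 each), 9 clue features per target
arranged into 6 unique ordered triplets (two presentation sets of three
blocks; each clue appears once per set, always at the same within-triplet
position), giving 360 trials.  Semantic structure is hierarchical Gaussian:
category centroids, target vectors around their centroid, and feature
vectors that load on their target vector with independent dispersion.

Voxel patterns follow a linear forward model embodying the
pattern-completion assumption: the beta row of a trial is
``W_fwd @ s_t + noise`` where ``s_t`` is the summed-feature
(ALL_FEATURES) coordinate of the trial's *target* — not of the presented
clues — so a decoder using the full feature set should outperform
clue-only models, and recovering that ordering is a meaningful test of the
analysis pipeline.  Only a subset of voxels is informative (random
placement by default; a contiguous blob for searchlight localization
tests); the rest carry pure Gaussian noise.

Everything is deterministic under the master seed via hierarchical
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .semantic_space import (
    CoordinateModel,
    FeatureNorms,
    KeywordMap,
    SemanticSpace,
    design_matrix,
    save_word_vectors,
    load_word_vectors,
)

__all__ = [
    "GenerationConfig",
    "GroundTruth",
    "BetaStack",
    "SyntheticDataset",
    "generate_space_and_norms",
    "assemble_trials",
    "generate_ground_truth",
    "simulate_betas",
    "generate_dataset",
    "write_fixtures",
    "read_fixtures",
]

_DEFAULT_CATEGORIES = ("animal", "fruit_vegetable", "tool", "vehicle")

# Position-preserving recombination of the 9 rank-sorted clues (1 = least
# distinctive) into two sets of three triplets.  Rows are triplets, columns
# are within-triplet positions; every triplet is strictly rank-increasing and
# every clue keeps its column between sets.
_SET1_TRIPLETS = ((1, 4, 7), (2, 5, 8), (3, 6, 9))
_SET2_TRIPLETS = ((1, 5, 9), (2, 6, 7), (3, 4, 8))


@dataclass
class GenerationConfig:
    """Knobs of the synthetic experiment.

    Dispersions are standard deviations of isotropic Gaussians in embedding
    units; ``alpha`` is the loading of each feature vector on its target
    vector; ``noise_sd`` is the per-voxel, per-trial measurement noise in
    beta units (forward weights are N(0, 1/dim) on informative voxels).
    Defaults reproduce the study-scale design: 60 targets, 540 clues, 360
    trials, 300-dim vectors, 3.1 mm isotropic voxels.
    """

    n_categories: int = 4
    items_per_category: int = 15
    clues_per_target: int = 9
    nonclue_features_per_target: int = 10
    dim: int = 300
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.1
    mask_radius_voxels: float | None = None
    n_informative: int = 500
    contiguous_informative: bool = False
    noise_sd: float = 60.0
    sigma_cat: float = 1.0
    sigma_item: float = 0.6
    sigma_feat: float = 2.0
    alpha: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        counts = {
            "n_categories": self.n_categories,
            "items_per_category": self.items_per_category,
            "clues_per_target": self.clues_per_target,
            "dim": self.dim,
            "n_informative": self.n_informative,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.nonclue_features_per_target < 0:
            raise ValueError("nonclue_features_per_target must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.clues_per_target != 9:
            raise ValueError(
                "the two-set triplet recombination is defined for exactly 9 clues"
            )
        if self.n_informative > self.mask_voxel_count():
            raise ValueError(
                f"n_informative={self.n_informative} exceeds masked voxel "
                f"count {self.mask_voxel_count()}"
            )

    @property
    def n_targets(self) -> int:
        return self.n_categories * self.items_per_category

    def category_names(self) -> list[str]:
        if self.n_categories == len(_DEFAULT_CATEGORIES):
            return list(_DEFAULT_CATEGORIES)
        return [f"category_{i + 1}" for i in range(self.n_categories)]

    def build_mask(self) -> np.ndarray:
        """Boolean 3-D mask: a sphere centered in the grid (a crude cortex
        stand-in leaving out-of-mask voxels for edge-case handling)."""
        radius = self.mask_radius_voxels
        if radius is None:
            radius = min(self.grid_shape) / 2 - 1
        centers = [(g - 1) / 2 for g in self.grid_shape]
        ii, jj, kk = np.meshgrid(
            *[np.arange(g) for g in self.grid_shape], indexing="ij"
        )
        dist2 = (
            (ii - centers[0]) ** 2 + (jj - centers[1]) ** 2 + (kk - centers[2]) ** 2
        )
        return dist2 <= radius**2

    def mask_voxel_count(self) -> int:
        return int(self.build_mask().sum())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generative parameters stored alongside every synthetic dataset."""

    forward_weights: np.ndarray  # [V_masked x D]; zero rows off the informative set
    informative: np.ndarray  # sorted indices into the masked-voxel axis
    target_coordinates: np.ndarray  # [n_targets x D] summed-feature coordinates
    targets: list[str]
    categories: list[str]

    def __post_init__(self) -> None:
        noninf = np.setdiff1d(
            np.arange(self.forward_weights.shape[0]), self.informative
        )
        if noninf.size and not np.all(self.forward_weights[noninf] == 0.0):
            raise ValueError("non-informative forward-weight rows must be all-zero")


@dataclass
class BetaStack:
    """Trials-by-voxels beta matrix plus grid geometry.

    Column ``j`` corresponds to the ``j``-th True voxel of ``mask`` in C
    (row-major) order; ``affine`` is the isotropic NIfTI affine.
    """

    betas: np.ndarray  # [n_trials x V_masked]
    mask: np.ndarray  # bool [X x Y x Z]
    voxel_size_mm: float

    def __post_init__(self) -> None:
        if self.betas.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"beta columns ({self.betas.shape[1]}) != mask voxels "
                f"({int(self.mask.sum())})"
            )
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def voxel_coordinates_mm(self) -> np.ndarray:
        """[V_masked x 3] center coordinates of the masked voxels in mm."""
        idx = np.argwhere(self.mask)
        return idx.astype(float) * self.voxel_size_mm


@dataclass
class SyntheticDataset:
    """One fully generated experiment (shared design, per-subject betas)."""

    config: GenerationConfig
    space: SemanticSpace
    norms: FeatureNorms
    keyword_map: KeywordMap
    trials: pd.DataFrame
    ground_truths: list[GroundTruth]
    beta_stacks: list[BetaStack]

    @property
    def n_subjects(self) -> int:
        return len(self.beta_stacks)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_space_and_norms(
    config: GenerationConfig,
) -> tuple[SemanticSpace, FeatureNorms, KeywordMap]:
    """Hierarchical-Gaussian semantic space plus self-consistent norms/key map.

    Category centroid ~ N(0, sigma_cat^2 I); target = centroid +
    N(0, sigma_item^2 I); feature = alpha * target + N(0, sigma_feat^2 I).
    Clue features get distinctiveness ranks 1..9 (1 = least distinctive);
    non-clue features rank after them.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    D = config.dim
    vectors: dict[str, np.ndarray] = {}
    rows = []
    kmap: dict[str, str] = {}
    for category in config.category_names():
        centroid = rng.normal(0.0, config.sigma_cat, size=D)
        for item in range(config.items_per_category):
            target = f"{category}_{item + 1:02d}"
            tvec = centroid + rng.normal(0.0, config.sigma_item, size=D)
            vectors[target] = tvec
            kmap[target] = target
            n_feat = config.clues_per_target + config.nonclue_features_per_target
            for j in range(n_feat):
                is_clue = j < config.clues_per_target
                token = f"{target}_f{j + 1:02d}"
                text = f"feature {j + 1} of {target}"
                vectors[token] = config.alpha * tvec + rng.normal(
                    0.0, config.sigma_feat, size=D
                )
                kmap[text] = token
                rows.append(
                    {
                        "target": target,
                        "category": category,
                        "feature": text,
                        "rank": j + 1,
                        "is_clue": is_clue,
                    }
                )
    norms = FeatureNorms(pd.DataFrame(rows))
    return SemanticSpace(vectors=vectors, dim=D), norms, KeywordMap(kmap)


def assemble_trials(norms: FeatureNorms, config: GenerationConfig) -> pd.DataFrame:
    """Build the 6-trials-per-target table with position-preserving
    recombination between the two presentation sets and disjoint
    MIXED_CLUES donors.

    Within each set the three triplets partition the nine clues, so the donor
    of a trial is the next triplet of the same set cyclically — guaranteed to
    share the target but no clue.
    """
    rows = []
    for target in norms.targets:
        clues = norms.clues(target)
        if len(clues) != config.clues_per_target:
            raise ValueError(
                f"target {target!r} has {len(clues)} clue features, "
                f"expected {config.clues_per_target}"
            )
        if len(set(clues)) != len(clues):
            raise ValueError(f"target {target!r} has duplicate clue texts")
        category = norms.table.loc[norms.table["target"] == target, "category"].iloc[0]
        for set_no, layout in ((1, _SET1_TRIPLETS), (2, _SET2_TRIPLETS)):
            for triplet_no, ranks in enumerate(layout):
                block = (set_no - 1) * 3 + triplet_no + 1
                donor_block = (set_no - 1) * 3 + (triplet_no + 1) % 3 + 1
                rows.append(
                    {
                        "trial_id": f"{target}_b{block}",
                        "target": target,
                        "category": category,
                        "block": block,
                        "set": set_no,
                        "clue1": clues[ranks[0] - 1],
                        "clue2": clues[ranks[1] - 1],
                        "clue3": clues[ranks[2] - 1],
                        "donor_trial": f"{target}_b{donor_block}",
                    }
                )
    return pd.DataFrame(rows)


def generate_ground_truth(
    space: SemanticSpace,
    norms: FeatureNorms,
    keyword_map: KeywordMap,
    config: GenerationConfig,
    seed_or_rng=None,
) -> GroundTruth:
    """Draw forward weights and the informative voxel set for one subject."""
    rng = _rng(
        seed_or_rng
        if seed_or_rng is not None
        else np.random.SeedSequence(config.seed).spawn(3)[1]
    )
    mask = config.build_mask()
    n_masked = int(mask.sum())
    if config.contiguous_informative:
        # blob location is part of the shared design (same across subjects,
        # like functional anatomy); only weights/noise vary per subject
        place_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(5)[4]
        )
        coords = np.argwhere(mask).astype(float)
        center_voxel = coords[place_rng.integers(len(coords))]
        dist = np.linalg.norm(coords - center_voxel, axis=1)
        informative = np.sort(np.argsort(dist, kind="stable")[: config.n_informative])
    else:
        informative = np.sort(
            rng.choice(n_masked, size=config.n_informative, replace=False)
        )
    weights = np.zeros((n_masked, config.dim))
    weights[informative] = rng.normal(
        0.0, 1.0 / np.sqrt(config.dim), size=(config.n_informative, config.dim)
    )
    targets = norms.targets
    coords = np.vstack(
        [
            sum(
                space.vector(keyword_map.resolve(f)) for f in norms.features(t)
            )
            for t in targets
        ]
    )
    categories = [
        norms.table.loc[norms.table["target"] == t, "category"].iloc[0]
        for t in targets
    ]
    return GroundTruth(
        forward_weights=weights,
        informative=informative,
        target_coordinates=coords,
        targets=targets,
        categories=categories,
    )


def simulate_betas(
    trials: pd.DataFrame,
    space: SemanticSpace,
    norms: FeatureNorms,
    keyword_map: KeywordMap,
    truth: GroundTruth,
    config: GenerationConfig,
    seed_or_rng=None,
) -> BetaStack:
    """Linear forward model: beta_t = W_fwd @ s_t + N(0, noise_sd^2 I).

    ``s_t`` is the ALL_FEATURES coordinate of the trial's target, so every
    repetition of a target shares its signal and differs only in noise.
    """
    if truth.forward_weights.shape[1] != space.dim:
        raise ValueError(
            f"ground truth dimension {truth.forward_weights.shape[1]} != "
            f"space dimension {space.dim}"
        )
    rng = _rng(
        seed_or_rng
        if seed_or_rng is not None
        else np.random.SeedSequence(config.seed).spawn(3)[2]
    )
    coord_by_target = dict(zip(truth.targets, truth.target_coordinates))
    signal = np.vstack(
        [truth.forward_weights @ coord_by_target[t] for t in trials["target"]]
    )
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
    return BetaStack(
        betas=signal + noise,
        mask=config.build_mask(),
        voxel_size_mm=config.voxel_size_mm,
    )


def generate_dataset(
    config: GenerationConfig, n_subjects: int = 1
) -> SyntheticDataset:
    """Full experiment: shared space/norms/design, independent subjects.

    Seeds split hierarchically (master -> [space, per-subject truth/noise])
    so any subject can be regenerated in isolation.
    """
    subjects_seed = np.random.SeedSequence(config.seed).spawn(4)[3]
    space, norms, kmap = generate_space_and_norms(config)
    trials = assemble_trials(norms, config)
    truths, stacks = [], []
    for subj_seq in subjects_seed.spawn(n_subjects):
        truth_seq, noise_seq = subj_seq.spawn(2)
        truth = generate_ground_truth(
            space, norms, kmap, config, np.random.default_rng(truth_seq)
        )
        stack = simulate_betas(
            trials, space, norms, kmap, truth, config, np.random.default_rng(noise_seq)
        )
        truths.append(truth)
        stacks.append(stack)
    return SyntheticDataset(
        config=config,
        space=space,
        norms=norms,
        keyword_map=kmap,
        trials=trials,
        ground_truths=truths,
        beta_stacks=stacks,
    )


def write_fixtures(
    dataset: SyntheticDataset, outdir: str | Path, subject: int = 0
) -> dict[str, Path]:
    """Persist one subject's data: 4-D beta NIfTI (trial along axis 3), mask
    NIfTI, TSV tables, word2vec text vectors, and a ground-truth .npz."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = dataset.beta_stacks[subject]
    truth = dataset.ground_truths[subject]
    grid = stack.mask.shape
    vol = np.zeros(grid + (stack.n_trials,))
    vol[stack.mask] = stack.betas.T
    paths = {
        "betas": outdir / "betas.nii",
        "mask": outdir / "mask.nii",
        "trials": outdir / "trials.tsv",
        "norms": outdir / "feature_norms.tsv",
        "keyword_map": outdir / "keyword_map.tsv",
        "vectors": outdir / "vectors.w2v.txt",
        "ground_truth": outdir / "ground_truth.npz",
        "config": outdir / "config.json",
    }
    nib.save(nib.Nifti1Image(vol, stack.affine), paths["betas"])
    nib.save(
        nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine), paths["mask"]
    )
    dataset.trials.to_csv(paths["trials"], sep="\t", index=False)
    dataset.norms.to_tsv(paths["norms"])
    dataset.keyword_map.to_tsv(paths["keyword_map"])
    save_word_vectors(dataset.space, paths["vectors"])
    np.savez(
        paths["ground_truth"],
        forward_weights=truth.forward_weights,
        informative=truth.informative,
        target_coordinates=truth.target_coordinates,
        targets=np.array(truth.targets),
        categories=np.array(truth.categories),
    )
    paths["config"].write_text(json.dumps(dataset.config.to_dict(), indent=2))
    return paths


def read_fixtures(outdir: str | Path) -> SyntheticDataset:
    """Inverse of :func:`write_fixtures` for a single subject."""
    outdir = Path(outdir)
    config = GenerationConfig.from_dict(
        json.loads((outdir / "config.json").read_text())
    )
    mask = np.asarray(nib.load(outdir / "mask.nii").dataobj).astype(bool)
    vol = np.asarray(nib.load(outdir / "betas.nii").dataobj)
    betas = vol[mask].T
    stack = BetaStack(
        betas=betas, mask=mask, voxel_size_mm=config.voxel_size_mm
    )
    with np.load(outdir / "ground_truth.npz") as gt:
        truth = GroundTruth(
            forward_weights=gt["forward_weights"],
            informative=gt["informative"],
            target_coordinates=gt["target_coordinates"],
            targets=[str(t) for t in gt["targets"]],
            categories=[str(c) for c in gt["categories"]],
        )
    return SyntheticDataset(
        config=config,
        space=load_word_vectors(outdir / "vectors.w2v.txt"),
        norms=FeatureNorms.from_tsv(outdir / "feature_norms.tsv"),
        keyword_map=KeywordMap.from_tsv(outdir / "keyword_map.tsv"),
        trials=pd.read_csv(outdir / "trials.tsv", sep="\t"),
        ground_truths=[truth],
        beta_stacks=[stack],
    )
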