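"""Voxel stability selection across stimulus repetitions.

A voxel is "stable" when its response profile over the training targets is
consistent across the six repetitions of each target.  For every voxel the
six repetition profiles (beta value per training target) are correlated
pairwise (15 Pearson correlations for 6 repetitions) and averaged; the k
voxels with the highest mean correlation are kept.  Scores use training
targets only, so held-out items never influence selection.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "stability_scores",
    "select_stable_voxels",
    "average_repetitions",
    "stability_select",
    "selection_mask_image",
    "StabilityResult",
]

from dataclasses import dataclass


@dataclass
class StabilityResult:
    scores: np.ndarray  # per-voxel mean pairwise Pearson r, in [-1, 1]
    selected: np.ndarray  # sorted voxel indices, exactly min(k, V) entries
    k: int


def stability_scores(
    betas: np.ndarray, training_targets: np.ndarray | None = None
) -> np.ndarray:
    """Mean pairwise Pearson correlation between repetition profiles.

    Parameters
    ----------
    betas : array [targets x repetitions x voxels]
    training_targets : indices of targets to use (e.g. the 58 targets left
        in the training set of a leave-two-out fold).  ``None`` uses all.

    A zero-variance profile contributes r = 0 to every pair it is part of (a
    flat voxel carries no stable signal); the result is NaN-free.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 3:
        raise ValueError("betas must be [targets x repetitions x voxels]")
    if training_targets is not None:
        betas = betas[np.asarray(training_targets)]
    n_targets, n_reps, _ = betas.shape
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions for stability scores")
    if n_targets < 2:
        raise ValueError("need at least 2 training targets for correlations")
    profiles = np.ascontiguousarray(betas.transpose(2, 1, 0))  # [V x reps x T]
    centered = profiles - profiles.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)  # [V x reps]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms[:, :, None] > 0, centered / norms[:, :, None], 0.0)
    # batched corr[v, r, s] = sum_t z[v, r, t] * z[v, s, t]
    corr = z @ z.transpose(0, 2, 1)
    iu, ju = np.triu_indices(n_reps, k=1)
    return np.clip(corr[:, iu, ju].mean(axis=1), -1.0, 1.0)


def select_stable_voxels(scores: np.ndarray, k: int = 500) -> np.ndarray:
    """Indices of the ``k`` highest-scoring voxels (ties broken by ascending
    voxel index), returned sorted.  ``k`` beyond the voxel count selects all
    voxels with a warning."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    scores = np.asarray(scores)
    if k >= scores.size:
        if k > scores.size:
            warnings.warn(
                f"k={k} exceeds voxel count {scores.size}; selecting all voxels",
                stacklevel=2,
            )
        return np.arange(scores.size)
    # stable sort on -scores: equal scores keep ascending index order
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def average_repetitions(betas: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the repetition axis of [targets x reps x voxels]."""
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 3:
        raise ValueError("betas must be [targets x repetitions x voxels]")
    return betas.mean(axis=1)


def stability_select(
    betas: np.ndarray, training_targets: np.ndarray | None, k: int = 500
) -> StabilityResult:
    """Convenience wrapper: scores + selection in one call."""
    scores = stability_scores(betas, training_targets)
    return StabilityResult(scores=scores, selected=select_stable_voxels(scores, k), k=k)


def selection_mask_image(stack, selected: np.ndarray):
    """Binary NIfTI image marking the selected voxels, for visual inspection."""
    import nibabel as nib

    vol = np.zeros(stack.mask.shape, dtype=np.uint8)
    masked_coords = np.argwhere(stack.mask)
    vol[tuple(masked_coords[np.asarray(selected)].T)] = 1
    return nib.Nifti1Image(vol, stack.affine)
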