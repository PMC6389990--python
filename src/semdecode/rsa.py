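"""Searchlight representational similarity analysis with nonparametric
group inference.

For every spherical voxel neighborhood (default radius 7 mm) the pairwise
dissimilarity structure of trial activation patterns (1 − Pearson r) is
compared — by Spearman rank correlation of the strictly-lower-triangle
entries — with a model dissimilarity matrix built from cosine distances
between trial semantic coordinates.  The Fisher-transformed correlation is
assigned to the sphere's center voxel.  Group inference uses the
sign-flipping maximum-statistic permutation scheme on subject z-maps with a
variance-smoothed pseudo-t statistic; the family-wise-error threshold is
the 95th percentile of the max-statistic null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "RDM",
    "SearchlightMap",
    "GroupStatResult",
    "model_rdm",
    "activation_rdm",
    "sphere_neighborhoods",
    "searchlight_rsa",
    "smooth_within_mask",
    "group_pseudo_t",
    "cluster_table",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_ATANH_CAP = 1.0 - 1e-15


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with zero diagonal."""

    matrix: np.ndarray
    metric: str  # 'cosine' | 'one-minus-pearson'

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"RDM must be square, got {m.shape}")
        if not np.allclose(m, m.T):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector."""
        iu, ju = np.tril_indices(self.n, k=-1)
        return self.matrix[iu, ju]


@dataclass
class SearchlightMap:
    """Per-voxel searchlight statistic on the masked grid."""

    values: np.ndarray  # Fisher z per masked voxel
    sphere_sizes: np.ndarray  # voxels per searchlight
    radius_mm: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("searchlight values must be finite")


@dataclass
class GroupStatResult:
    """Sign-flip permutation pseudo-t inference over subject maps."""

    pseudo_t: np.ndarray  # per masked voxel
    max_null: np.ndarray  # max statistic per permutation
    n_perm: int
    variance_fwhm_mm: float

    @property
    def threshold(self) -> float:
        """FWE-controlling height threshold (95th percentile of max null)."""
        return float(np.percentile(self.max_null, 95))

    @property
    def flagged(self) -> np.ndarray:
        """Masked-voxel indices exceeding the FWE threshold."""
        return np.flatnonzero(self.pseudo_t > self.threshold)

    def voxel_fwe_p(self) -> np.ndarray:
        """Per-voxel FWE-corrected p: fraction of max-null >= observed."""
        return (
            self.max_null[None, :] >= self.pseudo_t[:, None]
        ).mean(axis=1)


def model_rdm(coordinates: np.ndarray) -> RDM:
    """Pairwise cosine distances between semantic coordinate rows."""
    X = np.asarray(coordinates, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        raise ValueError(
            f"zero-norm coordinate rows at {np.flatnonzero(norms == 0.0).tolist()}"
        )
    Z = X / norms[:, None]
    m = 1.0 - Z @ Z.T
    np.fill_diagonal(m, 0.0)
    return RDM(matrix=(m + m.T) / 2.0, metric="cosine")


def _correlation_distances(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1 - Pearson r between pattern rows; flat (zero-variance) rows get
    distance 1 to everything (r treated as 0).  Returns (matrix, flat-rows)."""
    X = np.asarray(patterns, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    flat = norms == 0.0
    Z = np.where(flat[:, None], 0.0, Xc / np.where(flat, 1.0, norms)[:, None])
    m = 1.0 - Z @ Z.T
    np.fill_diagonal(m, 0.0)
    return (m + m.T) / 2.0, flat


def activation_rdm(patterns: np.ndarray) -> RDM:
    """Correlation-distance RDM (1 − Pearson r) between activation patterns."""
    m, flat = _correlation_distances(patterns)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance activation patterns; their "
            "distances were set to 1",
            stacklevel=2,
        )
    return RDM(matrix=m, metric="one-minus-pearson")


def sphere_neighborhoods(
    mask: np.ndarray, voxel_size_mm: float, radius_mm: float = 7.0
) -> list[np.ndarray]:
    """Masked-voxel index lists of every spherical searchlight.

    For each mask voxel, all mask voxels whose center-to-center Euclidean
    distance is <= ``radius_mm`` (center included).  On the reference
    3.1 mm isotropic grid a 7 mm sphere holds 57 voxels in the interior;
    neighborhoods at the mask edge are strict subsets.
    """
    if radius_mm < voxel_size_mm:
        warnings.warn(
            f"radius {radius_mm} mm below voxel size {voxel_size_mm} mm: "
            "single-voxel searchlights",
            stacklevel=2,
        )
    mask = np.asarray(mask, dtype=bool)
    r_vox = radius_mm / voxel_size_mm
    max_off = int(np.floor(r_vox))
    offs = np.array(
        [
            (i, j, k)
            for i in range(-max_off, max_off + 1)
            for j in range(-max_off, max_off + 1)
            for k in range(-max_off, max_off + 1)
            if i * i + j * j + k * k <= r_vox * r_vox
        ]
    )
    index_vol = -np.ones(mask.shape, dtype=int)
    coords = np.argwhere(mask)
    index_vol[mask] = np.arange(len(coords))
    neighborhoods = []
    shape = np.array(mask.shape)
    for c in coords:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        idx = index_vol[tuple(pts[ok].T)]
        neighborhoods.append(np.sort(idx[idx >= 0]))
    return neighborhoods


def _fisher_z(rho: float) -> float:
    return float(np.arctanh(np.clip(rho, -_ATANH_CAP, _ATANH_CAP)))


def searchlight_rsa(
    betas: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float,
    model: RDM,
    radius_mm: float = 7.0,
) -> SearchlightMap:
    """Spearman correlation between sphere activation RDMs and the model RDM.

    Per center voxel: build the 1 − Pearson activation RDM over the sphere's
    voxels, Spearman-correlate (average ranks on ties) its strictly-lower
    triangle with the model's, Fisher-transform, and assign to the center.
    Centers whose sphere has < 2 voxels, or whose distance vector is
    constant (undefined rank correlation), get z = 0 with a warning.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] != model.n:
        raise ValueError(
            f"model RDM size {model.n} does not match trial count {betas.shape[0]}"
        )
    neighborhoods = sphere_neighborhoods(mask, voxel_size_mm, radius_mm)
    if len(neighborhoods) != betas.shape[1]:
        raise ValueError("mask voxel count does not match beta columns")
    iu, ju = np.tril_indices(model.n, k=-1)
    model_ranks = stats.rankdata(model.matrix[iu, ju])
    model_ranks = model_ranks - model_ranks.mean()
    model_norm = np.linalg.norm(model_ranks)
    values = np.zeros(len(neighborhoods))
    sizes = np.array([len(nb) for nb in neighborhoods])
    n_degenerate = 0
    for v, nb in enumerate(neighborhoods):
        if len(nb) < 2:
            n_degenerate += 1
            continue
        dist, _ = _correlation_distances(betas[:, nb])
        vec = dist[iu, ju]
        ranks = stats.rankdata(vec)
        ranks = ranks - ranks.mean()
        norm = np.linalg.norm(ranks)
        if norm == 0.0 or model_norm == 0.0:
            n_degenerate += 1
            continue
        rho = float(ranks @ model_ranks / (norm * model_norm))
        values[v] = _fisher_z(rho)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} searchlight centers had undefined correlations; "
            "set to 0",
            stacklevel=2,
        )
    return SearchlightMap(values=values, sphere_sizes=sizes, radius_mm=radius_mm)


def smooth_within_mask(
    values: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float,
    fwhm_mm: float,
) -> np.ndarray:
    """Gaussian smoothing restricted to the mask with kernel renormalization
    (no signal bleeds in from outside the mask).  FWHM -> sigma uses
    FWHM / (2 sqrt(2 ln 2))."""
    if fwhm_mm <= 0:
        return np.asarray(values, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    vol = np.zeros(mask.shape)
    vol[mask] = values
    num = ndimage.gaussian_filter(vol, sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, 0.0)
    return sm[mask]


def _pseudo_t(
    maps: np.ndarray, mask: np.ndarray, voxel_size_mm: float, fwhm_mm: float
) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    var = maps.var(axis=0, ddof=1)
    svar = smooth_within_mask(var, mask, voxel_size_mm, fwhm_mm)
    svar = np.clip(svar, 0.0, None)
    denom = np.sqrt(svar / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, mean / denom, 0.0)
    return t


def group_pseudo_t(
    z_maps: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float,
    variance_fwhm_mm: float = 6.0,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> GroupStatResult:
    """One-sample sign-flip permutation test with variance smoothing.

    ``z_maps``: [subjects x masked voxels], already spatially smoothed.
    pseudo-t = mean / sqrt(smoothed variance / n).  The null flips the sign
    of whole subject maps; with 2^n distinct patterns <= ``n_perm`` the flip
    set is enumerated exhaustively, otherwise ``n_perm`` random flips are
    drawn with the identity flip always included.  The FWE threshold is the
    95th percentile of the per-permutation maximum statistic.
    """
    z_maps = np.asarray(z_maps, dtype=float)
    if z_maps.ndim != 2 or z_maps.shape[0] < 2:
        raise ValueError("need [subjects x voxels] maps for >= 2 subjects")
    n = z_maps.shape[0]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if n <= 30 and 2**n <= n_perm:
        flips = np.array(
            [[1 if (p >> s) & 1 else -1 for s in range(n)] for p in range(2**n)]
        )
    else:
        flips = rng.choice([-1, 1], size=(n_perm, n))
        flips[0] = 1
    observed = _pseudo_t(z_maps, mask, voxel_size_mm, variance_fwhm_mm)
    max_null = np.empty(len(flips))
    for p, signs in enumerate(flips):
        t = _pseudo_t(
            signs[:, None] * z_maps, mask, voxel_size_mm, variance_fwhm_mm
        )
        max_null[p] = t.max()
    return GroupStatResult(
        pseudo_t=observed,
        max_null=max_null,
        n_perm=len(flips),
        variance_fwhm_mm=variance_fwhm_mm,
    )


def cluster_table(
    result: GroupStatResult, mask: np.ndarray, voxel_size_mm: float
) -> pd.DataFrame:
    """Connected components (6-connectivity) of supra-threshold voxels.

    One row per cluster: peak voxel coordinate (mm), peak pseudo-t, cluster
    extent in voxels, and the peak's FWE-corrected p.
    """
    mask = np.asarray(mask, dtype=bool)
    supra = np.zeros(mask.shape, dtype=bool)
    coords = np.argwhere(mask)
    supra[tuple(coords[result.flagged].T)] = True
    labels, n_clusters = ndimage.label(
        supra, structure=ndimage.generate_binary_structure(3, 1)
    )
    tvol = np.zeros(mask.shape)
    tvol[mask] = result.pseudo_t
    fwe_p = np.ones(mask.shape)
    fwe_p[mask] = result.voxel_fwe_p()
    rows = []
    for c in range(1, n_clusters + 1):
        in_c = labels == c
        peak_flat = np.argmax(np.where(in_c, tvol, -np.inf))
        peak = np.unravel_index(peak_flat, mask.shape)
        rows.append(
            {
                "x_mm": peak[0] * voxel_size_mm,
                "y_mm": peak[1] * voxel_size_mm,
                "z_mm": peak[2] * voxel_size_mm,
                "pseudo_t": tvol[peak],
                "extent": int(in_c.sum()),
                "fwe_p": fwe_p[peak],
            }
        )
    return pd.DataFrame(
        rows, columns=["x_mm", "y_mm", "z_mm", "pseudo_t", "extent", "fwe_p"]
    ).sort_values("pseudo_t", ascending=False, ignore_index=True)
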