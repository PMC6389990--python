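"""Zero-shot leave-two-out decoding of semantic coordinates from beta maps.

A regularized linear mapping (ridge regression, one output per semantic
dimension, shared penalty) is fitted from voxel patterns to semantic
coordinates on all items except two.  The two held-out items are then
predicted and scored with the pairwise cosine rule: the labeling is correct
when the summed cosine distance of the matched assignment is smaller than
that of the swapped assignment.  Because held-out items never contribute to
fitting, standardization, stability selection, or penalty selection, any
item with known semantic coordinates can be decoded without ever appearing
in training — the zero-shot property.

Chance level is calibrated by permutation: the target-to-coordinate
assignment is shuffled in the training set only, the whole scheme is re-run,
and the 95th percentile of the resulting accuracies is the significance
cutoff.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stability import (
    average_repetitions,
    select_stable_voxels,
    stability_scores,
)

__all__ = [
    "DecoderMapping",
    "PairOutcome",
    "DecodingResult",
    "PermutationNull",
    "fit_mapping",
    "pair_decision",
    "leave_two_out_averaged",
    "leave_two_out_single_trial",
    "enumerate_trial_pairs",
    "permutation_null",
    "roi_decode",
    "predict_activation",
    "compare_models",
]

#: default log-spaced ridge grid for in-fold generalized cross-validation,
#: as multiples of the mean kernel eigenvalue
_GCV_GRID = np.logspace(-6.0, 2.0, 17)


@dataclass
class DecoderMapping:
    """Fitted voxel-to-semantic-space ridge mapping.

    ``weights`` act on standardized predictors; :meth:`predict` applies the
    stored training-fold standardization first.  ``intercept`` equals the
    training mean of the semantic coordinates (predictors are centered).
    """

    weights: np.ndarray  # [V_used x D]
    intercept: np.ndarray  # [D]
    lam: float
    x_mean: np.ndarray  # [V_used]
    x_sd: np.ndarray  # [V_used]
    voxel_indices: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.x_mean) / self.x_sd) @ self.weights + self.intercept


@dataclass
class PairOutcome:
    """One leave-two-out comparison.

    ``distances`` = (d(p1,t1), d(p2,t2), d(p1,t2), d(p2,t1)) cosine
    distances; ``decision`` is 'correct' when the matched sum is strictly
    smaller, 'tie' on exact equality.
    """

    item1: object
    item2: object
    distances: tuple[float, float, float, float]
    decision: str  # correct | incorrect | tie
    relation: str = "across"  # within | across | same-target
    n_train: int = 0  # training samples behind the fitted mapping

    @property
    def score(self) -> float:
        return {"correct": 1.0, "incorrect": 0.0, "tie": 0.5}[self.decision]


@dataclass
class DecodingResult:
    """Per-pair outcomes with stratified accuracies (percent).

    Same-target pairs (possible only in single-trial analyses) are kept as a
    separate stratum and excluded from the headline accuracy.
    """

    pairs: pd.DataFrame  # columns: item1, item2, category1, category2,
    #                              relation, decision, score

    def _subset(self, mask) -> float:
        sub = self.pairs[mask]
        return float("nan") if sub.empty else 100.0 * sub["score"].mean()

    @property
    def overall_accuracy(self) -> float:
        return self._subset(self.pairs["relation"] != "same-target")

    @property
    def within_category_accuracy(self) -> float:
        return self._subset(self.pairs["relation"] == "within")

    @property
    def across_category_accuracy(self) -> float:
        return self._subset(self.pairs["relation"] == "across")

    @property
    def same_target_accuracy(self) -> float:
        return self._subset(self.pairs["relation"] == "same-target")

    def per_category_accuracy(self) -> dict[str, float]:
        """Accuracy of within-category pairs, per category."""
        out = {}
        within = self.pairs[self.pairs["relation"] == "within"]
        for cat, sub in within.groupby("category1"):
            out[str(cat)] = 100.0 * sub["score"].mean()
        return out

    def counts(self) -> dict[str, int]:
        return self.pairs["relation"].value_counts().to_dict()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class PermutationNull:
    """Null accuracies from training-set label permutation."""

    accuracies: np.ndarray  # percent, one per iteration
    n_iter: int

    @property
    def threshold(self) -> float:
        """Empirical 95th percentile of the null accuracies (percent)."""
        return float(np.percentile(self.accuracies, 95))

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _gcv_lambda(K: np.ndarray, Yc: np.ndarray) -> float:
    """Generalized cross-validation for the shared ridge penalty, in the
    kernel (dual) form, on the training fold only."""
    n = K.shape[0]
    d, Q = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    U = Q.T @ Yc  # [n x D]
    u2 = (U**2).sum(axis=1)
    scale = max(d.mean(), np.finfo(float).tiny)
    best_lam, best_gcv = None, np.inf
    for lam in _GCV_GRID * scale:
        shrink = lam / (d + lam)
        rss = float((shrink**2 * u2).sum())
        # +1 effective df for the (implicit, exact-fit) intercept
        edf = float((d / (d + lam)).sum()) + 1.0
        denom = max(1.0 - edf / n, 1.0 / n) ** 2
        gcv = rss / n / denom
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, float(lam)
    return best_lam


def fit_mapping(
    X: np.ndarray, Y: np.ndarray, lam: float | str = "gcv"
) -> DecoderMapping:
    """Ridge regression from voxel patterns to semantic coordinates.

    Predictors are standardized and outputs centered with training
    statistics; a single penalty is shared across semantic dimensions.
    ``lam`` may be a nonnegative float or ``"gcv"`` (generalized
    cross-validation over a log grid inside the training fold).  ``lam=0``
    with more samples than voxels reduces to ordinary least squares; a very
    large ``lam`` shrinks predictions to the training mean of Y.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError(f"incompatible shapes X{X.shape} Y{Y.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in training data")
    n, V = X.shape
    Xs, x_mean, x_sd = _standardize(X)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    if lam == "gcv":
        lam = _gcv_lambda(Xs @ Xs.T, Yc)
    lam = float(lam)
    if lam < 0:
        raise ValueError("regularization strength must be nonnegative")
    if lam == 0.0:
        W = np.linalg.lstsq(Xs, Yc, rcond=None)[0]
    elif V > n:
        K = Xs @ Xs.T
        alpha = np.linalg.solve(K + lam * np.eye(n), Yc)
        W = Xs.T @ alpha
    else:
        A = Xs.T @ Xs + lam * np.eye(V)
        W = np.linalg.solve(A, Xs.T @ Yc)
    return DecoderMapping(
        weights=W, intercept=y_mean, lam=lam, x_mean=x_mean, x_sd=x_sd
    )


def _cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm vector")
    return float(1.0 - np.dot(a, b) / (na * nb))


def pair_decision(
    pred1: np.ndarray,
    pred2: np.ndarray,
    true1: np.ndarray,
    true2: np.ndarray,
    item1: object = 0,
    item2: object = 1,
    relation: str = "across",
    n_train: int = 0,
) -> PairOutcome:
    """Cosine pair rule: correct iff d(p1,t1)+d(p2,t2) < d(p1,t2)+d(p2,t1)."""
    d11 = _cosine_distance(pred1, true1)
    d22 = _cosine_distance(pred2, true2)
    d12 = _cosine_distance(pred1, true2)
    d21 = _cosine_distance(pred2, true1)
    matched, swapped = d11 + d22, d12 + d21
    if matched < swapped:
        decision = "correct"
    elif matched > swapped:
        decision = "incorrect"
    else:
        decision = "tie"
    return PairOutcome(
        item1=item1,
        item2=item2,
        distances=(d11, d22, d12, d21),
        decision=decision,
        relation=relation,
        n_train=n_train,
    )


def _as_result(outcomes: list[PairOutcome], categories: dict) -> DecodingResult:
    rows = [
        {
            "item1": o.item1,
            "item2": o.item2,
            "category1": categories.get(o.item1),
            "category2": categories.get(o.item2),
            "relation": o.relation,
            "decision": o.decision,
            "score": o.score,
            "n_train": o.n_train,
        }
        for o in outcomes
    ]
    return DecodingResult(pairs=pd.DataFrame(rows))


def _relation(cat1, cat2) -> str:
    return "within" if cat1 == cat2 else "across"


def leave_two_out_averaged(
    betas: np.ndarray,
    Y: np.ndarray,
    categories: list | None = None,
    targets: list | None = None,
    k: int | None = 500,
    lam: float | str = "gcv",
    Y_train: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-two-out decoding on repetition-averaged data.

    Parameters
    ----------
    betas : array [targets x repetitions x voxels]
    Y : array [targets x D] true semantic coordinates (target-level model)
    k : stability-selection size (``None`` disables selection)
    Y_train : optional alternative coordinate assignment used for fitting
        only (permutation null); truths for evaluation always come from
        ``Y``.

    Every fold recomputes stability scores on its 58 training targets, so no
    held-out information reaches voxel selection; all C(n, 2) folds are run.
    """
    betas = np.asarray(betas, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if betas.ndim != 3:
        raise ValueError("betas must be [targets x repetitions x voxels]")
    n = betas.shape[0]
    if Y.shape[0] != n:
        raise ValueError("Y rows must match target count")
    if Y_train is None:
        Y_train = Y
    if categories is None:
        categories = [None] * n
    if targets is None:
        targets = list(range(n))
    averaged = average_repetitions(betas)
    outcomes = []
    for i, j in itertools.combinations(range(n), 2):
        train = np.array([t for t in range(n) if t not in (i, j)])
        assert i not in train and j not in train  # zero-shot guarantee
        if k is not None:
            scores = stability_scores(betas, train)
            sel = select_stable_voxels(scores, k)
        else:
            sel = slice(None)
        mapping = fit_mapping(averaged[train][:, sel], Y_train[train], lam)
        preds = mapping.predict(averaged[[i, j]][:, sel])
        outcomes.append(
            pair_decision(
                preds[0],
                preds[1],
                Y[i],
                Y[j],
                item1=targets[i],
                item2=targets[j],
                relation=_relation(categories[i], categories[j]),
                n_train=len(train),
            )
        )
    return _as_result(outcomes, dict(zip(targets, categories)))


def _trial_groups(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Row indices per target, in table order."""
    groups: dict[str, list[int]] = {}
    for pos, target in enumerate(trials["target"]):
        groups.setdefault(target, []).append(pos)
    return {t: np.array(ix) for t, ix in groups.items()}


def enumerate_trial_pairs(trials: pd.DataFrame) -> dict[str, int]:
    """Counts of the full single-trial pair enumeration, by stratum."""
    groups = _trial_groups(trials)
    sizes = [len(ix) for ix in groups.values()]
    same = sum(s * (s - 1) // 2 for s in sizes)
    total = len(trials) * (len(trials) - 1) // 2
    return {
        "total": total,
        "same_target": same,
        "distinct_target": total - same,
        "target_pairs": len(sizes) * (len(sizes) - 1) // 2,
    }


def leave_two_out_single_trial(
    betas: np.ndarray,
    trials: pd.DataFrame,
    Y: np.ndarray,
    lam: float | str = "gcv",
    target_pairs: list[tuple[str, str]] | None = None,
    n_pair_subsample: int | None = None,
    include_same_target: bool = True,
    rng: np.random.Generator | None = None,
    Y_train: np.ndarray | None = None,
) -> DecodingResult:
    """Single-trial leave-two-out decoding over all trial pairs.

    No repetition averaging and no stability selection.  For a pair of
    trials from two distinct targets, *all* trials of both targets are
    removed from training (348 of 360 in the full design); the fitted
    mapping is shared by the 36 trial pairs of that target pair.  Pairs of
    trials of the same target form a separate stratum (trained without that
    target's trials) and are excluded from the headline accuracy.

    ``n_pair_subsample`` draws a seeded random subset of the unordered
    target pairs for cheaper Monte-Carlo estimates of the mean accuracy
    (same-target strata are then skipped).
    """
    betas = np.asarray(betas, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if betas.shape[0] != len(trials) or Y.shape[0] != len(trials):
        raise ValueError("betas/Y rows must match the trial table")
    if Y_train is None:
        Y_train = Y
    groups = _trial_groups(trials)
    cats = dict(zip(trials["trial_id"], trials["category"]))
    trial_ids = list(trials["trial_id"])
    target_list = list(groups)
    all_pairs = list(itertools.combinations(target_list, 2))
    if target_pairs is None:
        target_pairs = all_pairs
        if n_pair_subsample is not None and n_pair_subsample < len(all_pairs):
            if rng is None:
                raise ValueError("n_pair_subsample requires an rng")
            chosen = rng.choice(len(all_pairs), size=n_pair_subsample, replace=False)
            target_pairs = [all_pairs[c] for c in np.sort(chosen)]
            include_same_target = False
    n = len(trials)
    outcomes: list[PairOutcome] = []
    for ta, tb in target_pairs:
        held = np.concatenate([groups[ta], groups[tb]])
        train = np.setdiff1d(np.arange(n), held)
        assert not np.intersect1d(train, held).size  # zero-shot guarantee
        mapping = fit_mapping(betas[train], Y_train[train], lam)
        preds = {int(t): mapping.predict(betas[[t]])[0] for t in held}
        for i in groups[ta]:
            for j in groups[tb]:
                outcomes.append(
                    pair_decision(
                        preds[int(i)],
                        preds[int(j)],
                        Y[i],
                        Y[j],
                        item1=trial_ids[i],
                        item2=trial_ids[j],
                        relation=_relation(
                            cats[trial_ids[i]], cats[trial_ids[j]]
                        ),
                        n_train=len(train),
                    )
                )
    if include_same_target:
        for target, idx in groups.items():
            if len(idx) < 2:
                continue
            train = np.setdiff1d(np.arange(n), idx)
            mapping = fit_mapping(betas[train], Y_train[train], lam)
            preds = mapping.predict(betas[idx])
            for a, b in itertools.combinations(range(len(idx)), 2):
                i, j = idx[a], idx[b]
                outcomes.append(
                    pair_decision(
                        preds[a],
                        preds[b],
                        Y[i],
                        Y[j],
                        item1=trial_ids[i],
                        item2=trial_ids[j],
                        relation="same-target",
                        n_train=len(train),
                    )
                )
    return _as_result(outcomes, cats)


def permutation_null(
    betas: np.ndarray,
    Y: np.ndarray,
    n_iter: int,
    seed: int | np.random.Generator,
    analysis: str = "averaged",
    trials: pd.DataFrame | None = None,
    categories: list | None = None,
    k: int | None = 500,
    lam: float | str = "gcv",
    n_pair_subsample: int | None = None,
) -> PermutationNull:
    """Null distribution of overall accuracy under training-label shuffling.

    Each iteration permutes the target-to-coordinate assignment *in the
    training set only* (test-pair truths stay intact), re-runs the full
    leave-two-out scheme — stability selection included, though it depends
    only on the betas — and records the overall accuracy.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    accs = np.empty(n_iter)
    for it in range(n_iter):
        if analysis == "averaged":
            perm = rng.permutation(Y.shape[0])
            res = leave_two_out_averaged(
                betas, Y, categories=categories, k=k, lam=lam, Y_train=Y[perm]
            )
        elif analysis == "single_trial":
            if trials is None:
                raise ValueError("single_trial permutation needs the trial table")
            groups = _trial_groups(trials)
            names = list(groups)
            perm = rng.permutation(len(names))
            Y_train = Y.copy()
            for src, dst in zip(names, (names[p] for p in perm)):
                Y_train[groups[src]] = Y[groups[dst]]
            res = leave_two_out_single_trial(
                betas,
                trials,
                Y,
                lam=lam,
                n_pair_subsample=n_pair_subsample,
                include_same_target=False,
                rng=rng,
                Y_train=Y_train,
            )
        else:
            raise ValueError(f"unknown analysis {analysis!r}")
        accs[it] = res.overall_accuracy
    return PermutationNull(accuracies=accs, n_iter=n_iter)


def roi_decode(
    betas: np.ndarray,
    roi: np.ndarray,
    Y: np.ndarray,
    categories: list | None = None,
    targets: list | None = None,
    lam: float | str = "gcv",
) -> DecodingResult:
    """Averaged leave-two-out decoding restricted to an ROI voxel index set
    (e.g. left+right perirhinal cortex concatenated), without stability
    selection."""
    roi = np.asarray(roi)
    if roi.size == 0:
        raise ValueError("empty ROI mask")
    return leave_two_out_averaged(
        np.asarray(betas)[:, :, roi],
        Y,
        categories=categories,
        targets=targets,
        k=None,
        lam=lam,
    )


def predict_activation(
    mapping: DecoderMapping, coordinate: np.ndarray
) -> np.ndarray:
    """Invert the fitted mapping: voxel pattern whose decoded coordinate is
    closest to ``coordinate`` (minimum-norm least-squares inverse image).

    The affine structure gives ``f(a + b) = f(a) + f(b) - f(0)``; the
    coordinate equal to the mapping's intercept maps to the training-mean
    pattern.  Rank deficiency is handled by the pseudo-inverse (no failure).
    """
    coordinate = np.asarray(coordinate, dtype=float)
    x_std = (coordinate - mapping.intercept) @ np.linalg.pinv(mapping.weights)
    return mapping.x_mean + mapping.x_sd * x_std


def compare_models(accuracies: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sided paired t-tests between model accuracy columns.

    ``accuracies``: one row per subject, one column per model (percent).
    Bonferroni correction multiplies p by the number of model pairs.
    Degenerate folds: identical columns give t = 0, p = 1; a constant
    nonzero difference gives t = +/-inf, p = 0.
    """
    if len(accuracies) < 2:
        raise ValueError("model comparison needs at least 2 subjects")
    models = list(accuracies.columns)
    n_pairs = len(models) * (len(models) - 1) // 2
    rows = []
    for a, b in itertools.combinations(models, 2):
        diff = accuracies[a].to_numpy() - accuracies[b].to_numpy()
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(diff.mean()) * np.inf, 0.0
        else:
            t, p = stats.ttest_rel(accuracies[a], accuracies[b])
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "mean_a": accuracies[a].mean(),
                "mean_b": accuracies[b].mean(),
                "t": float(t),
                "p": float(p),
                "p_bonferroni": min(1.0, float(p) * n_pairs),
            }
        )
    table = pd.DataFrame(rows)
    ranks = accuracies.mean().rank(ascending=False).astype(int)
    table.attrs["rank_by_mean"] = {m: int(ranks[m]) for m in models}
    return table
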