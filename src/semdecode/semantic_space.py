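"""Distributional semantic space and trial-level coordinate construction.

A :class:`SemanticSpace` holds a vocabulary of D-dimensional word vectors
(word2vec-style skip-gram embeddings; D = 300 by convention).  Each
experimental trial probes a target object with an ordered triplet of verbal
clues, and the trial's position in the semantic space can be constructed
under six different feature-combination models
(:class:`CoordinateModel`): the single third clue, the summed clue triplet,
the target word itself, the sum over every feature in the target's property
norms, the clue triplet of a donor trial of the same target, or the sum over
all non-clue features.  Feature texts resolve to vocabulary tokens through a
:class:`KeywordMap` (one key word per feature phrase); the map is supplied as
data, never computed — lemmatization is out of scope.

Vectors are summed without length normalization, which preserves the exact
linear identity  ALL_FEATURES = ALL_NONCLUES + sum(clue vectors)  relied on
by the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SemanticSpace",
    "KeywordMap",
    "CoordinateModel",
    "FeatureNorms",
    "MissingTokenError",
    "WordVectorFormatError",
    "DegenerateCoordinateWarning",
    "load_word_vectors",
    "save_word_vectors",
    "sum_feature_vectors",
    "trial_coordinate",
    "design_matrix",
]


class MissingTokenError(KeyError):
    """A feature or clue failed to resolve to a vector in the space."""


class WordVectorFormatError(ValueError):
    """Malformed word2vec text file (bad header or row)."""


class DegenerateCoordinateWarning(UserWarning):
    """A coordinate model produced an all-zero (empty-sum) vector."""


class CoordinateModel(Enum):
    """The six feature-combination models for trial semantic coordinates."""

    CLUE3 = "clue3"
    CLUE123 = "clue123"
    TARGET = "target"
    ALL_FEATURES = "all_features"
    MIXED_CLUES = "mixed_clues"
    ALL_NONCLUES = "all_nonclues"


#: Models defined at the target level (usable with repetition-averaged data).
TARGET_LEVEL_MODELS = (CoordinateModel.TARGET, CoordinateModel.ALL_FEATURES)


@dataclass
class SemanticSpace:
    """Vocabulary of D-dimensional embedding vectors.

    Lookups are case-normalized: tokens are lower-cased on insertion and on
    lookup; no fuzzy matching.
    """

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        normalized: dict[str, np.ndarray] = {}
        for token, vec in self.vectors.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (self.dim,):
                raise ValueError(
                    f"vector for {token!r} has shape {arr.shape}, expected ({self.dim},)"
                )
            normalized[token.lower()] = arr
        self.vectors = normalized

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.vectors

    def vector(self, token: str) -> np.ndarray:
        """Return the vector for ``token`` (case-insensitive, exact match)."""
        try:
            return self.vectors[token.lower()]
        except KeyError:
            raise MissingTokenError(f"token {token!r} not in semantic space") from None


@dataclass
class KeywordMap:
    """Maps clue/feature phrases to the single key token carrying the vector.

    Mirrors the manual key-word selection used when a feature consists of
    several words (e.g. "has legs" -> "leg").
    """

    mapping: dict[str, str]

    def resolve(self, text: str) -> str:
        try:
            return self.mapping[text]
        except KeyError:
            raise MissingTokenError(f"no key word for feature {text!r}") from None

    def __len__(self) -> int:
        return len(self.mapping)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"text": list(self.mapping), "token": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeywordMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["text"], df["token"])))


@dataclass
class FeatureNorms:
    """Property norms: per-target feature lists with distinctiveness ranks.

    ``table`` columns: ``target``, ``feature`` (text), ``rank`` (integer
    distinctiveness rank, 1 = least distinctive), ``is_clue`` (bool flag for
    the nine features used as clues in the task).
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = ("target", "feature", "rank", "is_clue")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"feature norm table missing columns {missing}")
        self.table = self.table.copy()
        self.table["is_clue"] = self.table["is_clue"].astype(bool)

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.table["target"]))

    def features(self, target: str) -> list[str]:
        """All feature texts of a target, in rank order."""
        sub = self.table[self.table["target"] == target]
        if sub.empty:
            raise KeyError(f"target {target!r} not in feature norms")
        return list(sub.sort_values("rank")["feature"])

    def clues(self, target: str) -> list[str]:
        """The clue-flagged features of a target, in rank order."""
        sub = self.table[(self.table["target"] == target) & self.table["is_clue"]]
        return list(sub.sort_values("rank")["feature"])

    def nonclues(self, target: str) -> list[str]:
        sub = self.table[(self.table["target"] == target) & ~self.table["is_clue"]]
        return list(sub.sort_values("rank")["feature"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureNorms":
        return cls(pd.read_csv(path, sep="\t"))


def load_word_vectors(path: str | Path, format: str = "word2vec-text") -> SemanticSpace:
    """Read a word2vec text-format vector file.

    The format is: a header line ``<vocab_size> <dim>`` followed by one line
    per token, ``<token> <v1> ... <vD>`` (whitespace separated).
    """
    if format != "word2vec-text":
        raise ValueError(f"unsupported format {format!r}; only 'word2vec-text'")
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise WordVectorFormatError(f"{path}: malformed header {header!r}")
        try:
            n_tokens, dim = int(header[0]), int(header[1])
        except ValueError:
            raise WordVectorFormatError(f"{path}: non-integer header {header!r}") from None
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise WordVectorFormatError(
                    f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}"
                )
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
    if len(vectors) != n_tokens:
        raise WordVectorFormatError(
            f"{path}: header declares {n_tokens} tokens, file has {len(vectors)}"
        )
    return SemanticSpace(vectors=vectors, dim=dim)


def save_word_vectors(space: SemanticSpace, path: str | Path) -> None:
    """Write a :class:`SemanticSpace` in word2vec text format (full float repr)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(space)} {space.dim}\n")
        for token, vec in space.vectors.items():
            fh.write(token + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def sum_feature_vectors(
    features: Sequence[str], keyword_map: KeywordMap, space: SemanticSpace
) -> np.ndarray:
    """Component-wise sum of the key-word vectors of ``features`` (no normalization)."""
    total = np.zeros(space.dim)
    for feature in features:
        total = total + space.vector(keyword_map.resolve(feature))
    return total


def trial_coordinate(
    trial: Mapping,
    model: CoordinateModel,
    norms: FeatureNorms,
    keyword_map: KeywordMap,
    space: SemanticSpace,
    trials: pd.DataFrame | None = None,
) -> np.ndarray:
    """Semantic coordinate of one trial under one of the six models.

    ``trial`` must carry ``target`` and, for the clue-based models, the
    ordered clue texts ``clue1``/``clue2``/``clue3``; for MIXED_CLUES it must
    carry ``donor_trial`` (a trial id) and ``trials`` (the full table indexed
    by ``trial_id``) must be given so the donor's clues can be looked up.
    """
    target = trial["target"]
    if model is CoordinateModel.CLUE3:
        return space.vector(keyword_map.resolve(trial["clue3"]))
    if model is CoordinateModel.CLUE123:
        return sum_feature_vectors(
            [trial["clue1"], trial["clue2"], trial["clue3"]], keyword_map, space
        )
    if model is CoordinateModel.TARGET:
        return space.vector(keyword_map.resolve(target))
    if model is CoordinateModel.ALL_FEATURES:
        return sum_feature_vectors(norms.features(target), keyword_map, space)
    if model is CoordinateModel.ALL_NONCLUES:
        nonclues = norms.nonclues(target)
        if not nonclues:
            warnings.warn(
                f"target {target!r} has no non-clue features; "
                "ALL_NONCLUES coordinate is the zero vector",
                DegenerateCoordinateWarning,
                stacklevel=2,
            )
            return np.zeros(space.dim)
        return sum_feature_vectors(nonclues, keyword_map, space)
    if model is CoordinateModel.MIXED_CLUES:
        donor_id = trial.get("donor_trial")
        if donor_id is None or trials is None:
            raise ValueError(
                "MIXED_CLUES requires a donor_trial id and the full trial table"
            )
        donors = trials[trials["trial_id"] == donor_id]
        if donors.empty:
            raise ValueError(f"donor trial {donor_id!r} not found in trial table")
        donor = donors.iloc[0]
        if donor["target"] != target:
            raise ValueError(
                f"donor trial {donor_id!r} has target {donor['target']!r}, "
                f"expected {target!r}"
            )
        own = {trial["clue1"], trial["clue2"], trial["clue3"]}
        donated = [donor["clue1"], donor["clue2"], donor["clue3"]]
        if own & set(donated):
            raise ValueError(
                f"donor trial {donor_id!r} shares clues {own & set(donated)} "
                "with the probed trial"
            )
        return sum_feature_vectors(donated, keyword_map, space)
    raise ValueError(f"unknown coordinate model {model!r}")


def design_matrix(
    trials: pd.DataFrame,
    model: CoordinateModel,
    norms: FeatureNorms,
    keyword_map: KeywordMap,
    space: SemanticSpace,
    averaged: bool = False,
) -> np.ndarray:
    """Stack trial (or per-target, if ``averaged``) coordinates into a matrix.

    Single-trial mode returns one row per trial, in table order (360 x D for
    the full design).  Averaged mode returns one row per target in order of
    first appearance (60 x D) and is defined only for the target-level models
    (TARGET, ALL_FEATURES), whose coordinate does not depend on the clue
    triplet.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if averaged:
        if model not in TARGET_LEVEL_MODELS:
            raise ValueError(
                f"averaged design only defined for {TARGET_LEVEL_MODELS}, got {model}"
            )
        rows = []
        for target in dict.fromkeys(trials["target"]):
            rep = trials[trials["target"] == target].iloc[0]
            rows.append(
                trial_coordinate(rep, model, norms, keyword_map, space, trials)
            )
        return np.vstack(rows)
    return np.vstack(
        [
            trial_coordinate(row, model, norms, keyword_map, space, trials)
            for _, row in trials.iterrows()
        ]
    )
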