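"""Variant encodings and label standardization.

One-hot encoding flattens an L × d_aa indicator matrix per variant (d_aa = 22:
the 20 canonical amino acids plus gap '-' and unknown 'X', in the frozen order
of :data:`fitbench.variants.DEFAULT_ALPHABET`).  Mean pooling collapses a
per-position embedding matrix to a single vector, the convention used for
transformer representations.  Labels are standardized per training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import DEFAULT_ALPHABET, Variant

_SOURCES = ("one_hot", "mean_pooled", "surrogate", "external")


@dataclass
class RepresentationMatrix:
    """n × d real matrix of per-variant representations."""

    values: np.ndarray
    row_ids: np.ndarray
    source: str = "external"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = np.asarray(self.row_ids)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be a 2-D matrix with d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("representation contains non-finite entries")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length mismatch")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def one_hot_encode(
    variants: Sequence[Variant],
    wildtype: str,
    alphabet: str = DEFAULT_ALPHABET,
) -> RepresentationMatrix:
    """Flattened per-site indicator encoding; exactly L ones per row."""
    index = {aa: i for i, aa in enumerate(alphabet)}
    L = len(wildtype)
    d_aa = len(alphabet)
    try:
        wt_cols = np.array([index[aa] for aa in wildtype])
    except KeyError as e:
        raise ValueError(f"wildtype residue {e} outside alphabet") from None

    X = np.zeros((len(variants), L * d_aa))
    base = np.arange(L) * d_aa + wt_cols
    for i, v in enumerate(variants):
        v.validate(wildtype)
        row_cols = base.copy()
        for s in v.substitutions:
            if s.mut_aa not in index:
                raise ValueError(f"residue {s.mut_aa!r} outside alphabet")
            row_cols[s.position - 1] = (s.position - 1) * d_aa + index[s.mut_aa]
        X[i, row_cols] = 1.0
    return RepresentationMatrix(values=X, row_ids=np.arange(len(variants)),
                                source="one_hot")


def mean_pool(per_position: np.ndarray) -> np.ndarray:
    """Coordinate-wise mean over sequence positions (rows)."""
    per_position = np.asarray(per_position, dtype=float)
    if per_position.ndim != 2 or per_position.shape[0] < 1:
        raise ValueError("expected a non-empty L x d matrix")
    return per_position.mean(axis=0)


@dataclass
class LabelStandardizer:
    """ȳ = (y − μ_y) / std(y), fitted on the training fold only."""

    mu: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("standardizer requires sd > 0")

    def apply(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mu) / self.sd

    def invert(self, y_std: np.ndarray) -> np.ndarray:
        return np.asarray(y_std, dtype=float) * self.sd + self.mu

    def invert_variance(self, var_std: np.ndarray) -> np.ndarray:
        return np.asarray(var_std, dtype=float) * self.sd**2


def fit_standardizer(train_labels: np.ndarray) -> LabelStandardizer:
    y = np.asarray(train_labels, dtype=float)
    if y.size < 2:
        raise ValueError("need >= 2 training labels")
    sd = float(np.std(y))
    if sd == 0.0:
        raise ValueError("constant training labels: standard deviation is zero")
    return LabelStandardizer(mu=float(np.mean(y)), sd=sd)


def load_embeddings(path: str | Path, n_expected: int | None = None) -> RepresentationMatrix:
    """Read an external embedding matrix (.npy or delimited text), one row per variant."""
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        values = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    values = np.atleast_2d(values)
    if n_expected is not None and values.shape[0] != n_expected:
        raise ValueError(
            f"embedding has {values.shape[0]} rows, expected {n_expected}"
        )
    return RepresentationMatrix(values=values, row_ids=np.arange(values.shape[0]),
                                source="external")


def save_embeddings(rep: RepresentationMatrix, path: str | Path) -> None:
    """Write an embedding matrix (.npy, or delimited text for .csv/.tsv/.txt),
    one row per variant in dataset row order."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, rep.values)
    else:
        np.savetxt(path, rep.values, delimiter="," if path.suffix == ".csv" else "\t")


def as_matrix(X) -> np.ndarray:
    """Accept a RepresentationMatrix or a plain array-like."""
    if isinstance(X, RepresentationMatrix):
        return X.values
    return np.asarray(X, dtype=float)
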