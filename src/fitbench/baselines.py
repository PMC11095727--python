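"""Reference predictors: training mean, additive composition, ranking oracle.

The additive baseline predicts a multi-mutant's label as the sum of the
observed labels of its constituent single mutants — the site-independence
assumption engineering pipelines often rely on.  The ranking oracle turns any
external score vector (e.g. an unsupervised evolutionary score) into a
selection order for optimization benchmarks.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import AssayDataset, Variant

logger = logging.getLogger(__name__)


@dataclass
class MeanBaseline:
    """Constant predictor at the training mean; adjusted R² = 0 by construction."""

    mu: float

    def predict(self, X) -> np.ndarray:
        n = len(X)
        return np.full(n, self.mu)


def mean_baseline(train_labels) -> MeanBaseline:
    y = np.asarray(train_labels, dtype=float)
    if y.size == 0:
        raise ValueError("empty training labels")
    return MeanBaseline(mu=float(np.mean(y)))


@dataclass
class SingleEffectTable:
    """Observed single-mutant labels keyed by (position, mutant residue).

    Duplicate measurements of the same substitution are averaged.
    """

    effects: dict
    source: str = ""

    @classmethod
    def from_dataset(cls, dataset: AssayDataset, source: str = "") -> "SingleEffectTable":
        sums: dict = defaultdict(float)
        counts: dict = defaultdict(int)
        for v, y in zip(dataset.variants, dataset.labels):
            if v.degree == 1:
                s = v.substitutions[0]
                key = (s.position, s.mut_aa)
                sums[key] += float(y)
                counts[key] += 1
        return cls({k: sums[k] / counts[k] for k in sums}, source=source)

    def __len__(self) -> int:
        return len(self.effects)

    def to_frame(self) -> pd.DataFrame:
        rows = [(pos, aa, val) for (pos, aa), val in sorted(self.effects.items())]
        return pd.DataFrame(rows, columns=["position", "mut_aa", "value"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SingleEffectTable":
        df = pd.read_csv(path)
        return cls({(int(r.position), str(r.mut_aa)): float(r.value)
                    for r in df.itertuples()})


def additive_baseline(
    table: SingleEffectTable, variant: Variant, mode: str = "singles"
) -> float | None:
    """Compose a multi-mutant prediction from observed single-mutant labels.

    ``mode="singles"`` (default) sums the single-mutant observations of all
    constituents: y(V1,...,Vk) = Σ y(Vi).  Returns None (missing) if any
    constituent is unobserved.  ``mode="decompositions"`` is accepted for API
    symmetry with :func:`additive_baseline_with_doubles`.
    """
    if variant.degree < 2:
        raise ValueError("additive baseline applies to degree >= 2 variants")
    values = []
    for s in variant.substitutions:
        key = (s.position, s.mut_aa)
        if key not in table.effects:
            return None
        values.append(table.effects[key])
    return float(sum(values))


def additive_baseline_with_doubles(
    single_table: SingleEffectTable,
    double_table: dict,
    variant: Variant,
) -> float | None:
    """Triple-variant composition averaging observed double+single decompositions.

    For a triple (a, b, c) the prediction is the mean of y(ab)+y(c),
    y(ac)+y(b), y(bc)+y(a) over the decompositions whose double was observed;
    it falls back to the plain singles sum when no double is available.
    ``double_table`` maps frozensets of two (position, mut_aa) keys to labels.
    """
    if variant.degree != 3:
        raise ValueError("decomposition mode is defined for triples")
    keys = [(s.position, s.mut_aa) for s in variant.substitutions]
    terms = []
    for i in range(3):
        single = keys[i]
        pair = frozenset(k for j, k in enumerate(keys) if j != i)
        if pair in double_table and single in single_table.effects:
            terms.append(double_table[pair] + single_table.effects[single])
    if terms:
        return float(np.mean(terms))
    return additive_baseline(single_table, variant)


def additive_predictions(
    table: SingleEffectTable, variants: Sequence[Variant]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized additive baseline; returns (predictions, observed mask).

    Variants with any unobserved constituent get NaN and mask False; the count
    of missing predictions is logged.
    """
    preds = np.full(len(variants), np.nan)
    mask = np.zeros(len(variants), dtype=bool)
    for i, v in enumerate(variants):
        p = additive_baseline(table, v)
        if p is not None:
            preds[i] = p
            mask[i] = True
    n_missing = int((~mask).sum())
    if n_missing:
        logger.info("additive baseline: %d/%d variants missing a constituent",
                    n_missing, len(variants))
    return preds, mask


def ranking_oracle(scores) -> np.ndarray:
    """Candidate indices sorted by descending score; ties keep index order."""
    s = np.asarray(scores, dtype=float)
    # stable sort on negated scores preserves index order among ties
    return np.argsort(-s, kind="stable")
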