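"""Train/test split protocols for variant-effect data.

Five protocols, each encoding a different notion of generalization:

* **Random CV** — k-fold over shuffled indices; appropriate for imputing
  values that are missing at random.
* **Positional CV** — hold out contiguous blocks of sequence positions; any
  variant with a mutation inside the block is tested, the rest train.  Probes
  generalization to unseen sequence regions.
* **Mutational CV** — train on low mutation degrees, test on a higher degree;
  probes extrapolation in mutation distance.
* **Fractional CV** — sub-sample training fractions against a fixed held-out
  evaluation set; a learning-curve proxy for data efficiency.
* **Chronological** — train on early acquisition rounds, test on later ones;
  the forecaster scenario for iterative campaigns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .variants import Variant


@dataclass
class SplitPlan:
    """Ordered folds of disjoint (train, test) index arrays over [0, n)."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    protocol: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tr, te in self.folds:
            if np.intersect1d(tr, te).size:
                raise ValueError("train and test overlap within a fold")

    def __iter__(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, (tr, te) in enumerate(self.folds):
            rows += [(f, "train", int(i)) for i in tr]
            rows += [(f, "test", int(i)) for i in te]
        return pd.DataFrame(rows, columns=["fold", "role", "index"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def random_cv(n: int, k: int = 10, seed: int = 0) -> SplitPlan:
    """Standard shuffled k-fold CV; test sets partition [0, n)."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n))]
    return SplitPlan(folds, "random_cv", {"k": k, "seed": seed})


def position_cv(variants: Sequence[Variant], L: int, p: int = 15) -> SplitPlan:
    """Hold out ⌈L/p⌉ contiguous position blocks.

    Fold j tests every variant with ANY mutated position in 1-based block
    [j·p+1, min((j+1)·p, L)] and trains on the rest; the wildtype (degree 0)
    is always a training point.
    """
    if not 1 <= p <= L:
        raise ValueError(f"need 1 <= p <= L, got p={p}, L={L}")
    for v in variants:
        for pos in v.positions:
            if not 1 <= pos <= L:
                raise ValueError(f"variant position {pos} outside [1, {L}]")
    n_folds = math.ceil(L / p)
    folds = []
    for j in range(n_folds):
        lo, hi = j * p + 1, min((j + 1) * p, L)
        in_block = np.array(
            [any(lo <= pos <= hi for pos in v.positions) for v in variants]
        )
        folds.append((np.flatnonzero(~in_block), np.flatnonzero(in_block)))
    return SplitPlan(folds, "position_cv", {"L": L, "p": p})


def mutational_cv(
    variants: Sequence[Variant],
    test_degree: int,
    include_equal_degree: bool = False,
    holdout_frac: float = 0.2,
    n_folds_equal: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Train on low degrees, test on degree ``test_degree``.

    With ``include_equal_degree=False``: one fold, train = degree < test_degree,
    test = degree == test_degree.  With True: ``n_folds_equal`` folds, each
    training on all lower-degree variants plus the (1 − holdout_frac) share of
    test-degree variants and testing on the held-out remainder, so every
    test-degree variant is tested exactly once across folds.
    """
    if test_degree < 1:
        raise ValueError("test_degree must be >= 1")
    degrees = np.array([v.degree for v in variants])
    lower = np.flatnonzero(degrees < test_degree)
    equal = np.flatnonzero(degrees == test_degree)
    if equal.size == 0:
        raise ValueError(f"no variants of degree {test_degree}")
    if not include_equal_degree:
        if lower.size == 0:
            raise ValueError("empty training set: no variants below test_degree")
        folds = [(lower, equal)]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(equal)
        chunks = np.array_split(perm, n_folds_equal)
        folds = []
        for held_out in chunks:
            if held_out.size == 0:
                raise ValueError("empty test chunk; fewer test-degree variants than folds")
            train_equal = np.setdiff1d(equal, held_out)
            folds.append((np.sort(np.concatenate([lower, train_equal])),
                          np.sort(held_out)))
    return SplitPlan(
        folds, "mutational_cv",
        {"test_degree": test_degree, "include_equal_degree": include_equal_degree,
         "holdout_frac": holdout_frac, "n_folds_equal": n_folds_equal, "seed": seed},
    )


def fractional_cv(
    n: int,
    fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    reps: int = 5,
    eval_frac: float = 0.2,
    seed: int = 0,
    mode: str = "fixed",
) -> SplitPlan:
    """Learning-curve folds: per (fraction q, repetition), hold out
    ⌈eval_frac·n⌉ test points and train on ⌈q·(n − n_test)⌉ of the remainder.

    ``mode="fixed"`` (default) keeps the test set at the fixed eval_frac size
    so difficulty is constant across q; ``mode="complement"`` tests on the
    entire non-training remainder instead.
    """
    if not all(0 < q <= 1 for q in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if not 0 < eval_frac < 1:
        raise ValueError("eval_frac must lie in (0, 1)")
    if mode not in ("fixed", "complement"):
        raise ValueError("mode must be 'fixed' or 'complement'")
    rng = np.random.default_rng(seed)
    folds = []
    for rep in range(reps):
        for q in fractions:
            perm = rng.permutation(n)
            n_test = math.ceil(eval_frac * n)
            test = np.sort(perm[:n_test])
            remainder = perm[n_test:]
            n_train = math.ceil(q * len(remainder))
            if n_train < 1:
                raise ValueError(f"training set empty at fraction {q}")
            train = np.sort(remainder[:n_train])
            if mode == "complement":
                test = np.sort(np.concatenate([test, remainder[n_train:]]))
            folds.append((train, test))
    return SplitPlan(
        folds, "fractional_cv",
        {"fractions": tuple(fractions), "reps": reps, "eval_frac": eval_frac,
         "seed": seed, "mode": mode},
    )


def chronological_split(round_index: np.ndarray, cut_round: int) -> SplitPlan:
    """Train on rounds < cut_round, test on rounds >= cut_round."""
    rounds = np.asarray(round_index, dtype=int)
    train = np.flatnonzero(rounds < cut_round)
    test = np.flatnonzero(rounds >= cut_round)
    if train.size == 0:
        raise ValueError("empty training side: cut_round at or below the first round")
    if test.size == 0:
        raise ValueError("empty test side: cut_round beyond the last round")
    return SplitPlan([(train, test)], "chronological", {"cut_round": cut_round})
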