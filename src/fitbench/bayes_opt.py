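"""Optimization-as-assessment: Expected Improvement over a labelled pool.

The benchmark treats a fully labelled candidate pool as an oracle-by-lookup:
starting from a few random observations, the surrogate regressor is refit at
every iteration (including its hyperparameter protocol), all unobserved
candidates are scored by Expected Improvement, and the argmax is revealed.
The figure of merit is how quickly the pool optimum is found, compared with
random selection and with ranking by an external score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .encodings import as_matrix
from .variants import AssayDataset


def expected_improvement(mu, sigma, best: float):
    """EI(μ, σ; best) = (μ−best)·Φ(z) + σ·φ(z), z = (μ−best)/σ (maximization).

    At σ = 0 the improvement is deterministic: EI = max(μ − best, 0).
    Accepts scalars or arrays.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    diff = mu - best
    out = np.maximum(diff, 0.0)
    pos = sigma > 0
    if np.any(pos):
        z = np.divide(diff, sigma, out=np.zeros_like(mu + sigma), where=pos)
        ei = diff * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
        out = np.where(pos, ei, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class BOTrace:
    """One optimization run: reveal order, best-so-far, iterations-to-optimum.

    Iterations are 1-based over *all* reveals (initial random points
    included); ``found_optimum_at`` is None when the pool optimum was never
    revealed within budget.
    """

    seed: int
    selected: list[int]
    best_so_far: list[float]
    found_optimum_at: int | None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be distinct")
        if any(b < a - 1e-12 for a, b in zip(self.best_so_far, self.best_so_far[1:])):
            raise ValueError("best-so-far must be non-decreasing")

    def __len__(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"seed": self.seed,
             "iteration": np.arange(1, len(self.selected) + 1),
             "selected_index": self.selected,
             "best_so_far": self.best_so_far}
        )


def _trace_from_reveals(seed: int, selected: list[int], labels: np.ndarray) -> BOTrace:
    optimum = float(np.max(labels))
    best, bests, found = -np.inf, [], None
    for it, idx in enumerate(selected, start=1):
        best = max(best, float(labels[idx]))
        bests.append(best)
        if found is None and labels[idx] == optimum:
            found = it
    return BOTrace(seed=seed, selected=selected, best_so_far=bests,
                   found_optimum_at=found)


def bo_loop(
    X_pool,
    y_pool,
    estimator,
    budget: int = 500,
    n_init: int = 5,
    seed: int = 0,
    refit_every: int = 1,
) -> BOTrace:
    """Expected-Improvement loop over a fixed labelled pool.

    ``budget`` counts total reveals including the ``n_init`` random initial
    points.  The estimator is cloned and refit on the observed points every
    ``refit_every`` acquisitions (1 = the full protocol; larger values are a
    desk-scale throttle).  EI ties resolve to the lowest pool index.
    """
    X = as_matrix(X_pool)
    y = np.asarray(y_pool, dtype=float)
    n = len(y)
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if n_init < 1 or n_init > n:
        raise ValueError("need 1 <= n_init <= pool size")
    rng = np.random.default_rng(seed)

    selected = [int(i) for i in rng.permutation(n)[: min(n_init, budget)]]
    observed = set(selected)
    model = None
    since_refit = None
    while len(selected) < min(budget, n):
        if model is None or since_refit >= refit_every:
            model = clone(estimator)
            if "random_state" in model.get_params():
                model.set_params(random_state=int(rng.integers(2**31)))
            obs = np.array(selected)
            model.fit(X[obs], y[obs])
            since_refit = 0
        remaining = np.array([i for i in range(n) if i not in observed])
        dist = model.predict_dist(X[remaining])
        best = max(y[i] for i in observed)
        ei = expected_improvement(dist.mean, dist.sd, best)
        nxt = int(remaining[int(np.argmax(ei))])  # argmax keeps lowest index on ties
        selected.append(nxt)
        observed.add(nxt)
        since_refit += 1
    return _trace_from_reveals(seed, selected, y)


def random_selection_trace(y_pool, budget: int = 500, seed: int = 0) -> BOTrace:
    """Uniformly random selection without replacement."""
    y = np.asarray(y_pool, dtype=float)
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    selected = [int(i) for i in rng.permutation(len(y))[: min(budget, len(y))]]
    return _trace_from_reveals(seed, selected, y)


def ranking_trace(y_pool, scores, budget: int = 500, seed: int = 0) -> BOTrace:
    """Selection by descending external score (e.g. an evolutionary score)."""
    from .baselines import ranking_oracle

    y = np.asarray(y_pool, dtype=float)
    order = ranking_oracle(scores)[: min(budget, len(y))]
    return _trace_from_reveals(seed, [int(i) for i in order], y)


def summarize_traces(traces: list[BOTrace], n_partitions: int = 4) -> pd.DataFrame:
    """Quarter-wise mean and standard error of best-so-far across traces.

    Partition j ends at iteration ⌈budget·j/n_partitions⌉ where budget is the
    longest trace; also reports the median iterations-to-optimum (over traces
    that found it) and the number of traces that did not.
    """
    if not traces:
        raise ValueError("need at least one trace")
    budget = max(len(t) for t in traces)
    rows = []
    for j in range(1, n_partitions + 1):
        cut = math.ceil(budget * j / n_partitions)
        vals = np.array([t.best_so_far[min(cut, len(t)) - 1] for t in traces])
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"partition": j, "iteration": cut,
                     "mean_best": float(np.mean(vals)), "stderr_best": se})
    summary = pd.DataFrame(rows)
    found = [t.found_optimum_at for t in traces if t.found_optimum_at is not None]
    summary.attrs["median_iterations_to_optimum"] = (
        float(np.median(found)) if found else float("nan")
    )
    summary.attrs["n_not_found"] = len(traces) - len(found)
    return summary


def traces_to_frame(traces: list[BOTrace]) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)
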