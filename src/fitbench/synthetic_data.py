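"""Synthetic fitness landscapes, variant samplers, noisy assays and campaigns.

The generator produces the data regimes a protein-engineering assessment has
to cope with: a near-complete single-mutant scan with a bimodal
functional/non-functional label distribution, multi-mutant sets whose labels
collapse toward non-functional with increasing mutation degree, iterative
acquisition campaigns whose fitness rises over rounds through greedy
selection, and dense surrogate embeddings standing in for mean-pooled
protein-language-model representations.

The ground truth is an additive-plus-pairwise-epistatic landscape: the raw
score of a variant is the sum of per-substitution additive effects plus any
pairwise epistatic terms whose two (site, residue) pairs are both present,
optionally passed through a sigmoid link to produce the bimodal
functional/non-functional picture.  Assay labels add homoscedastic Gaussian
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .variants import AA20, AssayDataset, Substitution, Variant

_LINKS = ("identity", "sigmoid")


@dataclass(frozen=True)
class LandscapeModel:
    """Ground-truth fitness model: additive effects + pairwise epistasis + link.

    ``additive_effects`` maps (1-based position, mutant residue) to a real
    effect; the wildtype residue at every site has effect zero by
    construction.  ``pairwise_effects`` maps ((i, aa), (j, aa')) with i < j to
    an epistatic term that fires only when both substitutions are present.
    """

    wildtype: str
    additive_effects: dict
    pairwise_effects: dict
    link: str = "identity"
    link_threshold: float = 0.0
    link_steepness: float = 1.0
    assay_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}; choose from {_LINKS}")
        if self.assay_noise_sd < 0:
            raise ValueError("assay_noise_sd must be >= 0")
        for (pos, aa) in self.additive_effects:
            if self.wildtype[pos - 1] == aa and self.additive_effects[(pos, aa)] != 0.0:
                raise ValueError(f"nonzero additive effect at wildtype residue {pos}")
        for (a, b) in self.pairwise_effects:
            if a[0] >= b[0]:
                raise ValueError("pairwise keys must have i < j")

    @property
    def length(self) -> int:
        return len(self.wildtype)

    def raw_score(self, variant: Variant) -> float:
        """Additive + epistatic score before the link function."""
        variant.validate(self.wildtype)
        total = 0.0
        subs = [(s.position, s.mut_aa) for s in variant.substitutions]
        for key in subs:
            total += self.additive_effects.get(key, 0.0)
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                total += self.pairwise_effects.get((subs[i], subs[j]), 0.0)
        return total

    def _apply_link(self, raw: float) -> float:
        if self.link == "identity":
            return raw
        z = self.link_steepness * (raw - self.link_threshold)
        return 1.0 / (1.0 + math.exp(-z))

    def true_fitness(self, variant: Variant) -> float:
        return self._apply_link(self.raw_score(variant))

    def true_fitness_many(self, variants: Sequence[Variant]) -> np.ndarray:
        return np.array([self.true_fitness(v) for v in variants])


def build_landscape(
    L: int,
    n_epistatic_pairs: int = 0,
    effect_scale: float = 0.5,
    epistasis_scale: float = 0.0,
    link: str = "identity",
    assay_noise_sd: float = 0.0,
    seed: int = 0,
    effect_mean: float = -0.5,
    site_effect_sd: float = 0.0,
    link_threshold: float = 0.0,
    link_steepness: float = 1.0,
    wildtype: str | None = None,
) -> LandscapeModel:
    """Draw a random landscape of sequence length ``L``.

    The additive effect of substituting residue ``aa`` at a site is
    site_effect + Normal(effect_mean, effect_scale²), where the site effect is
    a per-position Normal(0, site_effect_sd²) term shared by all substitutions
    at that position.  ``site_effect_sd > 0`` emulates position-level
    conservation (mutating a critical site hurts regardless of the residue),
    the structure that makes a single-mutant scan learnable across variants;
    with ``site_effect_sd = 0`` effects are i.i.d. per substitution.  The
    deleterious default mean makes most mutations harmful, which under the
    sigmoid link reproduces the bimodal functional/non-functional label
    picture.  Epistatic pairs are placed uniformly at random over site pairs
    with Normal(0, epistasis_scale²) magnitudes.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if effect_scale < 0 or epistasis_scale < 0:
        raise ValueError("scales must be >= 0")
    if link not in _LINKS:
        raise ValueError(f"unknown link {link!r}; choose from {_LINKS}")
    rng = np.random.default_rng(seed)
    if wildtype is None:
        wildtype = "".join(rng.choice(list(AA20), size=L))
    elif len(wildtype) != L:
        raise ValueError("wildtype length disagrees with L")

    additive = {}
    for pos in range(1, L + 1):
        wt_aa = wildtype[pos - 1]
        site = site_effect_sd * rng.standard_normal()
        for aa in AA20:
            if aa != wt_aa:
                additive[(pos, aa)] = (
                    effect_mean + site + effect_scale * rng.standard_normal()
                )

    pairwise = {}
    if n_epistatic_pairs > 0 and epistasis_scale > 0:
        while len(pairwise) < n_epistatic_pairs:
            i, j = sorted(rng.choice(L, size=2, replace=False) + 1)
            aa_i = _random_non_wt(rng, wildtype[i - 1])
            aa_j = _random_non_wt(rng, wildtype[j - 1])
            key = ((int(i), aa_i), (int(j), aa_j))
            if key not in pairwise:
                pairwise[key] = epistasis_scale * rng.standard_normal()

    return LandscapeModel(
        wildtype=wildtype,
        additive_effects=additive,
        pairwise_effects=pairwise,
        link=link,
        link_threshold=link_threshold,
        link_steepness=link_steepness,
        assay_noise_sd=assay_noise_sd,
    )


def _random_non_wt(rng: np.random.Generator, wt_aa: str) -> str:
    choices = [aa for aa in AA20 if aa != wt_aa]
    return str(rng.choice(choices))


def enumerate_single_mutants(landscape: LandscapeModel) -> list[Variant]:
    """All 19·L single substitutions of the wildtype, in position/alphabet order."""
    out = []
    for pos in range(1, landscape.length + 1):
        wt_aa = landscape.wildtype[pos - 1]
        for aa in AA20:
            if aa != wt_aa:
                out.append(Variant((Substitution(wt_aa, pos, aa),)))
    return out


def count_variants(L: int, degree: int) -> int:
    """Number of distinct degree-d variants of a length-L sequence."""
    return math.comb(L, degree) * 19**degree


def _unrank_combination(idx: int, L: int, d: int) -> list[int]:
    """idx-th (lexicographic) d-combination of {0..L-1}."""
    combo = []
    x = 0
    for slot in range(d, 0, -1):
        while True:
            c = math.comb(L - x - 1, slot - 1)
            if idx < c:
                combo.append(x)
                x += 1
                break
            idx -= c
            x += 1
    return combo


def _variant_from_index(landscape: LandscapeModel, degree: int, idx: int) -> Variant:
    sites_idx, residues_idx = divmod(idx, 19**degree)
    sites = _unrank_combination(sites_idx, landscape.length, degree)
    subs = []
    for site in sites:
        residues_idx, r = divmod(residues_idx, 19)
        wt_aa = landscape.wildtype[site]
        choices = [aa for aa in AA20 if aa != wt_aa]
        subs.append(Substitution(wt_aa, site + 1, choices[r]))
    return Variant(tuple(subs))


def sample_variants(
    landscape: LandscapeModel, degree: int, n: int, seed: int = 0
) -> list[Variant]:
    """n distinct degree-d variants sampled uniformly without replacement."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    total = count_variants(landscape.length, degree)
    if n > total:
        raise ValueError(f"requested {n} variants but only {total} exist at degree {degree}")
    rng = np.random.default_rng(seed)
    if total <= 2_000_000:
        indices = rng.choice(total, size=n, replace=False)
        return [_variant_from_index(landscape, degree, int(i)) for i in indices]
    # Rejection sampling in the astronomically large regime: draw sites and
    # residues directly, de-duplicate.
    out: list[Variant] = []
    seen: set[str] = set()
    while len(out) < n:
        sites = np.sort(rng.choice(landscape.length, size=degree, replace=False))
        subs = []
        for site in sites:
            wt_aa = landscape.wildtype[site]
            choices = [aa for aa in AA20 if aa != wt_aa]
            subs.append(Substitution(wt_aa, int(site) + 1, choices[int(rng.integers(19))]))
        cand = Variant(tuple(subs))
        if str(cand) not in seen:
            seen.add(str(cand))
            out.append(cand)
    return out


def assay(
    landscape: LandscapeModel, variants: Sequence[Variant], seed: int = 0
) -> AssayDataset:
    """Measure variants: true fitness plus i.i.d. Gaussian assay noise."""
    truth = landscape.true_fitness_many(variants)
    rng = np.random.default_rng(seed)
    labels = truth + landscape.assay_noise_sd * rng.standard_normal(len(variants))
    return AssayDataset(list(variants), labels)


@dataclass(frozen=True)
class CampaignConfig:
    """Iterative acquisition campaign settings.

    Each batch after round 0 draws a ``greedy_fraction`` share by adding one
    substitution to current top performers and the remainder uniformly at
    random at the current frontier degree.
    """

    n_rounds: int = 10
    batch_size: int = 20
    greedy_fraction: float = 0.9
    max_degree: int = 12

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.batch_size < 1 or self.max_degree < 1:
            raise ValueError("n_rounds, batch_size and max_degree must be >= 1")
        if not 0.0 <= self.greedy_fraction <= 1.0:
            raise ValueError("greedy_fraction must lie in [0, 1]")


def _add_random_substitution(
    rng: np.random.Generator, landscape: LandscapeModel, parent: Variant
) -> Variant | None:
    """Parent plus one substitution at a previously unmutated site."""
    free = [p for p in range(1, landscape.length + 1) if p not in parent.positions]
    if not free:
        return None
    pos = int(rng.choice(free))
    wt_aa = landscape.wildtype[pos - 1]
    sub = Substitution(wt_aa, pos, _random_non_wt(rng, wt_aa))
    subs = tuple(sorted(parent.substitutions + (sub,), key=lambda s: s.position))
    return Variant(subs)


def _swap_random_residue(
    rng: np.random.Generator, landscape: LandscapeModel, parent: Variant
) -> Variant | None:
    """Change the residue at one already-mutated site (degree preserved)."""
    if parent.degree == 0:
        return None
    i = int(rng.integers(parent.degree))
    old = parent.substitutions[i]
    choices = [aa for aa in AA20 if aa not in (old.wt_aa, old.mut_aa)]
    new = Substitution(old.wt_aa, old.position, str(rng.choice(choices)))
    subs = list(parent.substitutions)
    subs[i] = new
    return Variant(tuple(subs))


def simulate_campaign(
    landscape: LandscapeModel, config: CampaignConfig, seed: int = 0
) -> AssayDataset:
    """Simulate an iterative engineering campaign with greedy selection bias.

    Round 0 assays random single mutants.  In round r >= 1 each batch slot is,
    with probability ``greedy_fraction``, one extra substitution added to a
    parent drawn from the current top 10% of observed labels (a residue swap at
    an already-mutated site once the parent is at ``max_degree``); otherwise a
    random variant of the current frontier degree (round + 1, capped at
    ``max_degree``).  Variants are never re-measured within a campaign.
    """
    rng = np.random.default_rng(seed)
    variants: list[Variant] = []
    labels: list[float] = []
    rounds: list[int] = []
    seen: set[str] = set()

    def reveal(v: Variant, rnd: int) -> None:
        y = landscape.true_fitness(v) + landscape.assay_noise_sd * rng.standard_normal()
        variants.append(v)
        labels.append(float(y))
        rounds.append(rnd)
        seen.add(str(v))

    # Round 0: uniform single mutants.
    singles = enumerate_single_mutants(landscape)
    order = rng.permutation(len(singles))
    for i in order[: config.batch_size]:
        reveal(singles[i], 0)

    for rnd in range(1, config.n_rounds):
        frontier_degree = min(rnd + 1, config.max_degree)
        batch: list[Variant] = []
        attempts = 0
        while len(batch) < config.batch_size and attempts < 200 * config.batch_size:
            attempts += 1
            if rng.random() < config.greedy_fraction:
                n_top = max(1, math.ceil(0.1 * len(labels)))
                top_idx = np.argsort(labels)[::-1][:n_top]
                parent = variants[int(rng.choice(top_idx))]
                if parent.degree >= config.max_degree:
                    # At the degree cap, explore sideways: swap a residue at an
                    # already-mutated site instead of adding a substitution.
                    cand = _swap_random_residue(rng, landscape, parent)
                else:
                    cand = _add_random_substitution(rng, landscape, parent)
            else:
                cand = sample_variants(landscape, frontier_degree, 1,
                                       seed=int(rng.integers(2**31)))[0]
            if cand is None or str(cand) in seen or any(str(cand) == str(b) for b in batch):
                continue
            batch.append(cand)
        for v in batch:
            reveal(v, rnd)

    return AssayDataset(variants, np.array(labels), np.array(rounds))


def surrogate_embedding(
    variants: Sequence[Variant],
    wildtype: str,
    d: int,
    nonlinearity: str = "none",
    seed: int = 0,
):
    """Dense surrogate embeddings: a fixed random projection of one-hot rows.

    Stands in for mean-pooled protein-language-model representations: a
    deterministic sequence→vector map of controllable dimension and
    (non)linearity, not a trained model.  With ``nonlinearity="none"`` the map
    is linear in the one-hot encoding, so substitution effects compose
    additively in embedding space.
    """
    from .encodings import one_hot_encode  # local import avoids cycle at import time

    if d < 1:
        raise ValueError("d must be >= 1")
    if nonlinearity not in ("none", "tanh"):
        raise ValueError("nonlinearity must be 'none' or 'tanh'")
    onehot = one_hot_encode(variants, wildtype)
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((onehot.values.shape[1], d)) / math.sqrt(len(wildtype))
    values = onehot.values @ W
    if nonlinearity == "tanh":
        values = np.tanh(values)
    from .encodings import RepresentationMatrix

    return RepresentationMatrix(values=values, row_ids=np.arange(len(variants)),
                                source="surrogate")
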