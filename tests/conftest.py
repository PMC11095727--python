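import numpy as np
import pytest

from fitbench.synthetic_data import LandscapeModel, build_landscape
from fitbench.variants import Substitution, Variant


@pytest.fixture
def tiny_landscape() -> LandscapeModel:
    """Hand-built landscape with known effects for oracle checks.

    Wildtype ``ACDEFGHIK`` (L=9); one epistatic pair ((3,K),(7,R)) = 0.5.
    """
    wildtype = "ACDEFGHIK"
    additive = {
        (1, "G"): 0.2, (3, "K"): -0.4, (5, "A"): 0.1,
        (7, "R"): 0.3, (9, "P"): -1.0,
    }
    pairwise = {((3, "K"), (7, "R")): 0.5}
    return LandscapeModel(wildtype=wildtype, additive_effects=additive,
                          pairwise_effects=pairwise)


@pytest.fixture
def random_landscape() -> LandscapeModel:
    return build_landscape(L=12, effect_scale=0.5, assay_noise_sd=0.0, seed=3)


def make_variant(wildtype: str, *subs: tuple[int, str]) -> Variant:
    """Variant from (position, mutant_aa) pairs against a wildtype."""
    ss = tuple(
        Substitution(wildtype[pos - 1], pos, aa)
        for pos, aa in sorted(subs)
    )
    return Variant(ss)


@pytest.fixture
def mkvar():
    return make_variant
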