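import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from moyastrat import AnnotatedVariant


def brute_force_mw_p(x, y) -> float:
    """Two-tailed Mann-Whitney p by full enumeration of label assignments.

    Independent oracle: enumerates every way of assigning |x| of the pooled
    values to the first group and compares midrank sums.
    """
    pooled = list(x) + list(y)
    n = len(x)
    ranks = rankdata(pooled)
    w_obs = ranks[:n].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n)]
    lower = sum(1 for s in sums if s <= w_obs + 1e-9) / len(sums)
    upper = sum(1 for s in sums if s >= w_obs - 1e-9) / len(sums)
    return min(1.0, 2.0 * min(lower, upper))


@pytest.fixture
def small_variants():
    return [
        AnnotatedVariant(variant_id="v1", gene="RNF213", cadd=28.0, vipur=0.8,
                         global_maf=0.0043, inheritance="maternal",
                         carrier_ids=("p1", "p2")),
        AnnotatedVariant(variant_id="v2", gene="RNF213", cadd=12.8, vipur=None,
                         inheritance="de_novo", carrier_ids=("p3",)),
        AnnotatedVariant(variant_id="v3", gene="BRCA1", cadd=24.0, vipur=0.46,
                         global_maf=0.025, inheritance="not_established"),
        AnnotatedVariant(variant_id="v4", gene="NF1", cadd=30.0, vipur=0.9,
                         global_maf=None, inheritance="paternal"),
        AnnotatedVariant(variant_id="v5", gene="acta2", cadd=5.0, vipur=0.1,
                         global_maf=0.001, inheritance="not_established"),
    ]


@pytest.fixture
def separated_scores():
    """Two well-separated clusters with known generating parameters."""
    rng = np.random.default_rng(42)
    low = rng.normal(10.0, 1.0, 100)
    high = rng.normal(30.0, 2.0, 100)
    return np.concatenate([low, high]), (10.0, 30.0)
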