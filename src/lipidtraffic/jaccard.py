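"""Jaccard-Tanimoto similarity of variable lists with permutation p-values.

J = |A ∩ B| / |A ∪ B| measures how similar two groups' variable lists are
(1 = identical, 0 = disjoint).  The accompanying p-value estimates the
probability that the observed (dis)similarity would arise if both lists
were random draws from the shared variable universe: both memberships are
resampled uniformly over the universe, preserving list sizes, and the
observed J is located in the null J distribution, two-sided.

Because J takes few distinct values at small list sizes, the default
p-value uses the smoothed Monte-Carlo CDF position (random tie placement),
which is exactly Uniform(0, 1) under the null and therefore calibrated;
``tie_break="conservative"`` gives the classic add-one permutation p
instead.  Both are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np

__all__ = ["JaccardResult", "jaccard_test", "jaccard_coefficient"]


@dataclass(frozen=True)
class JaccardResult:
    j: float
    p: float
    n_common: int
    n_only_a: int
    n_only_b: int
    n_perm: int
    seed: int

    @property
    def n_union(self) -> int:
        return self.n_common + self.n_only_a + self.n_only_b


def jaccard_coefficient(set_a: Collection, set_b: Collection) -> float:
    """Plain J = |A ∩ B| / |A ∪ B|; undefined (raises) when both sets are empty."""
    sa, sb = set(set_a), set(set_b)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard coefficient undefined: both sets are empty")
    return len(sa & sb) / len(union)


def _null_j(rng: np.random.Generator, n_universe: int, ka: int, kb: int, n_perm: int) -> np.ndarray:
    """Null J for random size-ka and size-kb subsets of an n_universe universe."""
    # rank-threshold trick: mark the ka smallest of a random row as members
    ra = rng.random((n_perm, n_universe))
    rb = rng.random((n_perm, n_universe))
    ta = np.partition(ra, ka - 1, axis=1)[:, ka - 1 : ka]
    tb = np.partition(rb, kb - 1, axis=1)[:, kb - 1 : kb]
    ma = ra <= ta
    mb = rb <= tb
    inter = (ma & mb).sum(axis=1)
    union = (ma | mb).sum(axis=1)
    return inter / union


def jaccard_test(
    set_a: Collection,
    set_b: Collection,
    universe: Collection,
    n_perm: int = 10_000,
    seed: int = 0,
    tie_break: str = "smoothed",
) -> JaccardResult:
    """Jaccard-Tanimoto J between two variable lists plus a permutation p-value.

    ``universe`` must contain both lists (the variables that could have
    appeared in either).  ``n_perm`` >= 1000 is recommended for stable
    p-values.  Deterministic for a given ``seed``.
    """
    sa, sb = set(set_a), set(set_b)
    uni = set(universe)
    stray = (sa | sb) - uni
    if stray:
        raise ValueError(f"universe does not contain {sorted(stray)[:5]}")
    if not sa and not sb:
        raise ValueError("Jaccard test undefined: both sets are empty")
    if tie_break not in ("smoothed", "conservative"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    j_obs = jaccard_coefficient(sa, sb)
    rng = np.random.default_rng(seed)
    j_null = _null_j(rng, len(uni), max(len(sa), 1), max(len(sb), 1), n_perm)

    if tie_break == "smoothed":
        less = int((j_null < j_obs).sum())
        equal = int((j_null == j_obs).sum())
        u = (less + rng.random() * (equal + 1)) / (n_perm + 1)
        p = min(1.0, 2.0 * min(u, 1.0 - u))
    else:
        p_lo = ((j_null <= j_obs).sum() + 1) / (n_perm + 1)
        p_hi = ((j_null >= j_obs).sum() + 1) / (n_perm + 1)
        p = min(1.0, 2.0 * min(p_lo, p_hi))

    return JaccardResult(
        j=j_obs,
        p=float(p),
        n_common=len(sa & sb),
        n_only_a=len(sa - sb),
        n_only_b=len(sb - sa),
        n_perm=n_perm,
        seed=seed,
    )
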