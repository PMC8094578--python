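"""Feature-selection stability via the Kuncheva consistency index.

Given omega equal-size feature subsets produced by repeated runs of a
selection algorithm on resampled data, the index averages the chance-corrected
pairwise overlap

    (|S_i intersect S_j| * p - p'^2) / (p' * (p - p'))

over all pairs, where p is the total number of features and p' the common
subset size.  It ranges from -1 (systematic disagreement) to 1 (identical
selections), with expectation 0 for random subsets.  By convention the index
is 0 when p' = p (the formula is 0/0 there and every run trivially selects
everything).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .exceptions import ValidationError

__all__ = ["SubsetCollection", "kuncheva_index", "stability_profile"]


@dataclass(frozen=True)
class SubsetCollection:
    """omega feature subsets of identical size drawn from p features."""

    subsets: list
    p: int

    def __post_init__(self):
        object.__setattr__(self, "subsets", [frozenset(s) for s in self.subsets])


def kuncheva_index(subsets, p: int | None = None) -> float:
    """Kuncheva consistency index of a collection of equal-size subsets.

    Parameters
    ----------
    subsets : SubsetCollection or sequence of feature-name sets
    p : int
        Total number of features (taken from the collection if given one).
    """
    if isinstance(subsets, SubsetCollection):
        p = subsets.p
        sets = subsets.subsets
    else:
        if p is None:
            raise ValidationError("p (total feature count) is required")
        sets = [frozenset(s) for s in subsets]
    omega = len(sets)
    if omega < 2:
        raise ValidationError("need at least 2 subsets")
    sizes = {len(s) for s in sets}
    if len(sizes) != 1:
        raise ValidationError(f"subsets have unequal sizes: {sorted(sizes)}")
    p_prime = sizes.pop()
    if p_prime < 1:
        raise ValidationError("subset size must be >= 1")
    if p_prime > p:
        raise ValidationError(f"subset size {p_prime} exceeds total features {p}")
    if p_prime == p:
        return 0.0  # convention: the index is null when everything is selected
    total = 0.0
    for s_i, s_j in combinations(sets, 2):
        total += (len(s_i & s_j) * p - p_prime ** 2) / (p_prime * (p - p_prime))
    return 2.0 * total / (omega * (omega - 1))


def stability_profile(rankings, cut_sizes) -> dict:
    """Kuncheva index of the top-p' sets of replicate rankings, per cut size.

    ``rankings`` are total orders over the same p features (e.g. the output
    of ``ImportanceRanking.replicate_rankings``).
    """
    rankings = [list(r) for r in rankings]
    if len(rankings) < 2:
        raise ValidationError("need at least 2 rankings")
    universe = set(rankings[0])
    p = len(universe)
    for r in rankings:
        if len(r) != p or set(r) != universe:
            raise ValidationError("rankings must be total orders over the same features")
    out = {}
    for p_prime in cut_sizes:
        if not 1 <= p_prime <= p:
            raise ValidationError(f"cut size {p_prime} out of range 1..{p}")
        out[int(p_prime)] = kuncheva_index([set(r[:p_prime]) for r in rankings], p)
    return out
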