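"""Permutation null for expected cross-biome transition counts.

Biome labels are shuffled across the tips of the pruned tree (preserving
the per-biome tip counts), MSG pairs are re-identified on the fixed
topology, and the per-type counts across iterations give expected numbers
and one-sided empirical probabilities.  A chi-squared goodness-of-fit then
compares the observed type composition against the expected fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chisquare

from .core import LabeledTree, derive_seed

TYPES = ("FB", "BM", "FM")
_STATE = {"freshwater": 1, "brackish": 2, "marine": 4}
_TYPE_OF_MASK = {1 | 2: "FB", 2 | 4: "BM", 1 | 4: "FM"}


@dataclass
class PermutationNullResult:
    n_iter: int
    observed: dict[str, int]
    expected: dict[str, int]
    expected_raw: dict[str, float]
    p_low: dict[str, float]
    p_high: dict[str, float]
    per_iteration_counts: np.ndarray          # n_iter x 3, column order TYPES
    zero_p_flags: list[str] = field(default_factory=list)


def _tree_arrays(tree: LabeledTree):
    """Postorder topology as index arrays for fast repeated label sweeps."""
    nodes = list(tree.tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    tip_idx, tip_labels = [], []
    children: list[tuple[int, int] | None] = []
    for nd in nodes:
        kids = nd.child_nodes()
        if not kids:
            tip_idx.append(index[id(nd)])
            tip_labels.append(nd.taxon.label)
            children.append(None)
        else:
            if len(kids) != 2:
                raise ValueError("permutation null requires a bifurcating tree")
            children.append((index[id(kids[0])], index[id(kids[1])]))
    return tip_idx, tip_labels, children


def count_transition_types(
    tip_idx, children, tip_states: np.ndarray
) -> dict[str, int]:
    """Count MSG pairs by type from biome bitmasks in one postorder sweep."""
    n = len(children)
    masks = np.zeros(n, dtype=np.int64)
    masks[tip_idx] = tip_states
    counts = {t: 0 for t in TYPES}
    for i, kids in enumerate(children):
        if kids is None:
            continue
        a, b = masks[kids[0]], masks[kids[1]]
        masks[i] = a | b
        if a != b and (a & (a - 1)) == 0 and (b & (b - 1)) == 0:
            counts[_TYPE_OF_MASK[a | b]] += 1
    return counts


def permute_expected_counts(
    tree: LabeledTree,
    biome_of: dict[str, str],
    n_iter: int = 100,
    seed: int = 0,
) -> PermutationNullResult:
    """Expected per-type transition counts under random tip-label shuffles.

    ``expected`` is the rounded mean count per type; the one-sided
    probabilities count iterations strictly below (p_low) or strictly above
    (p_high) the observed count, divided by ``n_iter`` — ties count toward
    neither side, so p_low + p_high can fall below 1.  An empirical p of 0
    means "< 1/n_iter" and is flagged.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    tip_idx, tip_labels, children = _tree_arrays(tree)
    base_states = np.array([_STATE[biome_of[t]] for t in tip_labels], dtype=np.int64)
    observed = count_transition_types(tip_idx, children, base_states)
    per_iter = np.zeros((n_iter, len(TYPES)), dtype=np.int64)
    for it in range(n_iter):
        rng = np.random.default_rng(derive_seed(seed, it))
        perm = rng.permutation(len(base_states))
        counts = count_transition_types(tip_idx, children, base_states[perm])
        per_iter[it] = [counts[t] for t in TYPES]
    expected_raw = {t: float(per_iter[:, j].mean()) for j, t in enumerate(TYPES)}
    expected = {t: int(np.floor(v + 0.5)) for t, v in expected_raw.items()}
    p_low, p_high, flags = {}, {}, []
    for j, t in enumerate(TYPES):
        p_low[t] = float((per_iter[:, j] < observed[t]).sum()) / n_iter
        p_high[t] = float((per_iter[:, j] > observed[t]).sum()) / n_iter
        for side, p in (("low", p_low[t]), ("high", p_high[t])):
            if p == 0.0:
                flags.append(f"{t}:{side}")
    return PermutationNullResult(
        n_iter=n_iter,
        observed=observed,
        expected=expected,
        expected_raw=expected_raw,
        p_low=p_low,
        p_high=p_high,
        per_iteration_counts=per_iter,
        zero_p_flags=flags,
    )


def chisq_type_fractions(
    observed: dict[str, int], expected_raw: dict[str, float]
) -> tuple[float, float]:
    """Goodness-of-fit of observed type counts to the expected fractions.

    The expected fractions (expected_raw normalized to 1) act as category
    probabilities for the observed total; df = number of types - 1.  No
    continuity correction.  A zero expected fraction with nonzero observed
    count yields an infinite statistic (p = 0).
    """
    obs = np.array([observed[t] for t in TYPES], dtype=float)
    exp = np.array([expected_raw[t] for t in TYPES], dtype=float)
    total_exp = exp.sum()
    if total_exp <= 0:
        raise ValueError("sum of expected counts must be positive")
    probs = exp / total_exp
    f_exp = probs * obs.sum()
    if np.any((f_exp == 0) & (obs > 0)):
        return float("inf"), 0.0
    keep = f_exp > 0
    stat, p = chisquare(obs[keep], f_exp=f_exp[keep], ddof=keep.sum() - 3)
    return float(stat), float(p)
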