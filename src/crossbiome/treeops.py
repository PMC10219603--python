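"""Tree preparation and detection of monobiomic sister groups (MSGs).

An MSG pair marks a most-recent cross-biome transition: an internal node
whose two child clades are each monobiomic (all tips from one biome) for
two *different* biomes.  The tree is first made strictly bifurcating
(seeded random polytomy resolution, zero-length branches replaced by a
small epsilon) and pruned to one representative per species cluster — or
one per biome within clusters spanning biomes — chosen as the genome with
the highest completeness minus contamination.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import dendropy

from .clustering import GenomeCluster
from .core import BIOMES, GenomeRecord, LabeledTree, TAXONOMY_RANKS

#: Replacement for zero-length branches, following the smallest observed
#: branch length in the source phylogeny.
ZERO_BRANCH_EPSILON = 5e-4

_BIOME_LETTER = {"freshwater": "F", "brackish": "B", "marine": "M"}
_PAIR_TYPE = {
    frozenset(("freshwater", "brackish")): "FB",
    frozenset(("brackish", "marine")): "BM",
    frozenset(("freshwater", "marine")): "FM",
}
#: For each type, (less saline, more saline) biome in salinity order.
TYPE_BIOMES = {
    "FB": ("freshwater", "brackish"),
    "BM": ("brackish", "marine"),
    "FM": ("freshwater", "marine"),
}


@dataclass
class MSG:
    """A maximal monobiomic clade participating in an MSG pair."""

    tips: frozenset[str]
    biome: str
    node: dendropy.Node


@dataclass
class MSGPair:
    pair_id: str
    msg_a: MSG
    msg_b: MSG
    type: str                      # FB / BM / FM
    mrca_node: dendropy.Node
    mrca_age: Optional[float] = None
    shared_taxon_rank: Optional[str] = None
    shared_taxon_name: Optional[str] = None

    def msg_for_biome(self, biome: str) -> MSG:
        if self.msg_a.biome == biome:
            return self.msg_a
        if self.msg_b.biome == biome:
            return self.msg_b
        raise KeyError(f"pair {self.pair_id} has no MSG from biome {biome}")


@dataclass
class NoTransitionPair:
    """The oldest within-MSG split — a same-biome divergence of similar age."""

    parent_msg: MSG
    group_a: frozenset[str]
    group_b: frozenset[str]
    divergence_age: Optional[float] = None


def resolve_polytomies(
    tree: LabeledTree, epsilon: float = ZERO_BRANCH_EPSILON, seed: int = 0
) -> LabeledTree:
    """Return a strictly bifurcating copy with all branch lengths > 0.

    Polytomies are resolved in seeded random order (the resolution near a
    polytomy can affect which sister pairs form, so the seed is part of the
    analysis provenance); zero-length and missing branch lengths — including
    the zero-length branches the resolution introduces — become ``epsilon``.
    """
    out = tree.clone()
    rng = random.Random(seed)
    out.tree.resolve_polytomies(limit=2, update_bipartitions=False, rng=rng)
    for edge in out.tree.preorder_edge_iter():
        if edge.head_node is out.tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0.0:
            edge.length = epsilon
    return out


def choose_representatives(
    clusters: Sequence[GenomeCluster], records: Sequence[GenomeRecord]
) -> list[str]:
    """Pick one genome per cluster — or per biome within multi-biome clusters.

    The representative maximizes completeness - contamination; ties break to
    the lexicographically smallest genome id.
    """
    meta = {r.genome_id: r for r in records}
    reps: list[str] = []
    for cl in clusters:
        by_biome: dict[str, list[GenomeRecord]] = {}
        for g in sorted(cl.members):
            if g in meta:
                by_biome.setdefault(meta[g].biome, []).append(meta[g])
        for biome in sorted(by_biome):
            cands = by_biome[biome]
            top = max(r.quality_score for r in cands)
            best = min((r for r in cands if r.quality_score == top),
                       key=lambda r: r.genome_id)
            reps.append(best.genome_id)
    return reps


def prune_representatives(
    tree: LabeledTree,
    clusters: Sequence[GenomeCluster],
    records: Sequence[GenomeRecord],
) -> LabeledTree:
    """Prune the tree down to cluster representatives.

    Degree-2 nodes left by pruning are suppressed with branch lengths
    summed.  Clusters with no tips on the tree are skipped with a warning.
    """
    import warnings as _w

    tips = set(tree.tip_labels())
    keep: list[str] = []
    for cl in clusters:
        on_tree = [GenomeCluster(cl.cluster_id, frozenset(m for m in cl.members if m in tips))]
        if not on_tree[0].members:
            _w.warn(f"cluster {cl.cluster_id} has no tips on the tree; skipped")
            continue
        keep.extend(choose_representatives(on_tree, records))
    keep_set = set(keep)
    out = tree.clone()
    out.tree.retain_taxa_with_labels(sorted(keep_set))
    return out


def find_msg_pairs(
    tree: LabeledTree, biome_of: Callable[[str], str] | dict[str, str]
) -> list[MSGPair]:
    """Find all MSG pairs: nodes whose two child clades are monobiomic for
    two different biomes.

    Qualifying nodes are necessarily disjoint in their child clades (inside
    a monobiomic clade no deeper node can pair two different biomes), so a
    single postorder sweep enumerates every most-recent transition exactly
    once.  Pair ids are assigned in order of the smallest tip label.
    """
    lookup = biome_of if callable(biome_of) else biome_of.__getitem__
    biomes_below: dict[dendropy.Node, frozenset[str]] = {}
    tips_below: dict[dendropy.Node, frozenset[str]] = {}
    raw: list[tuple[MSG, MSG, dendropy.Node]] = []
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            biomes_below[nd] = frozenset([lookup(label)])
            tips_below[nd] = frozenset([label])
            continue
        kids = nd.child_nodes()
        biomes_below[nd] = frozenset().union(*(biomes_below[k] for k in kids))
        tips_below[nd] = frozenset().union(*(tips_below[k] for k in kids))
        if len(kids) != 2:
            continue
        ba, bb = biomes_below[kids[0]], biomes_below[kids[1]]
        if len(ba) == 1 and len(bb) == 1 and ba != bb:
            msg_a = MSG(tips=tips_below[kids[0]], biome=next(iter(ba)), node=kids[0])
            msg_b = MSG(tips=tips_below[kids[1]], biome=next(iter(bb)), node=kids[1])
            raw.append((msg_a, msg_b, nd))
    raw.sort(key=lambda t: min(t[0].tips | t[1].tips))
    pairs = []
    for i, (msg_a, msg_b, nd) in enumerate(raw, start=1):
        pairs.append(
            MSGPair(
                pair_id=f"MSG{i:04d}",
                msg_a=msg_a,
                msg_b=msg_b,
                type=_PAIR_TYPE[frozenset((msg_a.biome, msg_b.biome))],
                mrca_node=nd,
                mrca_age=tree.node_age(nd),
            )
        )
    return pairs


def classify_transition(pair: MSGPair) -> str:
    """Unordered biome-pair label of an MSG pair (FB, BM or FM)."""
    if pair.msg_a.biome == pair.msg_b.biome:
        raise ValueError(f"pair {pair.pair_id}: both MSGs from {pair.msg_a.biome}")
    return _PAIR_TYPE[frozenset((pair.msg_a.biome, pair.msg_b.biome))]


def lowest_shared_taxon(
    pair: MSGPair, records: Sequence[GenomeRecord]
) -> tuple[str, str]:
    """Deepest rank at which all members of both MSGs share one non-empty name.

    Ranks where any member lacks annotation are skipped upward; if nothing
    is shared even at domain level, returns ("none", "").
    """
    meta = {r.genome_id: r for r in records}
    tips = sorted(pair.msg_a.tips | pair.msg_b.tips)
    for rank in reversed(TAXONOMY_RANKS):
        names = {meta[t].taxonomy.get(rank, "") for t in tips}
        if "" in names or len(names) != 1:
            continue
        return rank, next(iter(names))
    return "none", ""


def annotate_shared_taxa(
    pairs: Sequence[MSGPair], records: Sequence[GenomeRecord]
) -> None:
    for p in pairs:
        p.shared_taxon_rank, p.shared_taxon_name = lowest_shared_taxon(p, records)


def no_transition_pairs(
    msgs: Sequence[MSG], tree: LabeledTree
) -> list[NoTransitionPair]:
    """Oldest same-biome split within each MSG of more than one tip.

    Within a clade the first (root) split is the oldest divergence, so the
    pair is formed by the two child clades of the MSG's own node.
    """
    out = []
    for msg in msgs:
        if len(msg.tips) < 2:
            continue
        kids = msg.node.child_nodes()
        tips_a = frozenset(lf.taxon.label for lf in kids[0].leaf_iter())
        tips_b = frozenset(lf.taxon.label for lf in kids[1].leaf_iter())
        out.append(
            NoTransitionPair(
                parent_msg=msg,
                group_a=tips_a,
                group_b=tips_b,
                divergence_age=tree.node_age(msg.node),
            )
        )
    return out


def summarize_transitions(
    pairs: Sequence[MSGPair], taxon_rank: str = "phylum",
    records: Optional[Sequence[GenomeRecord]] = None,
) -> dict:
    """Contingency summaries of MSG pairs: by type, shared rank, and taxon."""
    by_type = {"FB": 0, "BM": 0, "FM": 0}
    by_rank: dict[str, int] = {}
    by_taxon: dict[str, int] = {}
    meta = {r.genome_id: r for r in records} if records else {}
    for p in pairs:
        by_type[p.type] += 1
        if p.shared_taxon_rank is not None:
            by_rank[p.shared_taxon_rank] = by_rank.get(p.shared_taxon_rank, 0) + 1
        if meta:
            names = {meta[t].taxonomy.get(taxon_rank, "")
                     for t in (p.msg_a.tips | p.msg_b.tips) if t in meta}
            names.discard("")
            label = next(iter(names)) if len(names) == 1 else "mixed"
            by_taxon[label] = by_taxon.get(label, 0) + 1
    return {"by_type": by_type, "by_rank": by_rank, "by_taxon": by_taxon}
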