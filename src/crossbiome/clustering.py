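"""ANI-based species clustering and biome/basin cluster-overlap statistics.

Genomes are grouped into ~species by agglomerative clustering on the
distance d = 100 - ANI, cutting the dendrogram at 100 - threshold (default
threshold 95%, the operational bacterial species boundary).  Cluster
overlap between biomes (or between brackish basins) is summarized as
shared / mean(total_A, total_B) and compared with Fisher's exact test
conditioned on the smaller category.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import fisher_exact

from .core import ANITable, BIOMES, GenomeRecord

#: Distance assigned to genome pairs with no reported ANI (below the
#: aligner's reporting range); guarantees they never merge.
MISSING_DISTANCE = 100.0


@dataclass
class GenomeCluster:
    cluster_id: int
    members: frozenset[str]
    biomes: frozenset[str] = frozenset()
    basins: frozenset[str] = frozenset()


def cluster_genomes(
    ani: ANITable,
    genomes: Sequence[str],
    threshold: float = 95.0,
    linkage: str = "complete",
    records: Optional[Sequence[GenomeRecord]] = None,
) -> list[GenomeCluster]:
    """Partition genomes into ANI clusters at the given identity threshold.

    Parameters
    ----------
    ani
        Pairwise ANI lookup; missing pairs are treated as maximally distant.
    genomes
        Genome ids to cluster (need not equal the ANI table's universe).
    threshold
        ANI percent cut; two clusters merge only while the linkage distance
        stays at or below ``100 - threshold``.
    linkage
        'complete' (default, hclust's default), 'single' or 'average'.
    records
        Optional metadata used to annotate clusters with biomes/basins.
    """
    if not genomes:
        raise ValueError("no genomes to cluster")
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must be in (0, 100)")
    if linkage not in ("complete", "single", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    genomes = list(genomes)
    n = len(genomes)
    if n == 1:
        assignments = np.array([1])
    else:
        dmat = np.full((n, n), MISSING_DISTANCE)
        np.fill_diagonal(dmat, 0.0)
        for i, j in itertools.combinations(range(n), 2):
            v = ani.get(genomes[i], genomes[j])
            if v is not None:
                dmat[i, j] = dmat[j, i] = max(0.0, 100.0 - v)
        z = sch.linkage(ssd.squareform(dmat, checks=False), method=linkage)
        assignments = sch.fcluster(z, t=100.0 - threshold, criterion="distance")
    by_label: dict[int, set[str]] = {}
    for g, lab in zip(genomes, assignments):
        by_label.setdefault(int(lab), set()).add(g)
    meta = {r.genome_id: r for r in records} if records else {}
    clusters = []
    # stable ids: sort clusters by their smallest member id
    for cid, members in enumerate(
        sorted(by_label.values(), key=lambda m: min(m)), start=1
    ):
        recs = [meta[g] for g in members if g in meta]
        clusters.append(
            GenomeCluster(
                cluster_id=cid,
                members=frozenset(members),
                biomes=frozenset(r.biome for r in recs),
                basins=frozenset(r.basin for r in recs if r.basin),
            )
        )
    return clusters


@dataclass
class OverlapSummary:
    """Counts and overlap fractions of clusters by biome combination."""

    n_clusters: int
    single_biome_counts: dict[str, int]
    shared_counts: dict[str, int]          # "FB", "BM", "FM", "FBM"
    biome_totals: dict[str, int]           # clusters containing each biome
    overlap_fraction: dict[str, float]     # per unordered biome pair
    basin_totals: dict[str, int] = field(default_factory=dict)
    basin_shared: dict[str, int] = field(default_factory=dict)
    basin_overlap_fraction: dict[str, float] = field(default_factory=dict)


_PAIR_CODE = {
    frozenset(("freshwater", "brackish")): "FB",
    frozenset(("brackish", "marine")): "BM",
    frozenset(("freshwater", "marine")): "FM",
}
_BIOME_LETTER = {"freshwater": "F", "brackish": "B", "marine": "M"}


def overlap_fraction(shared: int, total_a: int, total_b: int) -> float:
    """Shared clusters relative to the mean of the two biome totals."""
    denom = (total_a + total_b) / 2.0
    return shared / denom if denom else 0.0


def summarize_biome_overlap(
    clusters: Sequence[GenomeCluster],
    records: Optional[Sequence[GenomeRecord]] = None,
    basin_biome: str = "brackish",
) -> OverlapSummary:
    """Tabulate clusters by biome combination and compute overlap fractions.

    ``biome_totals[x]`` counts every cluster containing biome x (shared
    clusters count toward both of their biomes).  Basin overlap is computed
    within ``basin_biome`` (brackish by default) across all basin pairs.
    """
    meta = {r.genome_id: r for r in records} if records else {}
    single = {b: 0 for b in BIOMES}
    shared: dict[str, int] = {"FB": 0, "BM": 0, "FM": 0, "FBM": 0}
    totals = {b: 0 for b in BIOMES}
    basin_clusters: dict[str, set[int]] = {}
    for cl in clusters:
        biomes = set(cl.biomes)
        basins = set(cl.basins)
        if meta:
            for g in cl.members:
                if g in meta:
                    biomes.add(meta[g].biome)
                    if meta[g].basin:
                        basins.add(meta[g].basin)
        if not biomes:
            continue
        for b in biomes:
            totals[b] += 1
        if len(biomes) == 1:
            single[next(iter(biomes))] += 1
        elif len(biomes) == 2:
            shared[_PAIR_CODE[frozenset(biomes)]] += 1
        else:
            shared["FBM"] += 1
        if basin_biome in biomes:
            for basin in basins:
                basin_clusters.setdefault(basin, set()).add(cl.cluster_id)
    frac = {}
    for pair, code in _PAIR_CODE.items():
        a, b = sorted(pair)
        frac[code] = overlap_fraction(shared[code], totals[a], totals[b])
    basin_totals = {k: len(v) for k, v in basin_clusters.items()}
    basin_shared = {}
    basin_frac = {}
    for x, y in itertools.combinations(sorted(basin_clusters), 2):
        n_sh = len(basin_clusters[x] & basin_clusters[y])
        key = f"{x}|{y}"
        basin_shared[key] = n_sh
        basin_frac[key] = overlap_fraction(n_sh, basin_totals[x], basin_totals[y])
    return OverlapSummary(
        n_clusters=len(clusters),
        single_biome_counts=single,
        shared_counts=shared,
        biome_totals=totals,
        overlap_fraction=frac,
        basin_totals=basin_totals,
        basin_shared=basin_shared,
        basin_overlap_fraction=basin_frac,
    )


def overlap_fisher_test(
    shared_1: int, total_smaller_1: int, shared_2: int, total_smaller_2: int
) -> float:
    """Two-sided Fisher exact p comparing two sharing proportions.

    Each comparison is conditioned on the side with fewer clusters: the 2x2
    table is [[shared_1, total_smaller_1 - shared_1],
              [shared_2, total_smaller_2 - shared_2]].
    """
    a, b = shared_1, total_smaller_1 - shared_1
    c, d = shared_2, total_smaller_2 - shared_2
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in Fisher table (shared > total?)")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
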