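"""Shared domain types for the cross-biome transition pipeline.

The pipeline operates on metagenome-assembled genomes (MAGs) classified
into one of three aquatic biomes — freshwater, brackish or marine — and
asks how lineages have moved between those biomes over evolutionary time.
The types here carry the per-genome quality/taxonomy metadata, the
pairwise average-nucleotide-identity (ANI) relation used for species
clustering, the biome-labeled phylogeny, and the binary gene-function
(KEGG Orthology, "KO") matrix used for gene gain/loss analyses.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

BIOMES = ("freshwater", "brackish", "marine")
#: Salinity rank used to orient "more saline minus less saline" contrasts.
SALINITY_ORDER = {"freshwater": 0, "brackish": 1, "marine": 2}

#: GTDB-style ranks, shallowest to deepest.
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: QC thresholds: genomes below 75% completeness or above 5% contamination
#: are excluded from all analyses.
MIN_COMPLETENESS = 75.0
MAX_CONTAMINATION = 5.0


class FormatError(ValueError):
    """A malformed input file (missing column, bad value, bad range)."""


class ReconciliationError(ValueError):
    """Cross-references between inputs do not resolve (e.g. orphan tree tips)."""


def parse_taxonomy(tax_string: str) -> dict[str, str]:
    """Parse a GTDB-style ``d__...;p__...;...;s__...`` string into a rank map.

    Missing trailing ranks and empty names are allowed; names keep their
    content after the rank prefix.
    """
    out = {r: "" for r in TAXONOMY_RANKS}
    if not tax_string or tax_string in ("-", "NA"):
        return out
    for part in tax_string.split(";"):
        part = part.strip()
        for rank, prefix in zip(TAXONOMY_RANKS, _RANK_PREFIXES):
            if part.startswith(prefix):
                out[rank] = part[len(prefix):].strip()
                break
    return out


def taxonomy_chain_violations(taxonomy: Mapping[str, str]) -> list[str]:
    """Ranks where an empty name is followed by a non-empty deeper one.

    Such gaps break prefix consistency of a GTDB lineage; they are reported
    but tolerated (the deeper names are still usable for shared-taxon
    lookups).
    """
    bad = []
    seen_empty = False
    for rank in TAXONOMY_RANKS:
        name = taxonomy.get(rank, "")
        if name == "":
            seen_empty = True
        elif seen_empty:
            bad.append(rank)
    return bad


@dataclass
class GenomeRecord:
    """One MAG with its quality, habitat and taxonomy metadata."""

    genome_id: str
    biome: str
    completeness: float
    contamination: float
    basin: Optional[str] = None
    taxonomy: dict[str, str] = field(default_factory=dict)
    proteome_path: Optional[str] = None
    n_genes: int = 0

    def __post_init__(self) -> None:
        if self.biome not in BIOMES:
            raise ValueError(
                f"genome {self.genome_id!r}: biome {self.biome!r} not one of {BIOMES}"
            )
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"genome {self.genome_id!r}: completeness out of [0,100]")
        if not (0.0 <= self.contamination <= 100.0):
            raise ValueError(f"genome {self.genome_id!r}: contamination out of [0,100]")

    @property
    def passes_qc(self) -> bool:
        return (
            self.completeness >= MIN_COMPLETENESS
            and self.contamination <= MAX_CONTAMINATION
        )

    @property
    def quality_score(self) -> float:
        """Completeness minus contamination; used to pick cluster representatives."""
        return self.completeness - self.contamination


class ANITable:
    """Symmetric pairwise ANI (%) lookup.

    Access is unordered: ``get(a, b)`` returns the value stored under either
    orientation; when both orientations were recorded (FastANI emits both)
    their mean is used.  Missing pairs mean "below the reporting threshold"
    and are returned as ``None``.
    """

    def __init__(self) -> None:
        self._sums: dict[tuple[str, str], float] = {}
        self._counts: dict[tuple[str, str], int] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, ani: float) -> None:
        if not (0.0 <= ani <= 100.0):
            raise FormatError(f"ANI value {ani} for ({a},{b}) outside [0,100]")
        k = self._key(a, b)
        self._sums[k] = self._sums.get(k, 0.0) + ani
        self._counts[k] = self._counts.get(k, 0) + 1

    def get(self, a: str, b: str, default: Optional[float] = None) -> Optional[float]:
        if a == b:
            return 100.0
        k = self._key(a, b)
        if k not in self._sums:
            return default
        return self._sums[k] / self._counts[k]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return a == b or self._key(a, b) in self._sums

    def __len__(self) -> int:
        return len(self._sums)

    def genomes(self) -> list[str]:
        seen: set[str] = set()
        for a, b in self._sums:
            seen.add(a)
            seen.add(b)
        return sorted(seen)


class LabeledTree:
    """A rooted phylogeny whose tips are genome ids.

    Thin wrapper over a :class:`dendropy.Tree`.  Optional node ages (Ma
    before present) live on each node as the ``age`` attribute, parsed from
    and written back as ``[&age=X]`` Newick comments; tips have age 0.
    """

    def __init__(self, tree: dendropy.Tree, has_ages: bool = False) -> None:
        self.tree = tree
        self.has_ages = has_ages

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        # the pipeline is defined on rooted phylogenies; without this,
        # pruning would collapse the root into a basal trifurcation
        tree.is_rooted = True
        has_ages = False
        for nd in tree.preorder_node_iter():
            val = nd.annotations.get_value("age", None)
            if val is not None:
                nd.age = float(val)
                has_ages = True
        if has_ages:
            for leaf in tree.leaf_node_iter():
                if not hasattr(leaf, "age") or leaf.annotations.get_value("age") is None:
                    leaf.age = 0.0
        return cls(tree, has_ages=has_ages)

    def clone(self) -> "LabeledTree":
        return LabeledTree(copy.deepcopy(self.tree), has_ages=self.has_ages)

    # -- queries ------------------------------------------------------
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def is_bifurcating(self) -> bool:
        for nd in self.tree.preorder_internal_node_iter():
            if len(nd.child_nodes()) != 2:
                return False
        return True

    def node_age(self, node: dendropy.Node) -> Optional[float]:
        return getattr(node, "age", None) if self.has_ages else None

    # -- serialization ------------------------------------------------
    def to_newick(self) -> str:
        if self.has_ages:
            for nd in self.tree.preorder_node_iter():
                nd.annotations.drop(name="age")
                if hasattr(nd, "age") and not nd.is_leaf():
                    nd.annotations.add_new("age", repr(float(nd.age)))
        s = self.tree.as_string(
            schema="newick",
            suppress_annotations=not self.has_ages,
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"


@dataclass
class KOMatrix:
    """Binary gene-function (KO) presence per genome.

    ``presence`` is a boolean genomes × kos matrix; an optional integer
    ``counts`` matrix carries raw occurrence counts (presence == counts > 0).
    """

    genomes: list[str]
    kos: list[str]
    presence: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome ids in KO matrix")
        if self.presence.shape != (len(self.genomes), len(self.kos)):
            raise ValueError("presence matrix shape does not match labels")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if not np.array_equal(self.presence, self.counts > 0):
                raise ValueError("presence must equal counts > 0")
        self._row = {g: i for i, g in enumerate(self.genomes)}

    def row(self, genome_id: str) -> np.ndarray:
        return self.presence[self._row[genome_id]]

    def ko_set(self, genome_id: str) -> set[str]:
        mask = self.row(genome_id)
        return {ko for ko, m in zip(self.kos, mask) if m}

    def subset(self, genome_ids: Sequence[str]) -> "KOMatrix":
        idx = [self._row[g] for g in genome_ids]
        return KOMatrix(
            genomes=list(genome_ids),
            kos=list(self.kos),
            presence=self.presence[idx],
            counts=None if self.counts is None else self.counts[idx],
        )

    @classmethod
    def from_long(cls, rows: Iterable[tuple[str, str, int]]) -> "KOMatrix":
        """Build from (genome, ko, count) triples; duplicates are summed."""
        acc: dict[tuple[str, str], int] = {}
        for g, ko, c in rows:
            acc[(g, ko)] = acc.get((g, ko), 0) + int(c)
        genomes = sorted({g for g, _ in acc})
        kos = sorted({k for _, k in acc})
        gi = {g: i for i, g in enumerate(genomes)}
        ki = {k: i for i, k in enumerate(kos)}
        counts = np.zeros((len(genomes), len(kos)), dtype=np.int64)
        for (g, k), c in acc.items():
            counts[gi[g], ki[k]] = c
        return cls(genomes=genomes, kos=kos, presence=counts > 0, counts=counts)


def derive_seed(seed: int, iteration: int) -> int:
    """Per-iteration seed protocol: base seed plus iteration index."""
    return int(seed) + int(iteration)
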