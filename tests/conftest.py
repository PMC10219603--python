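import numpy as np
import pytest

from crossbiome.core import ANITable, GenomeRecord, LabeledTree, parse_taxonomy


@pytest.fixture
def make_record():
    def _make(genome_id, biome="freshwater", completeness=90.0, contamination=1.0,
              basin=None, taxonomy="", n_genes=0):
        return GenomeRecord(
            genome_id=genome_id, biome=biome, completeness=completeness,
            contamination=contamination, basin=basin,
            taxonomy=parse_taxonomy(taxonomy), n_genes=n_genes,
        )
    return _make


@pytest.fixture
def four_tip_tree():
    return LabeledTree.from_newick("((t1:1,t2:1):1,(t3:1,t4:1):1);")


@pytest.fixture
def ani_table():
    def _make(pairs):
        t = ANITable()
        for a, b, v in pairs:
            t.add(a, b, v)
        return t
    return _make


def random_labeled_tree(n_tips, rng, biomes=("freshwater", "brackish", "marine")):
    """Random bifurcating rooted tree plus random tip biomes (test helper)."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    nodes = [tree.seed_node]
    while len([n for n in nodes if n.is_leaf()]) < n_tips:
        leaves = [n for n in nodes if n.is_leaf() and n.taxon is None]
        nd = leaves[rng.integers(len(leaves))]
        for _ in range(2):
            child = nd.new_child(edge_length=float(rng.uniform(0.1, 2.0)))
            nodes.append(child)
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = tns.new_taxon(label=f"t{i}")
    lt = LabeledTree(tree)
    labels = {lf.taxon.label: biomes[rng.integers(len(biomes))]
              for lf in tree.leaf_node_iter()}
    return lt, labels
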