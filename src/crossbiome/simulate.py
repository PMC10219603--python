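"""Synthetic data with the statistical structure the pipeline assumes.

Generates, from one seed: a time-calibrated species tree (Yule process),
biome states evolved on it under a 3-state Markov model, ANI blocks of
near-identical genomes around each species, proteomes whose amino-acid
composition shifts with salinity, and a KO presence/absence matrix with
core/accessory structure, planted biome-differential KOs and
completeness censoring.  Truth tables (generating rates, planted KO ids,
true ancestral states, cluster labels) are retained so recovery can be
scored.

Sizes default to a desk-scale study: 200 species on a 1,000-Ma tree —
roughly one-twentieth of the MAG compendium the analyses were designed
for, with transition rates set high enough that each transition type is
represented by a few dozen sister-group pairs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .core import ANITable, BIOMES, GenomeRecord, KOMatrix, LabeledTree, derive_seed
from .proteome import AMINO_ACIDS

#: Mean amino-acid frequencies typical of bacterial proteomes.
BACTERIAL_AA_FREQ = {
    "A": 0.089, "C": 0.012, "D": 0.054, "E": 0.058, "F": 0.040,
    "G": 0.074, "H": 0.021, "I": 0.059, "K": 0.052, "L": 0.099,
    "M": 0.023, "N": 0.041, "P": 0.044, "Q": 0.038, "R": 0.055,
    "S": 0.060, "T": 0.054, "V": 0.071, "W": 0.013, "Y": 0.033,
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults define the demo study conditions."""

    n_species: int = 200
    tree_age: float = 1000.0            # Ma
    birth_rate: float = 0.01            # per Ma (shape only; size is fixed)
    #: biome transition rates per Ma (off-diagonal, row -> column,
    #: state order freshwater, brackish, marine)
    q_sim: np.ndarray = field(default_factory=lambda: np.array(
        [[-1.2e-2, 5.0e-3, 7.0e-3],
         [4.0e-3, -9.0e-3, 5.0e-3],
         [6.0e-3, 5.0e-3, -1.1e-2]]))
    root_biome: str = "freshwater"
    #: within-species genome clusters: P(size = k) ~ geometric
    cluster_size_p: float = 0.6
    max_cluster_size: int = 5
    ani_within: tuple[float, float] = (97.0, 0.5)     # mean, sd (%)
    ani_between: tuple[float, float] = (85.0, 2.0)
    #: proteins per genome and residues per protein (means of lognormals)
    n_proteins_mean: int = 300
    protein_length_mean: int = 250
    #: additive shift on D/E frequency per salinity step (F=0, B=1, M=2),
    #: compensated on P and the pool of nonpolar residues
    salinity_effect: float = 0.02
    n_core_kos: int = 60
    n_accessory_kos: int = 120
    accessory_gain_rate: float = 1.5e-3   # per Ma, gain = loss
    n_planted_kos: int = 10               # per transition type
    planted_p_high: float = 0.95
    planted_p_low: float = 0.05
    #: biome histories are redrawn until every transition type is
    #: represented by at least this many sister-group pairs, so each type
    #: is analyzable (mirrors conditioning on an observed study design)
    min_pairs_per_type: int = 16
    max_biome_draws: int = 300
    completeness_range: tuple[float, float] = (75.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 5.0)
    seed: int = 0


# ---------------------------------------------------------------------------
# tree + biomes


def simulate_tree(config: SimulationConfig, seed: Optional[int] = None) -> LabeledTree:
    """Ultrametric Yule tree with ``n_species`` tips scaled to ``tree_age``."""
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    import random as _random

    from dendropy.simulate import treesim

    rng = _random.Random(config.seed if seed is None else seed)
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=rng,
    )
    tree.seed_node.edge.length = None
    # scale depths so the root sits at tree_age
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = config.tree_age / max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    lt = LabeledTree(tree, has_ages=True)
    _set_ages_ultrametric(lt)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    return lt


def _set_ages_ultrametric(tree: LabeledTree) -> None:
    tree.tree.calc_node_root_distances()
    max_d = max(lf.root_distance for lf in tree.tree.leaf_node_iter())
    for nd in tree.tree.preorder_node_iter():
        nd.age = max(0.0, max_d - nd.root_distance)
    for lf in tree.tree.leaf_node_iter():
        lf.age = 0.0
    tree.has_ages = True


def simulate_biomes(
    tree: LabeledTree,
    q_sim: np.ndarray,
    seed: int = 0,
    root_biome: str = "freshwater",
) -> tuple[dict[str, str], dict[int, str], int]:
    """Evolve the biome state root-to-tip by exponential waiting times.

    Returns (tip biomes, true node states keyed by node id, number of
    realized state changes on branches).
    """
    q = np.asarray(q_sim, dtype=float)
    rng = np.random.default_rng(seed)
    state_of: dict[int, int] = {}
    n_changes = 0
    root = tree.tree.seed_node
    state_of[id(root)] = BIOMES.index(root_biome)
    for nd in tree.tree.preorder_node_iter():
        if nd is root:
            continue
        s = state_of[id(nd.parent_node)]
        t_left = nd.edge.length or 0.0
        while True:
            rate = -q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= t_left:
                break
            t_left -= wait
            probs = q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(3, p=probs))
            n_changes += 1
        state_of[id(nd)] = s
    tip_biomes = {
        lf.taxon.label: BIOMES[state_of[id(lf)]] for lf in tree.tree.leaf_node_iter()
    }
    node_states = {k: BIOMES[v] for k, v in state_of.items()}
    return tip_biomes, node_states, n_changes


def simulate_biomes_conditioned(
    tree: LabeledTree,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[dict[str, str], dict[int, str], int]:
    """Biome history conditioned on a minimum pair count per transition type.

    Redraws the Markov history (with derived seeds) until every type has at
    least ``config.min_pairs_per_type`` monobiomic sister pairs on the
    species tree, so all three transition types are analyzable downstream.
    """
    from .treeops import find_msg_pairs

    last = None
    for attempt in range(config.max_biome_draws):
        tips, states, n_changes = simulate_biomes(
            tree, config.q_sim, seed=derive_seed(seed, attempt),
            root_biome=config.root_biome,
        )
        counts = {"FB": 0, "BM": 0, "FM": 0}
        for p in find_msg_pairs(tree, tips):
            counts[p.type] += 1
        last = (tips, states, n_changes)
        if min(counts.values()) >= config.min_pairs_per_type:
            return last
    raise RuntimeError(
        f"no biome history with >= {config.min_pairs_per_type} pairs per type "
        f"in {config.max_biome_draws} draws; lower the requirement or raise "
        "the transition rates"
    )


def simulate_labeled_species_tree(
    config: SimulationConfig, seed: int = 0, biome_draws_per_tree: int = 30
) -> tuple[LabeledTree, dict[str, str], dict[int, str], int]:
    """Jointly draw (tree, biome history) meeting the per-type pair minimum.

    Some topologies cannot host many sister pairs of every type, so both
    the tree and the history are redrawn until the condition holds.
    """
    for attempt in range(20):
        tree = simulate_tree(config, seed=derive_seed(seed, 1000 * attempt + 1))
        try:
            cfg = SimulationConfig(**{**config.__dict__,
                                      "max_biome_draws": biome_draws_per_tree})
            tips, states, n_changes = simulate_biomes_conditioned(
                tree, cfg, seed=derive_seed(seed, 1000 * attempt + 2)
            )
            return tree, tips, states, n_changes
        except RuntimeError:
            continue
    raise RuntimeError("could not satisfy per-type pair minimum in 20 trees")


# ---------------------------------------------------------------------------
# clusters + ANI


def simulate_clusters(
    species: Sequence[str], config: SimulationConfig, seed: int = 0
) -> dict[str, list[str]]:
    """Expand each species into a cluster of near-identical genome ids."""
    rng = np.random.default_rng(seed)
    clusters = {}
    for sp in species:
        size = min(int(rng.geometric(config.cluster_size_p)), config.max_cluster_size)
        clusters[sp] = [f"{sp}_g{k + 1}" for k in range(size)]
    return clusters


def simulate_ani(
    clusters: dict[str, list[str]],
    config: SimulationConfig,
    seed: int = 0,
    n_between_pairs: int = 2000,
) -> tuple[ANITable, dict[str, str]]:
    """Block-structured ANI: high within clusters, low between.

    Between-cluster values are emitted only for a random subset of pairs
    (mirroring an aligner that skips distant pairs); missing pairs are
    treated as maximally distant by the clustering step.  Returns the
    table plus genome -> true-cluster labels.
    """
    rng = np.random.default_rng(seed)
    mu_w, sd_w = config.ani_within
    mu_b, sd_b = config.ani_between
    if mu_w <= mu_b:
        raise ValueError("within-cluster ANI must exceed between-cluster ANI")
    table = ANITable()
    truth: dict[str, str] = {}
    names = sorted(clusters)
    for sp in names:
        members = clusters[sp]
        for g in members:
            truth[g] = sp
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                v = float(np.clip(rng.normal(mu_w, sd_w), 70.0, 100.0))
                table.add(members[i], members[j], v)
    all_genomes = [g for sp in names for g in clusters[sp]]
    for _ in range(n_between_pairs):
        a, b = rng.choice(len(all_genomes), size=2, replace=False)
        ga, gb = all_genomes[a], all_genomes[b]
        if truth[ga] == truth[gb]:
            continue
        v = float(np.clip(rng.normal(mu_b, sd_b), 70.0, 100.0))
        table.add(ga, gb, v)
    return table, truth


# ---------------------------------------------------------------------------
# proteomes


def biome_aa_freq(biome: str, config: SimulationConfig) -> np.ndarray:
    """Base composition shifted by salinity: acidic D/E up, P down."""
    step = {"freshwater": 0, "brackish": 1, "marine": 2}[biome]
    freq = np.array([BACTERIAL_AA_FREQ[a] for a in AMINO_ACIDS])
    delta = config.salinity_effect * step
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    freq[idx["D"]] += delta / 2
    freq[idx["E"]] += delta / 2
    freq[idx["P"]] = max(freq[idx["P"]] - delta / 4, 1e-4)
    freq = np.clip(freq, 1e-6, None)
    return freq / freq.sum()


def simulate_proteome(
    genome_id: str, biome: str, config: SimulationConfig, seed: int = 0
) -> list[str]:
    """I.i.d.-residue proteins with biome-shifted composition."""
    rng = np.random.default_rng(seed)
    freq = biome_aa_freq(biome, config)
    n_prot = max(10, int(rng.lognormal(np.log(config.n_proteins_mean), 0.2)))
    lengths = np.maximum(
        30, rng.lognormal(np.log(config.protein_length_mean), 0.35, n_prot).astype(int)
    )
    aa = np.array(list(AMINO_ACIDS))
    residues = rng.choice(20, size=int(lengths.sum()), p=freq)
    seqs = []
    pos = 0
    for L in lengths:
        seqs.append("".join(aa[residues[pos:pos + L]]))
        pos += L
    return seqs


def write_proteome_fasta(path: str, genome_id: str, sequences: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sequences, start=1):
            fh.write(f">{genome_id}_p{i}\n")
            for k in range(0, len(s), 60):
                fh.write(s[k:k + 60] + "\n")


# ---------------------------------------------------------------------------
# KO matrix


@dataclass
class KOTruth:
    planted: dict[str, dict]      # ko -> {type, high_biome, p_high, p_low}
    core: list[str]
    accessory: list[str]
    completeness: dict[str, float]


def simulate_ko_matrix(
    tree: LabeledTree,
    tip_biomes: dict[str, str],
    config: SimulationConfig,
    seed: int = 0,
    completeness: Optional[dict[str, float]] = None,
) -> tuple[KOMatrix, KOMatrix, KOTruth]:
    """KO presence with core/accessory structure, planted differential KOs
    and completeness censoring.

    Returns (observed matrix, truth matrix, truth record).  Accessory KOs
    evolve by gain/loss along the tree (equal rates), which creates the
    clade-level confounding that the paired test is designed to discount.
    Planted KOs are present with probability ``planted_p_high`` in genomes
    of one biome of their transition type and ``planted_p_low`` in the
    other.
    """
    rng = np.random.default_rng(seed)
    tips = list(tip_biomes)
    n = len(tips)
    kos: list[str] = []
    cols: list[np.ndarray] = []
    core = [f"K_core{i:04d}" for i in range(config.n_core_kos)]
    for ko in core:
        kos.append(ko)
        cols.append(np.ones(n, dtype=bool))
    accessory = [f"K_acc{i:04d}" for i in range(config.n_accessory_kos)]
    acc_presence = _evolve_accessory(
        tree, tips, len(accessory), config.accessory_gain_rate, rng
    )
    for j, ko in enumerate(accessory):
        kos.append(ko)
        cols.append(acc_presence[:, j])
    planted: dict[str, dict] = {}
    type_biomes = {"FB": ("freshwater", "brackish"),
                   "BM": ("brackish", "marine"),
                   "FM": ("freshwater", "marine")}
    for ttype, (blo, bhi) in type_biomes.items():
        for i in range(config.n_planted_kos):
            ko = f"K_plant_{ttype}{i:02d}"
            high_biome = bhi if rng.random() < 0.5 else blo
            other = blo if high_biome == bhi else bhi
            p = np.where(
                [tip_biomes[t] == high_biome for t in tips],
                config.planted_p_high,
                np.where([tip_biomes[t] == other for t in tips],
                         config.planted_p_low,
                         0.5),
            )
            kos.append(ko)
            cols.append(rng.random(n) < p)
            planted[ko] = {"type": ttype, "high_biome": high_biome,
                           "p_high": config.planted_p_high,
                           "p_low": config.planted_p_low}
    truth_matrix = KOMatrix(genomes=tips, kos=kos,
                            presence=np.column_stack(cols))
    if completeness is None:
        lo, hi = config.completeness_range
        completeness = {t: float(rng.uniform(lo, hi)) for t in tips}
    observed = truth_matrix.presence.copy()
    for i, t in enumerate(tips):
        keep = rng.random(observed.shape[1]) < completeness[t] / 100.0
        observed[i] &= keep
    obs_matrix = KOMatrix(genomes=tips, kos=kos, presence=observed)
    return obs_matrix, truth_matrix, KOTruth(
        planted=planted, core=core, accessory=accessory, completeness=completeness
    )


def _evolve_accessory(
    tree: LabeledTree, tips: Sequence[str], n_kos: int,
    rate: float, rng: np.random.Generator,
) -> np.ndarray:
    tip_index = {t: i for i, t in enumerate(tips)}
    presence: dict[int, np.ndarray] = {}
    root = tree.tree.seed_node
    presence[id(root)] = rng.random(n_kos) < 0.5
    out = np.zeros((len(tips), n_kos), dtype=bool)
    for nd in tree.tree.preorder_node_iter():
        if nd is not root:
            state = presence[id(nd.parent_node)].copy()
            t = nd.edge.length or 0.0
            # two-state chain with equal gain/loss: flip prob (1-e^{-2rt})/2
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * rate * t))
            flips = rng.random(n_kos) < p_flip
            state ^= flips
            presence[id(nd)] = state
        if nd.is_leaf():
            out[tip_index[nd.taxon.label]] = presence[id(nd)]
    return out


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: SimulationConfig, outdir: Optional[str] = None) -> dict:
    """Generate the complete synthetic study and optionally write it out.

    Returns a dict with the species tree (expanded to all genomes), genome
    records, ANI table, KO matrices, proteome sequences, and truth tables.
    When ``outdir`` is given, writes tree.nwk, qc.tsv, ani.tsv, ko.tsv,
    proteomes/*.faa, truth/*.json and manifest.json.
    """
    seed = config.seed
    species_tree, tip_biomes, node_states, n_changes = simulate_labeled_species_tree(
        config, seed
    )
    species = species_tree.tip_labels()
    clusters = simulate_clusters(species, config, seed=derive_seed(seed, 3))
    ani, cluster_truth = simulate_ani(clusters, config, seed=derive_seed(seed, 4))
    full_tree = _expand_clusters_on_tree(species_tree, clusters)
    rng = np.random.default_rng(derive_seed(seed, 5))
    records: list[GenomeRecord] = []
    genome_biome: dict[str, str] = {}
    lo_c, hi_c = config.completeness_range
    lo_x, hi_x = config.contamination_range
    basins = ("Baltic", "Caspian")
    for sp in species:
        taxonomy = _species_taxonomy(sp, species_tree, config)
        for g in clusters[sp]:
            biome = tip_biomes[sp]
            genome_biome[g] = biome
            records.append(GenomeRecord(
                genome_id=g,
                biome=biome,
                completeness=float(rng.uniform(lo_c, hi_c)),
                contamination=float(rng.uniform(lo_x, hi_x)),
                basin=(basins[int(rng.integers(2))] if biome == "brackish" else None),
                taxonomy=taxonomy,
                n_genes=0,
            ))
    proteomes: dict[str, list[str]] = {}
    for i, rec in enumerate(records):
        seqs = simulate_proteome(rec.genome_id, rec.biome, config,
                                 seed=derive_seed(seed, 100 + i))
        proteomes[rec.genome_id] = seqs
        rec.n_genes = len(seqs)
    completeness = {r.genome_id: r.completeness for r in records}
    ko_obs, ko_truth_matrix, ko_truth = simulate_ko_matrix(
        full_tree, genome_biome, config, seed=derive_seed(seed, 6),
        completeness=completeness,
    )
    data = {
        "config": config,
        "species_tree": species_tree,
        "tree": full_tree,
        "tip_biomes": tip_biomes,
        "node_states": node_states,
        "n_true_changes": n_changes,
        "clusters": clusters,
        "cluster_truth": cluster_truth,
        "ani": ani,
        "records": records,
        "proteomes": proteomes,
        "ko_observed": ko_obs,
        "ko_truth_matrix": ko_truth_matrix,
        "ko_truth": ko_truth,
    }
    if outdir is not None:
        _write_dataset(data, outdir)
    return data


def _expand_clusters_on_tree(
    species_tree: LabeledTree, clusters: dict[str, list[str]]
) -> LabeledTree:
    """Replace each species tip by a zero-length polytomy of its genomes.

    Single-genome clusters just rename the tip.  The zero-length child
    branches exercise the polytomy-resolution / epsilon-replacement step.
    """
    tree = species_tree.clone()
    tns = tree.tree.taxon_namespace
    for leaf in list(tree.tree.leaf_node_iter()):
        sp = leaf.taxon.label
        members = clusters[sp]
        if len(members) == 1:
            leaf.taxon.label = members[0]
            continue
        leaf.taxon = None
        for g in members:
            child = leaf.new_child(edge_length=0.0)
            child.taxon = tns.new_taxon(label=g)
            child.age = 0.0
        leaf.age = 0.0
    # drop stale species taxa from the namespace
    used = {lf.taxon for lf in tree.tree.leaf_node_iter()}
    for tx in list(tns):
        if tx not in used:
            tns.remove_taxon(tx)
    return tree


def _species_taxonomy(
    sp: str, species_tree: LabeledTree, config: SimulationConfig
) -> dict[str, str]:
    """Clade-derived GTDB-style taxonomy: deep clades define higher ranks."""
    # rank is defined by the ancestor at a fixed age fraction
    fractions = {"phylum": 0.85, "class": 0.6, "order": 0.4,
                 "family": 0.25, "genus": 0.1}
    leaf = next(lf for lf in species_tree.tree.leaf_node_iter()
                if lf.taxon.label == sp)
    tax = {"domain": "Bacteria"}
    node_ids = _ancestor_clade_ids(species_tree)
    for rank, frac in fractions.items():
        cutoff = frac * config.tree_age
        nd = leaf
        while nd.parent_node is not None and getattr(nd.parent_node, "age", 0.0) <= cutoff:
            nd = nd.parent_node
        tax[rank] = f"{rank[0]}{node_ids[id(nd)]:04d}"
    tax["species"] = sp
    return tax


def _ancestor_clade_ids(tree: LabeledTree) -> dict[int, int]:
    return {id(nd): i for i, nd in enumerate(tree.tree.preorder_node_iter())}


def _write_dataset(data: dict, outdir: str) -> None:
    import pandas as pd

    from .core import TAXONOMY_RANKS
    from .io import write_tree

    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "proteomes"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
    write_tree(data["tree"], os.path.join(outdir, "tree.nwk"))
    prefixes = dict(zip(TAXONOMY_RANKS, ("d__", "p__", "c__", "o__", "f__", "g__", "s__")))
    rows = []
    for r in data["records"]:
        tax = ";".join(prefixes[k] + r.taxonomy.get(k, "") for k in TAXONOMY_RANKS)
        rows.append({"genome": r.genome_id, "completeness": r.completeness,
                     "contamination": r.contamination, "biome": r.biome,
                     "basin": r.basin or "", "taxonomy": tax,
                     "n_genes": r.n_genes,
                     "proteome": f"proteomes/{r.genome_id}.faa"})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "qc.tsv"), sep="\t", index=False)
    ani_rows = [{"genomeA": a, "genomeB": b, "ani": data["ani"].get(a, b)}
                for (a, b) in sorted(data["ani"]._sums)]
    pd.DataFrame(ani_rows).to_csv(os.path.join(outdir, "ani.tsv"), sep="\t", index=False)
    ko = data["ko_observed"]
    ko_rows = []
    for i, g in enumerate(ko.genomes):
        for j in np.flatnonzero(ko.presence[i]):
            ko_rows.append({"genome": g, "ko": ko.kos[j], "count": 1})
    pd.DataFrame(ko_rows).to_csv(os.path.join(outdir, "ko.tsv"), sep="\t", index=False)
    for g, seqs in data["proteomes"].items():
        write_proteome_fasta(os.path.join(outdir, "proteomes", f"{g}.faa"), g, seqs)
    truth = {
        "planted_kos": data["ko_truth"].planted,
        "cluster_truth": data["cluster_truth"],
        "tip_biomes": data["tip_biomes"],
        "n_true_changes": data["n_true_changes"],
    }
    with open(os.path.join(outdir, "truth", "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    cfg = data["config"]
    manifest = {
        "seed": cfg.seed,
        "n_species": cfg.n_species,
        "tree_age": cfg.tree_age,
        "q_sim": np.asarray(cfg.q_sim).tolist(),
        "n_genomes": len(data["records"]),
        "files": ["tree.nwk", "qc.tsv", "ani.tsv", "ko.tsv"],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# planted-direction scenario


def simulate_directional_scenario(
    n_fb_units: int = 40,
    n_f_backbone: int = 160,
    n_b_region: int = 140,
    n_m_region: int = 120,
    cherry_age: tuple[float, float] = (60.0, 160.0),
    region_age: float = 700.0,
    tree_age: float = 1000.0,
    seed: int = 0,
) -> tuple[LabeledTree, dict[str, str]]:
    """A tree with a known dominant freshwater-to-brackish direction.

    The tree joins three deep monobiomic regions — freshwater, brackish
    and marine Yule clades — as ((F-region, B-region), M-region), with
    ``n_fb_units`` freshwater/brackish cherries (the planted F->B
    transitions) grafted inside the freshwater region.  The pure regions
    supply the long-timescale rate context (same-biome tips cluster, so a
    rate-saturated model is heavily penalized), the cherries are the only
    cross-biome signal, and every FB pair's true ancestral state is
    freshwater.  The brackish and marine regions sit next to mixed
    clades, so their tips stay outside any MSG and remain available for
    biome balancing.
    """
    rng = np.random.default_rng(seed)

    def _region(n, label_prefix, sub_seed):
        cfg = SimulationConfig(n_species=n, tree_age=region_age, seed=sub_seed)
        t = simulate_tree(cfg, seed=sub_seed)
        for i, lf in enumerate(t.tree.leaf_node_iter()):
            lf.taxon.label = f"{label_prefix}{i + 1:03d}"
        return t

    f_region = _region(n_fb_units + n_f_backbone, "f", derive_seed(seed, 1))
    b_region = _region(n_b_region, "b", derive_seed(seed, 2))
    m_region = _region(n_m_region, "m", derive_seed(seed, 3))
    biomes: dict[str, str] = {}
    # graft FB cherries onto random freshwater-region tips
    tips = list(f_region.tree.leaf_node_iter())
    unit_set = set(int(i) for i in rng.choice(len(tips), size=n_fb_units, replace=False))
    tns_f = f_region.tree.taxon_namespace
    for i, leaf in enumerate(tips):
        if i not in unit_set:
            biomes[leaf.taxon.label] = "freshwater"
            continue
        base = leaf.taxon.label
        # keep the cherry stem short so the freshwater backbone context sits
        # directly above the transition node
        stem = min(float(rng.uniform(10.0, 30.0)), 0.3 * leaf.edge.length)
        ch_age = max(leaf.edge.length - stem, min(cherry_age[0], leaf.edge.length / 2))
        leaf.taxon = None
        leaf.edge.length = max(leaf.edge.length - ch_age, 1.0)
        leaf.age = ch_age
        for suffix, biome in (("_F", "freshwater"), ("_B", "brackish")):
            t = leaf.new_child(edge_length=ch_age)
            t.age = 0.0
            t.taxon = tns_f.new_taxon(label=f"{base}{suffix}")
            biomes[t.taxon.label] = biome
    for lf in b_region.tree.leaf_node_iter():
        biomes[lf.taxon.label] = "brackish"
    for lf in m_region.tree.leaf_node_iter():
        biomes[lf.taxon.label] = "marine"
    # assemble ((F, B), M) on a fresh namespace
    import dendropy as _dp

    tns = _dp.TaxonNamespace()
    root_tree = _dp.Tree(taxon_namespace=tns)
    root = root_tree.seed_node
    root.age = tree_age
    inner = root.new_child(edge_length=tree_age - (region_age + 50.0))
    inner.age = region_age + 50.0
    for parent, region in ((inner, f_region), (inner, b_region), (root, m_region)):
        sub_root = region.tree.seed_node
        sub_root.parent_node = None
        parent.add_child(sub_root)
        sub_root.edge.length = parent.age - region_age
    for lf in root_tree.leaf_node_iter():
        lf.taxon = tns.new_taxon(label=lf.taxon.label)
    root_tree.is_rooted = True
    out = LabeledTree(root_tree, has_ages=True)
    return out, biomes
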