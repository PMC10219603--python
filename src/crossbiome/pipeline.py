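"""End-to-end orchestration: cluster → prune → MSG → null → direction →
proteome → genes, with provenance manifest and input validation."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import ancestral, clustering, genes, io, nulls, proteome, treeops
from .core import LabeledTree, derive_seed


@dataclass
class PipelineConfig:
    qc: str
    tree: str
    ani: Optional[str] = None
    ko: Optional[str] = None
    proteome_dir: Optional[str] = None
    out: str = "crossbiome_out"
    seed: int = 0
    ani_threshold: float = 95.0
    linkage: str = "complete"
    null_iters: int = 100
    direction_iters: int = 25
    ko_iters: int = 50
    stages: tuple[str, ...] = (
        "cluster", "msg", "null", "direction", "proteome", "genes"
    )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> dict:
    """Cross-reference genome ids across QC, tree, ANI, KO and proteomes."""
    report: dict = {"orphans": {}, "missing_files": [], "coverage": {}}
    for name in ("qc", "tree", "ani", "ko"):
        path = getattr(config, name)
        if path and not os.path.exists(path):
            report["missing_files"].append(path)
    if report["missing_files"]:
        return report
    qc = io.read_qc_table(config.qc)
    ids = {r.genome_id for r in qc.records} | {r.genome_id for r in qc.rejects}
    tree = io.read_tree(config.tree)
    tree_tips = set(tree.tip_labels())
    report["orphans"]["tree_tips_without_qc"] = sorted(tree_tips - ids)
    report["coverage"]["qc"] = len(ids)
    report["coverage"]["tree_tips"] = len(tree_tips)
    if config.ani:
        ani = io.read_ani_table(config.ani)
        report["orphans"]["ani_without_qc"] = sorted(set(ani.genomes()) - ids)
    if config.ko:
        ko = io.read_ko_table(config.ko)
        report["orphans"]["ko_without_qc"] = sorted(set(ko.genomes) - ids)
    if config.proteome_dir:
        missing = [r.genome_id for r in qc.records
                   if not os.path.exists(os.path.join(
                       config.proteome_dir, f"{r.genome_id}.faa"))]
        report["orphans"]["qc_without_proteome"] = missing
    return report


def run_all(config: PipelineConfig) -> dict:
    """Run the configured stages and return the manifest."""
    os.makedirs(config.out, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": [],
    }
    for name in ("qc", "tree", "ani", "ko"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    qc = io.read_qc_table(config.qc)
    records = qc.records
    by_id = qc.by_id()
    tree = io.read_tree(config.tree, records=records)

    def _stage(name):
        return name in config.stages

    t0 = time.time()
    clusters = None
    if _stage("cluster") and config.ani:
        ani = io.read_ani_table(config.ani)
        clusters = clustering.cluster_genomes(
            ani, [r.genome_id for r in records if r.genome_id in set(tree.tip_labels())],
            threshold=config.ani_threshold, linkage=config.linkage, records=records,
        )
        summary = clustering.summarize_biome_overlap(clusters, records)
        rows = [{"cluster_id": c.cluster_id,
                 "members": ",".join(sorted(c.members)),
                 "biomes": ",".join(sorted(c.biomes))} for c in clusters]
        io.write_results(pd.DataFrame(rows), os.path.join(config.out, "clusters.tsv"))
        with open(os.path.join(config.out, "overlap_summary.json"), "w") as fh:
            json.dump({
                "n_clusters": summary.n_clusters,
                "single_biome_counts": summary.single_biome_counts,
                "shared_counts": summary.shared_counts,
                "biome_totals": summary.biome_totals,
                "overlap_fraction": summary.overlap_fraction,
                "basin_overlap_fraction": summary.basin_overlap_fraction,
            }, fh, indent=1)
        manifest["outputs"] += ["clusters.tsv", "overlap_summary.json"]
        manifest["stages"]["cluster"] = {"seconds": round(time.time() - t0, 2),
                                         "n_clusters": len(clusters)}

    t0 = time.time()
    resolved = treeops.resolve_polytomies(tree, seed=derive_seed(config.seed, 1))
    if clusters is not None:
        pruned = treeops.prune_representatives(resolved, clusters, records)
    else:
        pruned = resolved
    io.write_tree(pruned, os.path.join(config.out, "pruned.nwk"))
    manifest["outputs"].append("pruned.nwk")
    biome_of = {t: by_id[t].biome for t in pruned.tip_labels()}
    pairs = treeops.find_msg_pairs(pruned, biome_of)
    treeops.annotate_shared_taxa(pairs, records)
    manifest["stages"]["msg"] = {
        "seconds": round(time.time() - t0, 2),
        "counts": treeops.summarize_transitions(pairs)["by_type"],
        "polytomy_seed": derive_seed(config.seed, 1),
    }
    rows = [{
        "pair_id": p.pair_id, "type": p.type,
        "biome_a": p.msg_a.biome, "tips_a": ",".join(sorted(p.msg_a.tips)),
        "biome_b": p.msg_b.biome, "tips_b": ",".join(sorted(p.msg_b.tips)),
        "mrca_age_ma": p.mrca_age if p.mrca_age is not None else np.nan,
        "shared_rank": p.shared_taxon_rank, "shared_name": p.shared_taxon_name,
    } for p in pairs]
    io.write_results(pd.DataFrame(rows), os.path.join(config.out, "msg_pairs.tsv"))
    manifest["outputs"].append("msg_pairs.tsv")

    if _stage("null"):
        t0 = time.time()
        null = nulls.permute_expected_counts(
            pruned, biome_of, n_iter=config.null_iters,
            seed=derive_seed(config.seed, 2),
        )
        stat, pval = nulls.chisq_type_fractions(null.observed, null.expected_raw)
        with open(os.path.join(config.out, "null_summary.json"), "w") as fh:
            json.dump({
                "observed": null.observed, "expected": null.expected,
                "expected_raw": null.expected_raw,
                "p_low": null.p_low, "p_high": null.p_high,
                "tie_policy": "ties counted in neither one-sided tail",
                "chisq": {"statistic": stat, "p": pval},
            }, fh, indent=1)
        manifest["outputs"].append("null_summary.json")
        manifest["stages"]["null"] = {"seconds": round(time.time() - t0, 2)}

    if _stage("direction") and pairs:
        t0 = time.time()
        direction = ancestral.balanced_direction_inference(
            pruned, pairs, records, n_iter=config.direction_iters,
            seed=derive_seed(config.seed, 3),
        )
        rows = [{"pair_id": pid, "type": direction.pair_types[pid],
                 "meanL_F": direction.mean_marginals[pid][0],
                 "meanL_B": direction.mean_marginals[pid][1],
                 "meanL_M": direction.mean_marginals[pid][2],
                 "call": direction.calls[pid]} for pid in direction.pair_ids]
        io.write_results(pd.DataFrame(rows), os.path.join(config.out, "direction.tsv"))
        manifest["outputs"].append("direction.tsv")
        manifest["stages"]["direction"] = {
            "seconds": round(time.time() - t0, 2),
            "type_mean_p": direction.type_mean_p,
        }

    if _stage("proteome") and config.proteome_dir and pairs:
        t0 = time.time()
        profiles = {}
        for p in pairs:
            for msg in (p.msg_a, p.msg_b):
                member_profiles = []
                for g in sorted(msg.tips):
                    fasta = os.path.join(config.proteome_dir, f"{g}.faa")
                    prot = io.read_fasta_proteome(fasta)
                    member_profiles.append(
                        proteome.profile_proteome(g, prot.sequences))
                profiles[proteome.pair_profile_key(p, msg.biome)] = (
                    proteome.msg_profile(f"{p.pair_id}:{msg.biome}", member_profiles)
                )
        comparison = proteome.compare_transitions(pairs, profiles)
        io.write_results(comparison.tests,
                         os.path.join(config.out, "proteome_tests.tsv"),
                         sort_by="quantity")
        manifest["outputs"].append("proteome_tests.tsv")
        manifest["stages"]["proteome"] = {"seconds": round(time.time() - t0, 2)}

    if _stage("genes") and config.ko:
        t0 = time.time()
        ko = io.read_ko_table(config.ko)
        diff = genes.paired_differential_kos(
            pairs, ko, records, n_iter=config.ko_iters,
            seed=derive_seed(config.seed, 4),
        )
        rows = [{"ko": r.ko_id, "type": r.transition_type, "mean_q": r.mean_q,
                 "direction": r.direction,
                 "frac_fresher": r.presence_fraction_fresher,
                 "frac_saline": r.presence_fraction_saline,
                 "significant": r.significant} for r in diff]
        io.write_results(pd.DataFrame(rows),
                         os.path.join(config.out, "differential_kos.tsv"),
                         sort_by="ko")
        gl = genes.gain_loss_map(diff, pairs, ko)
        if len(gl):
            io.write_results(gl, os.path.join(config.out, "gain_loss_map.tsv"),
                             sort_by="ko")
            manifest["outputs"].append("gain_loss_map.tsv")
        manifest["outputs"].append("differential_kos.tsv")
        manifest["stages"]["genes"] = {
            "seconds": round(time.time() - t0, 2),
            "n_significant": sum(r.significant for r in diff),
        }

    with open(os.path.join(config.out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
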