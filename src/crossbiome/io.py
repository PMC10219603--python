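"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular inputs are tab-delimited UTF-8 with a header row; lines
starting with ``#`` are ignored.  Trees are Newick with optional
``[&age=X]`` node-age comments (Ma); proteomes are standard protein FASTA.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    ANITable,
    FormatError,
    GenomeRecord,
    KOMatrix,
    LabeledTree,
    ReconciliationError,
    parse_taxonomy,
    taxonomy_chain_violations,
)

_QC_COLUMNS = ("genome", "completeness", "contamination", "biome")


@dataclass
class QCReadResult:
    """Outcome of reading a QC table: kept records, rejects, and warnings."""

    records: list[GenomeRecord]
    rejects: list[GenomeRecord]
    warnings: list[str] = field(default_factory=list)

    def by_id(self) -> dict[str, GenomeRecord]:
        return {r.genome_id: r for r in self.records}


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_qc_table(path: str) -> QCReadResult:
    """Read the per-genome QC/metadata table.

    Required columns: genome, completeness, contamination, biome.  Optional:
    basin, taxonomy, n_genes, proteome.  Rows failing the QC thresholds
    (completeness >= 75, contamination <= 5) go to ``rejects``.
    """
    df = _read_tsv(path)
    for col in _QC_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"QC table {path}: missing required column {col!r}")
    kept: list[GenomeRecord] = []
    rejects: list[GenomeRecord] = []
    warns: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            rec = GenomeRecord(
                genome_id=d["genome"],
                biome=d["biome"],
                completeness=float(d["completeness"]),
                contamination=float(d["contamination"]),
                basin=d.get("basin") or None,
                taxonomy=parse_taxonomy(d.get("taxonomy", "")),
                proteome_path=d.get("proteome") or None,
                n_genes=int(d["n_genes"]) if d.get("n_genes") else 0,
            )
        except ValueError as exc:
            raise FormatError(f"QC table {path}, line {i}: {exc}") from exc
        gaps = taxonomy_chain_violations(rec.taxonomy)
        if gaps:
            warns.append(
                f"{rec.genome_id}: taxonomy gap before rank(s) {','.join(gaps)}"
            )
        (kept if rec.passes_qc else rejects).append(rec)
    return QCReadResult(records=kept, rejects=rejects, warnings=warns)


def read_ani_table(path: str) -> ANITable:
    """Read pairwise ANI rows (genomeA, genomeB, ANI%); duplicates averaged."""
    table = ANITable()
    df = _read_tsv(path)
    if df.empty:
        return table
    cols = list(df.columns)
    if len(cols) < 3:
        raise FormatError(f"ANI table {path}: expected 3 columns, got {cols}")
    for row in df.itertuples(index=False):
        a, b, ani = row[0], row[1], float(row[2])
        if a == b:
            continue
        table.add(a, b, ani)
    return table


def read_tree(
    path_or_newick: str, records: Optional[Sequence[GenomeRecord]] = None
) -> LabeledTree:
    """Read a rooted Newick tree; polytomies are permitted at this stage.

    When ``records`` is supplied, every tip label must match a genome id;
    orphan tips raise a :class:`ReconciliationError` listing them.
    """
    if os.path.exists(path_or_newick):
        with open(path_or_newick) as fh:
            newick = fh.read()
    else:
        newick = path_or_newick
    tree = LabeledTree.from_newick(newick)
    if records is not None:
        known = {r.genome_id for r in records}
        orphans = sorted(set(tree.tip_labels()) - known)
        if orphans:
            raise ReconciliationError(
                f"tree tips with no genome record: {', '.join(orphans)}"
            )
    return tree


@dataclass
class Proteome:
    """Protein sequences of one genome, uppercased, with ambiguity flags."""

    sequences: list[str]
    ids: list[str]
    flagged: list[str] = field(default_factory=list)  # ids containing B/Z/X/U/O/*
    duplicate_ids: list[str] = field(default_factory=list)


_AMBIGUOUS = set("BZXUO*")


def read_fasta_proteome(path: str) -> Proteome:
    """Read a protein FASTA; ambiguous residues are retained but flagged."""
    seqs: list[str] = []
    ids: list[str] = []
    flagged: list[str] = []
    dupes: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        s = str(rec.seq).upper()
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        ids.append(rec.id)
        seqs.append(s)
        if any(c in _AMBIGUOUS for c in s):
            flagged.append(rec.id)
    if not seqs:
        warnings.warn(f"empty proteome file: {path}")
    return Proteome(sequences=seqs, ids=ids, flagged=flagged, duplicate_ids=dupes)


def read_ko_table(path: str) -> KOMatrix:
    """Read the long-form KO table (genome, ko, count) into a KOMatrix."""
    df = _read_tsv(path)
    for col in ("genome", "ko", "count"):
        if col not in df.columns:
            raise FormatError(f"KO table {path}: missing required column {col!r}")
    return KOMatrix.from_long(
        (g, k, int(c)) for g, k, c in zip(df["genome"], df["ko"], df["count"])
    )


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        return f"{v:.6g}"
    if v is None:
        return "NA"
    return str(v)


def write_results(table: pd.DataFrame, path: str, sort_by: Optional[str] = None) -> None:
    """Write a result table as deterministic TSV.

    Rows are sorted by ``sort_by`` (default: the first column) and floats
    formatted with 6 significant digits so re-runs on identical inputs are
    byte-identical.
    """
    df = table.copy()
    key = sort_by if sort_by is not None else (df.columns[0] if len(df.columns) else None)
    if key is not None and len(df):
        df = df.sort_values(key, kind="mergesort")
    out = df.map(_format_value)
    out.to_csv(path, sep="\t", index=False)


def write_tree(tree: LabeledTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())
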