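"""Gene-repertoire analyses across biome transitions.

Covers (i) gene-content overlap between genomes versus divergence time,
(ii) gene-number differences across MSG pairs, and (iii) the iterated,
completeness-corrected differential-KO procedure that finds gene
functions repeatedly gained or lost with transitions — plus its
phylogeny-unaware counterpart for contrast.

Genome completeness matters because an absent KO in a draft genome may be
an assembly gap: in each sampled genome pair the more complete genome's
present KOs are randomly censored so both genomes are observed at the
same effective completeness before testing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, mannwhitneyu, norm, wilcoxon
from statsmodels.stats.multitest import multipletests

from .core import BIOMES, SALINITY_ORDER, GenomeRecord, KOMatrix, derive_seed
from .treeops import TYPE_BIOMES, MSG, MSGPair


def gene_overlap(kos_a: set[str], kos_b: set[str]) -> float:
    """Sørensen-type repertoire overlap: |A∩B| / mean(|A|, |B|)."""
    if not kos_a and not kos_b:
        raise ValueError("both KO sets empty")
    return len(kos_a & kos_b) / ((len(kos_a) + len(kos_b)) / 2.0)


@dataclass
class OverlapPoint:
    pair_id: str
    overlap: float
    time: float
    group: str   # FB / BM / FM / none


@dataclass
class OverlapFitResult:
    coefficients: pd.DataFrame   # group, model, intercept, slope
    contrasts: pd.DataFrame      # group_a, group_b, model, estimate, se, t, p


def fit_overlap_vs_time(points: Sequence[OverlapPoint]) -> OverlapFitResult:
    """Per-group log/linear fits of overlap vs time plus group contrasts.

    The logarithmic model regresses log(overlap) on time, the linear model
    overlap on time.  Groups are compared via least-squares means: adjusted
    group means at the grand-mean time from a common slope (ANCOVA) model
    with pooled residual variance.
    """
    df = pd.DataFrame(
        {
            "group": [p.group for p in points],
            "time": [p.time for p in points],
            "overlap": [p.overlap for p in points],
        }
    )
    coef_rows = []
    contrast_rows = []
    for model in ("log", "linear"):
        sub = df.copy()
        if model == "log":
            zero = sub["overlap"] <= 0
            if zero.any():
                warnings.warn(f"{int(zero.sum())} zero-overlap points dropped "
                              "for the log model")
                sub = sub[~zero]
            sub = sub.assign(y=np.log(sub["overlap"]))
        else:
            sub = sub.assign(y=sub["overlap"])
        groups = sorted(sub["group"].unique())
        for g in groups:
            gg = sub[sub["group"] == g]
            if len(gg) < 3:
                continue
            x = np.column_stack([np.ones(len(gg)), gg["time"]])
            coef, *_ = np.linalg.lstsq(x, gg["y"].to_numpy(), rcond=None)
            coef_rows.append({"group": g, "model": model,
                              "intercept": float(coef[0]), "slope": float(coef[1])})
        if len(groups) >= 2:
            # ANCOVA: y ~ group + time, adjusted means at the grand-mean time
            dummies = pd.get_dummies(sub["group"], dtype=float)
            x = np.column_stack([dummies.to_numpy(), sub["time"].to_numpy()])
            y = sub["y"].to_numpy()
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            dof = max(len(sub) - x.shape[1], 1)
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.pinv(x.T @ x)
            cols = list(dummies.columns)
            for ga, gb in itertools.combinations(cols, 2):
                c = np.zeros(x.shape[1])
                c[cols.index(ga)] = 1.0
                c[cols.index(gb)] = -1.0
                est = float(c @ coef)
                se = float(np.sqrt(c @ cov @ c))
                t = est / se if se > 0 else np.inf
                from scipy.stats import t as tdist

                p = float(2 * tdist.sf(abs(t), dof))
                contrast_rows.append({"group_a": ga, "group_b": gb, "model": model,
                                      "estimate": est, "se": se, "t": t, "p": p})
    return OverlapFitResult(
        coefficients=pd.DataFrame(coef_rows),
        contrasts=pd.DataFrame(contrast_rows),
    )


def gene_number_difference(
    pairs: Sequence[MSGPair], records: Sequence[GenomeRecord]
) -> pd.DataFrame:
    """Per-pair gene-count differences (saline minus fresher) and type tests.

    The per-MSG gene number is the mean number of distinct proteins over
    its representative genomes.  Returns the per-pair table; per-type
    Wilcoxon signed-rank p-values (Bonferroni across the three types) are
    attached as a DataFrame attribute ``type_tests``.
    """
    meta = {r.genome_id: r for r in records}
    rows = []
    for p in pairs:
        low_b, high_b = TYPE_BIOMES[p.type]
        low = p.msg_for_biome(low_b)
        high = p.msg_for_biome(high_b)
        mean_low = float(np.mean([meta[t].n_genes for t in sorted(low.tips)]))
        mean_high = float(np.mean([meta[t].n_genes for t in sorted(high.tips)]))
        rows.append({"pair_id": p.pair_id, "type": p.type,
                     "delta_genes": mean_high - mean_low})
    df = pd.DataFrame(rows)
    tests = []
    for ttype in ("FB", "BM", "FM"):
        vals = df.loc[df["type"] == ttype, "delta_genes"].to_numpy()
        nz = vals[vals != 0.0]
        if nz.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_raw = float(wilcoxon(nz).pvalue)
        tests.append({"type": ttype, "n": int(vals.size),
                      "median_delta": float(np.median(vals)),
                      "p_raw": p_raw, "p_bonf": min(1.0, p_raw * 3)})
    df.attrs["type_tests"] = pd.DataFrame(tests)
    return df


@dataclass
class DifferentialKOResult:
    ko_id: str
    transition_type: str
    mean_q: float
    direction: str                 # more_in_saline / more_in_fresher
    presence_fraction_fresher: float
    presence_fraction_saline: float
    annotation: Optional[str] = None

    @property
    def significant(self) -> bool:
        return self.mean_q < 0.1


def _sign_test_p(n_pos: int, n_neg: int) -> float:
    """Paired Wilcoxon on binary differences: an exact/approximate sign test.

    Exact binomial for up to 25 informative pairs, normal approximation
    with continuity correction beyond.
    """
    n = n_pos + n_neg
    if n == 0:
        return 1.0
    if n <= 25:
        return float(binomtest(n_pos, n, 0.5).pvalue)
    z = (abs(n_pos - n / 2.0) - 0.5) / np.sqrt(n / 4.0)
    return float(2 * norm.sf(z))


def censor_presence(
    presence: np.ndarray,
    completeness: float,
    target_completeness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomly delete present KOs to emulate a lower completeness.

    Each present KO is kept with probability target/actual so the expected
    retained fraction matches the less complete genome's level.
    """
    if target_completeness >= completeness:
        return presence
    keep_p = target_completeness / completeness
    out = presence.copy()
    idx = np.flatnonzero(presence)
    out[idx] = rng.random(idx.size) < keep_p
    return out


def paired_differential_kos(
    pairs: Sequence[MSGPair],
    komatrix: KOMatrix,
    records: Sequence[GenomeRecord],
    n_iter: int = 100,
    seed: int = 0,
    min_pairs: int = 5,
    correct_completeness: bool = True,
) -> list[DifferentialKOResult]:
    """Iterated paired differential-KO test with completeness correction.

    Per iteration and transition type: one random genome is drawn from each
    MSG of every pair; within each genome pair the more complete genome's
    present KOs are randomly censored down to the less complete genome's
    completeness; each KO present in at least one genome of at least one
    pair is tested with a paired-samples Wilcoxon (sign) test across
    pairs; p-values are Benjamini-Hochberg adjusted within the iteration.
    After ``n_iter`` iterations the mean q per KO is reported; KOs with
    mean q < 0.1 are called significant, with direction from the censored
    presence fractions.
    """
    meta = {r.genome_id: r for r in records}
    ko_index = {k: j for j, k in enumerate(komatrix.kos)}
    results: list[DifferentialKOResult] = []
    for ttype in ("FB", "BM", "FM"):
        tpairs = [p for p in pairs if p.type == ttype]
        if len(tpairs) < min_pairs:
            if tpairs:
                warnings.warn(
                    f"type {ttype}: only {len(tpairs)} pairs (<{min_pairs}); skipped"
                )
            continue
        low_biome, high_biome = TYPE_BIOMES[ttype]
        # KO universe: present in >=1 genome of >=1 MSG of this type
        union = np.zeros(len(komatrix.kos), dtype=bool)
        for p in tpairs:
            for t in p.msg_a.tips | p.msg_b.tips:
                if t in komatrix._row:
                    union |= komatrix.row(t)
        ko_cols = np.flatnonzero(union)
        if ko_cols.size == 0:
            continue
        q_sum = np.zeros(ko_cols.size)
        frac_low_sum = np.zeros(ko_cols.size)
        frac_high_sum = np.zeros(ko_cols.size)
        for it in range(n_iter):
            rng = np.random.default_rng(derive_seed(seed, it))
            low_rows = np.zeros((len(tpairs), ko_cols.size), dtype=bool)
            high_rows = np.zeros((len(tpairs), ko_cols.size), dtype=bool)
            for i, p in enumerate(tpairs):
                g_low_tips = sorted(p.msg_for_biome(low_biome).tips)
                g_high_tips = sorted(p.msg_for_biome(high_biome).tips)
                g_low = g_low_tips[rng.integers(len(g_low_tips))]
                g_high = g_high_tips[rng.integers(len(g_high_tips))]
                row_low = komatrix.row(g_low)[ko_cols]
                row_high = komatrix.row(g_high)[ko_cols]
                if correct_completeness:
                    c_low = meta[g_low].completeness
                    c_high = meta[g_high].completeness
                    target = min(c_low, c_high)
                    row_low = censor_presence(row_low, c_low, target, rng)
                    row_high = censor_presence(row_high, c_high, target, rng)
                low_rows[i] = row_low
                high_rows[i] = row_high
            n_pos = (high_rows & ~low_rows).sum(axis=0)   # more in saline
            n_neg = (low_rows & ~high_rows).sum(axis=0)
            pvals = np.array([_sign_test_p(int(a), int(b))
                              for a, b in zip(n_pos, n_neg)])
            qvals = multipletests(pvals, method="fdr_bh")[1]
            q_sum += qvals
            frac_low_sum += low_rows.mean(axis=0)
            frac_high_sum += high_rows.mean(axis=0)
        mean_q = q_sum / n_iter
        frac_low = frac_low_sum / n_iter
        frac_high = frac_high_sum / n_iter
        for j, col in enumerate(ko_cols):
            results.append(
                DifferentialKOResult(
                    ko_id=komatrix.kos[col],
                    transition_type=ttype,
                    mean_q=float(mean_q[j]),
                    direction=(
                        "more_in_saline" if frac_high[j] >= frac_low[j]
                        else "more_in_fresher"
                    ),
                    presence_fraction_fresher=float(frac_low[j]),
                    presence_fraction_saline=float(frac_high[j]),
                )
            )
    return results


def msg_presence(msg: MSG, ko_id: str, komatrix: KOMatrix) -> bool:
    """A KO counts as present in an MSG when >0.5 of its species carry it."""
    j = komatrix.kos.index(ko_id)
    members = [t for t in sorted(msg.tips) if t in komatrix._row]
    if not members:
        return False
    frac = float(np.mean([komatrix.presence[komatrix._row[t], j] for t in members]))
    return frac > 0.5


def gain_loss_map(
    results: Sequence[DifferentialKOResult],
    pairs: Sequence[MSGPair],
    komatrix: KOMatrix,
) -> pd.DataFrame:
    """Presence pattern of significant KOs across MSG pairs (Fig-style map).

    Cells: 'fresher_only', 'saline_only', 'both' or 'neither', using the
    >0.5-of-species MSG presence rule.
    """
    sig = [r for r in results if r.significant]
    rows = []
    for r in sig:
        row: dict[str, object] = {"ko": r.ko_id, "type": r.transition_type,
                                  "direction": r.direction}
        for p in pairs:
            if p.type != r.transition_type:
                continue
            low_b, high_b = TYPE_BIOMES[p.type]
            in_low = msg_presence(p.msg_for_biome(low_b), r.ko_id, komatrix)
            in_high = msg_presence(p.msg_for_biome(high_b), r.ko_id, komatrix)
            cell = {(False, False): "neither", (True, False): "fresher_only",
                    (False, True): "saline_only", (True, True): "both"}[(in_low, in_high)]
            row[p.pair_id] = cell
        rows.append(row)
    return pd.DataFrame(rows)


def unpaired_differential_kos(
    records: Sequence[GenomeRecord],
    komatrix: KOMatrix,
    seed: int = 0,
    biome_pair: tuple[str, str] = ("freshwater", "brackish"),
) -> list[DifferentialKOResult]:
    """Phylogeny-unaware biome comparison of KO presence.

    Every representative genome's present KOs are first thinned to the 75%
    completeness floor (retention probability 0.75 / (completeness/100)),
    then each KO is compared between the two biomes' species with an
    unpaired Wilcoxon rank-sum test and BH correction.  Run on the same
    data as :func:`paired_differential_kos`, this typically returns far
    more hits because clade-level (taxonomic) differences are not
    controlled.
    """
    rng = np.random.default_rng(seed)
    low_b, high_b = biome_pair
    if SALINITY_ORDER[low_b] > SALINITY_ORDER[high_b]:
        low_b, high_b = high_b, low_b
    meta = {r.genome_id: r for r in records}
    ids = [g for g in komatrix.genomes if g in meta and meta[g].biome in (low_b, high_b)]
    thinned = np.zeros((len(ids), len(komatrix.kos)), dtype=bool)
    for i, g in enumerate(ids):
        row = komatrix.row(g)
        thinned[i] = censor_presence(row, meta[g].completeness / 100.0, 0.75, rng)
    is_high = np.array([meta[g].biome == high_b for g in ids])
    tested = np.flatnonzero(thinned.any(axis=0))
    pvals = np.ones(tested.size)
    for j, col in enumerate(tested):
        x = thinned[is_high, col].astype(float)
        y = thinned[~is_high, col].astype(float)
        if x.size == 0 or y.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[j] = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
    qvals = multipletests(pvals, method="fdr_bh")[1] if tested.size else np.array([])
    ttype = {frozenset(("freshwater", "brackish")): "FB",
             frozenset(("brackish", "marine")): "BM",
             frozenset(("freshwater", "marine")): "FM"}[frozenset(biome_pair)]
    out = []
    for j, col in enumerate(tested):
        f_high = float(thinned[is_high, col].mean()) if is_high.any() else 0.0
        f_low = float(thinned[~is_high, col].mean()) if (~is_high).any() else 0.0
        out.append(
            DifferentialKOResult(
                ko_id=komatrix.kos[col],
                transition_type=ttype,
                mean_q=float(qvals[j]),
                direction="more_in_saline" if f_high >= f_low else "more_in_fresher",
                presence_fraction_fresher=f_low,
                presence_fraction_saline=f_high,
            )
        )
    return out
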