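"""Proteome isoelectric-point and amino-acid-composition profiling.

Each protein's isoelectric point (pI) is the pH where the
Henderson–Hasselbalch net charge over its ionizable groups (termini plus
C, D, E, H, K, R, Y side chains) is zero, found by bisection.  Per-genome
profiles bin pI values into 0.5-pH bins over [3.0, 12.5), classify
proteins as acidic [3.0, 5.5), neutral [5.5, 8.5) or basic [8.5, 12.5],
and record amino-acid and category frequencies over the concatenated
proteome.  Profiles are compared across MSG pairs as "value in the more
saline biome minus value in the less saline biome".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .core import SALINITY_ORDER
from .treeops import TYPE_BIOMES, MSGPair

#: pK values of ionizable groups, as used by the EMBOSS pepstats program.
DEFAULT_PK = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
_ACIDIC_GROUPS = ("Cterm", "C", "D", "E", "Y")   # deprotonate to -1
_BASIC_GROUPS = ("Nterm", "H", "K", "R")         # protonate to +1

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: pepstats-compatible amino-acid categories; the charged set is exactly
#: the union of the acidic and basic residues, and polar contains charged.
AA_CATEGORIES = {
    "tiny": set("ACGST"),
    "small": set("ACDGNPSTV"),
    "aliphatic": set("AILV"),
    "aromatic": set("FHWY"),
    "nonpolar": set("ACFGILMPVWY"),
    "polar": set("DEHKNQRST"),
    "charged": set("DEHKR"),
    "acidic_aa": set("DE"),
    "basic_aa": set("HKR"),
}

PI_BIN_EDGES = np.arange(3.0, 13.0, 0.5)   # 19 bins [3.0, 12.5)
N_BINS = len(PI_BIN_EDGES) - 1
CLASS_BOUNDS = {"acidic": (3.0, 5.5), "neutral": (5.5, 8.5), "basic": (8.5, 12.5)}


def load_pk_table(path: str) -> dict[str, float]:
    """Read a two-column TSV (group, pK) overriding the built-in pK set."""
    df = pd.read_csv(path, sep="\t", comment="#")
    table = dict(DEFAULT_PK)
    for grp, pk in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if grp not in table:
            raise ValueError(f"unknown ionizable group {grp!r}")
        table[grp] = float(pk)
    return table


def net_charge(sequence: str, ph: float, pk: Mapping[str, float] = DEFAULT_PK) -> float:
    """Henderson–Hasselbalch net charge of a protein at a given pH.

    Non-canonical residues are ignored; the termini always contribute.
    """
    counts = {g: 0 for g in pk}
    counts["Nterm"] = counts["Cterm"] = 1
    for c in sequence:
        if c in counts:
            counts[c] += 1
    charge = 0.0
    for g in _BASIC_GROUPS:
        if counts[g]:
            charge += counts[g] / (1.0 + 10.0 ** (ph - pk[g]))
    for g in _ACIDIC_GROUPS:
        if counts[g]:
            charge -= counts[g] / (1.0 + 10.0 ** (pk[g] - ph))
    return charge


def protein_pi(
    sequence: str,
    pk: Mapping[str, float] = DEFAULT_PK,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """Isoelectric point: the pH at which the net charge crosses zero.

    The net-charge function is strictly decreasing in pH, so bisection on
    [0, 14] converges to the unique root; iteration stops when
    |charge| < tol.
    """
    if not sequence:
        raise ValueError("empty sequence has no isoelectric point")
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, pk)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def proteome_pis(
    sequences: Sequence[str],
    pk: Mapping[str, float] = DEFAULT_PK,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> np.ndarray:
    """Vectorized pI for many proteins at once.

    Counts each protein's ionizable groups once, then runs the bisection
    simultaneously across the whole proteome; agrees with
    :func:`protein_pi` to the bisection tolerance.
    """
    groups = _BASIC_GROUPS + _ACIDIC_GROUPS
    counts = np.zeros((len(sequences), len(groups)), dtype=np.int64)
    for i, seq in enumerate(sequences):
        for j, g in enumerate(groups):
            if g == "Nterm" or g == "Cterm":
                counts[i, j] = 1
            else:
                counts[i, j] = seq.count(g)
    pks = np.array([pk[g] for g in groups])
    sign = np.array([1.0 if g in _BASIC_GROUPS else -1.0 for g in groups])
    lo = np.zeros(len(sequences))
    hi = np.full(len(sequences), 14.0)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        # charge per group: basic n/(1+10^(pH-pK)), acidic -n/(1+10^(pK-pH))
        expo = sign * (mid[:, None] - pks[None, :])
        charge = (counts * sign / (1.0 + 10.0 ** expo)).sum(axis=1)
        done = np.abs(charge) < tol
        if done.all():
            break
        pos = charge > 0
        lo = np.where(pos & ~done, mid, lo)
        hi = np.where(~pos & ~done, mid, hi)
    return 0.5 * (lo + hi)


@dataclass
class ProteomeProfile:
    """Binned pI distribution and composition of one genome (or MSG mean)."""

    profile_id: str
    pi_bins: np.ndarray            # 19 frequencies, sum 1
    class_fractions: dict[str, float]
    aa_freq: np.ndarray            # 20 frequencies over canonical residues
    category_freq: dict[str, float]
    n_proteins: int
    n_residues: int
    n_clamped: int = 0             # proteins with pI outside [3.0, 12.5)


def pi_distribution(pi_values: Sequence[float]) -> tuple[np.ndarray, dict[str, float], int]:
    """Bin per-protein pI values into the 0.5-pH grid and the three classes.

    Values outside [3.0, 12.5) are clamped into the terminal bins (their
    count is returned so overflow is visible).
    """
    vals = np.asarray(list(pi_values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty proteome: no pI values to bin")
    n_clamped = int(((vals < PI_BIN_EDGES[0]) | (vals >= PI_BIN_EDGES[-1])).sum())
    clamped = np.clip(vals, PI_BIN_EDGES[0], np.nextafter(PI_BIN_EDGES[-1], 0.0))
    idx = np.minimum(((clamped - PI_BIN_EDGES[0]) / 0.5).astype(int), N_BINS - 1)
    bins = np.bincount(idx, minlength=N_BINS).astype(float) / vals.size
    classes = {}
    for name, (lo, hi) in CLASS_BOUNDS.items():
        if name == "basic":
            mask = (clamped >= lo) & (clamped <= hi)
        else:
            mask = (clamped >= lo) & (clamped < hi)
        classes[name] = float(mask.sum()) / vals.size
    return bins, classes, n_clamped


def aa_composition(sequences: Sequence[str]) -> tuple[np.ndarray, dict[str, float], int]:
    """Residue and category frequencies over the concatenated proteome.

    Non-canonical residues (B, Z, X, U, O, *) are excluded from both the
    numerator and denominator; their count is returned.
    """
    concat = "".join(sequences)
    counts = np.array([concat.count(a) for a in AMINO_ACIDS], dtype=np.int64)
    n_skipped = len(concat) - int(counts.sum())
    total = counts.sum()
    if total == 0:
        raise ValueError("no canonical residues in proteome")
    freq = counts / total
    cat = {
        name: float(sum(freq[_AA_INDEX[a]] for a in members))
        for name, members in AA_CATEGORIES.items()
    }
    return freq, cat, n_skipped


def profile_proteome(
    profile_id: str,
    sequences: Sequence[str],
    pk: Mapping[str, float] = DEFAULT_PK,
) -> ProteomeProfile:
    """Full per-genome profile: pI distribution plus composition."""
    if not sequences:
        raise ValueError(f"{profile_id}: empty proteome")
    pis = proteome_pis(sequences, pk)
    bins, classes, n_clamped = pi_distribution(pis)
    freq, cats, _ = aa_composition(sequences)
    return ProteomeProfile(
        profile_id=profile_id,
        pi_bins=bins,
        class_fractions=classes,
        aa_freq=freq,
        category_freq=cats,
        n_proteins=len(sequences),
        n_residues=sum(len(s) for s in sequences),
        n_clamped=n_clamped,
    )


def msg_profile(
    msg_id: str, member_profiles: Sequence[ProteomeProfile]
) -> ProteomeProfile:
    """Unweighted mean of member profiles (MSGs with more than one genome)."""
    if not member_profiles:
        raise ValueError(f"MSG {msg_id}: no member profiles")
    n = len(member_profiles)
    return ProteomeProfile(
        profile_id=msg_id,
        pi_bins=np.mean([p.pi_bins for p in member_profiles], axis=0),
        class_fractions={
            k: float(np.mean([p.class_fractions[k] for p in member_profiles]))
            for k in member_profiles[0].class_fractions
        },
        aa_freq=np.mean([p.aa_freq for p in member_profiles], axis=0),
        category_freq={
            k: float(np.mean([p.category_freq[k] for p in member_profiles]))
            for k in member_profiles[0].category_freq
        },
        n_proteins=int(np.mean([p.n_proteins for p in member_profiles])),
        n_residues=int(np.mean([p.n_residues for p in member_profiles])),
        n_clamped=sum(p.n_clamped for p in member_profiles),
    )


def total_pi_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of absolute per-bin differences of two pI distributions (in [0, 2])."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pI bin vectors must share the same binning")
    return float(np.abs(a - b).sum())


@dataclass
class TransitionDelta:
    """Per-pair profile differences oriented more-saline minus less-saline."""

    pair_id: str
    type: str
    bin_deltas: np.ndarray
    class_deltas: dict[str, float]
    category_deltas: dict[str, float]
    aa_deltas: np.ndarray
    total_pi_difference: float


@dataclass
class TransitionComparison:
    deltas: list[TransitionDelta]
    tests: pd.DataFrame    # columns: type, quantity, n, median_delta, p_raw, p_bonf
    excluded_types: list[str] = field(default_factory=list)


def _oriented_profiles(
    pair: MSGPair, profiles: Mapping[str, ProteomeProfile]
) -> tuple[ProteomeProfile, ProteomeProfile]:
    """(less saline, more saline) member profiles of a pair."""
    a, b = pair.msg_a, pair.msg_b
    if SALINITY_ORDER[a.biome] > SALINITY_ORDER[b.biome]:
        a, b = b, a
    key_a = f"{pair.pair_id}:{a.biome}"
    key_b = f"{pair.pair_id}:{b.biome}"
    return profiles[key_a], profiles[key_b]


def pair_profile_key(pair: MSGPair, biome: str) -> str:
    return f"{pair.pair_id}:{biome}"


def compare_transitions(
    pairs: Sequence[MSGPair],
    profiles: Mapping[str, ProteomeProfile],
    min_pairs: int = 1,
) -> TransitionComparison:
    """Profile deltas across MSG pairs and per-type significance tests.

    For each transition type and each quantity (pI bin, pI class,
    amino-acid category, residue frequency), a Wilcoxon signed-rank test
    asks whether the per-pair saline-minus-fresh delta is located away
    from 0; zero deltas are dropped and p-values Bonferroni-corrected
    across all quantities tested within the type.
    """
    deltas: list[TransitionDelta] = []
    for p in pairs:
        low, high = _oriented_profiles(p, profiles)
        deltas.append(
            TransitionDelta(
                pair_id=p.pair_id,
                type=p.type,
                bin_deltas=high.pi_bins - low.pi_bins,
                class_deltas={
                    k: high.class_fractions[k] - low.class_fractions[k]
                    for k in low.class_fractions
                },
                category_deltas={
                    k: high.category_freq[k] - low.category_freq[k]
                    for k in low.category_freq
                },
                aa_deltas=high.aa_freq - low.aa_freq,
                total_pi_difference=total_pi_difference(high.pi_bins, low.pi_bins),
            )
        )
    rows = []
    excluded = []
    for ttype in ("FB", "BM", "FM"):
        sub = [d for d in deltas if d.type == ttype]
        if len(sub) < max(min_pairs, 1):
            excluded.append(ttype)
            continue
        quantities: dict[str, np.ndarray] = {}
        for j in range(N_BINS):
            lo = PI_BIN_EDGES[j]
            quantities[f"pi_bin_{lo:.1f}"] = np.array([d.bin_deltas[j] for d in sub])
        for k in CLASS_BOUNDS:
            quantities[f"class_{k}"] = np.array([d.class_deltas[k] for d in sub])
        for k in AA_CATEGORIES:
            quantities[f"cat_{k}"] = np.array([d.category_deltas[k] for d in sub])
        for a in AMINO_ACIDS:
            quantities[f"aa_{a}"] = np.array([d.aa_deltas[_AA_INDEX[a]] for d in sub])
        n_tests = len(quantities)
        for name, vals in quantities.items():
            nz = vals[vals != 0.0]
            if nz.size == 0:
                p_raw = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p_raw = float(wilcoxon(nz).pvalue)
            rows.append(
                {
                    "type": ttype,
                    "quantity": name,
                    "n": len(vals),
                    "median_delta": float(np.median(vals)),
                    "p_raw": p_raw,
                    "p_bonf": min(1.0, p_raw * n_tests),
                }
            )
    if excluded:
        warnings.warn(f"transition types with too few pairs: {excluded}")
    return TransitionComparison(
        deltas=deltas, tests=pd.DataFrame(rows), excluded_types=excluded
    )


@dataclass
class LogFit:
    """Least-squares fit of y = alpha + beta * ln(t)."""

    group: str
    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    n: int
    cov: np.ndarray

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.alpha + self.beta * np.log(t)

    def mean_se(self, t: np.ndarray) -> np.ndarray:
        x = np.column_stack([np.ones_like(t), np.log(t)])
        var = np.einsum("ij,jk,ik->i", x, self.cov, x)
        return np.sqrt(np.maximum(var, 0.0))


def fit_log_curve(group: str, times: np.ndarray, values: np.ndarray) -> LogFit:
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be positive for the logarithmic fit")
    if times.size < 3:
        raise ValueError("need at least 3 points per group")
    x = np.column_stack([np.ones_like(times), np.log(times)])
    coef, *_ = np.linalg.lstsq(x, values, rcond=None)
    resid = values - x @ coef
    dof = max(times.size - 2, 1)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    cov = s2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    return LogFit(group=group, alpha=float(coef[0]), beta=float(coef[1]),
                  alpha_se=float(se[0]), beta_se=float(se[1]),
                  n=int(times.size), cov=cov)


def fit_difference_vs_time(
    points: Mapping[str, tuple[np.ndarray, np.ndarray]],
    reference_group: str = "none",
    n_grid: int = 200,
) -> tuple[dict[str, LogFit], dict[str, Optional[float]]]:
    """Fit total-pI-difference vs time curves and find separation times.

    ``points`` maps group ("FB"/"BM"/"FM"/"none") to (times Ma, total pI
    differences).  For each transition group, the separation time is the
    smallest grid time from which the ±1 SE bands of its fit and the
    no-transition fit no longer overlap anywhere to the right; None when
    the bands still overlap at the largest observed time.
    """
    fits = {g: fit_log_curve(g, t, y) for g, (t, y) in points.items()}
    if reference_group not in fits:
        raise ValueError(f"no points for reference group {reference_group!r}")
    ref = fits[reference_group]
    all_times = np.concatenate([np.asarray(t, dtype=float) for t, _ in points.values()])
    grid = np.geomspace(all_times.min(), all_times.max(), n_grid)
    ref_mu = ref.predict(grid)
    ref_se = ref.mean_se(grid)
    separation: dict[str, Optional[float]] = {}
    for g, fit in fits.items():
        if g == reference_group:
            continue
        mu = fit.predict(grid)
        se = fit.mean_se(grid)
        disjoint = (mu - se > ref_mu + ref_se) | (mu + se < ref_mu - ref_se)
        sep = None
        # smallest grid time with no overlap from there on
        suffix_ok = np.flip(np.logical_and.accumulate(np.flip(disjoint)))
        idx = np.argmax(suffix_ok) if suffix_ok.any() else None
        if suffix_ok.any():
            sep = float(grid[idx])
        separation[g] = sep
    return fits, separation


def posttransition_convergence(
    cross_diffs: np.ndarray,
    within_diffs: np.ndarray,
    cross_times: np.ndarray,
    within_times: np.ndarray,
    alpha: float = 0.05,
    min_points: int = 5,
) -> tuple[Optional[float], pd.DataFrame]:
    """Time since transition beyond which proteomes have measurably diverged.

    For matched pairs, Δy = cross-transition total pI difference minus the
    within-MSG (post-transition) one, and Δt the difference of the
    corresponding ages.  The excess Δy emerges once the transition is much
    older than the within-MSG divergence, so candidate thresholds τ scan
    the observed Δt values and the returned threshold is the largest τ at
    which the one-sided signed-rank test of {Δy : Δt <= τ} > 0 is *not*
    significant — up to that age gap the transition has not yet produced a
    measurable pI shift.  Returns float('-inf') ("< min") when even the
    smallest testable gap set is significant, and the scan table for
    inspection.
    """
    dy = np.asarray(cross_diffs, dtype=float) - np.asarray(within_diffs, dtype=float)
    dt = np.asarray(cross_times, dtype=float) - np.asarray(within_times, dtype=float)
    order = np.argsort(dt)
    dy, dt = dy[order], dt[order]
    taus = np.unique(dt)
    usable = [tau for tau in taus if (dt <= tau).sum() >= min_points]
    if len(usable) < len(taus):
        warnings.warn("candidate thresholds truncated: fewer than "
                      f"{min_points} points below the smallest ones")
    rows = []
    not_significant: list[float] = []
    for tau in usable:
        vals = dy[dt <= tau]
        nz = vals[vals != 0.0]
        if nz.size == 0:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(wilcoxon(nz, alternative="greater").pvalue)
        rows.append({"tau": float(tau), "n": int(vals.size), "p_greater": p})
        if p >= alpha:
            not_significant.append(float(tau))
    scan = pd.DataFrame(rows)
    if not usable:
        return None, scan
    if not not_significant:
        return float("-inf"), scan
    return max(not_significant), scan
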