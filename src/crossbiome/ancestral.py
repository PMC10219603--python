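"""Maximum-likelihood Mk ancestral biome reconstruction (all-rates-different).

The biome character evolves on the tree under a 3-state continuous-time
Markov model with six free instantaneous rates (Mk-ARD).  The likelihood
is computed with Felsenstein's pruning algorithm; the six rates are fitted
by multi-start box-constrained quasi-Newton optimization on log-rates.
Marginal (empirical-Bayes) state probabilities at internal nodes are
obtained from the up/down pass under the fitted rate matrix.

Transition *directions* are inferred with a biome-balanced downsampling
protocol: one genome is kept per MSG, additional non-MSG tips are drawn so
all three biomes have equal representation, the model is refitted on the
restricted tree, and the MRCA marginals of every MSG pair are averaged
over iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import ranksums

from .core import BIOMES, GenomeRecord, LabeledTree, derive_seed
from .treeops import MSGPair

STATES = BIOMES  # ordered (freshwater, brackish, marine)
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

RATE_MIN = 1e-8
RATE_MAX = 1e3


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, best_rates=None, grad_norm=None):
        super().__init__(message)
        self.best_rates = best_rates
        self.grad_norm = grad_norm


@dataclass
class ARDModel:
    states: tuple[str, ...]
    rates: np.ndarray          # 3x3 Q matrix, rows sum to 0
    log_likelihood: float

    @property
    def off_diagonal(self) -> np.ndarray:
        q = self.rates
        return np.array([q[i, j] for i in range(3) for j in range(3) if i != j])


def _q_from_params(params: np.ndarray) -> np.ndarray:
    """Six off-diagonal rates (order: 01,02,10,12,20,21) to a Q matrix."""
    q = np.zeros((3, 3))
    k = 0
    for i in range(3):
        for j in range(3):
            if i != j:
                q[i, j] = params[k]
                k += 1
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


class TreeData:
    """Array form of a bifurcating tree for fast pruning-likelihood passes."""

    def __init__(self, tree: LabeledTree, tip_states: dict[str, str]):
        nodes = list(tree.tree.postorder_node_iter())
        self.n = len(nodes)
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.nodes = nodes
        self.children: list[Optional[tuple[int, int]]] = []
        self.edge_len = np.zeros(self.n)
        self.tip_state = np.full(self.n, -1, dtype=int)
        for nd in nodes:
            i = self.index[id(nd)]
            if nd.edge.length is not None:
                self.edge_len[i] = nd.edge.length
            kids = nd.child_nodes()
            if not kids:
                self.children.append(None)
                self.tip_state[i] = _STATE_INDEX[tip_states[nd.taxon.label]]
            else:
                if len(kids) != 2:
                    raise ValueError("ARD likelihood requires a bifurcating tree")
                self.children.append((self.index[id(kids[0])], self.index[id(kids[1])]))
        self.root = self.n - 1
        self.internal = [i for i, c in enumerate(self.children) if c is not None]

    def node_index(self, node) -> int:
        return self.index[id(node)]


def _edge_pmats(q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for every edge, via one eigendecomposition of Q.

    Falls back to scipy's expm per edge when Q is close to defective.
    """
    vals, vecs = np.linalg.eig(q)
    use_eig = True
    try:
        if np.linalg.cond(vecs) > 1e8:
            use_eig = False
        else:
            vinv = np.linalg.inv(vecs)
    except np.linalg.LinAlgError:
        use_eig = False
    if use_eig:
        ex = np.exp(np.outer(lengths, vals))        # E x 3
        p = np.einsum("ij,ej,jk->eik", vecs, ex, vinv)
        p = np.real(p)
    else:
        from scipy.linalg import expm

        p = np.stack([expm(q * t) for t in lengths])
    # floor keeps numerically-zero transition probabilities positive so a
    # single unresolvable entry cannot zero out a whole subtree
    np.clip(p, 1e-300, None, out=p)
    return p


def _partials(td: TreeData, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Scaled conditional likelihoods at every node plus log scaling total."""
    pmats = _edge_pmats(q, td.edge_len)
    down = np.zeros((td.n, 3))
    log_scale = 0.0
    for i in range(td.n):
        kids = td.children[i]
        if kids is None:
            down[i, td.tip_state[i]] = 1.0
            continue
        a, b = kids
        la = pmats[a] @ down[a]
        lb = pmats[b] @ down[b]
        v = la * lb
        s = v.sum()
        if s <= 0 or not np.isfinite(s):
            return down, -np.inf
        down[i] = v / s
        log_scale += np.log(s)
    return down, log_scale


def log_likelihood(
    td: TreeData, q: np.ndarray, root_prior: str = "fitzjohn"
) -> float:
    """Pruning-algorithm log-likelihood of tip states under Q.

    root_prior 'flat' sums the root partial likelihoods (each root state
    weighted 1), matching exhaustive enumeration over all internal-state
    assignments; 'fitzjohn' weights each root state by its share of the
    root partials (conditional weighting, the default for fitting).
    """
    down, log_scale = _partials(td, q)
    if not np.isfinite(log_scale):
        return -np.inf
    root = down[td.root]
    if root_prior == "flat":
        lik = root.sum()
    elif root_prior == "fitzjohn":
        tot = root.sum()
        lik = float((root * (root / tot)).sum()) if tot > 0 else 0.0
    else:
        raise ValueError(f"unknown root prior {root_prior!r}")
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def fit_ard(
    tree: LabeledTree,
    tip_states: dict[str, str],
    n_starts: int = 3,
    seed: int = 0,
    root_prior: str = "fitzjohn",
) -> ARDModel:
    """Fit the six ARD rates by maximum likelihood.

    Multi-start L-BFGS-B on log-rates (bounds [1e-8, 1e3] per unit branch
    length); the ARD surface on three states can be multimodal, so the best
    of the starts is returned.  Monomorphic tip data yield rates at the
    lower bound (no change is the ML explanation).
    """
    td = TreeData(tree, tip_states)
    observed_states = {tip_states[lab] for lab in
                       (nd.taxon.label for nd in tree.tree.leaf_node_iter())}
    # rate bounds are per unit branch length: normalize so the mean edge
    # is 1, which also conditions the optimization on time-scaled trees
    edge_scale = float(np.mean(td.edge_len[td.edge_len > 0]))
    raw_len = td.edge_len
    td.edge_len = raw_len / edge_scale
    n_edges = max((td.edge_len > 0).sum(), 1)

    def nll(log_params):
        ll = log_likelihood(td, _q_from_params(np.exp(log_params)), root_prior)
        # finite penalty keeps quasi-Newton line searches NaN-free
        return -ll if np.isfinite(ll) else 1e10

    bounds = [(np.log(RATE_MIN), np.log(RATE_MAX))] * 6
    rng = np.random.default_rng(seed)
    # heuristic start: a few expected changes over the whole tree
    starts = [np.full(6, np.log(3.0 / n_edges))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(np.log(0.1 / n_edges), np.log(30.0 / n_edges), 6))
    best = None
    for x0 in starts:
        res = minimize(nll, np.clip(x0, bounds[0][0], bounds[0][1]),
                       method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    td.edge_len = raw_len
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise ConvergenceError(
            "ARD optimization failed to find a finite optimum",
            best_rates=None if best is None else np.exp(best.x) / edge_scale,
            grad_norm=None if best is None else float(np.linalg.norm(best.jac)),
        )
    if len(observed_states) < 2:
        # monomorphic data: likelihood is maximized as rates -> 0
        q = _q_from_params(np.full(6, RATE_MIN))
        return ARDModel(states=STATES, rates=q,
                        log_likelihood=log_likelihood(td, q, root_prior))
    q = _q_from_params(np.exp(best.x)) / edge_scale
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return ARDModel(states=STATES, rates=q, log_likelihood=-float(best.fun))


def marginal_at_node(
    model: ARDModel,
    tree: LabeledTree,
    tip_states: dict[str, str],
    node,
) -> np.ndarray:
    """Empirical-Bayes marginal posterior of one internal node's state.

    Combines the node's downward partial likelihoods with the likelihood of
    the rest of the tree (up-pass), under the fitted Q and a flat root
    weighting, and normalizes to sum to 1.
    """
    td = TreeData(tree, tip_states)
    i = td.node_index(node)
    if td.children[i] is None:
        raise ValueError("marginals are defined for internal nodes")
    down, log_scale = _partials(td, model.rates)
    if not np.isfinite(log_scale):
        raise ValueError("zero likelihood under supplied model")
    up = _up_pass(td, model.rates, down)
    post = down[i] * up[i]
    return post / post.sum()


def _up_pass(td: TreeData, q: np.ndarray, down: np.ndarray) -> np.ndarray:
    """Likelihood of everything outside each node's subtree, per state."""
    pmats = _edge_pmats(q, td.edge_len)
    up = np.zeros((td.n, 3))
    up[td.root] = 1.0
    for i in reversed(range(td.n)):
        kids = td.children[i]
        if kids is None:
            continue
        a, b = kids
        la = pmats[a] @ down[a]
        lb = pmats[b] @ down[b]
        for child, other_contrib in ((a, lb), (b, la)):
            v = up[i] * other_contrib
            res = v @ pmats[child]
            s = res.sum()
            up[child] = res / s if s > 0 else res
    return up


@dataclass
class DirectionResult:
    n_iter: int
    pair_ids: list[str]
    pair_types: dict[str, str]
    mean_marginals: dict[str, np.ndarray]     # pair_id -> 3 probs (F,B,M)
    type_mean_p: dict[str, float]             # Wilcoxon rank-sum, per type
    calls: dict[str, str]                     # pair_id -> destination biome or "undecided"
    warnings: list[str] = field(default_factory=list)

    def recovery_fraction(self, expected_call: str, pair_type: str) -> float:
        ids = [p for p in self.pair_ids if self.pair_types[p] == pair_type]
        if not ids:
            return float("nan")
        return sum(self.calls[p] == expected_call for p in ids) / len(ids)


def _balanced_tip_sample(
    tips_by_biome: dict[str, list[str]],
    msg_reps: dict[str, str],          # msg key -> chosen representative tip
    rep_biome: dict[str, str],
    rng: np.random.Generator,
    warnings_out: list[str],
) -> list[str]:
    reps_by_biome: dict[str, list[str]] = {b: [] for b in BIOMES}
    for rep in msg_reps.values():
        reps_by_biome[rep_biome[rep]].append(rep)
    collapsed = {}
    for b in BIOMES:
        non_msg = tips_by_biome.get(b, [])
        collapsed[b] = len(reps_by_biome[b]) + len(non_msg)
        if collapsed[b] == 0:
            raise ValueError(f"cannot balance biomes: no tips from {b}")
    target = min(collapsed.values())
    chosen: list[str] = []
    for b in BIOMES:
        reps = reps_by_biome[b]
        if len(reps) >= target:
            if len(reps) > target:
                warnings_out.append(
                    f"{b}: {len(reps)} MSG representatives exceed balance "
                    f"target {target}; keeping all representatives"
                )
            chosen.extend(reps)
            continue
        pool = tips_by_biome.get(b, [])
        extra = rng.choice(len(pool), size=target - len(reps), replace=False)
        chosen.extend(reps)
        chosen.extend(pool[k] for k in sorted(extra))
    return chosen


def balanced_direction_inference(
    tree: LabeledTree,
    msg_pairs: Sequence[MSGPair],
    records: Sequence[GenomeRecord],
    n_iter: int = 100,
    seed: int = 0,
    n_starts: int = 3,
) -> DirectionResult:
    """Infer transition directions from MRCA marginals on balanced subsamples.

    Per iteration: one random tip is kept per MSG; non-MSG tips are then
    drawn so each biome contributes the same number of tips (the smallest
    per-biome count after MSG collapsing).  The ARD model is refitted on
    the restricted tree and the MRCA marginal of every MSG pair recorded.
    Marginals are averaged over iterations; per transition type a Wilcoxon
    rank-sum test compares the two origin-biome likelihood vectors across
    pairs, and a pair is called "into X" when the *other* biome's mean
    origin probability exceeds 0.5 (i.e. beats the two alternatives
    combined).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    biome_of = {r.genome_id: r.biome for r in records}
    all_tips = tree.tip_labels()
    msg_tips: set[str] = set()
    msgs = {}
    for p in msg_pairs:
        msgs[(p.pair_id, "a")] = sorted(p.msg_a.tips)
        msgs[(p.pair_id, "b")] = sorted(p.msg_b.tips)
        msg_tips |= p.msg_a.tips | p.msg_b.tips
    tips_by_biome: dict[str, list[str]] = {b: [] for b in BIOMES}
    for t in all_tips:
        if t not in msg_tips:
            tips_by_biome[biome_of[t]].append(t)
    pair_ids = [p.pair_id for p in msg_pairs]
    pair_types = {p.pair_id: p.type for p in msg_pairs}
    acc = {pid: np.zeros(3) for pid in pair_ids}
    type_p_acc: dict[str, list[float]] = {t: [] for t in ("FB", "BM", "FM")}
    warns: list[str] = []
    for it in range(n_iter):
        rng = np.random.default_rng(derive_seed(seed, it))
        reps = {key: tips[rng.integers(len(tips))] for key, tips in msgs.items()}
        rep_biome = {tip: biome_of[tip] for tip in reps.values()}
        chosen = _balanced_tip_sample(tips_by_biome, reps, rep_biome, rng, warns)
        sub = tree.clone()
        sub.tree.retain_taxa_with_labels(sorted(set(chosen)))
        sub.tree.suppress_unifurcations()
        while len(sub.tree.seed_node.child_nodes()) == 1:
            child = sub.tree.seed_node.child_nodes()[0]
            sub.tree.seed_node = child
            child.parent_node = None
            child.edge.length = None
        states = {t: biome_of[t] for t in sub.tip_labels()}
        model = fit_ard(sub, states, n_starts=n_starts, seed=derive_seed(seed, it))
        taxa = {tx.label: tx for tx in sub.tree.taxon_namespace}
        iter_marg: dict[str, np.ndarray] = {}
        for p in msg_pairs:
            ta = taxa[reps[(p.pair_id, "a")]]
            tb = taxa[reps[(p.pair_id, "b")]]
            mrca = sub.tree.mrca(taxa=[ta, tb])
            marg = marginal_at_node(model, sub, states, mrca)
            acc[p.pair_id] += marg
            iter_marg[p.pair_id] = marg
        for ttype, (b_low, b_high) in (
            ("FB", ("freshwater", "brackish")),
            ("BM", ("brackish", "marine")),
            ("FM", ("freshwater", "marine")),
        ):
            ids = [pid for pid in pair_ids if pair_types[pid] == ttype]
            if len(ids) < 2:
                continue
            x = [iter_marg[pid][_STATE_INDEX[b_low]] for pid in ids]
            y = [iter_marg[pid][_STATE_INDEX[b_high]] for pid in ids]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                type_p_acc[ttype].append(float(ranksums(x, y).pvalue))
    mean_marg = {pid: acc[pid] / n_iter for pid in pair_ids}
    calls = {}
    for p in msg_pairs:
        m = mean_marg[p.pair_id]
        ia, ib = _STATE_INDEX[p.msg_a.biome], _STATE_INDEX[p.msg_b.biome]
        if m[ia] > 0.5:
            calls[p.pair_id] = f"into_{p.msg_b.biome}"
        elif m[ib] > 0.5:
            calls[p.pair_id] = f"into_{p.msg_a.biome}"
        else:
            calls[p.pair_id] = "undecided"
    type_mean_p = {t: (float(np.mean(v)) if v else float("nan"))
                   for t, v in type_p_acc.items()}
    return DirectionResult(
        n_iter=n_iter,
        pair_ids=pair_ids,
        pair_types=pair_types,
        mean_marginals=mean_marg,
        type_mean_p=type_mean_p,
        calls=calls,
        warnings=warns,
    )
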