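"""Mk-model inference and stochastic mapping of bias gain/loss on a species tree.

Generation bias is encoded as two independent binary characters per
orthogroup (GA-bias present / SP-bias present).  Each character evolves under
a two-state continuous-time Markov chain with gain rate q01 (unbiased ->
biased) and loss rate q10.  The equal-rates model (ER, q01 = q10) is compared
against the all-rates-different model (ARD) by a likelihood-ratio test, and
character histories are sampled conditional on the tip states (stochastic
mapping).  Following the endpoint-counting rule, an event is recorded on a
branch only when the sampled states at its two ends differ: a gain when the
parent is 0 and the child 1, a loss for the reverse.  Within-branch multiple
hits therefore deliberately do not contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats

RATE_BOUNDS = (1e-8, 1e3)
_N_MULTISTART = 5

MISSING = -1  # tip-state code for a missing species


# ---------------------------------------------------------------------------
# tree indexing


@dataclass
class Phylogeny:
    """A rooted tree compiled into arrays for fast pruning.

    Nodes are numbered in postorder; every non-root node carries a branch id
    derived from the sorted leaf set below it (stable across runs and across
    child reorderings).
    """

    newick: str
    postorder: list[int] = field(default_factory=list)
    children: dict[int, list[int]] = field(default_factory=dict)
    parent: dict[int, int] = field(default_factory=dict)
    blen: dict[int, float] = field(default_factory=dict)
    leaf_index: dict[str, int] = field(default_factory=dict)
    branch_id: dict[int, str] = field(default_factory=dict)
    root: int = -1

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        self = cls(newick=newick)
        nodes = list(tree.postorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        leafsets: dict[int, tuple[str, ...]] = {}
        for n in nodes:
            i = idx[id(n)]
            self.postorder.append(i)
            kids = [idx[id(c)] for c in n.child_nodes()]
            self.children[i] = kids
            for c in n.child_nodes():
                self.parent[idx[id(c)]] = i
                bl = c.edge.length
                if bl is None or bl <= 0:
                    raise ValueError("all branch lengths must be positive")
                self.blen[idx[id(c)]] = float(bl)
            if n.is_leaf():
                name = n.taxon.label.replace(" ", "_")
                if name in self.leaf_index:
                    raise ValueError(f"duplicate leaf label {name!r}")
                self.leaf_index[name] = i
                leafsets[i] = (name,)
            else:
                ls: list[str] = []
                for c in kids:
                    ls.extend(leafsets[c])
                leafsets[i] = tuple(sorted(ls))
        self.root = self.postorder[-1]
        for i in self.postorder:
            if i != self.root:
                self.branch_id[i] = "|".join(leafsets[i])
        return self

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_index)

    @property
    def branch_ids(self) -> list[str]:
        return sorted(self.branch_id.values())


@dataclass(frozen=True)
class MkModel:
    """Two-state Mk model: q01 = gain rate, q10 = loss rate."""

    q01: float
    q10: float
    root_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        if abs(sum(self.root_prior) - 1.0) > 1e-9:
            raise ValueError("root prior must sum to 1")

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t) in closed form for the 2-state chain."""
        q = self.q01 + self.q10
        if q == 0.0:
            return np.eye(2)
        e = math.exp(-q * t)
        return np.array(
            [
                [(self.q10 + self.q01 * e) / q, self.q01 * (1 - e) / q],
                [self.q10 * (1 - e) / q, (self.q01 + self.q10 * e) / q],
            ]
        )


def _tip_partial(state: int) -> np.ndarray:
    if state == MISSING:
        return np.ones(2)
    if state not in (0, 1):
        raise ValueError(f"tip states must be 0, 1 or missing; got {state}")
    v = np.zeros(2)
    v[state] = 1.0
    return v


def _states_to_array(tree: Phylogeny, tip_states: dict[str, int]) -> dict[int, int]:
    unknown = set(tip_states) - set(tree.leaf_index)
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    out = {}
    for leaf, i in tree.leaf_index.items():
        out[i] = int(tip_states.get(leaf, MISSING))
    return out


def _partials(tree: Phylogeny, tip_states: dict[str, int], model: MkModel) -> dict[int, np.ndarray]:
    """Postorder conditional likelihoods L_v[s] = P(tips below v | v = s)."""
    states = _states_to_array(tree, tip_states)
    L: dict[int, np.ndarray] = {}
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            L[i] = _tip_partial(states[i])
        else:
            v = np.ones(2)
            for c in kids:
                P = model.transition_matrix(tree.blen[c])
                v = v * (P @ L[c])
            L[i] = v
    return L


def mk_loglik(tree: Phylogeny, tip_states: dict[str, int], model: MkModel) -> float:
    """Log-likelihood of the tip states by Felsenstein pruning."""
    L = _partials(tree, tip_states, model)
    lik = float(np.dot(model.root_prior, L[tree.root]))
    if lik <= 0.0:
        return -np.inf
    return math.log(lik)


# ---------------------------------------------------------------------------
# ML fitting and the ER/ARD likelihood-ratio test


@dataclass
class MkFit:
    model: MkModel
    lnL: float
    kind: str  # "ER" | "ARD"
    invariant: bool = False


def _is_invariant(tip_states: dict[str, int]) -> int | None:
    """The shared state if all non-missing tips agree (or all missing), else None."""
    seen = {s for s in tip_states.values() if s != MISSING}
    if len(seen) <= 1:
        return next(iter(seen), 0)
    return None


def fit_mk(
    tree: Phylogeny,
    tip_states: dict[str, int],
    kind: str = "ER",
    root_prior: tuple[float, float] = (0.5, 0.5),
    n_starts: int = _N_MULTISTART,
    seed: int = 20200615,
) -> MkFit:
    """Maximum-likelihood Mk rates by bounded optimization on log-rates.

    ER constrains q01 = q10.  Invariant tip patterns pin the rate at the
    lower bound (no change is ever implied by the data).
    """
    if all(s == MISSING for s in tip_states.values()) or not tip_states:
        raise ValueError("all tip states missing; nothing to fit")
    if kind not in ("ER", "ARD"):
        raise ValueError("kind must be 'ER' or 'ARD'")

    if _is_invariant(tip_states) is not None:
        lo = RATE_BOUNDS[0]
        model = MkModel(lo, lo, root_prior)
        return MkFit(model=model, lnL=mk_loglik(tree, tip_states, model), kind=kind, invariant=True)

    ndim = 1 if kind == "ER" else 2
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])

    def neg(params: np.ndarray) -> float:
        r = np.exp(params)
        model = MkModel(r[0], r[0] if ndim == 1 else r[1], root_prior)
        return -mk_loglik(tree, tip_states, model)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(ndim)] + [rng.uniform(math.log(1e-2), math.log(10.0), ndim) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * ndim)
        if best is None or res.fun < best.fun:
            best = res
    r = np.exp(best.x)
    model = MkModel(float(r[0]), float(r[0] if ndim == 1 else r[1]), root_prior)
    return MkFit(model=model, lnL=-float(best.fun), kind=kind)


def fit_mk_pooled(
    tree: Phylogeny,
    tip_state_tables: list[dict[str, int]],
    kind: str = "ER",
    root_prior: tuple[float, float] = (0.5, 0.5),
    n_starts: int = _N_MULTISTART,
    seed: int = 20200615,
) -> MkFit:
    """One Mk model fitted jointly to many genes (summed log-likelihood).

    Single-gene rate MLEs on a small tree often sit on a bound; pooling over
    genes gives a well-behaved estimate of the shared turnover rate.
    Identical tip patterns are collapsed to pattern counts.
    """
    if not tip_state_tables:
        raise ValueError("no genes to fit")
    if kind not in ("ER", "ARD"):
        raise ValueError("kind must be 'ER' or 'ARD'")
    from collections import Counter

    patterns = Counter(tuple(sorted(t.items())) for t in tip_state_tables)
    ndim = 1 if kind == "ER" else 2
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])

    def neg(params: np.ndarray) -> float:
        r = np.exp(params)
        model = MkModel(r[0], r[0] if ndim == 1 else r[1], root_prior)
        return -sum(
            mult * mk_loglik(tree, dict(pat), model) for pat, mult in patterns.items()
        )

    rng = np.random.default_rng(seed)
    starts = [np.zeros(ndim)] + [rng.uniform(math.log(1e-2), math.log(10.0), ndim) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * ndim)
        if best is None or res.fun < best.fun:
            best = res
    r = np.exp(best.x)
    model = MkModel(float(r[0]), float(r[0] if ndim == 1 else r[1]), root_prior)
    return MkFit(model=model, lnL=-float(best.fun), kind=kind)


def lrt_er_ard(lnl_er: float, lnl_ard: float) -> float:
    """ER-vs-ARD likelihood-ratio p (chi-squared, df = 1; negative statistics
    from optimizer jitter clamped to 0)."""
    stat = max(0.0, 2.0 * (lnl_ard - lnl_er))
    return float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# stochastic mapping (endpoint counting) and its exact counterpart


def _outside(tree: Phylogeny, L: dict[int, np.ndarray], model: MkModel) -> dict[int, np.ndarray]:
    """Downward pass: O_v[s] = P(data outside v's subtree, v = s)."""
    O: dict[int, np.ndarray] = {tree.root: np.asarray(model.root_prior, dtype=float)}
    for i in reversed(tree.postorder):
        for c in tree.children[i]:
            sib_msg = np.ones(2)
            for s in tree.children[i]:
                if s != c:
                    P = model.transition_matrix(tree.blen[s])
                    sib_msg = sib_msg * (P @ L[s])
            P = model.transition_matrix(tree.blen[c])
            O[c] = (O[i] * sib_msg) @ P
    return O


def expected_endpoint_changes_exact(
    tree: Phylogeny, tip_states: dict[str, int], model: MkModel
) -> dict[str, dict[str, float]]:
    """Exact posterior probabilities of an endpoint change per branch.

    For the branch above node c with parent u, the gain probability is
    P(u = 0, c = 1 | tips) computed from inside (pruning) and outside
    passes; losses mirrored.  These are the n_maps -> infinity limits of the
    stochastic-mapping event expectations.
    """
    L = _partials(tree, tip_states, model)
    O = _outside(tree, L, model)
    evidence = float(np.dot(model.root_prior, L[tree.root]))
    if evidence <= 0:
        raise ValueError("tip configuration has zero likelihood under the model")
    out: dict[str, dict[str, float]] = {}
    for c, u in tree.parent.items():
        sib_msg = np.ones(2)
        for s in tree.children[u]:
            if s != c:
                P = model.transition_matrix(tree.blen[s])
                sib_msg = sib_msg * (P @ L[s])
        P = model.transition_matrix(tree.blen[c])
        joint = (O[u] * sib_msg)[:, None] * P * L[c][None, :]
        joint = joint / evidence
        out[tree.branch_id[c]] = {"gain": float(joint[0, 1]), "loss": float(joint[1, 0])}
    return out


@dataclass
class MappingResult:
    """Stochastic-mapping summary for one gene/character."""

    branch_expected_gains: dict[str, float]
    branch_expected_losses: dict[str, float]
    n_maps: int
    seed: int
    model: MkModel
    lnl_er: float | None = None
    lnl_ard: float | None = None
    lrt_p: float | None = None


def simmap(
    tree: Phylogeny,
    tip_states: dict[str, int],
    model: MkModel,
    n_maps: int = 1000,
    seed: int = 0,
) -> MappingResult:
    """Sample joint node states from their posterior and count endpoint
    changes per branch (gain: parent 0 -> child 1; loss: 1 -> 0).

    Node states are drawn exactly: the root from prior x partial, then each
    child conditional on its sampled parent via P(t) x partial.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    L = _partials(tree, tip_states, model)
    root_w = np.asarray(model.root_prior) * L[tree.root]
    if root_w.sum() <= 0:
        raise ValueError("tip configuration has zero likelihood under the model")
    rng = np.random.default_rng(seed)

    # per-branch sampling kernels: K[c][i, j] prop to P_ij(t_c) * L_c[j]
    kernels: dict[int, np.ndarray] = {}
    for c in tree.parent:
        P = model.transition_matrix(tree.blen[c])
        W = P * L[c][None, :]
        rowsum = W.sum(axis=1, keepdims=True)
        # rows for parent states of zero posterior mass are never sampled
        kernels[c] = np.divide(W, rowsum, out=np.full_like(W, 0.5), where=rowsum > 0)

    root_p = root_w / root_w.sum()
    order = [i for i in reversed(tree.postorder) if i != tree.root]

    gains = {c: 0 for c in tree.parent}
    losses = {c: 0 for c in tree.parent}
    root_states = rng.choice(2, size=n_maps, p=root_p)
    u = rng.random((n_maps, len(order)))
    for m in range(n_maps):
        state = {tree.root: int(root_states[m])}
        for k, c in enumerate(order):
            i = state[tree.parent[c]]
            j = int(u[m, k] > kernels[c][i, 0])
            state[c] = j
            if i == 0 and j == 1:
                gains[c] += 1
            elif i == 1 and j == 0:
                losses[c] += 1
    return MappingResult(
        branch_expected_gains={tree.branch_id[c]: gains[c] / n_maps for c in tree.parent},
        branch_expected_losses={tree.branch_id[c]: losses[c] / n_maps for c in tree.parent},
        n_maps=n_maps,
        seed=seed,
        model=model,
    )


# ---------------------------------------------------------------------------
# many-gene driver and aggregation


def fit_and_map_genes(
    tree: Phylogeny,
    tip_state_table: dict[str, dict[str, int]],
    n_maps: int = 1000,
    seed: int = 0,
    root_prior: tuple[float, float] = (0.5, 0.5),
    pooled: bool = False,
) -> dict[str, MappingResult]:
    """ER and ARD fits, LRT, and stochastic mapping under the
    better-supported model (ER unless the LRT rejects at 0.05).

    With ``pooled=False`` each gene gets its own ML fit (identical tip
    patterns share one fit, which keeps many-gene runs fast); single-gene
    rate MLEs on a small tree frequently sit on an optimization bound, so
    ``pooled=True`` instead fits one shared model to all genes jointly and
    maps every gene under it.
    """
    results: dict[str, MappingResult] = {}
    rng = np.random.default_rng(seed)
    if pooled:
        tables = [tip_state_table[g] for g in sorted(tip_state_table)]
        er = fit_mk_pooled(tree, tables, "ER", root_prior)
        ard = fit_mk_pooled(tree, tables, "ARD", root_prior)
        p = lrt_er_ard(er.lnL, ard.lnL)
        chosen = ard if p < 0.05 else er
        for gene, states in sorted(tip_state_table.items()):
            res = simmap(tree, states, chosen.model, n_maps=n_maps, seed=int(rng.integers(2**31)))
            res.lnl_er, res.lnl_ard, res.lrt_p = er.lnL, ard.lnL, p
            results[gene] = res
        return results

    fit_cache: dict[tuple, tuple[MkFit, MkFit, float]] = {}
    for gene, states in sorted(tip_state_table.items()):
        key = tuple(sorted(states.items()))
        if key not in fit_cache:
            er = fit_mk(tree, states, "ER", root_prior)
            if er.invariant:
                fit_cache[key] = (er, er, 1.0)
            else:
                ard = fit_mk(tree, states, "ARD", root_prior)
                fit_cache[key] = (er, ard, lrt_er_ard(er.lnL, ard.lnL))
        er, ard, p = fit_cache[key]
        chosen = ard if p < 0.05 else er
        res = simmap(tree, states, chosen.model, n_maps=n_maps, seed=int(rng.integers(2**31)))
        res.lnl_er, res.lnl_ard, res.lrt_p = er.lnL, ard.lnL, p
        results[gene] = res
    return results


def aggregate(results: dict[str, MappingResult], tree: Phylogeny) -> dict:
    """Branchwise totals of expected gains/losses over genes and the mean
    fitted rates across genes."""
    if not results:
        return {"empty": True, "n_genes": 0}
    branch_ids = tree.branch_ids
    totals = {b: {"gain": 0.0, "loss": 0.0} for b in branch_ids}
    q01s, q10s = [], []
    for res in results.values():
        if set(res.branch_expected_gains) != set(branch_ids):
            raise ValueError("mapping results computed on a different tree")
        for b in branch_ids:
            totals[b]["gain"] += res.branch_expected_gains[b]
            totals[b]["loss"] += res.branch_expected_losses[b]
        q01s.append(res.model.q01)
        q10s.append(res.model.q10)
    return {
        "empty": False,
        "n_genes": len(results),
        "branch_totals": totals,
        "total_gains": float(sum(t["gain"] for t in totals.values())),
        "total_losses": float(sum(t["loss"] for t in totals.values())),
        "mean_q01": float(np.mean(q01s)),
        "mean_q10": float(np.mean(q10s)),
    }
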