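"""Ancestral-state reconstruction for a binary (VCL/HL) character.

Two reconstructions are provided: unit-cost maximum parsimony (Fitch/Sankoff
with most-parsimonious-reconstruction sets, reported as uniform probabilities
over tied states) and stochastic character mapping under the equal-rates
2-state Markov model, with the rate fitted by maximum likelihood via the
pruning algorithm and an equal (0.5, 0.5) root prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .trees import PhyloTree, node_label

INF = float("inf")


def _states_of(tip_states: Mapping[str, str]) -> list[str]:
    return sorted(set(tip_states.values()))


# ---------------------------------------------------------------------------
# Parsimony


@dataclass
class ParsimonyResult:
    states: list[str]
    node_probabilities: dict[str, np.ndarray]  # node label -> prob per state
    root_probabilities: np.ndarray
    score: int


def asr_parsimony(tree: PhyloTree, tip_states: Mapping[str, str]) -> ParsimonyResult:
    """Unit-cost parsimony ancestral states with MPR-set probabilities.

    Each node's probability vector is uniform over the states appearing in at
    least one most-parsimonious reconstruction when that node is constrained
    to the state (Sankoff up-down pass with unit substitution costs).
    """
    states = _states_of(tip_states)
    if len(states) < 1:
        raise ValueError("no tip states")
    s_index = {s: i for i, s in enumerate(states)}
    ns = len(states)
    t = tree.dendropy_tree
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label not in tip_states:
            raise ValueError(f"missing state for tip {leaf.taxon.label!r}")

    # up-pass: subtree cost c[v][s]
    cost: dict[dendropy.Node, np.ndarray] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            c = np.full(ns, INF)
            c[s_index[tip_states[node.taxon.label]]] = 0.0
            cost[node] = c
        else:
            c = np.zeros(ns)
            for child in node.child_nodes():
                cc = cost[child]
                # min over child state of (unit cost + subtree cost)
                trans = np.array([min(cc[j] + (0 if i == j else 1) for j in range(ns)) for i in range(ns)])
                c = c + trans
            cost[node] = c

    # down-pass: cost of everything above node when node is in state s
    above: dict[dendropy.Node, np.ndarray] = {t.seed_node: np.zeros(ns)}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            sibs = [c for c in children if c is not child]
            a = np.full(ns, INF)
            for s in range(ns):  # child state
                best = INF
                for su in range(ns):  # parent state
                    v = above[node][su] + (0 if su == s else 1)
                    for sib in sibs:
                        cc = cost[sib]
                        v += min(cc[j] + (0 if su == j else 1) for j in range(ns))
                    best = min(best, v)
                a[s] = best
            above[child] = a

    node_probs: dict[str, np.ndarray] = {}
    for node in t.preorder_internal_node_iter():
        total = above[node] + cost[node]
        best = total.min()
        mpr = np.isclose(total, best)
        p = mpr / mpr.sum()
        node_probs[node_label(node)] = p
    root_p = node_probs[node_label(t.seed_node)]
    score = int(round(cost[t.seed_node].min()))
    return ParsimonyResult(
        states=states, node_probabilities=node_probs, root_probabilities=root_p, score=score
    )


def parsimony_score(tree: PhyloTree, tip_states: Mapping[str, str]) -> int:
    return asr_parsimony(tree, tip_states).score


# ---------------------------------------------------------------------------
# Stochastic character mapping (equal-rates 2-state model)


def _transition_matrix(rate: float, t: float) -> np.ndarray:
    e = np.exp(-2.0 * rate * t)
    same = 0.5 * (1.0 + e)
    diff = 0.5 * (1.0 - e)
    return np.array([[same, diff], [diff, same]])


def _partial_likelihoods(
    tree: dendropy.Tree, tip_states: Mapping[str, str], s_index: Mapping[str, int], rate: float
) -> dict[dendropy.Node, np.ndarray]:
    L: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(2)
            v[s_index[tip_states[node.taxon.label]]] = 1.0
            L[node] = v
        else:
            v = np.ones(2)
            for child in node.child_nodes():
                P = _transition_matrix(rate, child.edge.length)
                v = v * (P @ L[child])
            L[node] = v
    return L


def er_log_likelihood(tree: PhyloTree, tip_states: Mapping[str, str], rate: float) -> float:
    states = _states_of(tip_states)
    s_index = {s: i for i, s in enumerate(states)}
    L = _partial_likelihoods(tree.dendropy_tree, tip_states, s_index, rate)
    root = L[tree.dendropy_tree.seed_node]
    lik = float(0.5 * root.sum())
    return -INF if lik <= 0 else float(np.log(lik))


def fit_er_rate(tree: PhyloTree, tip_states: Mapping[str, str]) -> float:
    """Maximum-likelihood transition rate of the equal-rates 2-state model."""
    if len(_states_of(tip_states)) < 2:
        return 0.0
    depth = tree.max_depth()
    res = minimize_scalar(
        lambda lg: -er_log_likelihood(tree, tip_states, float(np.exp(lg))),
        bounds=(np.log(1e-6 / depth), np.log(1e3 / depth)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def _sample_parity_poisson(rng: np.random.Generator, lam: float, odd: bool) -> int:
    """Sample N ~ Poisson(lam) conditioned on parity (uniformization jump count)."""
    kmax = max(20, int(lam + 12 * np.sqrt(lam + 1)))
    ks = np.arange(1 if odd else 0, kmax + 1, 2)
    if len(ks) == 0:
        return 1 if odd else 0
    logp = ks * np.log(lam if lam > 0 else 1e-300) - np.array(
        [np.sum(np.log(np.arange(1, k + 1))) if k else 0.0 for k in ks]
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return int(rng.choice(ks, p=p))


@dataclass
class SimmapResult:
    states: list[str]
    rate: float
    nsim: int
    node_frequencies: dict[str, np.ndarray]  # posterior state frequencies per node
    node_mc_se: dict[str, np.ndarray]
    changes_per_map: np.ndarray  # total state changes in each sampled history
    root_prior: tuple[float, float] = (0.5, 0.5)


def simmap_er(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    nsim: int = 1000,
    seed: int | None = None,
    rate: float | None = None,
) -> SimmapResult:
    """Stochastic character maps under the fitted equal-rates model.

    Node states are sampled from their joint conditional distribution
    (pruning + preorder sampling); within-branch histories are drawn by
    uniformization conditioned on the branch endpoints, which for the 2-state
    equal-rates chain reduces to a parity-constrained Poisson jump count.
    """
    rng = np.random.default_rng(seed)
    states = _states_of(tip_states)
    t = tree.dendropy_tree
    internal = list(t.preorder_internal_node_iter())
    if len(states) == 1:
        freqs = {node_label(n): np.array([1.0]) for n in internal}
        ses = {node_label(n): np.array([0.0]) for n in internal}
        return SimmapResult(states, 0.0, nsim, freqs, ses, np.zeros(nsim))

    s_index = {s: i for i, s in enumerate(states)}
    if rate is None:
        rate = fit_er_rate(tree, tip_states)
    L = _partial_likelihoods(t, tip_states, s_index, rate)

    counts = {node_label(n): np.zeros(2) for n in internal}
    changes = np.zeros(nsim)
    root = t.seed_node
    for m in range(nsim):
        assignment: dict[dendropy.Node, int] = {}
        w = 0.5 * L[root]
        w = w / w.sum()
        assignment[root] = int(rng.choice(2, p=w))
        n_changes = 0
        for node in t.preorder_node_iter():
            if node is root:
                continue
            su = assignment[node.parent_node]
            P = _transition_matrix(rate, node.edge.length)
            if node.is_leaf():
                sv = s_index[tip_states[node.taxon.label]]
            else:
                w = P[su] * L[node]
                w = w / w.sum()
                sv = int(rng.choice(2, p=w))
            assignment[node] = sv
            lam = rate * node.edge.length
            n_changes += _sample_parity_poisson(rng, lam, odd=(su != sv))
        changes[m] = n_changes
        for n in internal:
            counts[node_label(n)][assignment[n]] += 1

    freqs = {lab: c / nsim for lab, c in counts.items()}
    ses = {lab: np.sqrt(f * (1 - f) / nsim) for lab, f in freqs.items()}
    return SimmapResult(states, rate, nsim, freqs, ses, changes)
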