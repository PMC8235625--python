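"""Branch-wise evolutionary rates by phylogenetic ridge regression,
and clade rate-shift detection by randomization.

Each tip phenotype is modelled as the root value plus the sum, over the
branches on its root-to-tip path, of branch length times a branch-specific
rate vector.  The rates are the ridge solution

    beta = (X'X + lambda I)^-1 X' (Y - root),

where X[i, b] = length of branch b if b lies on tip i's root path, else 0,
and the root value is the phylogenetic GLS mean.  When lambda is not given
it is tuned by golden-section search on log-lambda minimizing leave-one-out
tip prediction error (computed through the ridge hat matrix).

A clade's rate shift is the difference between the mean rate magnitude of
its branches and the mean over all other branches, with a null distribution
from shuffling branch magnitudes across the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import PhyloTree, node_label


def _branch_table(tree: PhyloTree):
    """Branches (one per non-root node) and the tips-x-branches design matrix."""
    t = tree.dendropy_tree
    nodes = [n for n in t.preorder_node_iter() if n.parent_node is not None]
    lengths = np.array([n.edge.length for n in nodes])
    labels = [node_label(n) for n in nodes]
    tips = sorted(tree.tip_labels)
    tip_pos = {lab: i for i, lab in enumerate(tips)}
    X = np.zeros((len(tips), len(nodes)))
    for b, node in enumerate(nodes):
        for leaf in node.leaf_iter():
            X[tip_pos[leaf.taxon.label], b] = lengths[b]
    clade_tips = [sorted(l.taxon.label for l in n.leaf_iter()) for n in nodes]
    return tips, labels, lengths, X, nodes, clade_tips


@dataclass
class RateField:
    """Per-branch evolutionary rate vectors and magnitudes."""

    branch_labels: list[str]
    rates: np.ndarray  # B x d
    magnitudes: np.ndarray  # B
    lam: float
    root_estimate: np.ndarray  # d
    tip_order: list[str]

    @property
    def n_branches(self) -> int:
        return len(self.branch_labels)


_GOLDEN = (np.sqrt(5) - 1) / 2


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3) -> float:
    """Golden-section minimization of a unimodal scalar function on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _loo_error(X: np.ndarray, Yc: np.ndarray, lam: float) -> float:
    n, B = X.shape
    G = X @ np.linalg.solve(X.T @ X + lam * np.eye(B), X.T)
    resid = Yc - G @ Yc
    h = np.clip(np.diag(G), None, 1 - 1e-8)
    loo = resid / (1 - h)[:, None]
    return float(np.sum(loo**2))


def rr_rates(
    tree: PhyloTree,
    tip_data: Mapping[str, np.ndarray | float],
    lam: float | None = None,
) -> RateField:
    """Phylogenetic ridge-regression rates for per-species data vectors."""
    tips, labels, lengths, X, _, _ = _branch_table(tree)
    missing = [l for l in tips if l not in tip_data]
    if missing:
        raise ValueError(f"tip data missing for: {missing}")
    Y = np.vstack([np.atleast_1d(np.asarray(tip_data[l], float)).ravel() for l in tips])

    # root estimate: phylogenetic GLS mean per dimension
    _, C = tree.vcv(order=tips)
    Cinv = np.linalg.inv(C)
    one = np.ones(len(tips))
    w = Cinv @ one
    root = (w @ Y) / (one @ w)
    Yc = Y - root

    scale = float(np.trace(X.T @ X)) / X.shape[1]
    if lam is None:
        lg = _golden_section(
            lambda lg_: _loo_error(X, Yc, float(np.exp(lg_)) * scale),
            np.log(1e-8),
            np.log(1e4),
        )
        lam = float(np.exp(lg)) * scale
    beta = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ Yc)
    mags = np.linalg.norm(beta, axis=1)
    return RateField(
        branch_labels=labels,
        rates=beta,
        magnitudes=mags,
        lam=float(lam),
        root_estimate=root,
        tip_order=tips,
    )


@dataclass
class CladeShiftReport:
    """Per-clade rate difference vs the rest of the tree, randomization-tested."""

    table: pd.DataFrame  # index: clade node id

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] <= alpha]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def search_shift_clades(
    tree: PhyloTree,
    rates: RateField,
    n_rand: int = 1000,
    seed: int | None = None,
    min_tips: int = 2,
    alpha: float = 0.05,
) -> CladeShiftReport:
    """Compare each clade's mean rate magnitude with the rest of the tree.

    Candidate clades have between ``min_tips`` and n/2 tips.  The clade's
    branch set is its stem branch plus all branches inside it.  The null
    shuffles branch magnitudes globally across the tree ``n_rand`` times;
    p-values are two-tailed with the add-one rule, and direction flags
    (higher / lower / ns) are assigned at ``alpha``.
    """
    tips, labels, lengths, X, nodes, clade_tips = _branch_table(tree)
    if labels != rates.branch_labels:
        raise ValueError("RateField does not match this tree's branches")
    mags = rates.magnitudes
    B = len(mags)
    n = len(tips)
    rng = np.random.default_rng(seed)

    # candidate clades: internal non-root nodes within the tip-count bounds
    cand = []
    for i, node in enumerate(nodes):
        if node.is_leaf():
            continue
        nt = len(clade_tips[i])
        if min_tips <= nt <= n // 2:
            cand.append(i)

    # branch membership masks (stem + descendants)
    node_index = {id(node): b for b, node in enumerate(nodes)}
    masks = np.zeros((len(cand), B), dtype=bool)
    for row, i in enumerate(cand):
        stack = [nodes[i]]
        while stack:
            nd = stack.pop()
            masks[row, node_index[id(nd)]] = True
            stack.extend(nd.child_nodes())

    perm = np.empty((n_rand, B))
    for r in range(n_rand):
        perm[r] = mags[rng.permutation(B)]

    rows = []
    for row, i in enumerate(cand):
        mask = masks[row]
        nc = int(mask.sum())
        mean_in = float(mags[mask].mean())
        mean_out = float(mags[~mask].mean())
        obs = mean_in - mean_out
        null = perm[:, mask].mean(axis=1) - perm[:, ~mask].mean(axis=1)
        p_hi = (np.sum(null >= obs) + 1) / (n_rand + 1)
        p_lo = (np.sum(null <= obs) + 1) / (n_rand + 1)
        p = min(1.0, 2 * min(p_hi, p_lo))
        if p <= alpha:
            direction = "higher" if obs > 0 else "lower"
        else:
            direction = "ns"
        rows.append(
            {
                "clade": node_label(nodes[i]),
                "n_tips": len(clade_tips[i]),
                "tips": ";".join(clade_tips[i]),
                "n_branches": nc,
                "mean_rate_clade": mean_in,
                "mean_rate_rest": mean_out,
                "difference": obs,
                "p": p,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("clade")
        # raw p reported (as in per-clade shift testing); FDR added as a column
        ps = df["p"].to_numpy()
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            val = min(prev, ps[idx] * m / (rank_pos + 1))
            adj[idx] = val
            prev = val
        df["p_fdr"] = adj
    return CladeShiftReport(df)
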