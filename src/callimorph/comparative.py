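"""Phylogenetic comparative statistics.

Blomberg's K and its multivariate generalization Kmult (permutation-tested),
phylogenetic ANOVA with a Brownian simulation null, PC retention at a
cumulative-variance threshold, and the sequential (Type I) MANCOVA with
Pillai's trace used for the allometry/locomotion test.

All covariances come from the Brownian-motion model on the tree:
C[i, j] = shared root-path length of tips i and j.  All permutation and
simulation p-values use the add-one rule (#extreme + 1)/(N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trees import PhyloTree


def _trait_vector(trait: Mapping[str, float], labels: Sequence[str]) -> np.ndarray:
    missing = [l for l in labels if l not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    return np.array([float(trait[l]) for l in labels])


def _phylo_mean(Cinv: np.ndarray, Y: np.ndarray) -> np.ndarray:
    one = np.ones(Cinv.shape[0])
    w = Cinv @ one
    return (w @ Y) / (one @ w)


def _k_statistic(Y: np.ndarray, Cinv: np.ndarray, expected_ratio: float) -> float:
    """Shared core of K and Kmult: observed/expected ratio of deviation sums."""
    a = _phylo_mean(Cinv, Y)
    E = Y - a
    num = float(np.sum(E * E))
    den = float(np.sum(E * (Cinv @ E)))
    if den <= 0:
        raise ValueError("degenerate phylogenetically transformed variance")
    return (num / den) / expected_ratio


def _expected_ratio(C: np.ndarray, Cinv: np.ndarray) -> float:
    n = C.shape[0]
    one = np.ones(n)
    return (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)


@dataclass
class SignalResult:
    statistic: float
    p_value: float
    n_perm: int


def blomberg_k(
    tree: PhyloTree,
    trait: Mapping[str, float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K for a univariate trait with a tip-permutation test.

    K = 1 is the Brownian expectation on the given tree; K > 1 indicates more
    signal than Brownian motion, K < 1 less.  The p-value counts permutations
    of tip values with K >= observed.
    """
    labels, C = tree.vcv()
    y = _trait_vector(trait, labels)
    if np.var(y) == 0:
        raise ValueError("constant trait: phylogenetic signal undefined")
    Cinv = np.linalg.inv(C)
    exp_ratio = _expected_ratio(C, Cinv)
    obs = _k_statistic(y[:, None], Cinv, exp_ratio)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        if _k_statistic(y[perm][:, None], Cinv, exp_ratio) >= obs:
            hits += 1
    return SignalResult(obs, (hits + 1) / (n_perm + 1), n_perm)


def k_mult(
    tree: PhyloTree,
    shapes: Mapping[str, np.ndarray],
    n_perm: int = 10000,
    seed: int | None = None,
) -> SignalResult:
    """Multivariate phylogenetic signal (Kmult) for per-species shape vectors.

    With one-dimensional input this reduces exactly to Blomberg's K.
    """
    labels, C = tree.vcv()
    missing = [l for l in labels if l not in shapes]
    if missing:
        raise ValueError(f"shape data missing for tips: {missing}")
    Y = np.vstack([np.ravel(shapes[l]) for l in labels])
    if Y.shape[0] < 3:
        raise ValueError("Kmult needs at least 3 species")
    if np.allclose(Y, Y[0]):
        raise ValueError("constant shapes: phylogenetic signal undefined")
    Cinv = np.linalg.inv(C)
    exp_ratio = _expected_ratio(C, Cinv)
    obs = _k_statistic(Y, Cinv, exp_ratio)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        if _k_statistic(Y[perm], Cinv, exp_ratio) >= obs:
            hits += 1
    return SignalResult(obs, (hits + 1) / (n_perm + 1), n_perm)


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA


def _anova_f(y: np.ndarray, g: np.ndarray, n_groups: int) -> float:
    n = len(y)
    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for level in range(n_groups):
        yi = y[g == level]
        ss_between += len(yi) * (yi.mean() - grand) ** 2
        ss_within += np.sum((yi - yi.mean()) ** 2)
    df_b = n_groups - 1
    df_w = n - n_groups
    return (ss_between / df_b) / (ss_within / df_w)


@dataclass
class PhylAnovaResult:
    f_statistic: float
    p_phylo: float
    p_standard: float
    n_sim: int


def phyl_anova(
    tree: PhyloTree,
    groups: Mapping[str, str],
    trait: Mapping[str, float],
    n_sim: int = 1000,
    seed: int | None = None,
) -> PhylAnovaResult:
    """Phylogenetic ANOVA: the null F distribution comes from Brownian
    simulations on the tree, with sigma^2 estimated from the data by the
    phylogenetic GLS estimator."""
    labels, C = tree.vcv()
    y = _trait_vector(trait, labels)
    levels = sorted(set(groups[l] for l in labels))
    if len(levels) < 2:
        raise ValueError("phylogenetic ANOVA needs at least two groups")
    g = np.array([levels.index(groups[l]) for l in labels])
    n = len(y)

    f_obs = _anova_f(y, g, len(levels))
    df_b, df_w = len(levels) - 1, n - len(levels)
    p_standard = float(stats.f.sf(f_obs, df_b, df_w))

    Cinv = np.linalg.inv(C)
    a = float(_phylo_mean(Cinv, y[:, None])[0])
    resid = y - a
    sigma2 = float(resid @ Cinv @ resid) / (n - 1)
    Lchol = np.linalg.cholesky(sigma2 * C)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sim, n))
    sims = a + Z @ Lchol.T
    hits = sum(1 for i in range(n_sim) if _anova_f(sims[i], g, len(levels)) >= f_obs)
    return PhylAnovaResult(f_obs, (hits + 1) / (n_sim + 1), p_standard, n_sim)


def size_comparison(
    log_cs: Mapping[str, float],
    groups: Mapping[str, str],
    tree: PhyloTree,
    n_sim: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Group comparison of log centroid size: Welch t-test plus phylogenetic ANOVA.

    The two are reported together because a significant plain t-test can
    vanish once phylogeny is taken into account when the groups are
    confounded with clades.
    """
    labels = sorted(tree.tip_labels)
    y = _trait_vector(log_cs, labels)
    levels = sorted(set(groups[l] for l in labels))
    if len(levels) != 2:
        raise ValueError("size comparison expects exactly two groups")
    y0 = y[[groups[l] == levels[0] for l in labels]]
    y1 = y[[groups[l] == levels[1] for l in labels]]
    t_res = stats.ttest_ind(y0, y1, equal_var=False)
    pa = phyl_anova(tree, groups, log_cs, n_sim=n_sim, seed=seed)
    return {
        "t_statistic": float(t_res.statistic),
        "t_test_p": float(t_res.pvalue),
        "phyl_anova_f": pa.f_statistic,
        "phyl_anova_p": pa.p_phylo,
    }


# ---------------------------------------------------------------------------
# PC retention and MANCOVA


@dataclass
class RetainedPCs:
    scores: np.ndarray  # n x a
    n_axes: int
    variance_fractions: np.ndarray  # all axes, non-increasing
    axes: np.ndarray  # a x p loading vectors
    mean: np.ndarray


def retain_pcs(data: np.ndarray, threshold: float = 0.95) -> RetainedPCs:
    """Scores on the smallest leading PC set reaching the variance threshold."""
    X = np.asarray(data, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    keep = var > var[0] * 1e-12 if var[0] > 0 else np.zeros_like(var, bool)
    var = var[keep]
    Vt = Vt[keep]
    frac = var / var.sum()
    cum = np.cumsum(frac)
    n_axes = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    n_axes = min(n_axes, len(frac))
    scores = Xc @ Vt[:n_axes].T
    return RetainedPCs(scores=scores, n_axes=n_axes, variance_fractions=frac, axes=Vt[:n_axes], mean=mean)


@dataclass
class MancovaTable:
    table: pd.DataFrame  # rows size, locomotion, interaction, residuals

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _pillai_f(H: np.ndarray, E: np.ndarray, df_h: int, df_e: int):
    q = H.shape[0]
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(df_h, q)
    m = (abs(df_h - q) - 1) / 2.0
    nn = (df_e - q - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or V >= s:
        return V, np.nan, df1, df2, np.nan
    F = (df2 / df1) * (V / (s - V))
    p = float(stats.f.sf(F, df1, df2))
    return V, F, df1, df2, p


def mancova_pillai(
    scores: np.ndarray,
    log_size: np.ndarray,
    groups: Sequence[str],
) -> MancovaTable:
    """Sequential (Type I) MANCOVA: scores ~ size + locomotion + size:locomotion.

    Pillai's trace per term with Rao's F approximation; the error SSCP and
    residual degrees of freedom come from the full model, mirroring the
    standard multivariate linear-model ANOVA table.
    """
    Y = np.asarray(scores, float)
    size = np.asarray(log_size, float)
    n, q = Y.shape
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError("MANCOVA here expects exactly two locomotor groups")
    g = np.array([1.0 if gr == levels[1] else 0.0 for gr in groups])
    if n <= q + 3:
        raise ValueError(f"too few observations ({n}) for {q} response axes")

    intercept = np.ones(n)
    columns = {
        "size": size,
        "locomotion": g,
        "interaction": size * g,
    }
    design = [intercept]
    term_dfs = {}
    rss = {}

    def residual_sscp(X: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    prev = residual_sscp(np.column_stack(design))
    for name, col in columns.items():
        design.append(col)
        X = np.column_stack(design)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design: term {name!r} is aliased")
        cur = residual_sscp(X)
        rss[name] = (prev, cur)
        term_dfs[name] = 1
        prev = cur

    E = prev  # full-model residual SSCP
    df_model = len(columns) + 1
    df_e = n - df_model
    rows = []
    for name in columns:
        H = rss[name][0] - rss[name][1]
        V, F, df1, df2, p = _pillai_f(H, E, term_dfs[name], df_e)
        rows.append(
            {"term": name, "Df": term_dfs[name], "Pillai": V, "approx_F": F,
             "num_Df": df1, "den_Df": df2, "p": p}
        )
    rows.append(
        {"term": "residuals", "Df": df_e, "Pillai": np.nan, "approx_F": np.nan,
         "num_Df": np.nan, "den_Df": np.nan, "p": np.nan}
    )
    df = pd.DataFrame(rows).set_index("term")
    return MancovaTable(df)
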