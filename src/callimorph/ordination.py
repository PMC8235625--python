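"""Ordination and group classification of Procrustes shape data.

PCA and phylomorphospace (internal nodes projected at their Brownian
ancestral estimates), between-group PCA on the covariance of group means,
cross-validated typicality-probability reclassification (small-sample
F-based Mahalanobis typicality), a permutation test on the Euclidean
distance between group mean shapes, and reconstruction of the shape
configurations at the extremes of an ordination axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trees import PhyloTree, node_label


@dataclass
class OrdinationResult:
    scores: np.ndarray  # n x a
    axes: np.ndarray  # a x p orthonormal loading vectors
    variance_fraction: np.ndarray  # per retained axis, non-increasing
    mean: np.ndarray  # p
    row_ids: list[str] | None = None
    node_scores: dict[str, np.ndarray] | None = None  # phylomorphospace only
    edges: list[tuple[str, str]] | None = None

    def scores_frame(self) -> pd.DataFrame:
        idx = self.row_ids if self.row_ids is not None else list(range(self.scores.shape[0]))
        cols = [f"axis{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=idx, columns=cols)


def _sign_fix(axes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude loading is positive."""
    out = axes.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


def pca(data: np.ndarray, row_ids: Sequence[str] | None = None) -> OrdinationResult:
    """Centered PCA of flattened shapes (rows = specimens or species)."""
    X = np.asarray(data, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    keep = var > (var[0] * 1e-12 if var[0] > 0 else np.inf)
    Vt = _sign_fix(Vt[keep])
    var = var[keep]
    scores = Xc @ Vt.T
    return OrdinationResult(
        scores=scores,
        axes=Vt,
        variance_fraction=var / var.sum(),
        mean=mean,
        row_ids=list(row_ids) if row_ids is not None else None,
    )


def ancestral_estimates(tree: PhyloTree, tip_values: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """ML (GLS) Brownian ancestral estimates at every internal node."""
    tips = sorted(tree.tip_labels)
    Y = np.vstack([np.atleast_1d(np.asarray(tip_values[l], float)) for l in tips])
    _, C = tree.vcv(order=tips)
    Cinv = np.linalg.inv(C)
    one = np.ones(len(tips))
    w = Cinv @ one
    root = (w @ Y) / (one @ w)

    # covariance between each internal node and the tips: shared root-path length
    t = tree.dendropy_tree
    t.calc_node_root_distances(return_leaf_distances_only=False)
    tip_pos = {lab: i for i, lab in enumerate(tips)}
    out: dict[str, np.ndarray] = {}
    for node in t.preorder_internal_node_iter():
        under = {l.taxon.label for l in node.leaf_iter()}
        cov = np.empty(len(tips))
        for lab in tips:
            if lab in under:
                cov[tip_pos[lab]] = node.root_distance
            else:
                # shared path = depth of MRCA(node, tip) = MRCA of the clade tip set and the tip
                anc = node
                while lab not in {l.taxon.label for l in anc.leaf_iter()}:
                    anc = anc.parent_node
                cov[tip_pos[lab]] = anc.root_distance
        est = root + cov @ Cinv @ (Y - root)
        out[node_label(node)] = est
    return out


def phylomorphospace(tree: PhyloTree, ordination: OrdinationResult) -> OrdinationResult:
    """Project the tree's internal nodes into an existing ordination.

    Node positions are the per-axis GLS Brownian ancestral estimates of the
    tip scores; edges (parent, child) are attached for plotting/export.
    """
    if ordination.row_ids is None:
        raise ValueError("ordination must carry row ids matching tip labels")
    tip_scores = {rid: ordination.scores[i] for i, rid in enumerate(ordination.row_ids)}
    missing = set(tree.tip_labels) - set(tip_scores)
    if missing:
        raise ValueError(f"scores missing for tips: {sorted(missing)}")
    node_scores = ancestral_estimates(tree, tip_scores)
    t = tree.dendropy_tree
    edges = []
    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            edges.append((node_label(node.parent_node), node_label(node)))
    return OrdinationResult(
        scores=ordination.scores,
        axes=ordination.axes,
        variance_fraction=ordination.variance_fraction,
        mean=ordination.mean,
        row_ids=ordination.row_ids,
        node_scores=node_scores,
        edges=edges,
    )


class DegenerateGroupsError(ValueError):
    pass


def between_group_pca(
    data: np.ndarray, groups: Sequence[str], row_ids: Sequence[str] | None = None
) -> OrdinationResult:
    """PCA of the covariance of group mean vectors (equal group weights).

    All specimens are projected onto the between-group axes.  With two groups
    there is exactly one axis, collinear with the difference of group means.
    """
    X = np.asarray(data, float)
    labels = list(groups)
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise DegenerateGroupsError("between-group PCA needs at least 2 groups")
    means = np.vstack([X[[g == lv for g in labels]].mean(axis=0) for lv in levels])
    grand = means.mean(axis=0)
    M = means - grand
    cov = M.T @ M / (len(levels) - 1)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    var = s**2
    keep = var > max(var[0], np.sum(X.var(axis=0))) * 1e-12
    if not np.any(keep):
        raise DegenerateGroupsError("group means coincide: no between-group variance")
    Vt = _sign_fix(Vt[keep][: len(levels) - 1])
    var = var[keep][: len(levels) - 1]
    scores = (X - grand) @ Vt.T
    return OrdinationResult(
        scores=scores,
        axes=Vt,
        variance_fraction=var / var.sum(),
        mean=grand,
        row_ids=list(row_ids) if row_ids is not None else None,
    )


# ---------------------------------------------------------------------------
# Typicality classification


@dataclass
class ClassificationReport:
    specimens: pd.DataFrame  # id, true group, assigned, typicality per group
    accuracy: float  # percent correctly re-classified
    cross_validated: bool

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accuracy_percent": self.accuracy,
            "cross_validated": self.cross_validated,
            "specimens": self.specimens.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassificationReport":
        payload = json.loads(Path(path).read_text())
        return cls(
            specimens=pd.DataFrame(payload["specimens"]),
            accuracy=payload["accuracy_percent"],
            cross_validated=payload["cross_validated"],
        )


def _typicality(d2: float, p: int, n_group: int, n_total: int, n_groups: int) -> float:
    """Small-sample F-based typicality probability of a squared Mahalanobis
    distance to a group centroid (pooled within-group covariance)."""
    df_e = n_total - n_groups
    df2 = df_e - p + 1
    if df2 <= 0:
        raise ValueError("pooled covariance df too small for this dimensionality")
    factor = (n_group / (n_group + 1.0)) * (df2 / (p * df_e))
    F = factor * d2
    return float(stats.f.sf(F, p, df2))


def classify_typicality(
    scores: np.ndarray,
    groups: Sequence[str],
    cross_validate: bool = True,
    row_ids: Sequence[str] | None = None,
    atypical_alpha: float = 0.05,
) -> ClassificationReport:
    """Reclassify specimens by typicality probability.

    Squared Mahalanobis distances to each group mean use the pooled
    within-group covariance; the small-sample F transformation converts them
    to typicality probabilities.  With cross-validation the evaluated
    specimen is left out of its own group's mean and the pooled covariance.
    Assignment is argmax typicality; specimens whose best typicality falls
    below ``atypical_alpha`` are flagged but still assigned.
    """
    X = np.atleast_2d(np.asarray(scores, float))
    if X.shape[0] != len(groups):
        raise ValueError("scores/groups length mismatch")
    labels = list(groups)
    levels = sorted(set(labels))
    n, p = X.shape
    counts = {lv: labels.count(lv) for lv in levels}
    for lv, c in counts.items():
        if c <= p:
            raise ValueError(
                f"group {lv!r} has {c} members for {p} dimensions; reduce dimensionality"
            )

    def pooled_cov(X_, labels_):
        S = np.zeros((p, p))
        for lv in levels:
            sub = X_[[g == lv for g in labels_]]
            R = sub - sub.mean(axis=0)
            S += R.T @ R
        df = len(labels_) - len(levels)
        return S / df

    rows = []
    correct = 0
    ids = list(row_ids) if row_ids is not None else list(range(n))
    for i in range(n):
        if cross_validate:
            keep = [j for j in range(n) if j != i]
            Xf = X[keep]
            lf = [labels[j] for j in keep]
        else:
            Xf, lf = X, labels
        S = pooled_cov(Xf, lf)
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular pooled covariance; reduce dimensionality") from exc
        probs = {}
        for lv in levels:
            sub = Xf[[g == lv for g in lf]]
            mu = sub.mean(axis=0)
            d = X[i] - mu
            d2 = float(d @ Sinv @ d)
            probs[lv] = _typicality(d2, p, sub.shape[0], len(lf), len(levels))
        assigned = max(levels, key=lambda lv: probs[lv])
        if assigned == labels[i]:
            correct += 1
        rows.append(
            {
                "specimen": ids[i],
                "group": labels[i],
                "assigned": assigned,
                "atypical": max(probs.values()) < atypical_alpha,
                **{f"typicality_{lv}": probs[lv] for lv in levels},
            }
        )
    return ClassificationReport(
        specimens=pd.DataFrame(rows),
        accuracy=100.0 * correct / n,
        cross_validated=cross_validate,
    )


def bgpca_classify(
    data: np.ndarray,
    groups: Sequence[str],
    cross_validate: bool = True,
    row_ids: Sequence[str] | None = None,
    atypical_alpha: float = 0.05,
) -> ClassificationReport:
    """Between-group PCA followed by typicality reclassification.

    With cross-validation the bgPCA axes themselves are recomputed without
    the evaluated specimen, and the specimen is excluded from its group's
    mean and the pooled covariance.  Leaving the axes fixed would leak the
    group labels through the projection (the known bgPCA overfitting
    artifact) and give above-chance accuracy on random labels.
    """
    X = np.asarray(data, float)
    labels = list(groups)
    levels = sorted(set(labels))
    n = X.shape[0]
    ids = list(row_ids) if row_ids is not None else list(range(n))
    if not cross_validate:
        bg = between_group_pca(X, labels)
        return classify_typicality(bg.scores, labels, cross_validate=False,
                                   row_ids=ids, atypical_alpha=atypical_alpha)

    rows = []
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        bg = between_group_pca(X[keep], [labels[j] for j in idx[keep]])
        scores = (X - bg.mean) @ bg.axes.T
        p = scores.shape[1]
        train = scores[keep]
        ltrain = [labels[j] for j in idx[keep]]
        S = np.zeros((p, p))
        for lv in levels:
            sub = train[[g == lv for g in ltrain]]
            R = sub - sub.mean(axis=0)
            S += R.T @ R
        S /= len(ltrain) - len(levels)
        Sinv = np.linalg.inv(S)
        probs = {}
        for lv in levels:
            sub = train[[g == lv for g in ltrain]]
            d = scores[i] - sub.mean(axis=0)
            d2 = float(d @ Sinv @ d)
            probs[lv] = _typicality(d2, p, sub.shape[0], len(ltrain), len(levels))
        assigned = max(levels, key=lambda lv: probs[lv])
        correct += assigned == labels[i]
        rows.append(
            {
                "specimen": ids[i],
                "group": labels[i],
                "assigned": assigned,
                "atypical": max(probs.values()) < atypical_alpha,
                **{f"typicality_{lv}": probs[lv] for lv in levels},
            }
        )
    return ClassificationReport(
        specimens=pd.DataFrame(rows), accuracy=100.0 * correct / n, cross_validated=True
    )


# ---------------------------------------------------------------------------
# Permutation test on group mean distance


@dataclass
class PermutationDistanceResult:
    observed: float
    p_value: float
    n_perm: int


def permutation_group_distance(
    data: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationDistanceResult:
    """Euclidean distance between the two group mean vectors, permutation-tested.

    One-tailed: only distances at least as large as observed count, since a
    distance is non-negative and only large values indicate separation.
    """
    X = np.asarray(data, float)
    labels = np.asarray(list(groups))
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError("permutation distance test expects exactly two groups")
    mask = labels == levels[0]

    def dist(m):
        return float(np.linalg.norm(X[m].mean(axis=0) - X[~m].mean(axis=0)))

    obs = dist(mask)
    rng = np.random.default_rng(seed)
    n0 = int(mask.sum())
    hits = 0
    idx = np.arange(len(labels))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        m = np.zeros(len(labels), bool)
        m[perm[:n0]] = True
        if dist(m) >= obs:
            hits += 1
    return PermutationDistanceResult(obs, (hits + 1) / (n_perm + 1), n_perm)


# ---------------------------------------------------------------------------
# Axis endpoint shapes


def axis_endpoint_shapes(
    ordination: OrdinationResult,
    axis: int = 0,
    quantiles: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Landmark configurations at the two extremes of an ordination axis.

    Reconstruction is consensus + score * axis, evaluated at the requested
    quantiles of the observed scores (defaults: the extremes).  Returns a
    pair of k x 3 configurations.
    """
    if not 0 <= axis < ordination.axes.shape[0]:
        raise ValueError(f"axis {axis} out of range")
    s = ordination.scores[:, axis]
    lo, hi = (float(np.quantile(s, q)) for q in quantiles)
    v = ordination.axes[axis]
    shape_lo = (ordination.mean + lo * v).reshape(-1, 3)
    shape_hi = (ordination.mean + hi * v).reshape(-1, 3)
    return shape_lo, shape_hi
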