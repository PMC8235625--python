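"""Semilandmark processing: curve resampling, surface patching, and sliding.

Curve and surface semilandmarks carry no point-to-point homology; after
digitization they are allowed to slide along their tangent directions so as
to minimize the thin-plate-spline bending energy between each specimen and a
reference (first the template, then the sample consensus).  Sliding uses the
closed-form generalized-least-squares solution and is always followed by
re-projection onto the specimen's own curve/mesh so semilandmarks stay on
the anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .landmarks import LandmarkConfiguration, Role
from .procrustes import gpa, ordinary_procrustes
from .tps import ThinPlateSpline


# ---------------------------------------------------------------------------
# Curve resampling


class DegenerateCurveError(ValueError):
    pass


def resample_curve(polyline: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline to n points at equal arc-length spacing.

    Endpoints are preserved exactly.
    """
    pts = np.asarray(polyline, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be m x d with m >= 2")
    if n < 2:
        raise ValueError("n must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise DegenerateCurveError("zero-length polyline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, pts.shape[1]))
    out[0] = pts[0]
    out[-1] = pts[-1]
    for j in range(1, n - 1):
        t = targets[j]
        i = int(np.searchsorted(cum, t, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = (t - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        out[j] = pts[i] + frac * (pts[i + 1] - pts[i])
    return out


# ---------------------------------------------------------------------------
# Template atlas and sliding plan


@dataclass
class TemplateAtlas:
    """Template specimen: full landmark configuration plus its surface mesh."""

    template_config: LandmarkConfiguration
    template_mesh: trimesh.Trimesh
    curve_counts: dict[str, int]
    surface_count: int

    def __post_init__(self):
        for cid, cnt in self.curve_counts.items():
            have = len(self.template_config.curve_indices(cid))
            if have != cnt:
                raise ValueError(f"curve {cid!r}: template has {have} points, expected {cnt}")
        n_surf = len(self.template_config.indices(Role.SURFACE))
        if n_surf != self.surface_count:
            raise ValueError(f"template has {n_surf} surface points, expected {self.surface_count}")


@dataclass
class SlidingPlan:
    """Per-landmark tangent basis: none (fixed), 1 vector (curve), 2 (surface)."""

    tangents: list[np.ndarray | None]  # entry i: (t, 3) array or None

    @property
    def n_params(self) -> int:
        return sum(0 if t is None else t.shape[0] for t in self.tangents)


def _orthonormal_complement(normal: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane orthogonal to ``normal``."""
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.vstack([u, v])


def _closest_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Closest point on each triangle for each query point (fully vectorized).

    points: (P, 3); triangles: (F, 3, 3).  Returns (P, F, 3) candidates.
    Standard region-classification algorithm for point-triangle distance.
    """
    p = points[:, None, :]  # P,1,3
    a = triangles[None, :, 0, :]
    b = triangles[None, :, 1, :]
    c = triangles[None, :, 2, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("pfx,pfx->pf", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("pfx,pfx->pf", np.broadcast_arrays(ac, ap)[0], ap)
    bp = p - b
    d3 = np.einsum("pfx,pfx->pf", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("pfx,pfx->pf", np.broadcast_arrays(ac, bp)[0], bp)
    cp = p - c
    d5 = np.einsum("pfx,pfx->pf", np.broadcast_arrays(ab, cp)[0], cp)
    d6 = np.einsum("pfx,pfx->pf", np.broadcast_arrays(ac, cp)[0], cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(np.abs(d1 - d3) > 0, d1 / (d1 - d3), 0.0)
        v_ac = np.where(np.abs(d2 - d6) > 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where(np.abs((d4 - d3) + (d5 - d6)) > 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        denom = va + vb + vc
        denom = np.where(np.abs(denom) > 0, denom, 1.0)
        v_in = vb / denom
        w_in = vc / denom
    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default
    cond_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(cond_bc[..., None], b + w_bc[..., None] * (c - b), out)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[..., None], a + v_ac[..., None] * ac, out)
    cond_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(cond_c[..., None], np.broadcast_arrays(c, out)[0], out)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[..., None], a + v_ab[..., None] * ab, out)
    cond_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(cond_b[..., None], np.broadcast_arrays(b, out)[0], out)
    cond_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(cond_a[..., None], np.broadcast_arrays(a, out)[0], out)
    return out


def closest_point_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray):
    """Closest surface point and face index per query point (brute force)."""
    pts = np.atleast_2d(np.asarray(points, float))
    tri = np.asarray(mesh.triangles)
    cand = _closest_on_triangles(pts, tri)  # P,F,3
    d2 = np.sum((cand - pts[:, None, :]) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    return cand[np.arange(len(pts)), best], best


def _surface_normals(points: np.ndarray, mesh: trimesh.Trimesh | None) -> np.ndarray:
    if mesh is not None:
        # nearest-VERTEX normals: semilandmarks often sit exactly on vertices,
        # where the closest face is tie-ambiguous, while the angle-weighted
        # vertex normal is smooth and rigid-motion equivariant
        from scipy.spatial import cKDTree

        _, vid = cKDTree(np.asarray(mesh.vertices)).query(np.atleast_2d(points))
        return np.asarray(mesh.vertex_normals)[vid]
    # no mesh: radial pseudo-normal from the configuration centroid
    c = points.mean(axis=0)
    d = points - c
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return d / norms


def build_sliding_plan(
    config: LandmarkConfiguration,
    mesh: trimesh.Trimesh | None = None,
    slide_curves: bool = True,
) -> SlidingPlan:
    """Tangent bases from the specimen's own geometry.

    Curve point i slides along the normalized chord between neighbours i-1 and
    i+1 (one-sided at curve ends); surface points slide in the plane orthogonal
    to the local mesh normal.
    """
    tangents: list[np.ndarray | None] = [None] * config.k
    if slide_curves:
        for cid in config.curve_ids():
            idx = config.curve_indices(cid)
            pts = config.points[idx]
            m = len(idx)
            for j, i in enumerate(idx):
                lo = max(j - 1, 0)
                hi = min(j + 1, m - 1)
                chord = pts[hi] - pts[lo]
                nrm = np.linalg.norm(chord)
                if nrm == 0:
                    continue
                tangents[i] = (chord / nrm)[None, :]
    surf_idx = config.indices(Role.SURFACE)
    if len(surf_idx):
        normals = _surface_normals(config.points[surf_idx], mesh)
        centroid = config.points.mean(axis=0)
        for i, nrm in zip(surf_idx, normals):
            # reference direction from the configuration's own geometry so the
            # basis (hence the whole sliding step) is rigid-motion equivariant
            n = nrm / np.linalg.norm(nrm)
            radial = config.points[i] - centroid
            u = radial - (radial @ n) * n
            if np.linalg.norm(u) > 1e-8 * max(np.linalg.norm(radial), 1.0):
                u = u / np.linalg.norm(u)
                v = np.cross(n, u)
                tangents[i] = np.vstack([u, v])
            else:
                tangents[i] = _orthonormal_complement(n)
    return SlidingPlan(tangents=tangents)


# ---------------------------------------------------------------------------
# Surface patching


def project_to_mesh(points: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    closest, _ = closest_point_on_mesh(mesh, np.atleast_2d(points))
    return closest


def place_patch(
    atlas: TemplateAtlas,
    specimen: LandmarkConfiguration,
    specimen_mesh: trimesh.Trimesh,
) -> LandmarkConfiguration:
    """Transfer the template's surface semilandmarks onto a specimen.

    The template's FIXED+CURVE scaffold is TPS-warped onto the specimen's
    digitized scaffold; the template surface points follow that warp and are
    then projected to the closest point on the specimen mesh.
    """
    if specimen_mesh is None:
        raise IOError("specimen mesh required for patching")
    tmpl = atlas.template_config
    scaffold_roles = (Role.FIXED, Role.CURVE)
    t_scaffold = np.concatenate([tmpl.indices(r) for r in scaffold_roles])
    t_scaffold.sort()
    s_scaffold = np.concatenate([specimen.indices(r) for r in scaffold_roles])
    s_scaffold.sort()
    if len(t_scaffold) != len(s_scaffold):
        raise ValueError("specimen scaffold does not match template layout")

    warp = ThinPlateSpline(tmpl.points[t_scaffold]).fit(specimen.points[s_scaffold])
    surf_idx_t = tmpl.indices(Role.SURFACE)
    warped = warp.transform(tmpl.points[surf_idx_t])
    projected = project_to_mesh(warped, specimen_mesh)

    # output uses the template's full role layout
    points = np.empty_like(tmpl.points)
    scaffold_map = dict(zip(t_scaffold, s_scaffold))
    for ti, si in scaffold_map.items():
        points[ti] = specimen.points[si]
    points[surf_idx_t] = projected
    return LandmarkConfiguration(
        specimen_id=specimen.specimen_id,
        species_id=specimen.species_id,
        points=points,
        roles=list(tmpl.roles),
        mesh_ref=specimen.mesh_ref,
    )


# ---------------------------------------------------------------------------
# Sliding


def _stack(points: np.ndarray) -> np.ndarray:
    """Axis-major stacking: [x0..xk-1, y0..yk-1, z0..zk-1]."""
    return points.T.ravel()


def _unstack(vec: np.ndarray, k: int) -> np.ndarray:
    return vec.reshape(3, k).T


def _tangent_matrix(plan: SlidingPlan, k: int) -> np.ndarray:
    """Block tangent-basis matrix U (3k x n_params) in axis-major stacking."""
    U = np.zeros((3 * k, plan.n_params))
    col = 0
    for i, t in enumerate(plan.tangents):
        if t is None:
            continue
        for row_t in t:
            for ax in range(3):
                U[ax * k + i, col] = row_t[ax]
            col += 1
    return U


@dataclass
class RelaxResult:
    config: LandmarkConfiguration
    energy_before: float
    energy_after: float
    t: np.ndarray


def relax_once(
    specimen: LandmarkConfiguration,
    reference: np.ndarray,
    plan: SlidingPlan | None = None,
    mesh: trimesh.Trimesh | None = None,
    slide_curves: bool = True,
    project: bool = True,
) -> RelaxResult:
    """One bending-energy sliding step of a specimen against a reference.

    Solves min_t (y + U t - x)' B (y + U t - x) in closed form, where x is the
    reference rigidly aligned (with scale) onto the specimen, B is the 3-axis
    block-diagonal bending-energy form of the aligned reference, and U holds
    the tangent bases.  Slid curve points are re-projected onto the specimen's
    original curve polylines and surface points onto the specimen mesh; FIXED
    landmarks never move.
    """
    k = specimen.k
    ref = np.asarray(reference, float)
    if ref.shape != specimen.points.shape:
        raise ValueError("reference must match specimen landmark count")
    if plan is None:
        plan = build_sliding_plan(specimen, mesh, slide_curves=slide_curves)

    # align the reference onto the specimen so sliding happens in specimen frame
    opa = ordinary_procrustes(ref, specimen.points, allow_scale=True)
    x = opa.apply(ref)
    bem = ThinPlateSpline(x).bending_energy_matrix
    Lb = bem.matrix
    y = _stack(specimen.points)
    xs = _stack(x)

    U = _tangent_matrix(plan, k)
    if U.shape[1] == 0:
        e = bem.energy(specimen.points - 0)  # energy of target w.r.t. aligned ref
        return RelaxResult(specimen, e, e, np.zeros(0))

    # B (y + U t - x) quadratic in t; B = I3 (x) Lb acts per axis
    def B_apply(v: np.ndarray) -> np.ndarray:
        return (Lb @ v.reshape(3, k).T).T.ravel()

    BU = np.column_stack([B_apply(U[:, j]) for j in range(U.shape[1])])
    A = U.T @ BU
    b = U.T @ B_apply(y - xs)
    # minimum-norm solution: robust when tangential motions are nearly affine
    # (Lb annihilates affine directions, so A can be close to singular)
    t = -np.linalg.lstsq(A, b, rcond=1e-10)[0]

    new_points = specimen.points + _unstack(U @ t, k)

    energy_before = bem.energy(specimen.points)
    if project:
        # curve points back onto the specimen's original curve polylines
        for cid in specimen.curve_ids():
            idx = specimen.curve_indices(cid)
            if plan.tangents[idx[0]] is None and slide_curves is False:
                continue
            poly = specimen.points[idx]
            for i in idx:
                new_points[i] = _project_to_polyline(new_points[i], poly)
        surf_idx = specimen.indices(Role.SURFACE)
        if len(surf_idx) and mesh is not None:
            new_points[surf_idx] = project_to_mesh(new_points[surf_idx], mesh)
    # fixed landmarks are bit-identical
    fixed_idx = specimen.indices(Role.FIXED)
    new_points[fixed_idx] = specimen.points[fixed_idx]

    out = specimen.with_points(new_points)
    energy_after = bem.energy(new_points)
    return RelaxResult(out, energy_before, energy_after, t)


def _project_to_polyline(point: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Closest point on a piecewise-linear curve."""
    best = poly[0]
    best_d = np.inf
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        s = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
        cand = a + s * ab
        d = float(np.sum((point - cand) ** 2))
        if d < best_d:
            best_d = d
            best = cand
    return best


@dataclass
class SlideTrace:
    """Per-iteration total bending energy of the sample during sliding."""

    energies: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"total_bending_energy": self.energies}, indent=2))


def relax_to_consensus(
    samples: Sequence[LandmarkConfiguration],
    meshes: Sequence[trimesh.Trimesh | None] | None = None,
    iterations: int = 3,
    slide_curves: bool = True,
) -> tuple[list[LandmarkConfiguration], SlideTrace]:
    """Iteratively slide every specimen against the updating Procrustes consensus.

    Each iteration: GPA -> consensus -> one relax step per specimen (with
    projection).  Returns the slid configurations and the trace of total
    bending energy (entry 0 is the pre-slide energy).
    """
    configs = list(samples)
    if meshes is None:
        meshes = [None] * len(configs)
    trace = SlideTrace()

    def consensus_mm(cfgs):
        aligned = gpa(cfgs)
        return aligned.consensus * float(aligned.centroid_sizes.mean())

    cons = consensus_mm(configs)
    trace.energies.append(_total_energy(configs, cons))
    for _ in range(iterations):
        new_configs = []
        total = 0.0
        for cfg, mesh in zip(configs, meshes):
            res = relax_once(cfg, cons, mesh=mesh, slide_curves=slide_curves)
            new_configs.append(res.config)
            total += res.energy_after
        configs = new_configs
        trace.energies.append(total)
        cons = consensus_mm(configs)
    return configs, trace


def _total_energy(configs: Sequence[LandmarkConfiguration], reference: np.ndarray) -> float:
    total = 0.0
    for cfg in configs:
        opa = ordinary_procrustes(reference, cfg.points, allow_scale=True)
        x = opa.apply(reference)
        total += ThinPlateSpline(x).bending_energy_matrix.energy(cfg.points)
    return total


def average_replicates(
    rep_a: LandmarkConfiguration, rep_b: LandmarkConfiguration
) -> LandmarkConfiguration:
    """Combine two digitizations of one specimen.

    The second replicate is rigidly aligned (no scaling) onto the first and
    the two are averaged pointwise — the minimal-variance combination of
    duplicate measurements.
    """
    opa = ordinary_procrustes(rep_b.points, rep_a.points, allow_scale=False)
    avg = 0.5 * (rep_a.points + opa.apply(rep_b.points))
    return rep_a.with_points(avg)
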