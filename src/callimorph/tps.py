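"""Thin-plate-spline interpolation and bending energy in 3D.

The 3D kernel is phi(r) = r.  The interpolant through reference landmarks
``X`` (k x 3) hitting targets ``Y`` solves the bordered system

    [ K  P ] [ W ]   [ Y ]
    [ P' 0 ] [ A ] = [ 0 ],   K_ij = |x_i - x_j|,  P = [1 | X].

The bending energy of a target configuration per coordinate axis is the
quadratic form ``y' Lb y`` where ``Lb`` is (minus) the landmark block of the
inverse bordered system; with phi(r) = r that block is negative semidefinite
(|r| is conditionally negative definite of order 1), so the sign flip makes
the energy matrix PSD with the affine subspace as its null space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


class SingularKernelError(np.linalg.LinAlgError):
    """Reference configuration is coplanar/collinear; the TPS system is singular."""


@dataclass
class BendingEnergyMatrix:
    """PSD k x k quadratic form whose null space is the affine maps of the reference."""

    reference_id: str
    matrix: np.ndarray

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    def energy(self, target: np.ndarray) -> float:
        """Total bending energy of a k x 3 target, summed over coordinate axes."""
        y = np.asarray(target, float)
        return float(np.einsum("ia,ij,ja->", y, self.matrix, y))


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cdist(a, b)


def _check_reference(reference: np.ndarray) -> np.ndarray:
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 4:
        raise ValueError("reference must be k x 3 with k >= 4")
    centered = ref - ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        raise SingularKernelError("reference landmarks are coplanar or collinear")
    return ref


class ThinPlateSpline:
    """TPS warp from a fixed reference to arbitrary targets.

    Build once per reference; :meth:`fit` solves for one target, after which
    :meth:`transform` maps arbitrary query points through the deformation.
    """

    def __init__(self, reference: np.ndarray, reference_id: str = "reference"):
        ref = _check_reference(reference)
        self.reference = ref
        self.reference_id = reference_id
        k = ref.shape[0]
        K = _kernel(ref, ref)
        P = np.hstack([np.ones((k, 1)), ref])
        L = np.zeros((k + 4, k + 4))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        try:
            self._L_inv = np.linalg.inv(L)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise SingularKernelError(str(exc)) from exc
        self._coefs: np.ndarray | None = None

    @property
    def bending_energy_matrix(self) -> BendingEnergyMatrix:
        k = self.reference.shape[0]
        Lb = -self._L_inv[:k, :k]
        Lb = 0.5 * (Lb + Lb.T)
        # project out numerically negative directions so the form is PSD
        w, V = np.linalg.eigh(Lb)
        w = np.where((w > -1e-10) & (w < 0), 0.0, w)
        Lb = (V * w) @ V.T
        return BendingEnergyMatrix(self.reference_id, 0.5 * (Lb + Lb.T))

    def fit(self, target: np.ndarray) -> "ThinPlateSpline":
        y = np.asarray(target, float)
        if y.shape != self.reference.shape:
            raise ValueError("target must match reference shape")
        k = y.shape[0]
        rhs = np.vstack([y, np.zeros((4, 3))])
        self._coefs = self._L_inv @ rhs
        self._target = y
        return self

    def transform(self, query_points: np.ndarray) -> np.ndarray:
        if self._coefs is None:
            raise RuntimeError("call fit(target) before transform")
        q = np.atleast_2d(np.asarray(query_points, float))
        k = self.reference.shape[0]
        U = _kernel(q, self.reference)
        P = np.hstack([np.ones((q.shape[0], 1)), q])
        return U @ self._coefs[:k] + P @ self._coefs[k:]

    def bending_energy(self, target: np.ndarray | None = None) -> float:
        if target is None:
            if self._coefs is None:
                raise RuntimeError("no target fitted")
            target = self._target
        return self.bending_energy_matrix.energy(target)


def tps_build(reference: np.ndarray, reference_id: str = "reference"):
    """Return ``(solver, BendingEnergyMatrix)`` for a k x 3 reference."""
    solver = ThinPlateSpline(reference, reference_id)
    return solver, solver.bending_energy_matrix


def tps_warp(reference: np.ndarray, target: np.ndarray, query_points: np.ndarray) -> np.ndarray:
    """Warp query points by the TPS interpolant taking reference onto target."""
    return ThinPlateSpline(reference).fit(target).transform(query_points)
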