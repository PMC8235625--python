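"""Ordinary and generalized Procrustes superimposition.

Full Procrustes: configurations are centred, scaled to unit centroid size,
and rotated (proper rotations only — reflections are never allowed, so
left/right bones cannot be mirrored implicitly).  The generalized procedure
iterates rotation to an updating consensus until the consensus stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landmarks import LandmarkConfiguration, centroid_size, same_layout


class DegenerateConfigurationError(ValueError):
    pass


@dataclass
class OPAResult:
    rotation: np.ndarray  # 3x3 proper rotation applied to the source
    scale: float
    translation: np.ndarray  # length-3
    residual: float  # root summed squared distance after fitting

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation + self.translation


def _optimal_rotation(source_c: np.ndarray, target_c: np.ndarray) -> np.ndarray:
    """Proper (det +1) rotation R minimizing ||source_c @ R - target_c||."""
    H = source_c.T @ target_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def ordinary_procrustes(
    source: np.ndarray, target: np.ndarray, allow_scale: bool = True
) -> OPAResult:
    """Least-squares rigid (optionally scaled) superimposition of source on target."""
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if src.shape != tgt.shape:
        raise ValueError("source and target must have matching shape")
    src_mean = src.mean(axis=0)
    tgt_mean = tgt.mean(axis=0)
    src_c = src - src_mean
    tgt_c = tgt - tgt_mean
    ss = np.sum(src_c**2)
    if ss < 1e-24:
        raise DegenerateConfigurationError("all source points coincide")
    R = _optimal_rotation(src_c, tgt_c)
    if allow_scale:
        scale = float(np.trace(src_c @ R @ tgt_c.T)) / ss
        if scale <= 0:
            scale = 1.0
    else:
        scale = 1.0
    translation = tgt_mean - scale * src_mean @ R
    fitted = scale * src @ R + translation
    residual = float(np.sqrt(np.sum((fitted - tgt) ** 2)))
    return OPAResult(rotation=R, scale=scale, translation=translation, residual=residual)


@dataclass
class AlignedSample:
    """Procrustes-aligned shapes (unit centroid size) with raw sizes and consensus."""

    shapes: np.ndarray  # n x k x 3
    centroid_sizes: np.ndarray  # n, in mm, from the raw inputs
    consensus: np.ndarray  # k x 3, unit centroid size
    converged: bool
    iterations: int
    specimen_ids: list[str] | None = None
    species_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """n x 3k matrix of flattened shapes."""
        return self.shapes.reshape(self.n, -1)


def _normalize(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))


def gpa(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes analysis (full Procrustes, no reflections)."""
    if isinstance(configs, np.ndarray):
        arrays = [np.asarray(c, float) for c in configs]
        specimen_ids = species_ids = None
    else:
        if len(configs) < 2:
            raise ValueError("GPA needs at least 2 configurations")
        if not same_layout(list(configs)):
            raise ValueError("configurations have mismatched landmark layout")
        arrays = [c.points for c in configs]
        specimen_ids = [c.specimen_id for c in configs]
        species_ids = [c.species_id for c in configs]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("configurations have mismatched landmark counts")

    sizes = np.array([centroid_size(a) for a in arrays])
    shapes = np.stack([_normalize(a) for a in arrays])
    n = shapes.shape[0]

    # initial alignment to the first shape
    consensus = shapes[0]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            R = _optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ R
        new_consensus = _normalize(shapes.mean(axis=0))
        change = np.sqrt(np.sum((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final rotation pass so every shape is aligned to the final consensus
    for i in range(n):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)

    return AlignedSample(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        converged=converged,
        iterations=iterations,
        specimen_ids=specimen_ids,
        species_ids=species_ids,
    )


@dataclass
class SpeciesMean:
    mean_form: np.ndarray  # k x 3, in mm (consensus x mean centroid size)
    mean_cs: float
    n_specimens: int


def species_mean(configs: Sequence[LandmarkConfiguration]) -> SpeciesMean:
    """Mean form of one species: GPA consensus rescaled by the mean centroid size."""
    if len(configs) == 0:
        raise ValueError("no specimens")
    if len(configs) == 1:
        cs = centroid_size(configs[0])
        return SpeciesMean(mean_form=_normalize(configs[0].points) * cs, mean_cs=cs, n_specimens=1)
    aligned = gpa(configs)
    mean_cs = float(aligned.centroid_sizes.mean())
    return SpeciesMean(
        mean_form=aligned.consensus * mean_cs, mean_cs=mean_cs, n_specimens=len(configs)
    )


def species_means(configs: Sequence[LandmarkConfiguration]) -> dict[str, SpeciesMean]:
    """Group specimens by species_id and compute each species' mean form."""
    by_species: dict[str, list[LandmarkConfiguration]] = {}
    for c in configs:
        by_species.setdefault(c.species_id, []).append(c)
    return {sp: species_mean(cs) for sp, cs in by_species.items()}
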