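"""Landmark configurations and their file formats.

A specimen is represented by an ordered set of 3D points, each carrying a
role: a *fixed* (anatomical) landmark, a point on a named *curve* (with its
position along the curve), or a *surface* semilandmark.  Coordinates are in
millimetres, right-handed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Role(Enum):
    FIXED = "fixed"
    CURVE = "curve"
    SURFACE = "surface"


@dataclass(frozen=True)
class PointRole:
    """Role of one landmark: FIXED, CURVE(curve_id, order_index) or SURFACE."""

    role: Role
    curve_id: str | None = None
    order_index: int | None = None

    def __post_init__(self):
        if self.role is Role.CURVE:
            if self.curve_id is None or self.order_index is None:
                raise ValueError("curve points need curve_id and order_index")
        elif self.curve_id is not None or self.order_index is not None:
            raise ValueError(f"{self.role} points carry no curve fields")


FIXED = PointRole(Role.FIXED)
SURFACE = PointRole(Role.SURFACE)


def curve_point(curve_id: str, order_index: int) -> PointRole:
    return PointRole(Role.CURVE, curve_id, order_index)


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 3 landmark coordinates with per-point roles."""

    specimen_id: str
    species_id: str
    points: np.ndarray
    roles: list[PointRole]
    mesh_ref: str | Path | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be k x 3")
        if len(self.roles) != self.points.shape[0]:
            raise ValueError("roles length must match number of points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        self._check_curves()

    def _check_curves(self) -> None:
        by_curve: dict[str, list[int]] = {}
        for r in self.roles:
            if r.role is Role.CURVE:
                by_curve.setdefault(r.curve_id, []).append(r.order_index)
        for cid, idx in by_curve.items():
            srt = sorted(idx)
            if len(set(srt)) != len(srt) or srt != list(range(srt[0], srt[0] + len(srt))):
                raise ValueError(f"curve {cid!r}: order_index not consecutive/unique")

    @property
    def k(self) -> int:
        return self.points.shape[0]

    def indices(self, role: Role) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r.role is role], dtype=int)

    def curve_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.roles:
            if r.role is Role.CURVE and r.curve_id not in seen:
                seen.append(r.curve_id)
        return seen

    def curve_indices(self, curve_id: str) -> np.ndarray:
        pairs = [
            (r.order_index, i)
            for i, r in enumerate(self.roles)
            if r.role is Role.CURVE and r.curve_id == curve_id
        ]
        return np.array([i for _, i in sorted(pairs)], dtype=int)

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, points=np.asarray(points, dtype=float))


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Scale-equivariant: scaling the coordinates by c multiplies the result by c.
    """
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if pts.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


# ---------------------------------------------------------------------------
# File formats

_CSV_COLUMNS = [
    "specimen_id",
    "species_id",
    "landmark_id",
    "role",
    "curve_id",
    "order_index",
    "x",
    "y",
    "z",
]


def _role_of_row(row) -> PointRole:
    role = str(row["role"]).lower()
    if role == "fixed":
        return FIXED
    if role == "surface":
        return SURFACE
    if role == "curve":
        return curve_point(str(row["curve_id"]), int(row["order_index"]))
    raise ValueError(f"unknown role {row['role']!r}")


def read_landmark_csv(path: str | Path) -> list[LandmarkConfiguration]:
    """Read the long-format landmark CSV (one row per landmark)."""
    df = pd.read_csv(path, dtype={"curve_id": "string"})
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    configs = []
    for (spec_id, sp_id), grp in df.groupby(["specimen_id", "species_id"], sort=False):
        grp = grp.sort_values("landmark_id")
        roles = [_role_of_row(row) for _, row in grp.iterrows()]
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(spec_id),
                species_id=str(sp_id),
                points=grp[["x", "y", "z"]].to_numpy(float),
                roles=roles,
            )
        )
    return configs


def write_landmark_csv(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    rows = []
    for cfg in configs:
        for i, (pt, role) in enumerate(zip(cfg.points, cfg.roles)):
            rows.append(
                {
                    "specimen_id": cfg.specimen_id,
                    "species_id": cfg.species_id,
                    "landmark_id": i,
                    "role": role.role.value,
                    "curve_id": role.curve_id if role.curve_id is not None else "",
                    "order_index": role.order_index if role.order_index is not None else "",
                    "x": pt[0],
                    "y": pt[1],
                    "z": pt[2],
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read the classic TPS text format (LM3= blocks, all points FIXED)."""
    text = Path(path).read_text()
    configs = []
    blocks = re.split(r"(?=^LM3?=)", text, flags=re.MULTILINE)
    for block in blocks:
        block = block.strip()
        if not block:
            continue
        lines = block.splitlines()
        m = re.match(r"LM3?=(\d+)", lines[0])
        if not m:
            raise ValueError(f"malformed TPS block header: {lines[0]!r}")
        k = int(m.group(1))
        pts = []
        ident = f"tps_{len(configs)}"
        for line in lines[1:]:
            line = line.strip()
            if line.upper().startswith(("ID=", "IMAGE=")):
                ident = line.split("=", 1)[1].strip() or ident
                continue
            if not line:
                continue
            vals = line.split()
            if len(vals) == 3:
                pts.append([float(v) for v in vals])
        if len(pts) != k:
            raise ValueError(f"TPS block declares {k} landmarks, found {len(pts)}")
        configs.append(
            LandmarkConfiguration(
                specimen_id=ident,
                species_id=ident,
                points=np.array(pts, float),
                roles=[FIXED] * k,
            )
        )
    return configs


def same_layout(configs: Sequence[LandmarkConfiguration]) -> bool:
    """True when all configurations share landmark count and role layout."""
    first = configs[0]
    return all(c.k == first.k and c.roles == first.roles for c in configs[1:])
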