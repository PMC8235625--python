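"""Synthetic test bed: trees, traits, and bone-like 3D landmark datasets.

The generator produces data with exactly the statistical structure the
analysis pipeline assumes: a template "bone" (cylindrical shaft with two
bulbous epiphyses) carrying fixed landmarks, ridge curves and surface
semilandmark patches; species mean shapes evolving by multivariate Brownian
motion on a tree, optionally with clade-specific rate multipliers; an
additive locomotor-group shape offset; an allometric shape component tied to
log centroid size; and independent specimen-level landmark noise.  Every
dataset is bit-reproducible from its recipe and seed.

Shape evolution is simulated in the tangent space at the template
(Procrustes-aligned coordinates) and configurations are re-embedded, the
standard small-deformation shortcut that avoids simulating on the curved
shape manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh
import yaml

import dendropy

from .landmarks import (
    FIXED,
    SURFACE,
    LandmarkConfiguration,
    centroid_size,
    curve_point,
    write_landmark_csv,
)
from .semilandmarks import TemplateAtlas
from .tps import ThinPlateSpline
from .trees import PhyloTree, callitrichid_traits, callitrichid_tree, node_label, write_trait_csv


# ---------------------------------------------------------------------------
# Random trees


def pure_birth_tree(n_tips: int, seed: int, depth: float = 10.0) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree rescaled to the requested root depth."""
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    a = dendropy.Node(edge_length=0.0)
    b = dendropy.Node(edge_length=0.0)
    root.add_child(a)
    root.add_child(b)
    tips = [a, b]
    t_now = 0.0
    events = [0.0, 0.0]  # birth time of each open lineage
    while len(tips) < n_tips:
        t_now += rng.exponential(1.0 / len(tips))
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        born = events.pop(i)
        node.edge.length = t_now - born
        c1 = dendropy.Node(edge_length=0.0)
        c2 = dendropy.Node(edge_length=0.0)
        node.add_child(c1)
        node.add_child(c2)
        tips.extend([c1, c2])
        events.extend([t_now, t_now])
    t_end = t_now + rng.exponential(1.0 / len(tips))
    for node, born in zip(tips, events):
        node.edge.length = t_end - born
    for i, node in enumerate(tips):
        node.taxon = taxa.new_taxon(label=f"sp{i+1:02d}")
    scale = depth / t_end
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    return PhyloTree(tree)


def _ladder_newick(labels: Sequence[str], crown_age: float, min_age: float = 0.1) -> str:
    """Pectinate (ladder) ultrametric subtree over the given tips."""
    m = len(labels)
    if m == 1:
        return f"{labels[0]}:{crown_age}"
    ages = np.linspace(min_age, crown_age, m - 1)
    s = f"({labels[0]}:{ages[0]},{labels[1]}:{ages[0]})"
    for i in range(2, m):
        prev_age = ages[i - 2]
        age = ages[i - 1]
        s = f"({s}:{age - prev_age},{labels[i]}:{age})"
    return s


def two_clade_tree(n_per_clade: int = 8, root_age: float = 10.0, crown_age: float = 1.0) -> PhyloTree:
    """Balanced two-clade tree with shallow crowns and a deep root split.

    Groups assigned to the two clades are strongly confounded with phylogeny:
    under Brownian motion the clade means drift apart, which is the situation
    where a naive ANOVA overstates group differences.
    """
    a = _ladder_newick([f"A{i+1:02d}" for i in range(n_per_clade)], crown_age, min_age=0.1 * crown_age)
    b = _ladder_newick([f"B{i+1:02d}" for i in range(n_per_clade)], crown_age, min_age=0.1 * crown_age)
    stem = root_age - crown_age
    return PhyloTree.from_newick(f"({a}:{stem},{b}:{stem});")


def two_clade_groups(tree: PhyloTree) -> dict[str, str]:
    return {lab: ("VCL" if lab.startswith("A") else "HL") for lab in tree.tip_labels}


# ---------------------------------------------------------------------------
# Template bone


def make_template(
    n_fixed: int = 6,
    curves: Mapping[str, int] | None = None,
    n_surface: int = 24,
    seed: int = 0,
    length: float = 40.0,
    shaft_radius: float = 3.0,
    epiphysis_radius: float = 7.0,
) -> TemplateAtlas:
    """Parametric bone-like template: shaft plus two bulbous epiphyses.

    All landmarks are placed on exact mesh vertices, so template surface
    points lie on the mesh to machine precision.  The seed perturbs the
    radial profile slightly so different seeds give different but valid
    atlases.  Dimensions are mm.
    """
    if curves is None:
        curves = {"ridge": 8}
    if n_fixed < 4:
        raise ValueError("need at least 4 fixed landmarks for TPS")
    rng = np.random.default_rng(seed)
    n_rings, n_around = 41, 24
    z = np.linspace(0.0, length, n_rings)
    w = length / 8.0
    profile = shaft_radius + (epiphysis_radius - shaft_radius) * (
        np.exp(-((z / w) ** 2)) + np.exp(-(((z - length) / w) ** 2))
    )
    # smooth seeded asymmetry
    wobble = 1.0 + 0.03 * np.sin(2 * np.pi * z / length + rng.uniform(0, 2 * np.pi))
    profile = profile * wobble
    theta = np.linspace(0, 2 * np.pi, n_around, endpoint=False)
    ecc = 1.0 + 0.1 * rng.uniform(-1, 1)  # elliptical cross-section

    verts = [np.array([0.0, 0.0, -0.75 * epiphysis_radius])]  # bottom pole
    for zi, ri in zip(z, profile):
        ring = np.column_stack(
            [ri * np.cos(theta), ecc * ri * np.sin(theta), np.full(n_around, zi)]
        )
        verts.append(ring)
    verts.append(np.array([0.0, 0.0, length + 0.75 * epiphysis_radius]))  # top pole
    vertices = np.vstack([verts[0][None, :], *verts[1:-1], verts[-1][None, :]])

    faces = []
    bottom, top = 0, len(vertices) - 1

    def ring_vertex(r, j):
        return 1 + r * n_around + (j % n_around)

    for j in range(n_around):
        faces.append([bottom, ring_vertex(0, j + 1), ring_vertex(0, j)])
        faces.append([top, ring_vertex(n_rings - 1, j), ring_vertex(n_rings - 1, j + 1)])
    for r in range(n_rings - 1):
        for j in range(n_around):
            a = ring_vertex(r, j)
            b = ring_vertex(r, j + 1)
            c = ring_vertex(r + 1, j)
            d = ring_vertex(r + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)

    # fixed landmarks: both poles, then points around the widest rings
    fixed_ids = [bottom, top]
    angle_slots = np.linspace(0, n_around, n_fixed - 2, endpoint=False).astype(int)
    for i, j in enumerate(angle_slots):
        ring = 2 if i % 2 == 0 else n_rings - 3
        fixed_ids.append(ring_vertex(ring, int(j)))
    fixed_ids = fixed_ids[:n_fixed]

    points = [vertices[i] for i in fixed_ids]
    roles = [FIXED] * n_fixed

    # curves: longitudinal ridgelines at distinct angles along the shaft
    used_angles = iter([0, n_around // 3, 2 * n_around // 3, n_around // 2])
    for cid, count in curves.items():
        j = next(used_angles)
        rings = np.linspace(4, n_rings - 5, count).astype(int)
        for order, r in enumerate(rings):
            points.append(vertices[ring_vertex(int(r), j)])
            roles.append(curve_point(cid, order))

    # surface semilandmarks: seeded choice of epiphysis vertices
    epi_rings = list(range(0, 4)) + list(range(n_rings - 4, n_rings))
    candidates = [ring_vertex(r, j) for r in epi_rings for j in range(n_around)]
    candidates = [c for c in candidates if c not in set(fixed_ids)]
    chosen = rng.choice(len(candidates), size=n_surface, replace=False)
    for c in sorted(chosen):
        points.append(vertices[candidates[c]])
        roles.append(SURFACE)

    config = LandmarkConfiguration(
        specimen_id="template",
        species_id="template",
        points=np.array(points),
        roles=roles,
    )
    return TemplateAtlas(
        template_config=config,
        template_mesh=mesh,
        curve_counts=dict(curves),
        surface_count=n_surface,
    )


# ---------------------------------------------------------------------------
# Recipe and simulation


@dataclass
class SimulationRecipe:
    """Ground-truth parameters of one synthetic study.

    Defaults emulate the study design: a 25-tip callitrichid-like tree, two
    locomotor groups, up to three specimens per species, small digitization
    noise relative to shape scale, and a modest allometric component.
    """

    seed: int
    tree: PhyloTree | None = None  # default: the 25-tip fixture tree
    n_taxa: int | None = None  # pure-birth tree if no explicit tree
    base_rate: float = 1e-4  # sigma^2, squared Procrustes units per My
    clade_rate_multipliers: dict[tuple[str, ...], float] = field(default_factory=dict)
    group_map: dict[str, str] | None = None  # default: fixture VCL/HL coding
    group_offset_magnitude: float = 0.02  # Procrustes units, added to VCL tips
    allometry_magnitude: float = 0.03  # Procrustes units per unit log size
    log_size_range: tuple[float, float] = (3.4, 4.0)  # log mm
    specimen_noise_sd: float = 0.004  # Procrustes units per coordinate
    n_specimens_per_species: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(m <= 0 for m in self.clade_rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")
        if self.specimen_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def resolve_tree(self) -> PhyloTree:
        if self.tree is not None:
            return self.tree
        if self.n_taxa is not None:
            return pure_birth_tree(self.n_taxa, seed=self.seed + 7)
        return callitrichid_tree()

    def resolve_groups(self, tree: PhyloTree) -> dict[str, str]:
        if self.group_map is not None:
            return dict(self.group_map)
        fixture = callitrichid_traits()
        if set(tree.tip_labels) <= set(fixture):
            return {l: fixture[l] for l in tree.tip_labels}
        # fall back: alternate assignment over sorted tips
        return {l: ("VCL" if i % 2 == 0 else "HL") for i, l in enumerate(sorted(tree.tip_labels))}

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "seed": self.seed,
            "base_rate": self.base_rate,
            "clade_rate_multipliers": {",".join(k): v for k, v in self.clade_rate_multipliers.items()},
            "group_offset_magnitude": self.group_offset_magnitude,
            "allometry_magnitude": self.allometry_magnitude,
            "log_size_range": list(self.log_size_range),
            "specimen_noise_sd": self.specimen_noise_sd,
            "n_specimens_per_species": self.n_specimens_per_species,
            "n_taxa": self.n_taxa,
            "tree_newick": self.resolve_tree().newick(),
        }
        Path(path).write_text(yaml.safe_dump(d))


def _branch_multipliers(tree: PhyloTree, clade_mults: Mapping[tuple[str, ...], float]):
    """Per-node (branch) rate multiplier; clade = MRCA of the given tip set."""
    t = tree.dendropy_tree
    mult = {}
    for node in t.preorder_node_iter():
        mult[id(node)] = 1.0
    taxa = {x.label: x for x in t.taxon_namespace}
    for tip_set, m in clade_mults.items():
        mrca = t.mrca(taxa=[taxa[l] for l in tip_set])
        stack = [mrca]
        while stack:
            nd = stack.pop()
            mult[id(nd)] = m
            stack.extend(nd.child_nodes())
    return mult


def simulate_bm_shapes(
    tree: PhyloTree,
    recipe: SimulationRecipe,
    template_flat: np.ndarray,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Species mean shape vectors by multivariate Brownian motion on the tree.

    Each branch adds N(0, sigma^2 * multiplier * length) noise per coordinate;
    tips in the VCL set additionally receive the group offset.  Deterministic
    given the recipe seed.
    """
    if rng is None:
        rng = np.random.default_rng(recipe.seed)
    d = len(template_flat)
    mult = _branch_multipliers(tree, recipe.clade_rate_multipliers)
    groups = recipe.resolve_groups(tree)
    t = tree.dendropy_tree
    values: dict[int, np.ndarray] = {id(t.seed_node): np.zeros(d)}
    out: dict[str, np.ndarray] = {}
    delta = _unit_vector(rng, d) * recipe.group_offset_magnitude
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        var = recipe.base_rate * mult[id(node)] * node.edge.length
        step = rng.standard_normal(d) * np.sqrt(var)
        values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            v = values[id(node)].copy()
            if groups.get(node.taxon.label) == "VCL":
                v = v + delta
            out[node.taxon.label] = template_flat + v
    return out


def _unit_vector(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@dataclass
class SyntheticDataset:
    tree: PhyloTree
    atlas: TemplateAtlas
    configs: list[LandmarkConfiguration]
    meshes: dict[str, trimesh.Trimesh]
    traits: dict[str, str]
    species_shapes: dict[str, np.ndarray]
    ground_truth: dict
    recipe: SimulationRecipe

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_landmark_csv(self.configs, out / "landmarks.csv")
        self.tree.write(out / "tree.nwk")
        write_trait_csv(self.traits, out / "traits.csv")
        self.recipe.to_yaml(out / "recipe.yaml")
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for spec_id, mesh in self.meshes.items():
            mesh.export(mesh_dir / f"{spec_id}.ply", encoding="ascii")


def realize_specimens(
    species_shapes: Mapping[str, np.ndarray],
    recipe: SimulationRecipe,
    atlas: TemplateAtlas,
    tree: PhyloTree | None = None,
    rng: np.random.Generator | None = None,
    with_meshes: bool = True,
) -> SyntheticDataset:
    """Per-specimen realizations of the species mean shapes.

    Each specimen gets an allometric deformation scaled by its drawn log
    centroid size, isotropic landmark noise, a mesh warped from the template
    through the specimen's landmarks, and a random rigid motion.
    """
    if rng is None:
        rng = np.random.default_rng(recipe.seed + 1)
    if tree is None:
        tree = recipe.resolve_tree()
    tmpl = atlas.template_config
    k = tmpl.k
    s0 = centroid_size(tmpl)
    allo = _unit_vector(rng, 3 * k) * recipe.allometry_magnitude
    lo, hi = recipe.log_size_range
    mid = 0.5 * (lo + hi)
    groups = recipe.resolve_groups(tree)

    configs: list[LandmarkConfiguration] = []
    meshes: dict[str, trimesh.Trimesh] = {}
    truth_specimens = {}
    for sp in sorted(species_shapes):
        base = np.asarray(species_shapes[sp], float).ravel()
        sp_log_size = rng.uniform(lo, hi)
        for j in range(recipe.n_specimens_per_species):
            log_cs = sp_log_size + rng.normal(0.0, 0.05)
            flat = base + allo * (log_cs - mid)
            flat = flat + rng.normal(0.0, recipe.specimen_noise_sd, size=3 * k)
            pts = flat.reshape(k, 3)
            # rescale to the drawn centroid size (shape lives at template scale)
            pts = pts - pts.mean(axis=0)
            pts = pts * (np.exp(log_cs) / np.sqrt(np.sum(pts**2)))
            spec_id = f"{sp}_s{j+1}"
            mesh = None
            if with_meshes:
                warp = ThinPlateSpline(tmpl.points).fit(
                    pts * 1.0
                )  # template landmarks -> specimen landmarks
                mv = warp.transform(atlas.template_mesh.vertices)
                mesh = trimesh.Trimesh(mv, atlas.template_mesh.faces.copy(), process=False)
            R = _random_rotation(rng)
            shift = rng.uniform(-100, 100, size=3)
            pts = pts @ R + shift
            if mesh is not None:
                mesh.vertices = np.asarray(mesh.vertices) @ R + shift
                meshes[spec_id] = mesh
            configs.append(
                LandmarkConfiguration(
                    specimen_id=spec_id,
                    species_id=sp,
                    points=pts,
                    roles=list(tmpl.roles),
                    mesh_ref=f"meshes/{spec_id}.ply" if with_meshes else None,
                )
            )
            truth_specimens[spec_id] = {"log_cs": float(log_cs)}

    traits = {sp: groups[sp] for sp in species_shapes}
    ground_truth = {
        "allometry_vector": allo,
        "specimens": truth_specimens,
        "group_offset_magnitude": recipe.group_offset_magnitude,
        "clade_rate_multipliers": {",".join(k_): v for k_, v in recipe.clade_rate_multipliers.items()},
    }
    return SyntheticDataset(
        tree=tree,
        atlas=atlas,
        configs=configs,
        meshes=meshes,
        traits=traits,
        species_shapes=dict(species_shapes),
        ground_truth=ground_truth,
        recipe=recipe,
    )


def generate_dataset(recipe: SimulationRecipe, atlas: TemplateAtlas | None = None,
                     with_meshes: bool = True) -> SyntheticDataset:
    """Recipe -> full dataset: tree, species shapes, specimens, traits."""
    if atlas is None:
        atlas = make_template(seed=recipe.seed)
    tree = recipe.resolve_tree()
    rng = np.random.default_rng(recipe.seed)
    # tangent space at the template: centered, unit centroid size
    tp = atlas.template_config.points
    tp = tp - tp.mean(axis=0)
    template_flat = (tp / np.sqrt(np.sum(tp**2))).ravel()
    shapes = simulate_bm_shapes(tree, recipe, template_flat, rng=rng)
    return realize_specimens(shapes, recipe, atlas, tree=tree, rng=rng, with_meshes=with_meshes)
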