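"""Phylogenetic trees: I/O, composite-tree construction, and covariance.

Trees are rooted, strictly bifurcating, with branch lengths in millions of
years (My).  Storage and parsing are delegated to dendropy; this module adds
the operations the comparative analyses need: grafting taxa from a patch
phylogeny onto a backbone with cross-multiplied branch-length scaling, tip
substitution, and the Brownian-motion covariance matrix.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np


class PolytomyError(ValueError):
    pass


class NewickParseError(ValueError):
    pass


class PhyloTree:
    """Rooted bifurcating tree with positive branch lengths (My)."""

    def __init__(self, tree: dendropy.Tree, validate: bool = True, allow_polytomies: bool = False):
        self._t = tree
        self._t.is_rooted = True
        self.allow_polytomies = allow_polytomies
        if validate:
            self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, allow_polytomies: bool = False) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(t, allow_polytomies=allow_polytomies)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def newick(self) -> str:
        return self._t.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def copy(self) -> "PhyloTree":
        # full deep copy via serialization: clone(depth=1) shares the taxon
        # namespace, so label edits would leak back into the source tree
        t = dendropy.Tree.get(
            data=self.newick(), schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
        return PhyloTree(t, validate=False, allow_polytomies=self.allow_polytomies)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")
        for node in self._t.preorder_node_iter():
            ch = node.child_nodes()
            if len(ch) not in (0, 2) and not self.allow_polytomies:
                where = "root" if node is self._t.seed_node else repr(node_label(node))
                raise PolytomyError(
                    f"{where} has {len(ch)} children; polytomies are rejected "
                    "(pass allow_polytomies=True only for analytic special cases "
                    "such as a star phylogeny)"
                )
            if node is self._t.seed_node:
                continue
            if node.edge.length is None or node.edge.length <= 0:
                raise ValueError(f"non-positive branch length at {node_label(node)!r}")

    # -- basic queries ------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._t.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._t.leaf_nodes())

    def find_tip(self, label: str) -> dendropy.Node:
        for leaf in self._t.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"tip {label!r} not in tree")

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        self._t.calc_node_root_distances(return_leaf_distances_only=False)
        return {leaf.taxon.label: leaf.root_distance for leaf in self._t.leaf_node_iter()}

    def max_depth(self) -> float:
        return max(self.depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = list(self.depths().values())
        return (max(d) - min(d)) <= rel_tol * max(d)

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        labels = sorted(self.tip_labels)
        pdm = self._t.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._t.taxon_namespace}
        n = len(labels)
        D = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
        return labels, D

    def vcv(self, order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Brownian-motion covariance: C[i, j] = shared root-path length of tips i, j."""
        depths = self.depths()
        labels = list(order) if order is not None else sorted(self.tip_labels)
        lab_set = set(self.tip_labels)
        for lab in labels:
            if lab not in lab_set:
                raise KeyError(f"tip {lab!r} not in tree")
        pdm_labels, D = self.patristic_distances()
        pos = {lab: i for i, lab in enumerate(pdm_labels)}
        n = len(labels)
        C = np.zeros((n, n))
        for i, a in enumerate(labels):
            C[i, i] = depths[a]
            for j in range(i + 1, n):
                b = labels[j]
                shared = 0.5 * (depths[a] + depths[b] - D[pos[a], pos[b]])
                C[i, j] = C[j, i] = shared
        return labels, C

    def internal_clades(self) -> dict[str, list[str]]:
        """Internal node id -> sorted tip labels of its clade (root included)."""
        out = {}
        for node in self._t.preorder_internal_node_iter():
            tips = sorted(l.taxon.label for l in node.leaf_iter())
            out[node_label(node)] = tips
        return out


def node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    tips = sorted(l.taxon.label for l in node.leaf_iter())
    return "mrca(" + ",".join(tips[:1] + tips[-1:]) + f")[{len(tips)}]"


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.read(path)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.write(path)


def substitute_tip(tree: PhyloTree, old_label: str, new_label: str) -> PhyloTree:
    """Swap one tip label; topology and branch lengths untouched."""
    out = tree.copy()
    leaf = out.find_tip(old_label)
    leaf.taxon.label = new_label
    return PhyloTree(out.dendropy_tree, validate=False)


# ---------------------------------------------------------------------------
# Composite-tree construction


def _time_before_present(tree: PhyloTree, label: str) -> float:
    return tree.depths()[label]


def _divergence_time(tree: PhyloTree, a: str, b: str) -> float:
    """Time before present of the MRCA of tips a, b (ultrametric patch)."""
    t = tree.dendropy_tree
    taxa = {x.label: x for x in t.taxon_namespace}
    mrca = t.mrca(taxa=[taxa[a], taxa[b]])
    t.calc_node_root_distances(return_leaf_distances_only=False)
    return tree.depths()[a] - mrca.root_distance


def graft_with_scaling(
    backbone: PhyloTree,
    patch: PhyloTree,
    new_taxa: Sequence[str | tuple[str, str]],
) -> PhyloTree:
    """Attach taxa from a patch phylogeny onto the backbone.

    Branch lengths of the patch are rescaled by cross multiplication: for a
    new taxon X with shared species S, the scaling factor is
    f = depth(S in backbone) / depth(S in patch), and X attaches to S's
    lineage at f * t_div My before present (t_div = X-S divergence in the
    patch), with pendant length f * t_div.  If that time falls beyond an
    internal node of the backbone the attachment climbs to the next ancestral
    edge; running past the root raises an error.

    ``new_taxa`` entries are either taxon names (the shared species is chosen
    as the patristically closest backbone tip within the patch) or explicit
    ``(new_taxon, shared_species)`` pairs.
    """
    out = backbone.copy()
    bb_labels = set(out.tip_labels)
    patch_labels = set(patch.tip_labels)
    for entry in new_taxa:
        if isinstance(entry, tuple):
            x, s = entry
        else:
            x = entry
            shared = sorted(bb_labels & patch_labels - {x})
            if not shared:
                raise ValueError(f"no species shared between backbone and patch for {x!r}")
            s = min(shared, key=lambda lab: _divergence_time(patch, x, lab))
        if x not in patch_labels:
            raise KeyError(f"taxon {x!r} not in patch")
        if s not in bb_labels or s not in patch_labels:
            raise KeyError(f"shared species {s!r} must be in both trees")
        f = _time_before_present(out, s) / _time_before_present(patch, s)
        t_div = _divergence_time(patch, x, s)
        _attach_tip(out, s, x, f * t_div)
        bb_labels.add(x)
    return PhyloTree(out.dendropy_tree)


def _attach_tip(tree: PhyloTree, anchor_label: str, new_label: str, t_attach: float) -> None:
    """Insert a new tip branching off ``anchor_label``'s lineage t_attach My ago."""
    t = tree.dendropy_tree
    node = tree.find_tip(anchor_label)
    below = 0.0  # time before present at the bottom (tipward end) of current edge
    while node.parent_node is not None:
        top = below + node.edge.length
        if t_attach <= top + 1e-12:
            break
        below = top
        node = node.parent_node
    else:
        raise ValueError(f"divergence older than backbone constraint for {new_label!r}")
    # split node's edge at t_attach
    parent = node.parent_node
    upper = below + node.edge.length - t_attach
    lower = t_attach - below
    if lower <= 0 or upper <= 0:
        # degenerate split exactly at a node: nudge into the edge
        eps = 1e-9 * max(node.edge.length, 1.0)
        lower = max(lower, eps)
        upper = max(node.edge.length - lower, eps)
    new_internal = dendropy.Node(edge_length=upper)
    parent.remove_child(node)
    parent.add_child(new_internal)
    node.edge.length = lower
    new_internal.add_child(node)
    taxon = t.taxon_namespace.new_taxon(label=new_label)
    new_tip = dendropy.Node(edge_length=t_attach)
    new_tip.taxon = taxon
    new_internal.add_child(new_tip)


# ---------------------------------------------------------------------------
# Trait tables


def read_trait_csv(path: str | Path) -> dict[str, str]:
    """Two-column CSV species_id,category -> mapping."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def write_trait_csv(traits: Mapping[str, str], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"species_id": list(traits.keys()), "category": list(traits.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Study-system fixture
#
# Topology of the composite callitrichid phylogeny used throughout the tests:
# the Leontocebus clade; the Saguinus clade containing the midas group and
# the geoffroyi/oedipus group; Leontopithecus sister to Callimico plus the
# marmosets (Callithrix, and Cebuella within the Mico region).  Branch
# lengths are APPROXIMATE round numbers in My: only topology-dependent
# analyses (parsimony ancestral states) may be asserted against this fixture.

_CALLITRICHID_NEWICK = (
    "(((Saguinus_leucopus:5,(Saguinus_geoffroyi:3,Saguinus_oedipus:3):2):5,"
    "((Saguinus_mystax:4,(Saguinus_imperator:2.5,Saguinus_labiatus:2.5):1.5):4.5,"
    "(Saguinus_bicolor:5.5,(Saguinus_midas:3,Saguinus_niger:3):2.5):3):1.5):5,"
    "((Leontocebus_fuscus:7,(Leontocebus_nigrifrons:6,(Leontocebus_tripartitus:4.5,"
    "(Leontocebus_melanoleucus:3,Leontocebus_weddelli:3):1.5):1.5):1):6,"
    "((Leontopithecus_chrysomelas:2.5,Leontopithecus_rosalia:2.5):9.5,"
    "(Callimico_goeldii:11,((Callithrix_geoffroyi:5,(Callithrix_kuhlii:3.5,"
    "(Callithrix_penicillata:2,Callithrix_jacchus:2):1.5):1.5):4,"
    "(Cebuella_pygmaea:6,(Mico_argentatus:4,(Mico_humeralifer:2.5,"
    "Mico_melanurus:2.5):1.5):2):3):2):1):1):2);"
)

# Locomotor category per species (Table-style coding): VCL = vertical
# clinging and leaping, HL = horizontal leaping.
CALLITRICHID_TRAITS: dict[str, str] = {
    "Callimico_goeldii": "VCL",
    "Callithrix_geoffroyi": "VCL",
    "Callithrix_jacchus": "VCL",
    "Callithrix_kuhlii": "VCL",
    "Callithrix_penicillata": "VCL",
    "Cebuella_pygmaea": "VCL",
    "Leontopithecus_chrysomelas": "HL",
    "Leontopithecus_rosalia": "HL",
    "Leontocebus_fuscus": "VCL",
    "Leontocebus_melanoleucus": "VCL",
    "Leontocebus_nigrifrons": "VCL",
    "Leontocebus_tripartitus": "VCL",
    "Leontocebus_weddelli": "VCL",
    "Mico_argentatus": "VCL",
    "Mico_humeralifer": "VCL",
    "Mico_melanurus": "VCL",
    "Saguinus_bicolor": "VCL",
    "Saguinus_geoffroyi": "HL",
    "Saguinus_imperator": "HL",
    "Saguinus_labiatus": "HL",
    "Saguinus_leucopus": "HL",
    "Saguinus_midas": "HL",
    "Saguinus_mystax": "HL",
    "Saguinus_niger": "HL",
    "Saguinus_oedipus": "HL",
}


def callitrichid_tree() -> PhyloTree:
    """25-tip callitrichid fixture tree (topology real, lengths APPROXIMATE)."""
    return PhyloTree.from_newick(_CALLITRICHID_NEWICK)


def callitrichid_traits() -> dict[str, str]:
    return dict(CALLITRICHID_TRAITS)


def star_tree(n_tips: int, depth: float = 1.0) -> PhyloTree:
    """Star phylogeny (single root polytomy, equal depths).

    On a star the Brownian covariance is diagonal, so Blomberg's K equals 1
    exactly for any non-constant trait; used as an analytic special case.
    """
    tips = ",".join(f"t{i+1:02d}:{depth:g}" for i in range(n_tips))
    return PhyloTree.from_newick(f"({tips});", allow_polytomies=True)
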