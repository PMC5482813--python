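"""Dated phylogeny parsing and queries.

The analysis runs on a rooted, dated (ultrametric) species tree with branch
lengths in million years (MY).  Node ages are reconstructed from branch
lengths; every leaf sits at age 0 and internal nodes at the divergence time
of their descendants.  A small packaged fixture tree over the 28 eukaryotes
used throughout the package is available via :func:`default_tree`, and the
matching taxonomic groupings (amphibian, fish, bird, fungi, plant, protist)
via :func:`default_clades`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "CladeMap",
    "parse_tree",
    "read_clades",
    "write_clades",
    "default_tree",
    "default_clades",
    "TreeValidationError",
]

#: leaves may deviate from age 0 by this fraction of the root age
ULTRAMETRIC_RTOL = 1e-3


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the dated-tree contract."""


@dataclass
class Phylogeny:
    """Rooted dated tree in postorder array form.

    Nodes are indexed 0..n_nodes-1 in postorder (children before parents,
    root last).  ``children[i]`` lists child indices, ``parent[i]`` is -1 for
    the root, ``edge_length[i]`` is the branch above node ``i`` in MY and
    ``age[i]`` the node's age in MY (leaves 0).  ``taxa`` holds leaf names in
    the order used by pattern vectors.
    """

    taxa: list[str]
    children: list[list[int]]
    parent: np.ndarray
    edge_length: np.ndarray
    age: np.ndarray
    leaf_nodes: np.ndarray  # node index of taxa[i]
    _newick: str = field(default="", repr=False)
    _leaf_lookup: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._leaf_lookup:
            self._leaf_lookup = {name: i for i, name in enumerate(self.taxa)}
        if len(self._leaf_lookup) != len(self.taxa):
            raise TreeValidationError("leaf names are not unique")

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    def leaf_index(self, name: str) -> int:
        try:
            return self._leaf_lookup[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def postorder(self) -> range:
        return range(self.n_nodes)

    def mrca(self, species: Iterable[str]) -> int:
        """Node index of the most recent common ancestor of ``species``."""
        names = list(species)
        if not names:
            raise ValueError("mrca of an empty species set is undefined")
        nodes = [int(self.leaf_nodes[self.leaf_index(n)]) for n in names]
        current = nodes[0]
        ancestors = {current}
        while self.parent[current] >= 0:
            current = int(self.parent[current])
            ancestors.add(current)
        deepest = nodes[0]
        for node in nodes[1:]:
            while node not in ancestors:
                node = int(self.parent[node])
            if self.age[node] > self.age[deepest]:
                deepest = node
        return deepest

    def mrca_age(self, species: Iterable[str]) -> float:
        """Age in MY of the most recent common ancestor of ``species``."""
        return float(self.age[self.mrca(species)])

    def serialize(self) -> str:
        """Newick string with branch lengths in MY."""

        def render(node: int) -> str:
            if not self.children[node]:
                label = self.taxa[int(np.nonzero(self.leaf_nodes == node)[0][0])]
            else:
                label = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if self.parent[node] >= 0:
                return f"{label}:{self.edge_length[node]:.10g}"
            return label

        return render(self.root) + ";"


def parse_tree(newick_text: str, *, ultrametric_rtol: float = ULTRAMETRIC_RTOL) -> Phylogeny:
    """Parse a newick tree with branch lengths in MY into a :class:`Phylogeny`.

    Node ages are computed by subtracting root-to-node path lengths from the
    tree height.  The tree must be ultrametric: every leaf's reconstructed
    age must be within ``ultrametric_rtol`` of the root age, otherwise a
    :class:`TreeValidationError` naming the worst-offending leaf is raised.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from exc

    dnodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    children: list[list[int]] = [[] for _ in range(n)]
    parent = np.full(n, -1, dtype=np.int64)
    edge_length = np.zeros(n)
    depth = np.zeros(n)

    for i, nd in enumerate(dnodes):
        edge_length[i] = float(nd.edge.length or 0.0)
        for ch in nd.child_nodes():
            j = index[id(ch)]
            children[i].append(j)
            parent[j] = i
    # depths top-down (reverse postorder)
    for i in reversed(range(n)):
        p = parent[i]
        depth[i] = (depth[p] if p >= 0 else 0.0) + (edge_length[i] if p >= 0 else 0.0)

    taxa: list[str] = []
    leaf_nodes: list[int] = []
    for i, nd in enumerate(dnodes):
        if not nd.child_nodes():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeValidationError("leaf without a name")
            taxa.append(nd.taxon.label)
            leaf_nodes.append(i)

    height = float(depth[leaf_nodes].max()) if leaf_nodes else 0.0
    age = height - depth
    # leaves must sit at (approximately) age 0
    if height > 0:
        leaf_ages = age[leaf_nodes]
        worst = int(np.argmax(np.abs(leaf_ages)))
        if abs(leaf_ages[worst]) > ultrametric_rtol * height:
            raise TreeValidationError(
                f"tree is not ultrametric: leaf {taxa[worst]!r} has age "
                f"{leaf_ages[worst]:.6g} MY (root age {height:.6g} MY)"
            )
        age[leaf_nodes] = 0.0
    age = np.maximum(age, 0.0)

    for i in range(n):
        for c in children[i]:
            if age[i] < age[c]:
                raise TreeValidationError("internal node younger than its child")

    return Phylogeny(
        taxa=taxa,
        children=children,
        parent=parent,
        edge_length=edge_length,
        age=age,
        leaf_nodes=np.asarray(leaf_nodes, dtype=np.int64),
        _newick=newick_text,
    )


# -- clade maps ------------------------------------------------------------

CladeMap = dict  # group name -> set of leaf names


def read_clades(source, tree: Phylogeny | None = None) -> CladeMap:
    """Read a two-column (group, species) TSV into a clade map.

    If ``tree`` is given, every member must be one of its leaves.
    """
    handle = source if hasattr(source, "read") else open(source)
    clades: CladeMap = {}
    with handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            group, species = line.split("\t")
            clades.setdefault(group, set()).add(species)
    if tree is not None:
        known = set(tree.taxa)
        for group, members in clades.items():
            missing = members - known
            if missing:
                raise KeyError(f"clade {group!r} members not in tree: {sorted(missing)}")
    return clades


def write_clades(clades: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for group in sorted(clades):
            for species in sorted(clades[group]):
                fh.write(f"{group}\t{species}\n")


def _data_text(name: str) -> str:
    return resources.files("intronfun.data").joinpath(name).read_text()


def default_tree() -> Phylogeny:
    """The packaged 28-species fixture tree (approximate ages, not ground truth)."""
    return parse_tree(_data_text("tree28.nwk"))


def default_clades(tree: Phylogeny | None = None) -> CladeMap:
    """Default taxonomic groupings matching the fixture tree.

    The 'amphibian' group contains both *Xenopus tropicalis* and *Anolis
    carolinensis*, matching the grouping the clade features were defined
    over; override with your own TSV if you prefer a strict taxonomy.
    """
    return read_clades(io.StringIO(_data_text("clades28.tsv")), tree=tree)
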