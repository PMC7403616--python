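"""Species-tree handling shared by the simulator and the estimator.

Trees are read and written as Newick via dendropy; for numerical work
they are flattened into an index structure of parent pointers and
traversal orders.  The fixed study topology places a human outgroup
against the rodents, with the murid clade splitting into Murinae (mice
and rat) and Gerbillinae (the gerbils); the most recent common ancestor
of those two subfamilies is labelled ``Muridae`` and is the node from
which per-species substitution rates are summed to the tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

#: Focal species of the analysis (two gerbils, two murines).
GERBIL_SPECIES = ("Psammomys_obesus", "Meriones_unguiculatus")
MURINE_SPECIES = ("Mus_musculus", "Rattus_norvegicus")
FOCAL_SPECIES = GERBIL_SPECIES + MURINE_SPECIES

#: Branches carrying the gerbil-lineage gBGC signal in simulations: the
#: Gerbillinae stem plus both gerbil terminal branches (the skewed
#: regions predate the within-gerbil divergence).
GERBIL_BRANCH_SET = ("Gerbillinae",) + GERBIL_SPECIES

#: Default study tree: human outgroup and ten rodent species, branch
#: lengths in expected substitutions per codon site.  The path from the
#: Muridae node to each gerbil tip is 0.30; to each murine tip 0.20.
DEFAULT_TREE_NEWICK = (
    "(Homo_sapiens:0.45,(Jaculus_jaculus:0.32,((Microtus_ochrogaster:0.14,"
    "Peromyscus_maniculatus:0.14)Cricetidae:0.10,((((Mus_musculus:0.04,"
    "Mus_spretus:0.04):0.02,(Mus_caroli:0.05,Mus_pahari:0.05):0.01):0.04,"
    "Rattus_norvegicus:0.10)Murinae:0.10,(Psammomys_obesus:0.14,"
    "Meriones_unguiculatus:0.14)Gerbillinae:0.16)Muridae:0.10)"
    "Eumuroida:0.08)Rodentia:0.10)Root;"
)

#: Reduced five-taxon tree (outgroup + the four focal species) used for
#: small validation runs; total tree length 1.0.
CORE_TREE_NEWICK = (
    "(Homo_sapiens:0.35,((Mus_musculus:0.10,Rattus_norvegicus:0.10)"
    "Murinae:0.08,(Psammomys_obesus:0.12,Meriones_unguiculatus:0.12)"
    "Gerbillinae:0.08)Muridae:0.05)Root;"
)


def read_tree(source: str, *, from_path: bool = False) -> dendropy.Tree:
    """Read a Newick tree, preserving internal node labels."""
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if from_path:
        return dendropy.Tree.get(path=source, **kwargs)
    return dendropy.Tree.get(data=source, **kwargs)


@dataclass
class TreeIndex:
    """Array-based view of a rooted tree for likelihood computations.

    Nodes are indexed 0..n-1 in postorder (root last).  ``edge_length[v]``
    is the length of the branch above node v (0 for the root).
    """

    names: list[str]
    parent: list[int]
    children: list[list[int]]
    postorder: list[int]
    edge_length: list[float] = field(repr=False)
    tip_index: dict[str, int] = field(repr=False)
    root: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)

    @property
    def branch_nodes(self) -> list[int]:
        """Nodes that own a branch (everything except the root)."""
        return [v for v in self.postorder if v != self.root]

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder))

    def path_to_ancestor(self, tip_name: str, ancestor: int) -> list[int]:
        """Nodes whose branches form the path tip -> ancestor (exclusive of
        the ancestor's own branch).  Raises KeyError / ValueError if the
        tip is absent or the node is not an ancestor of the tip."""
        v = self.tip_index[tip_name]
        path = []
        while v != ancestor:
            path.append(v)
            v = self.parent[v]
            if v == -1:
                raise ValueError(
                    f"node {self.names[ancestor]!r} is not an ancestor of "
                    f"{tip_name!r}"
                )
        return path

    def find_node(self, name: str) -> int:
        for i, n in enumerate(self.names):
            if n == name:
                return i
        raise KeyError(name)

    def mrca(self, tip_names: list[str]) -> int:
        """Most recent common ancestor of the named tips."""
        paths = []
        for t in tip_names:
            v = self.tip_index[t]
            anc = []
            while v != -1:
                anc.append(v)
                v = self.parent[v]
            paths.append(anc)
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common ancestor = first along any tip's root-ward path
        for v in paths[0]:
            if v in common:
                return v
        raise ValueError("tips share no ancestor (malformed tree)")


def index_tree(tree: dendropy.Tree) -> TreeIndex:
    """Flatten a dendropy tree into a :class:`TreeIndex`."""
    nodes = list(tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    names: list[str] = []
    parent: list[int] = []
    children: list[list[int]] = []
    edge_length: list[float] = []
    tip_index: dict[str, int] = {}
    for i, n in enumerate(nodes):
        if n.taxon is not None:
            name = n.taxon.label
        else:
            name = n.label or f"node{i}"
        names.append(name)
        parent.append(idx[id(n.parent_node)] if n.parent_node else -1)
        children.append([idx[id(c)] for c in n.child_nodes()])
        length = n.edge.length if n.parent_node and n.edge.length else 0.0
        if length < 0:
            raise ValueError(f"negative branch length above {name!r}")
        edge_length.append(float(length))
        if n.is_leaf():
            tip_index[name] = i
    root = idx[id(tree.seed_node)]
    return TreeIndex(
        names=names,
        parent=parent,
        children=children,
        postorder=list(range(len(nodes))),
        edge_length=edge_length,
        tip_index=tip_index,
        root=root,
    )


def prune_to_species(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Return a copy of the tree restricted to the given tip set.

    Unifurcations created by pruning are suppressed (their branch lengths
    are summed), matching the trimming of the fixed tree to the species
    present in each alignment.
    """
    keep = set(species)
    present = {t.label for t in tree.taxon_namespace}
    missing = keep - present
    if missing:
        raise KeyError(f"species not in tree: {sorted(missing)}")
    sub = tree.extract_tree_with_taxa_labels(keep)
    # extract_tree preserves internal labels; suppress_unifurcations is
    # applied by dendropy during extraction.
    return sub


def muridae_node(index: TreeIndex, focal_species=FOCAL_SPECIES) -> int:
    """Locate the murine-gerbil divergence node.

    Prefers an internal node labelled ``Muridae``; falls back to the MRCA
    of the focal species present in the tree.
    """
    try:
        return index.find_node("Muridae")
    except KeyError:
        present = [s for s in focal_species if s in index.tip_index]
        if len(present) < 2:
            raise ValueError(
                "cannot locate murine-gerbil divergence: no Muridae label "
                f"and fewer than two focal species present ({present})"
            )
        return index.mrca(present)
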