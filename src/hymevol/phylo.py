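"""Species phylogeny and per-ortholog gene-tree containers.

The analyses in :mod:`hymevol.tree_rates` assume a single rooted species
topology shared by every per-ortholog gene tree; only branch lengths vary
between orthologs.  Two anchor points on that topology matter:

* the *clade root* — the most recent common ancestor (MRCA) of the focal
  clade (here, the four chalcidoid wasps), and
* the *order root* — the MRCA of the wider comparison set (here, the seven
  hymenopterans remaining after the sister-to-all sawfly outgroup is
  dropped).

Anchors are always resolved per gene tree as the MRCA of a leaf-name set,
never by internal node labels, so trees produced by any phylogenetics
program can be consumed as-is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

#: Leaf names of the default eight-taxon comparison phylogeny.
DEFAULT_TAXA = (
    "Athalia",
    "Orussus",
    "Apis",
    "Microplitis",
    "Trichogramma",
    "Ceratosolen",
    "Copidosoma",
    "Nasonia",
)

#: The four chalcidoid wasps (the focal clade of the place-ranking analyses).
CHALCIDS = ("Trichogramma", "Copidosoma", "Ceratosolen", "Nasonia")

# Rooted on the sawfly; branch lengths are plausible amino-acid distances
# (substitutions per site) chosen once for the synthetic study conditions.
_DEFAULT_NEWICK = (
    "(Athalia:0.35,(Orussus:0.30,(Apis:0.25,(Microplitis:0.22,"
    "(Trichogramma:0.18,(Ceratosolen:0.12,(Copidosoma:0.11,Nasonia:0.13)"
    ":0.03):0.04):0.10):0.04):0.05):0.05);"
)


def _parse_newick(newick: str, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=taxon_namespace,
        rooting="default-rooted",
        preserve_underscores=True,
    )


def leaf_names(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def mrca(tree: dendropy.Tree, names) -> dendropy.Node:
    """MRCA node of the given leaf names (resolved by leaf set, D-style)."""
    node = tree.mrca(taxon_labels=list(names))
    if node is None:
        raise ValueError(f"no MRCA for taxa {sorted(names)}")
    return node


def path_length(node: dendropy.Node, ancestor: dendropy.Node) -> float:
    """Sum of branch lengths on the path from ``node`` up to ``ancestor``."""
    total = 0.0
    cur = node
    while cur is not ancestor:
        if cur.parent_node is None:
            raise ValueError("ancestor is not on the root path of node")
        total += cur.edge.length or 0.0
        cur = cur.parent_node
    return total


@dataclass(frozen=True)
class SpeciesPhylogeny:
    """Rooted species topology with the two named anchor points.

    Parameters
    ----------
    tree:
        Rooted dendropy tree with branch lengths.
    clade_members:
        Leaf names of the focal clade; the clade root is their MRCA.
    order_members:
        Leaf names spanning the wider comparison set; the order root is
        their MRCA.  Taxa outside this set (e.g. a sister-to-all outgroup)
        still appear in the tree but take no part in anchored distances.
    """

    tree: dendropy.Tree
    clade_members: frozenset = field(default=frozenset(CHALCIDS))
    order_members: frozenset = field(
        default=frozenset(t for t in DEFAULT_TAXA if t != "Athalia")
    )

    def __post_init__(self):
        leaves = leaf_names(self.tree)
        for name, members in (
            ("clade_members", self.clade_members),
            ("order_members", self.order_members),
        ):
            missing = set(members) - leaves
            if missing:
                raise ValueError(f"{name} not in tree: {sorted(missing)}")
        if not set(self.clade_members) <= set(self.order_members):
            raise ValueError("clade_members must be a subset of order_members")
        # the clade must be monophyletic: its MRCA subtends exactly its members
        node = mrca(self.tree, self.clade_members)
        under = {lf.taxon.label for lf in node.leaf_iter()}
        if under != set(self.clade_members):
            raise ValueError(
                f"clade_members are not monophyletic; MRCA subtends {sorted(under)}"
            )
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in species phylogeny")

    @property
    def taxa(self) -> tuple:
        return tuple(sorted(leaf_names(self.tree)))

    def clade_root(self, tree: dendropy.Tree | None = None) -> dendropy.Node:
        return mrca(tree if tree is not None else self.tree, self.clade_members)

    def order_root(self, tree: dendropy.Tree | None = None) -> dendropy.Node:
        return mrca(tree if tree is not None else self.tree, self.order_members)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# Same topology with zero-length branches inside the chalcid clade and equal
# chalcid terminal branches: under iid per-branch rate noise every clade
# member's root-to-clade distance is identically distributed, so place ranks
# are exchangeable — the exact null of the place-count calibration tests.
_NULL_NEWICK = (
    "(Athalia:0.35,(Orussus:0.30,(Apis:0.25,(Microplitis:0.22,"
    "(Trichogramma:0.18,(Ceratosolen:0.18,(Copidosoma:0.18,Nasonia:0.18)"
    ":0.0):0.0):0.10):0.04):0.05):0.05);"
)


def default_phylogeny() -> SpeciesPhylogeny:
    """The eight-taxon hymenopteran comparison phylogeny.

    Four chalcids (*Trichogramma*, *Copidosoma*, *Ceratosolen*, *Nasonia*),
    a braconid (*Microplitis*), the honey bee (*Apis*), a parasitic wood
    wasp (*Orussus*) and, as sister to everything else, the sawfly
    (*Athalia*), which is excluded from order-anchored comparisons.
    """
    return SpeciesPhylogeny(tree=_parse_newick(_DEFAULT_NEWICK))


def null_phylogeny() -> SpeciesPhylogeny:
    """Exchangeable-clade variant of the default phylogeny.

    All four chalcids sit at the same distance from the chalcid root and
    the clade-internal branches have zero length, so with iid per-branch
    rate noise and equal lineage multipliers each chalcid is equally
    likely to carry the longest branch of an orthologous group.
    """
    return SpeciesPhylogeny(tree=_parse_newick(_NULL_NEWICK))


@dataclass
class OrthologTreeSet:
    """Per-ortholog gene trees sharing one topology, own branch lengths."""

    trees: dict  # ortholog_id -> dendropy.Tree

    def __post_init__(self):
        if len(self.trees) != len(set(self.trees)):
            raise ValueError("duplicate ortholog ids")

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees.items())

    def __getitem__(self, ortholog_id: str) -> dendropy.Tree:
        return self.trees[ortholog_id]

    def write(self, path) -> None:
        """Write one ``ortholog_id<TAB>newick`` line per tree."""
        with open(path, "w") as fh:
            for oid, tree in self.trees.items():
                nwk = tree.as_string(
                    schema="newick", suppress_rooting=True
                ).strip()
                fh.write(f"{oid}\t{nwk}\n")


def read_tree_lines(path) -> dict:
    """Parse a ``ortholog_id<TAB>newick`` file into raw (id, newick) pairs."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                oid, nwk = line.split("\t", 1)
            except ValueError:
                raise ValueError(f"line {lineno}: expected 'id<TAB>newick'")
            if oid in out:
                raise ValueError(f"line {lineno}: duplicate ortholog id {oid!r}")
            out[oid] = nwk
    return out


def parse_gene_tree(newick: str) -> dendropy.Tree:
    return _parse_newick(io.StringIO(newick).read())
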