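"""Phylogeny I/O and the phylogenetic variance-covariance matrix.

Trees are held as :class:`dendropy.Tree` objects (rooted, branch lengths
mandatory).  The covariance construction is the standard Brownian-motion
one: the (i, j) entry of the species covariance matrix is the summed
branch length shared by tips i and j on their paths from the root, i.e.
the depth of their most recent common ancestor.  Pagel's lambda rescales
the off-diagonal entries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "validate_tree",
    "vcv_matrix",
    "lambda_transform",
    "prune",
]


@dataclass
class PhyloCovariance:
    """Species-by-species phylogenetic covariance matrix.

    Attributes
    ----------
    species : list of str
        Tip labels fixing the row/column order.
    matrix : ndarray of shape (n, n)
        Shared root-to-MRCA path lengths, in the units of the tree's
        branch lengths.  Symmetric, positive semi-definite.
    lam : float
        Pagel's lambda applied to the off-diagonal (1.0 = untransformed
        Brownian motion, 0.0 = star phylogeny).
    """

    species: list[str]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"covariance matrix shape {self.matrix.shape} does not match "
                f"{n} species"
            )

    @property
    def n_species(self) -> int:
        return len(self.species)


def validate_tree(tree: dendropy.Tree) -> None:
    """Check the invariants required of an input phylogeny.

    Raises ``ValueError`` on duplicate/empty tip labels, missing branch
    lengths (anywhere except the root edge), or negative/non-finite
    branch lengths.  A missing or zero root edge is permitted and
    ignored throughout.
    """
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None or lab == "" for lab in labels):
        raise ValueError("tree contains unlabeled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue  # root edge may be absent
        bl = node.edge.length
        if bl is None:
            raise ValueError(
                "tree has a branch without a length; branch lengths are "
                "required for the phylogenetic covariance"
            )
        if not np.isfinite(bl) or bl < 0:
            raise ValueError(f"invalid branch length {bl!r}")


def read_newick(path: str) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Underscores in labels are preserved literally (no space conversion).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as err:
        raise ValueError(f"failed to parse Newick file {path}: {err}") from err
    validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    """Write ``tree`` to ``path`` as a single Newick string."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    """Newick serialization with full float precision, trailing newline."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    return s.strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def vcv_matrix(
    tree: dendropy.Tree, species_order: Sequence[str] | None = None
) -> PhyloCovariance:
    """Brownian-motion phylogenetic covariance of the tree's tips.

    ``V[i, j]`` is the total branch length on the shared root-to-MRCA
    path of tips i and j — equivalently, the sum of lengths of edges
    ancestral to both.  The diagonal holds root-to-tip distances; the
    tree need not be ultrametric.

    Parameters
    ----------
    species_order : sequence of tip labels, optional
        Row/column order of the result; defaults to the tree's leaf
        iteration order.  Must be a subset of the tip labels.
    """
    validate_tree(tree)
    labels = tip_labels(tree)
    if species_order is None:
        species_order = labels
    else:
        unknown = [s for s in species_order if s not in set(labels)]
        if unknown:
            raise KeyError(f"species not in tree: {unknown}")
        if len(set(species_order)) != len(species_order):
            raise ValueError("species_order contains duplicates")
    index = {lab: i for i, lab in enumerate(species_order)}
    n = len(species_order)
    V = np.zeros((n, n))
    # Each edge of length b contributes b to V[i, j] for every pair of
    # retained tips below it (including i == j).
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length
        below = [
            index[leaf.taxon.label]
            for leaf in node.leaf_iter()
            if leaf.taxon.label in index
        ]
        if below:
            idx = np.array(below)
            V[np.ix_(idx, idx)] += bl
    return PhyloCovariance(species=list(species_order), matrix=V, lam=1.0)


def lambda_transform(V: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Apply Pagel's lambda: multiply off-diagonal entries by ``lam``.

    The diagonal (tip variances) is unchanged.  ``lam`` must lie in
    [0, 1]; 1 returns an identical matrix, 0 the star-phylogeny
    diagonal.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = V.matrix * lam
    np.fill_diagonal(M, np.diag(V.matrix))
    return PhyloCovariance(species=list(V.species), matrix=M, lam=lam)


def prune(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` restricted to the tips in ``keep``.

    Root-to-tip distances of retained tips are preserved: collapsed
    unary nodes have their branch lengths summed.
    """
    keep = list(dict.fromkeys(keep))
    if len(keep) < 2:
        raise ValueError("need at least two tips to keep")
    have = set(tip_labels(tree))
    missing = [s for s in keep if s not in have]
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    pruned = tree.clone(depth=1)
    drop = [tx for tx in pruned.taxon_namespace if tx.label not in set(keep)]
    # Keep a unary root as-is so the basal shared path survives in the
    # covariance; only interior unary nodes are collapsed (lengths summed).
    pruned.prune_taxa(drop, suppress_unifurcations=False)
    for node in list(pruned.postorder_node_iter()):
        children = node.child_nodes()
        if node is pruned.seed_node or len(children) != 1:
            continue
        child = children[0]
        child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
        parent = node.parent_node
        parent.remove_child(node)
        parent.add_child(child)
    pruned.purge_taxon_namespace()
    validate_tree(pruned)
    return pruned
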