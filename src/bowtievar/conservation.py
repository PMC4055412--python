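"""Phylogenetic tree-based conservation scoring.

A protein's conservation score is the fraction of a weighted species
tree's total branch length covered by the minimal (Steiner) subtree
connecting the species in which the protein has a homolog:

    c_i = sum_{e in E_i} w(e) / sum_{e in E} w(e)

where E is the edge set of the full tree T, w(e) the branch length of
edge e, and E_i the edge set of the pruned subtree T_i spanning the
retained species.  The pruned subtree is defined unrooted: an edge
belongs to E_i exactly when both components obtained by deleting it
contain at least one retained tip, so the score does not depend on root
placement and the path from the subtree up to an arbitrary root is never
counted.  A protein found only in the reference species has an empty
subtree and score 0; one found in every species scores 1.

The reference species (human) is always treated as retained: a human
protein trivially exists in human.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTree",
    "read_newick",
    "pruned_subtree_edges",
    "subtree_length",
    "conservation_scores",
    "read_homology_tsv",
    "write_scores_tsv",
]

REFERENCE_SPECIES = "Homo_sapiens"


class SpeciesTree:
    """A rooted binary tree with branch lengths, indexed for fast
    bipartition queries.

    Each edge (every node-to-parent edge except the root's phantom edge)
    is stored with its length and the set of tips on its child side as a
    boolean mask.  ``tip_labels`` fixes the tip order used by all masks.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(lb is None for lb in labels):
            raise ValueError("tree contains an unlabeled tip")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise ValueError(f"duplicate tip label(s): {dupes}")
        self.tip_labels: list[str] = sorted(labels)
        self._tip_index = {lb: i for i, lb in enumerate(self.tip_labels)}

        n_tips = len(self.tip_labels)
        lengths: list[float] = []
        masks: list[np.ndarray] = []
        # postorder: accumulate the tip mask below every node
        node_mask: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                m = np.zeros(n_tips, dtype=bool)
                m[self._tip_index[node.taxon.label]] = True
            else:
                m = np.zeros(n_tips, dtype=bool)
                for child in node.child_nodes():
                    m |= node_mask[id(child)]
            node_mask[id(node)] = m
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                label = node.taxon.label if node.is_leaf() else "internal node"
                raise ValueError(
                    f"edge above {label} (tips: "
                    f"{sorted(np.array(self.tip_labels)[m])[:3]}...) "
                    "has no branch length"
                )
            if node.edge.length < 0:
                raise ValueError("negative branch length")
            lengths.append(float(node.edge.length))
            masks.append(m)

        self.edge_lengths = np.array(lengths, dtype=float)
        self.edge_masks = np.array(masks, dtype=bool)  # (n_edges, n_tips)
        self.total_length = float(self.edge_lengths.sum())
        if self.total_length <= 0:
            raise ValueError("tree has zero total branch length")

    # -- basic accessors -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_edges(self) -> int:
        return self.edge_lengths.size

    def edge_bipartitions(self) -> list[frozenset]:
        """Canonical bipartition of each edge as the smaller tip side
        (ties broken lexicographically) — useful for root-invariant
        edge-set comparisons."""
        tips = np.array(self.tip_labels)
        out = []
        for m in self.edge_masks:
            side_a = frozenset(tips[m])
            side_b = frozenset(tips[~m])
            if len(side_a) != len(side_b):
                out.append(side_a if len(side_a) < len(side_b) else side_b)
            else:
                out.append(min(side_a, side_b, key=lambda s: sorted(s)))
        return out

    def _retained_mask(self, retained_tips: Iterable[str]) -> np.ndarray:
        mask = np.zeros(self.n_tips, dtype=bool)
        for sp in retained_tips:
            idx = self._tip_index.get(sp)
            if idx is None:
                raise KeyError(f"species {sp!r} is not a tip of the tree")
            mask[idx] = True
        return mask

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def clone(self) -> "SpeciesTree":
        return SpeciesTree(self._tree.clone(depth=1))

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def read_newick(source: str) -> SpeciesTree:
    """Parse a Newick tree from a path or a literal Newick string.

    Branch lengths are required on every non-root edge; duplicate tip
    labels are rejected.  Round-tripping through :meth:`SpeciesTree.as_newick`
    preserves topology and branch lengths to 1e-9.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        data = source
    else:
        with open(source) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick input: {exc}") from exc
    return SpeciesTree(tree)


def pruned_subtree_edges(tree: SpeciesTree, retained_tips: Iterable[str],
                         reference: str | None = REFERENCE_SPECIES) -> np.ndarray:
    """Boolean edge mask of the minimal unrooted subtree spanning
    ``retained_tips`` (plus the reference species when given and present
    in the tree).

    An edge is in the subtree iff its bipartition separates retained
    tips on both sides.  A single retained tip yields no edges.
    """
    retained = set(retained_tips)
    if reference is not None and reference in tree._tip_index:
        retained.add(reference)
    mask = tree._retained_mask(retained)
    k = int(mask.sum())
    if k <= 1:
        return np.zeros(tree.n_edges, dtype=bool)
    counts = tree.edge_masks.astype(np.int32) @ mask.astype(np.int32)
    return (counts > 0) & (counts < k)


def subtree_length(tree: SpeciesTree, retained_tips: Iterable[str],
                   reference: str | None = REFERENCE_SPECIES) -> float:
    """Total branch length of the pruned spanning subtree."""
    edges = pruned_subtree_edges(tree, retained_tips, reference=reference)
    return float(tree.edge_lengths[edges].sum())


def conservation_scores(
    tree: SpeciesTree,
    homology: Mapping[str, Iterable[str]],
    reference: str = REFERENCE_SPECIES,
) -> pd.DataFrame:
    """Conservation score for every protein in a homology table.

    ``homology`` maps protein id -> species labels with a homolog (the
    reference species need not be listed; it is always retained).  Every
    listed species must be a tip of the tree — an unknown label is an
    error, not a silent prune.

    Returns a DataFrame indexed by protein_id with columns ``score``,
    ``subtree_length``, ``tree_length``.
    """
    proteins = list(homology.keys())
    n_tips = tree.n_tips
    retained = np.zeros((n_tips, len(proteins)), dtype=bool)
    for j, pid in enumerate(proteins):
        for sp in homology[pid]:
            idx = tree._tip_index.get(sp)
            if idx is None:
                raise KeyError(
                    f"protein {pid!r} lists species {sp!r} absent from the tree"
                )
            retained[idx, j] = True
    if reference in tree._tip_index:
        retained[tree._tip_index[reference], :] = True
    k = retained.sum(axis=0)  # retained tips per protein
    counts = tree.edge_masks.astype(np.int32) @ retained.astype(np.int32)
    included = (counts > 0) & (counts < np.maximum(k, 1))
    sub_len = tree.edge_lengths @ included
    return pd.DataFrame(
        {
            "score": sub_len / tree.total_length,
            "subtree_length": sub_len,
            "tree_length": tree.total_length,
        },
        index=pd.Index(proteins, name="protein_id"),
    )


# -- TSV dialect -------------------------------------------------------

def read_homology_tsv(path) -> dict[str, set[str]]:
    """Read the two-column homology table (protein_id, comma-separated
    species; empty field = conserved in the reference species only)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, set[str]] = {}
    for pid, sp in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[pid] = set(s for s in sp.split(",") if s)
    return out


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", float_format="%.10g")
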