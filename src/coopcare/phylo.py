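"""Newick tree ensembles and the Brownian-motion covariance they induce.

The phylogenetic covariance matrix C has C[i, j] equal to the shared
root-to-MRCA path length of tips i and j (the time two lineages evolved
together under Brownian motion). Trees are normalized to unit height so
that C has a unit diagonal on ultrametric trees and the residual variance
parameter of the regression stays interpretable across tree ensembles.
Pagel's lambda scales the off-diagonal (shared-history) part of C.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["Phylogeny", "PhyloCov", "read_newick", "vcv", "lambda_transform"]


def _norm_label(label: str) -> str:
    """Exact tip matching up to the underscore/space Newick dialect."""
    return label.strip().replace(" ", "_")


class Phylogeny:
    """A rooted tree with branch lengths, thinly wrapping dendropy.

    Polytomies are accepted; tip names must be unique and there must be at
    least two tips. Missing branch lengths are treated as a parse error
    except on the root edge, which does not contribute to shared paths.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        tips = [_norm_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise ValueError("degenerate tree: fewer than 2 tips")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip names: {dupes}")
        root = tree.seed_node
        if len(root.child_nodes()) == 1:
            raise ValueError("degenerate tree: single-child root")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue
            if edge.length is None:
                raise ValueError(
                    f"missing branch length on edge above "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'}")
            if edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self._tips = tips

    @property
    def tips(self) -> list[str]:
        return list(self._tips)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depth = {self._tree.seed_node: 0.0}
        out: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depth[node] = depth[node.parent_node] + node.edge.length
            if node.is_leaf():
                out[_norm_label(node.taxon.label)] = depth[node]
        return out

    def height(self) -> float:
        return max(self.depths().values())

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({len(self._tips)} tips)"


@dataclass
class PhyloCov:
    """Species-by-species phylogenetic covariance (optionally unit-height)."""

    taxa: tuple[str, ...]
    C: np.ndarray
    height: float

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.taxa)
        if self.C.shape != (n, n):
            raise ValueError(f"C shape {self.C.shape} inconsistent with {n} taxa")


def read_newick(source) -> list[Phylogeny]:
    """Read one or more Newick trees (path, stream, or string).

    Multi-tree files (one tree per line, or concatenated) are supported;
    order is preserved. Parse failures raise with dendropy's position
    diagnostics.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        text = str(source)
        if ";" in text or "(" in text:
            data = text
        else:
            with open(source, "r", encoding="utf-8") as fh:
                data = fh.read()
    try:
        tl = dendropy.TreeList.get(data=data, schema="newick",
                                   suppress_internal_node_taxa=True)
    except Exception as exc:   # dendropy errors carry line/column diagnostics
        raise ValueError(f"Newick parse error: {exc}") from exc
    if len(tl) == 0:
        raise ValueError("no trees found in input")
    return [Phylogeny(t) for t in tl]


def vcv(tree: Phylogeny, taxa_order=None, normalize: bool = True) -> PhyloCov:
    """Brownian covariance matrix of a tree, ordered as ``taxa_order``.

    C[i, j] is the root-to-MRCA path length shared by tips i and j;
    C[i, i] is tip i's depth. With ``normalize``, C is divided by the tree
    height over the retained tips (ultrametric diagonal becomes 1); on a
    non-ultrametric tree the mean root-to-tip depth is used instead, with
    a warning. Tips not in ``taxa_order`` are pruned (rows/columns
    dropped; shared paths among retained tips are unchanged).
    """
    tips = tree.tips
    if taxa_order is None:
        taxa_order = tips
    taxa_order = [_norm_label(t) for t in taxa_order]
    missing = sorted(set(taxa_order) - set(tips))
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")

    index = {name: i for i, name in enumerate(tips)}
    n_all = len(tips)
    C = np.zeros((n_all, n_all))

    # node depths and, per node, the tip indices below it (postorder)
    depth: dict = {tree.tree.seed_node: 0.0}
    for node in tree.tree.preorder_node_iter():
        if node is not tree.tree.seed_node:
            depth[node] = depth[node.parent_node] + node.edge.length
    below: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[_norm_label(node.taxon.label)]
            below[node] = [i]
            C[i, i] = depth[node]
        else:
            kids = [below[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    C[np.ix_(kids[a], kids[b])] = d
                    C[np.ix_(kids[b], kids[a])] = d
            below[node] = [i for kid in kids for i in kid]

    sel = [index[t] for t in taxa_order]
    C = C[np.ix_(sel, sel)]
    diag = np.diag(C).copy()
    height = float(diag.max())
    if normalize:
        if np.allclose(diag, height, rtol=1e-8, atol=1e-10):
            scale = height
        else:
            scale = float(diag.mean())
            warnings.warn(
                "tree is not ultrametric over the selected taxa; normalizing "
                "the covariance by the mean root-to-tip depth", stacklevel=2)
        C = C / scale
    return PhyloCov(taxa=tuple(taxa_order), C=C, height=height)


def lambda_transform(cov: PhyloCov, lam: float) -> PhyloCov:
    """Pagel's lambda: scale the off-diagonal of C by ``lam`` in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCov(taxa=cov.taxa, C=C, height=cov.height)
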