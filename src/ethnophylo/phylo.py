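"""Rooted phylogeny model: Newick I/O, patristic distances, MRCA queries.

The tree itself is held as a :mod:`dendropy` tree; this module adds the
validation, label normalization and distance machinery the downstream
community-phylogenetic tests need, and a deterministic naming convention
for internal nodes (``MRCA(first_tip,last_tip)``) used in reports.

Distances are *patristic*: the sum of branch lengths along the unique path
between two tips. Units are whatever the input tree uses (typically
substitutions/site for ML trees); every downstream statistic is invariant
under rescaling all branch lengths by a positive constant.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhylogenyError",
    "parse_newick",
    "write_newick",
    "patristic_matrix",
    "normalize_label",
]


class PhylogenyError(ValueError):
    """Raised for malformed trees or invalid tree queries."""


def normalize_label(label: str) -> str:
    """Strip surrounding whitespace and convert internal spaces to underscores.

    ML pipelines routinely swap spaces and underscores in tip names (the
    accession-style names this package targets look like ``P.angolensis2``);
    normalizing both sides of every lookup makes matching robust.
    """
    return "_".join(str(label).strip().split())


class Phylogeny:
    """A rooted phylogeny with labeled tips and (optionally) branch lengths.

    Wraps a :class:`dendropy.Tree`. Tip labels are normalized and must be
    unique; polytomies are preserved; internal node labels (e.g. bootstrap
    values) are retained but never confused with tip labels. The tree is
    treated as rooted exactly as written — no rerooting is ever performed.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._refresh_index()

    # -- construction / indexing ------------------------------------------

    def _refresh_index(self) -> None:
        tips = list(self._tree.leaf_node_iter())
        if len(tips) < 2:
            raise PhylogenyError(
                f"tree must have at least 2 tips, found {len(tips)}"
            )
        labels = []
        for leaf in tips:
            if leaf.taxon is None or leaf.taxon.label is None:
                raise PhylogenyError("tree contains an unlabeled tip")
            norm = normalize_label(leaf.taxon.label)
            if not norm:
                raise PhylogenyError("tree contains a tip with an empty label")
            leaf.taxon.label = norm
            labels.append(norm)
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise PhylogenyError(
                "duplicate tip labels after normalization: " + ", ".join(dupes)
            )
        self._tips = tips
        self._tip_labels = labels
        self._tip_index = {l: i for i, l in enumerate(labels)}
        self._leaf_by_label = {l: t for l, t in zip(labels, tips)}

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in tree (leaf-iteration) order."""
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def has_tip(self, label: str) -> bool:
        return normalize_label(label) in self._tip_index

    def internal_nodes(self, exclude_root: bool = False) -> list[dendropy.Node]:
        nodes = [
            nd for nd in self._tree.preorder_node_iter() if not nd.is_leaf()
        ]
        if exclude_root:
            nodes = [nd for nd in nodes if nd is not self.root]
        return nodes

    def _resolve_tips(self, labels: Iterable[str]) -> list[str]:
        norm = [normalize_label(l) for l in labels]
        unknown = sorted(set(l for l in norm if l not in self._tip_index))
        if unknown:
            raise PhylogenyError(
                "tip labels not found in tree: " + ", ".join(unknown)
            )
        return norm

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of a nonempty set of tip labels."""
        norm = self._resolve_tips(tips)
        if not norm:
            raise PhylogenyError("mrca requires at least one tip label")
        target = set(norm)
        # walk up from one member until the descendant set covers all targets
        node = self._leaf_by_label[norm[0]]
        while node is not None:
            if target <= self.descendant_tips(node):
                return node
            node = node.parent_node
        raise PhylogenyError("mrca walk escaped the root")  # pragma: no cover

    def descendant_tips(self, node: dendropy.Node) -> frozenset[str]:
        """Labels of tips in the subtree rooted at *node* (singleton for a tip)."""
        if node.is_leaf():
            return frozenset([normalize_label(node.taxon.label)])
        return frozenset(
            normalize_label(l.taxon.label) for l in node.leaf_iter()
        )

    def node_report_label(self, node: dendropy.Node) -> str:
        """Deterministic report name ``MRCA(x,y)``.

        ``x`` and ``y`` are the first and last descendant tips in the tree's
        child order, so for any internal node with >= 2 children the MRCA of
        the named pair is the node itself.
        """
        if node.is_leaf():
            raise PhylogenyError("node_report_label is defined for internal nodes only")
        leaves = list(node.leaf_iter())
        return f"MRCA({normalize_label(leaves[0].taxon.label)},{normalize_label(leaves[-1].taxon.label)})"

    def node_by_report_label(self) -> dict[str, dendropy.Node]:
        """Map report labels to internal nodes (deterministic for a fixed tree)."""
        return {self.node_report_label(nd): nd for nd in self.internal_nodes()}

    # -- distances ---------------------------------------------------------

    def patristic_matrix(self, unit_branch_lengths: bool = False) -> pd.DataFrame:
        """Symmetric tip-by-tip patristic distance matrix.

        Single post-order pass: each node carries the distances from its
        subtree's tips to itself; cross-child blocks fill the matrix, so no
        per-pair path traversal occurs. With ``unit_branch_lengths`` every
        branch counts 1 (this changes *all* distances; use only for trees
        lacking lengths).

        Raises :class:`PhylogenyError` on unresolved branch lengths unless
        the unit-length fallback is enabled.
        """
        n = self.n_tips
        D = np.zeros((n, n))
        idx_of = {id(t): i for i, t in enumerate(self._tips)}
        carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                carry[id(nd)] = (
                    np.array([idx_of[id(nd)]], dtype=np.intp),
                    np.zeros(1),
                )
                continue
            parts = []
            for ch in nd.child_nodes():
                length = ch.edge.length
                if unit_branch_lengths:
                    length = 1.0
                elif length is None:
                    raise PhylogenyError(
                        "unresolved branch length on an edge; pass "
                        "unit_branch_lengths=True to substitute unit lengths"
                    )
                elif length < 0:
                    raise PhylogenyError("negative branch length in tree")
                ids, dist = carry.pop(id(ch))
                parts.append((ids, dist + length))
            for a in range(len(parts)):
                ia, da = parts[a]
                for b in range(a + 1, len(parts)):
                    ib, db = parts[b]
                    block = da[:, None] + db[None, :]
                    D[np.ix_(ia, ib)] = block
                    D[np.ix_(ib, ia)] = block.T
            carry[id(nd)] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
        off = D[~np.eye(n, dtype=bool)]
        if off.size and np.any(off == 0):
            warnings.warn(
                "zero patristic distance between distinct tips "
                "(zero-length branches); nearest-taxon distances may tie",
                stacklevel=2,
            )
        return pd.DataFrame(D, index=self._tip_labels, columns=self._tip_labels)

    # -- depths / shape ----------------------------------------------------

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path lengths (requires resolved branch lengths)."""
        depths = {}
        for nd in self._tree.preorder_node_iter():
            if nd is self.root:
                nd._depth = 0.0
            else:
                if nd.edge.length is None:
                    raise PhylogenyError("unresolved branch length on an edge")
                nd._depth = nd.parent_node._depth + nd.edge.length
            if nd.is_leaf():
                depths[normalize_label(nd.taxon.label)] = nd._depth
        return pd.Series(depths)

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        d = self.tip_depths().to_numpy()
        scale = max(abs(d).max(), 1e-300)
        return bool((d.max() - d.min()) / scale <= rel_tol)

    # -- manipulation ------------------------------------------------------

    def prune(self, labels: Iterable[str]) -> "Phylogeny":
        """Return a new tree with the given tips removed (e.g. outgroups)."""
        norm = self._resolve_tips(labels)
        keep = [l for l in self._tip_labels if l not in set(norm)]
        if len(keep) < 2:
            raise PhylogenyError("pruning would leave fewer than 2 tips")
        clone = self._tree.extract_tree()
        clone.retain_taxa_with_labels(keep)
        clone.purge_taxon_namespace()
        return Phylogeny(clone)

    # -- output ------------------------------------------------------------

    def to_newick(
        self,
        node_labels: Optional[Mapping[dendropy.Node, str]] = None,
        precision: int = 10,
    ) -> str:
        return write_newick(self, node_labels=node_labels, precision=precision)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Standard dialect: quoted labels, ``[...]`` comments ignored, internal
    node labels retained as annotations, underscores preserved verbatim.
    Malformed input (unbalanced parentheses, missing semicolon, duplicate
    tip labels, <2 tips) raises :class:`PhylogenyError`.
    """
    if not text or not text.strip():
        raise PhylogenyError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise PhylogenyError(f"Newick parse error: {exc}") from exc
    return Phylogeny(tree)


def write_newick(
    tree: Phylogeny,
    node_labels: Optional[Mapping[dendropy.Node, str]] = None,
    precision: int = 10,
) -> str:
    """Serialize to Newick, optionally labeling internal nodes.

    ``node_labels`` maps nodes of *tree* to strings emitted after the node's
    closing parenthesis; labels containing Newick metacharacters are quoted.
    ``precision`` is the number of significant digits for branch lengths.
    """
    dtree = tree._tree
    saved = {}
    try:
        if node_labels:
            for nd, lab in node_labels.items():
                saved[id(nd)] = (nd, nd.label)
                nd.label = str(lab)
        out = dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}g",
        )
    finally:
        for nd, lab in saved.values():
            nd.label = lab
    return out.strip() + "\n"


def patristic_matrix(
    tree: Phylogeny, unit_branch_lengths: bool = False
) -> pd.DataFrame:
    """Functional alias for :meth:`Phylogeny.patristic_matrix`."""
    return tree.patristic_matrix(unit_branch_lengths=unit_branch_lengths)
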