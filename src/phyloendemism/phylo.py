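"""Rooted phylogenies: parsing, megatree binding, pruning, branch ranges.

Trees are handled through :mod:`dendropy`; this module wraps a
:class:`dendropy.Tree` in :class:`PhyloTree`, which adds the conventions the
metrics rely on:

* the tree is rooted; polytomies are preserved, never arbitrarily resolved;
* branch lengths are finite and >= 0 (zero-length branches, a common
  artifact of megatree pruning, are legal and contribute nothing);
* after binding to a species list, any residual edge above the MRCA of the
  retained tips is dropped, so all metrics are functions of the induced
  subtree spanning the retained tips.

Binding a large published megatree to a dataset species list follows the
usual practice of substituting unplaced taxa by sister or near-synonym tips
and renaming them back afterwards (one tip per species; many-to-one reuse is
rejected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core_data import DataError, IncidenceMatrix


@dataclass(frozen=True)
class TreeArrays:
    """Flat postorder view of a tree used by all metric computations.

    ``edge_tip[e, t]`` is True when tip ``t`` descends through edge ``e``
    (the edge above postorder node ``e``); the root's own edge is excluded.
    """

    edge_lengths: np.ndarray  # (E,) float
    edge_tip: np.ndarray  # (E, T) bool
    tip_labels: list[str]
    terminal: np.ndarray  # (E,) bool: edge subtends a single tip

    @property
    def n_edges(self) -> int:
        return len(self.edge_lengths)

    @property
    def n_tips_per_edge(self) -> np.ndarray:
        return self.edge_tip.sum(axis=1)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())


class PhyloTree:
    """A rooted tree with branch lengths and unique tip labels."""

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = True
        self._tree = dtree
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataError(f"duplicate tip labels: {dupes}")
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is dtree.seed_node:
                continue
            if edge.length is not None and (
                not np.isfinite(edge.length) or edge.length < 0
            ):
                raise DataError(f"invalid branch length {edge.length!r}")

    # -- structure -------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_internal_nodes(self) -> int:
        return sum(1 for n in self._tree.preorder_node_iter() if not n.is_leaf())

    @property
    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def as_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
            + "\n"
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick())

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- flattened arrays ------------------------------------------------

    @cached_property
    def arrays(self) -> TreeArrays:
        """Postorder edge arrays (cached; the tree must not be mutated after)."""
        tips = self.tip_labels
        tip_index = {t: i for i, t in enumerate(tips)}
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        terminal: list[bool] = []
        node_mask: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(len(tips), dtype=bool)
                mask[tip_index[node.taxon.label]] = True
            else:
                mask = np.zeros(len(tips), dtype=bool)
                for child in node.child_nodes():
                    mask |= node_mask[id(child)]
            node_mask[id(node)] = mask
            if node is self._tree.seed_node:
                continue
            lengths.append(node.edge.length or 0.0)
            rows.append(mask)
            terminal.append(node.is_leaf())
        return TreeArrays(
            edge_lengths=np.asarray(lengths, dtype=float),
            edge_tip=np.vstack(rows) if rows else np.zeros((0, len(tips)), bool),
            tip_labels=tips,
            terminal=np.asarray(terminal, dtype=bool),
        )


# ---------------------------------------------------------------------------
# parsing


def parse_newick(text: str, missing_lengths: str = "error") -> PhyloTree:
    """Parse a Newick string into a rooted :class:`PhyloTree`.

    ``missing_lengths`` is ``"error"`` (default) or ``"zero"``, which assigns
    0 to absent branch lengths with a warning.
    """
    if missing_lengths not in ("error", "zero"):
        raise ValueError("missing_lengths must be 'error' or 'zero'")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise DataError(f"invalid Newick: {exc}") from exc
    n_missing = 0
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            continue
        if edge.length is None:
            n_missing += 1
            edge.length = 0.0
    if n_missing:
        if missing_lengths == "error":
            raise DataError(f"{n_missing} branches lack lengths")
        warnings.warn(f"assigned length 0 to {n_missing} branches", stacklevel=2)
    return PhyloTree(dtree)


def read_newick(path: str | Path, missing_lengths: str = "error") -> PhyloTree:
    return parse_newick(Path(path).read_text(), missing_lengths=missing_lengths)


# ---------------------------------------------------------------------------
# megatree binding


def bind_taxa(
    tree: PhyloTree,
    species: list[str],
    substitutions: dict[str, str] | None = None,
) -> PhyloTree:
    """Prune *tree* to *species*, applying name substitutions first.

    Each dataset species must either match a tip label or map, via
    ``substitutions`` (dataset name -> tree tip name), to a tip that is then
    renamed to the dataset name.  Substitutions are one-to-one: two species
    may not claim the same tip.  The returned tree is rooted at the MRCA of
    the retained tips with no residual root edge.
    """
    substitutions = substitutions or {}
    species = list(species)
    if len(set(species)) != len(species):
        raise DataError("duplicate species in binding list")
    tips = set(tree.tip_labels)

    applied: dict[str, str] = {}  # tree tip -> dataset name
    unresolved: list[str] = []
    for sp in species:
        if sp in tips:
            continue
        target = substitutions.get(sp)
        if target is None:
            unresolved.append(sp)
        elif target not in tips:
            raise DataError(
                f"substitution target {target!r} for {sp!r} is not a tree tip"
            )
        elif target in applied:
            raise DataError(
                f"substitution target {target!r} claimed by both "
                f"{applied[target]!r} and {sp!r}"
            )
        elif target in species:
            raise DataError(
                f"substitution target {target!r} is itself a dataset species"
            )
        else:
            applied[target] = sp
    if unresolved:
        raise DataError(
            f"species with no tree tip and no substitution: {sorted(unresolved)}"
        )

    bound = tree.dendropy_tree.clone(depth=1)
    for leaf in bound.leaf_node_iter():
        if leaf.taxon.label in applied:
            leaf.taxon.label = applied[leaf.taxon.label]
    bound.retain_taxa_with_labels(species)
    # Re-root bookkeeping: drop any chain of unifurcations above the MRCA
    # and the residual root edge itself.
    while len(bound.seed_node.child_nodes()) == 1:
        child = bound.seed_node.child_nodes()[0]
        child.parent_node = None
        bound.seed_node = child
    bound.seed_node.edge.length = None
    out = PhyloTree(bound)
    got = set(out.tip_labels)
    if got != set(species):
        raise DataError(
            f"binding failed: missing {sorted(set(species) - got)}, "
            f"extra {sorted(got - set(species))}"
        )
    return out


# ---------------------------------------------------------------------------
# branch ranges


def branch_ranges(tree: PhyloTree, incidence: IncidenceMatrix) -> pd.DataFrame:
    """Per-edge descendant-tip count ``n_tips`` and occupied-cell range ``n_cells``.

    ``n_cells`` (R_b) is the number of grid cells containing at least one
    descendant tip of the edge — the branch-level analogue of species range
    size that phylogenetic endemism divides by.  Rows follow the tree's
    postorder edge order; terminal edges carry their tip label in ``tip``.
    """
    arr = tree.arrays
    missing = [t for t in arr.tip_labels if t not in incidence._species_index]
    if missing:
        raise DataError(f"tree tips absent from incidence: {missing[:10]}")
    tip_rows = np.vstack([incidence.species_row(t) for t in arr.tip_labels])
    edge_cells = arr.edge_tip @ tip_rows.astype(np.int64) > 0  # (E, C)
    tip_col = []
    for is_term, row in zip(arr.terminal, arr.edge_tip):
        tip_col.append(arr.tip_labels[int(np.nonzero(row)[0][0])] if is_term else "")
    return pd.DataFrame(
        {
            "tip": tip_col,
            "length": arr.edge_lengths,
            "n_tips": arr.n_tips_per_edge,
            "n_cells": edge_cells.sum(axis=1),
        }
    )


def edge_cell_incidence(tree: PhyloTree, incidence: IncidenceMatrix) -> np.ndarray:
    """Boolean (edges x cells) matrix: edge b lies on cell c's PD subtree.

    An edge belongs to a cell's subtree exactly when at least one of its
    descendant tips occurs in the cell.
    """
    arr = tree.arrays
    missing = [t for t in arr.tip_labels if t not in incidence._species_index]
    if missing:
        raise DataError(f"tree tips absent from incidence: {missing[:10]}")
    tip_rows = np.vstack([incidence.species_row(t) for t in arr.tip_labels])
    return (arr.edge_tip.astype(np.float32) @ tip_rows.astype(np.float32)) > 0
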