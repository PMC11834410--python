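"""Vectorized branch-coverage machinery shared by Faith PD and UniFrac.

A rooted tree over J taxa is flattened once into (branch lengths, node x taxon
descendant indicator matrix); any number of samples can then be scored with
dense boolean algebra.  Both metrics are root-inclusive: every branch on the
path from an observed leaf up to (but excluding) the root contributes.
"""

from __future__ import annotations

import numpy as np
import skbio

from .errors import InvalidArgumentError


class BranchIndex:
    """Flattened view of a rooted tree for fast presence-set metrics."""

    def __init__(self, tree: skbio.TreeNode, taxon_ids: list[str]):
        leaf_pos = {t: i for i, t in enumerate(taxon_ids)}
        tree_leaves = {tip.name for tip in tree.tips()}
        missing = [t for t in taxon_ids if t not in tree_leaves]
        if missing:
            raise InvalidArgumentError(f"taxa absent from tree: {missing}")

        lengths: list[float] = []
        rows: list[np.ndarray] = []
        # postorder over non-root nodes; each node's row marks descendant taxa
        cache: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                row = np.zeros(len(taxon_ids), dtype=bool)
                if node.name in leaf_pos:
                    row[leaf_pos[node.name]] = True
            else:
                row = np.zeros(len(taxon_ids), dtype=bool)
                for child in node.children:
                    row |= cache.pop(id(child))
            cache[id(node)] = row
            if node.parent is not None:  # root carries no branch
                lengths.append(node.length if node.length is not None else 0.0)
                rows.append(row)

        self.taxon_ids = list(taxon_ids)
        self.lengths = np.asarray(lengths, dtype=float)
        self.descendants = np.asarray(rows, dtype=bool)  # (n_branches, n_taxa)
        self.total_length = float(self.lengths.sum())

    def coverage(self, presence: np.ndarray) -> np.ndarray:
        """Branch coverage for each sample: (n_samples, n_branches) boolean."""
        presence = np.atleast_2d(np.asarray(presence, dtype=bool))
        if presence.shape[1] != len(self.taxon_ids):
            raise InvalidArgumentError(
                f"presence matrix has {presence.shape[1]} columns, "
                f"expected {len(self.taxon_ids)}"
            )
        return presence @ self.descendants.T

    def faith_pd(self, presence: np.ndarray) -> np.ndarray:
        """Root-inclusive Faith PD for each row of a presence matrix."""
        return self.coverage(presence).astype(float) @ self.lengths

    def unweighted_unifrac(self, presence: np.ndarray) -> np.ndarray:
        """Pairwise unweighted UniFrac over the rows of a presence matrix."""
        cov = self.coverage(presence).astype(float)
        w = cov * self.lengths  # length-weighted coverage
        shared = w @ cov.T  # branch length covered by both samples
        own = w.sum(axis=1)
        union = own[:, None] + own[None, :] - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - shared / union
        dist[union == 0] = 0.0  # two empty samples: no branches at all
        np.fill_diagonal(dist, 0.0)
        return dist
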