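"""Patristic distances and the tip-label randomization behind the null model.

The null model used throughout the package is the "taxa labels" shuffle:
taxon identities are permuted across the tips of the phylogeny while the
abundance table stays fixed.  Equivalently, the rows and columns of the
cophenetic distance matrix are jointly permuted — distances are therefore
computed once per analysis and every null replicate is a cheap index
permutation, never a new tree traversal.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = ["cophenetic_distances", "permute_taxa", "is_ultrametric"]


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Pairwise patristic distances between tips.

    The patristic (cophenetic) distance between two tips is the sum of
    branch lengths along the path connecting them; it is a tree metric and
    so satisfies the triangle inequality.
    """
    n_tips = sum(1 for _ in tree.tips())
    if n_tips < 2:
        raise ValueError("cophenetic distances need a tree with >= 2 tips")
    return tree.tip_tip_distances()


def permute_taxa(dist: DistanceMatrix, seed=None) -> DistanceMatrix:
    """Jointly permute rows/columns of a distance matrix (tip-label shuffle).

    Reassigns taxon identifiers by a uniform random permutation while the
    multiset of pairwise distances is conserved.  `seed` may be an integer,
    a :class:`numpy.random.Generator`, or None.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    perm = rng.permutation(len(dist.ids))
    return DistanceMatrix(dist.data[np.ix_(perm, perm)], ids=dist.ids)


def is_ultrametric(tree: TreeNode, rtol: float = 1e-9) -> bool:
    """True when all root-to-tip path lengths agree within tolerance."""
    depths = []
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths.append(d)
    depths = np.asarray(depths)
    scale = max(depths.max(), 1.0)
    return float(depths.max() - depths.min()) <= rtol * scale
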