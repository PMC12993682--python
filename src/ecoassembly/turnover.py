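"""Observed pairwise turnover metrics.

Implements abundance-weighted beta mean nearest taxon distance (betaMNTD),
Bray-Curtis dissimilarity matrices, and squared-Pearson similarity between
samples after an abundance filter.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from skbio import DistanceMatrix

from .data_io import CommunityMatrix, hellinger_transform

__all__ = ["beta_mntd", "bray_curtis_matrix", "pairwise_r2"]


def _beta_mntd_core(
    dist: np.ndarray,
    present_k: np.ndarray,
    present_m: np.ndarray,
    weights_k: np.ndarray,
    weights_m: np.ndarray,
) -> float:
    """Abundance-weighted mean nearest-taxon distance on index arrays.

    `dist` is the full cophenetic matrix; `present_*` are integer indices of
    taxa present in each community and `weights_*` their relative abundances
    (summing to 1 over the present taxa).  Shared taxa contribute a
    nearest-taxon distance of 0 through the zero diagonal.
    """
    sub = dist[np.ix_(present_k, present_m)]
    return 0.5 * (weights_k @ sub.min(axis=1) + weights_m @ sub.min(axis=0))


def beta_mntd(
    f_k,
    f_m,
    dist: DistanceMatrix,
    include_conspecifics: bool = True,
) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two samples.

    For every taxon present in one community the patristic distance to its
    nearest relative present in the other community is found; these minima
    are averaged with abundance weights, symmetrically in the two
    communities:

        betaMNTD = 0.5 * [ sum_i f_ik * min_j D_ij + sum_j f_jm * min_i D_ij ]

    with i ranging over taxa present in sample k and j over taxa present in
    sample m.  A taxon present in both communities has a nearest-taxon
    distance of 0 unless ``include_conspecifics=False``.

    Parameters
    ----------
    f_k, f_m :
        Abundance vectors indexed by the same taxon set as `dist`
        (pandas Series, dict, or array in the order of ``dist.ids``);
        each must sum to 1 and contain at least one positive entry.
    dist :
        Cophenetic distance matrix over the harmonized taxon set.
    """
    ids = list(dist.ids)
    vk = _as_vector(f_k, ids)
    vm = _as_vector(f_m, ids)
    for name, v in (("first", vk), ("second", vm)):
        if v.sum() <= 0:
            raise ValueError(f"{name} community is empty")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} abundance vector must sum to 1")
    pk = np.flatnonzero(vk > 0)
    pm = np.flatnonzero(vm > 0)
    d = dist.data
    if not include_conspecifics:
        shared = np.intersect1d(pk, pm)
        if shared.size:
            d = d.copy()
            d[shared, shared] = np.inf
    return float(_beta_mntd_core(d, pk, pm, vk[pk], vm[pm]))


def _as_vector(f, ids: list[str]) -> np.ndarray:
    if isinstance(f, pd.Series):
        extra = set(f.index) - set(ids)
        if extra or len(f) != len(ids):
            raise ValueError("abundance vector taxa do not match distance matrix ids")
        return f.reindex(ids).to_numpy(dtype=float)
    if isinstance(f, dict):
        if set(f) - set(ids):
            raise ValueError("abundance vector taxa do not match distance matrix ids")
        return np.array([f.get(i, 0.0) for i in ids], dtype=float)
    arr = np.asarray(f, dtype=float)
    if arr.shape != (len(ids),):
        raise ValueError("abundance vector length does not match distance matrix ids")
    return arr


def bray_curtis_matrix(matrix: CommunityMatrix) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarity, BC in [0, 1].

    BC(k, m) = sum_i |x_ik - x_im| / sum_i (x_ik + x_im).  Identical on
    relative abundances and on pseudo-counts after row normalization.
    """
    vals = matrix.values
    if (vals.sum(axis=1) <= 0).any():
        raise ValueError("all-zero row in abundance matrix")
    return DistanceMatrix(squareform(pdist(vals, metric="braycurtis")), ids=matrix.sample_ids)


def pairwise_r2(
    matrix: CommunityMatrix,
    min_abundance: float = 0.001,
    transform: str = "hellinger",
    filter_mode: str = "max",
) -> pd.DataFrame:
    """Squared Pearson correlation between sample pairs after a filter.

    For each pair of samples, taxa whose abundance statistic (``max`` over
    the two samples by default, ``mean`` optionally) exceeds `min_abundance`
    are retained, the retained relative abundances are optionally
    Hellinger-transformed, and the squared Pearson correlation of the two
    vectors is returned as a symmetric samples x samples table with unit
    diagonal.
    """
    if matrix.mode != "relative":
        raise ValueError("pairwise_r2 requires mode='relative'")
    if transform not in {"hellinger", "none"}:
        raise ValueError(f"unknown transform {transform!r}")
    if filter_mode not in {"max", "mean"}:
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    data = matrix.data
    if transform == "hellinger":
        data = hellinger_transform(matrix).data
    raw = matrix.data
    n = matrix.n_samples
    out = pd.DataFrame(np.eye(n), index=matrix.sample_ids, columns=matrix.sample_ids)
    for a, b in itertools.combinations(matrix.sample_ids, 2):
        pair = raw.loc[[a, b]]
        stat = pair.max(axis=0) if filter_mode == "max" else pair.mean(axis=0)
        keep = stat > min_abundance
        if keep.sum() < 2:
            raise ValueError(f"fewer than 2 taxa survive the filter for pair ({a}, {b})")
        x = data.loc[a, keep].to_numpy(dtype=float)
        y = data.loc[b, keep].to_numpy(dtype=float)
        r = pearsonr(x, y).statistic
        out.loc[a, b] = out.loc[b, a] = r * r
    return out
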