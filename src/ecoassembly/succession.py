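"""Phase-level succession statistics.

Alpha diversity indices, one-way ANOVA with Tukey HSD post-hoc tests,
per-feature phase-peak tests with Benjamini-Hochberg FDR control,
permutation group tests (PERMANOVA / ANOSIM), principal coordinates
analysis, average-linkage (UPGMA) clustering, and the phase-summary
percentage arithmetic used in digester performance reporting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova
from statsmodels.stats.multitest import multipletests

from .data_io import CommunityMatrix, hellinger_transform

__all__ = [
    "alpha_diversity",
    "one_way_anova",
    "tukey_hsd",
    "bh_adjust",
    "phase_peak_test",
    "group_significance",
    "pcoa",
    "PCoAResult",
    "upgma_cluster",
    "Dendrogram",
    "percent_reduction",
    "round_half_up",
]


def alpha_diversity(counts) -> dict[str, float]:
    """Shannon, Simpson, inverse Simpson and Fisher's alpha for one sample.

    ``counts`` are non-negative integers.  Shannon H = -sum p ln p (nats);
    Simpson D = sum p^2 (probability two draws are conspecific); inverse
    Simpson = 1/D; Fisher's alpha is the unique positive root of
    S = alpha * ln(1 + N/alpha) for richness S and total count N.  Fisher's
    alpha is undefined when S = N (every individual its own species, e.g.
    S = N = 1) and is returned as NaN in that case.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be a 1-D vector of non-negative integers")
    total = x.sum()
    if total < 1:
        raise ValueError("zero total count")
    present = x[x > 0]
    s, n = len(present), float(total)
    p = present / n
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p * p).sum())
    if s >= n:  # S = N: alpha -> infinity, undefined
        fisher = float("nan")
    else:
        fisher = float(brentq(lambda a: a * math.log1p(n / a) - s, 1e-12, 1e12, xtol=1e-12))
    return {
        "shannon": shannon,
        "simpson": simpson,
        "inv_simpson": 1.0 / simpson,
        "fisher_alpha": fisher,
        "richness": s,
    }


def one_way_anova(groups: list) -> dict[str, float]:
    """Classical one-way fixed-effects ANOVA from sums of squares.

    F = MSB / MSW with df_between = g - 1 and df_within = n - g; the p-value
    comes from the F distribution.  Degenerate cases follow fixed contracts:
    zero within-group variance with between-group spread gives F = inf and
    p = 0; all values identical gives F = 0 and p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 1 for a in arrs):
        raise ValueError("need >= 2 groups, each non-empty")
    n = sum(a.size for a in arrs)
    g = len(arrs)
    if n - g < 1:
        raise ValueError("need at least one group with >= 2 values")
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfb, dfw = g - 1, n - g
    if ssw <= 0:
        if ssb <= 1e-300:
            return {"F": 0.0, "p": 1.0, "df_between": dfb, "df_within": dfw}
        return {"F": float("inf"), "p": 0.0, "df_between": dfb, "df_within": dfw}
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return {"F": float(f), "p": p, "df_between": dfb, "df_within": dfw}


def tukey_hsd(groups: list, alpha: float = 0.05, labels=None) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    Uses the mean square within from the omnibus ANOVA; the studentized
    range statistic for groups i, j is
    ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` (Tukey-Kramer
    for unequal sizes) with the adjusted p from the studentized range
    distribution on (g, n - g).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("Tukey HSD needs >= 2 values per group")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(arrs))]
    n = sum(a.size for a in arrs)
    g = len(arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfw = n - g
    msw = ssw / dfw
    rows = []
    for i, j in itertools.combinations(range(g), 2):
        diff = arrs[j].mean() - arrs[i].mean()
        if msw <= 0:
            q = float("inf") if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, g, dfw))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "difference": float(diff),
                "q": float(q),
                "p_adj": min(max(p, 0.0), 1.0),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def phase_peak_test(
    matrix: CommunityMatrix,
    fdr_q: float = 0.05,
    transform: str = "hellinger",
) -> pd.DataFrame:
    """Which features peak in which phase, with FDR control.

    Each feature (taxon, family, ...) is tested across phases by one-way
    ANOVA on its (optionally Hellinger-transformed) abundances, using the
    digesters within a phase as replicates; raw p-values are
    Benjamini-Hochberg adjusted across features; the peak phase is the phase
    with the largest mean abundance.  Features constant across all samples
    get p = 1 and are never significant.
    """
    if matrix.sample_meta is None or "phase" not in matrix.sample_meta.columns:
        raise ValueError("matrix needs sample_meta with a 'phase' column")
    phases = matrix.sample_meta["phase"]
    sizes = phases.value_counts()
    if (sizes < 2).any():
        raise ValueError("each phase needs >= 2 samples (replicates)")
    if transform == "hellinger":
        data = hellinger_transform(matrix).data
    elif transform == "none":
        data = matrix.data
    else:
        raise ValueError(f"unknown transform {transform!r}")
    phase_levels = sorted(sizes.index)
    groups_idx = {p: phases.index[phases == p] for p in phase_levels}

    raw_means = matrix.data  # peak phase judged on untransformed abundances
    rows = []
    for feature in data.columns:
        groups = [data.loc[groups_idx[p], feature].to_numpy() for p in phase_levels]
        if np.ptp(np.concatenate(groups)) == 0:
            p_raw = 1.0
        else:
            p_raw = one_way_anova(groups)["p"]
        means = {p: raw_means.loc[groups_idx[p], feature].mean() for p in phase_levels}
        rows.append(
            {
                "feature": feature,
                "peak_phase": max(means, key=means.get),
                "p_raw": p_raw,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"])
    out["significant"] = out["p_adj"] < fdr_q
    return out


def group_significance(
    dist: DistanceMatrix,
    labels,
    method: str = "permanova",
    permutations: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """PERMANOVA pseudo-F or ANOSIM R with a permutation p-value.

    p = (1 + #{permuted statistic >= observed}) / (1 + permutations), so the
    smallest attainable p is 1/(permutations + 1).  Labels must partition
    the samples into >= 2 groups of >= 2.
    """
    labels = pd.Series(list(labels), index=dist.ids)
    sizes = labels.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    fn = {"permanova": _skbio_permanova, "anosim": _skbio_anosim}.get(method)
    if fn is None:
        raise ValueError(f"unknown method {method!r}")
    res = fn(dist, labels.to_numpy(), permutations=permutations, seed=seed)
    return {
        "statistic": float(res["test statistic"]),
        "p": float(res["p-value"]),
        "method": method,
        "permutations": permutations,
    }


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix | np.ndarray, ids=None) -> PCoAResult:
    """Principal coordinates analysis (classical metric scaling).

    The squared distance matrix is Gower double-centered
    (B = -1/2 * J D2 J) and eigendecomposed; axes are ordered by descending
    eigenvalue and scaled by sqrt(eigenvalue).  Negative eigenvalues (from
    non-Euclidean dissimilarities such as Bray-Curtis) are reported but
    contribute no axes; proportions explained are over the sum of positive
    eigenvalues only.
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.data
        ids = list(dist.ids)
    else:
        d = np.asarray(dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        ids = list(ids) if ids is not None else [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    pos_sum = eigvals[pos].sum()
    prop = np.where(pos, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass
class Dendrogram:
    """UPGMA merge list; heights are raw average-linkage distances."""

    linkage: np.ndarray  # scipy linkage matrix
    ids: list[str]

    def cophenetic(self) -> DistanceMatrix:
        return DistanceMatrix(squareform(hierarchy.cophenet(self.linkage)), ids=self.ids)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = node.get_left(), node.get_right()
            bl = node.dist - (0.0 if left.is_leaf() else left.dist)
            br = node.dist - (0.0 if right.is_leaf() else right.dist)
            lb = node.dist if left.is_leaf() else bl
            rb = node.dist if right.is_leaf() else br
            return f"({rec(left)}:{lb / 2:.10g},{rec(right)}:{rb / 2:.10g})"

        return rec(tree) + ";"


def upgma_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering.

    Merge heights are recorded as the raw average linkage distances (not
    halved), are non-decreasing, and ties are resolved deterministically by
    scipy's ordering, so permuting input order yields identical merges.
    """
    if len(dist.ids) < 2:
        raise ValueError("need >= 2 items to cluster")
    z = hierarchy.linkage(squareform(dist.data, checks=False), method="average")
    return Dendrogram(linkage=z, ids=list(dist.ids))


def percent_reduction(start: float, end: float) -> float:
    """Percent decrease from `start` to `end`: 100 * (start - end) / start."""
    if start <= 0:
        raise ValueError("start must be positive")
    return 100.0 * (start - end) / start


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (reporting rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
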