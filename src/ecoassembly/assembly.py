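"""Null-model inference of community assembly processes.

For every pair of samples this module computes:

* the beta nearest taxon index (betaNTI) — a z-score of the observed
  abundance-weighted betaMNTD against a null ensemble obtained by shuffling
  taxon labels across the tips of the phylogeny;
* the abundance-based Raup-Crick Bray-Curtis index (RCbray) — the observed
  Bray-Curtis dissimilarity ranked within a null ensemble that fixes each
  sample's richness and total abundance while drawing species membership
  with probability proportional to occupancy and individuals with
  probability proportional to mean relative abundance across the
  metacommunity (all samples in the current analysis);
* a five-way classification: |betaNTI| > 2 indicates selection (variable
  when positive, homogeneous when negative); otherwise RCbray > +0.95
  indicates dispersal limitation with drift, RCbray < -0.95 homogenizing
  dispersal, and anything else is undominated.

Randomness is driven by one root seed; each (operation, sample-pair) gets
its own child stream so results do not depend on iteration order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .data_io import CommunityMatrix
from .turnover import _beta_mntd_core

__all__ = [
    "PROCESS_LABELS",
    "NullDistribution",
    "beta_nti",
    "raup_crick_bray",
    "classify_process",
    "infer_assembly",
    "phase_pair_summary",
]

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

_OP_BNTI = 1
_OP_RC = 2


@dataclass
class NullDistribution:
    """Null ensemble for one sample pair and one metric."""

    metric: str  # "beta_mntd" | "bray_curtis"
    values: np.ndarray
    reps: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.reps,):
            raise ValueError("null distribution length must equal reps")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite null values")


def _pair_rng(seed: int, op: int, ia: int, ib: int) -> np.random.Generator:
    lo, hi = (ia, ib) if ia <= ib else (ib, ia)
    return np.random.default_rng([int(seed), int(op), int(lo), int(hi)])


def _sample_pairs(sample_ids, pairs):
    if pairs is None:
        return list(itertools.combinations(range(len(sample_ids)), 2))
    index = {s: i for i, s in enumerate(sample_ids)}
    return [(index[a], index[b]) for a, b in pairs]


def beta_nti(
    matrix: CommunityMatrix,
    dist: DistanceMatrix,
    reps: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    keep_nulls: bool = False,
    on_degenerate: str = "raise",
):
    """betaNTI for every (or selected) unordered sample pair.

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null), with
    the null generated by jointly permuting rows/columns of the cophenetic
    matrix (taxon-label shuffle) and the sample-standard-deviation (n-1)
    denominator.  Abundances are renormalized over the harmonized taxon set
    before weighting.

    A degenerate null (every shuffle gives the same betaMNTD, e.g. a star
    phylogeny or two samples whose taxon sets overlap completely) raises by
    default; ``on_degenerate="nan"`` records NaN for that pair instead so a
    multi-pair analysis can continue.

    Returns a DataFrame with columns sample_a, sample_b, beta_mntd_obs,
    beta_nti (and, when ``keep_nulls``, a dict mapping (sample_a, sample_b)
    to :class:`NullDistribution`).
    """
    if reps < 99:
        raise ValueError("reps must be >= 99")
    ids = list(dist.ids)
    if set(matrix.taxon_ids) != set(ids):
        raise ValueError("matrix taxa and distance-matrix ids differ; harmonize first")
    vals = matrix.data[ids].to_numpy(dtype=float)
    rowsums = vals.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValueError("empty community")
    rel = vals / rowsums[:, None]
    d = dist.data
    n_taxa = len(ids)

    rows = []
    nulls: dict[tuple[str, str], NullDistribution] = {}
    for ia, ib in _sample_pairs(matrix.sample_ids, pairs):
        pk = np.flatnonzero(rel[ia] > 0)
        pm = np.flatnonzero(rel[ib] > 0)
        wk = rel[ia, pk] / rel[ia, pk].sum()
        wm = rel[ib, pm] / rel[ib, pm].sum()
        obs = _beta_mntd_core(d, pk, pm, wk, wm)
        rng = _pair_rng(seed, _OP_BNTI, ia, ib)
        null = np.empty(reps)
        for r in range(reps):
            perm = rng.permutation(n_taxa)
            null[r] = _beta_mntd_core(d, perm[pk], perm[pm], wk, wm)
        sd = null.std(ddof=1)
        if sd < 1e-12:
            if on_degenerate == "raise":
                raise ValueError(
                    "degenerate null distribution (all shuffles give identical betaMNTD)"
                )
            z = float("nan")
        else:
            z = float((obs - null.mean()) / sd)
        a, b = matrix.sample_ids[ia], matrix.sample_ids[ib]
        rows.append((a, b, float(obs), z))
        if keep_nulls:
            nulls[(a, b)] = NullDistribution("beta_mntd", null, reps, seed)
    out = pd.DataFrame(rows, columns=["sample_a", "sample_b", "beta_mntd_obs", "beta_nti"])
    return (out, nulls) if keep_nulls else out


def _draw_null_community(
    rng: np.random.Generator,
    richness: int,
    depth: int,
    occupancy: np.ndarray,
    mean_rel: np.ndarray,
) -> np.ndarray:
    """One null community: richness species by occupancy, individuals by abundance.

    Species membership is a weighted sample without replacement (probability
    proportional to occupancy, drawn via Gumbel top-k over the occupied
    pool); each member is seeded with one individual and the remaining
    ``depth - richness`` individuals are distributed multinomially with
    probability proportional to the species' mean relative abundance across
    the metacommunity.
    """
    pool = np.flatnonzero(occupancy > 0)
    if richness > pool.size:
        raise ValueError("observed richness exceeds occupied species pool")
    if depth < richness:
        raise ValueError("total abundance below richness")
    keys = np.log(occupancy[pool]) + rng.gumbel(size=pool.size)
    chosen = pool[np.argpartition(-keys, richness - 1)[:richness]]
    counts = np.zeros(occupancy.size, dtype=np.int64)
    counts[chosen] = 1
    extra = depth - richness
    if extra > 0:
        p = mean_rel[chosen]
        p = p / p.sum()
        counts[chosen] += rng.multinomial(extra, p)
    return counts


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom)


def raup_crick_bray(
    matrix: CommunityMatrix,
    reps: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    keep_nulls: bool = False,
    occupancy: np.ndarray | None = None,
    mean_rel: np.ndarray | None = None,
):
    """Abundance-based Raup-Crick standardized Bray-Curtis per sample pair.

    RCbray = 2 * [ (#null < obs + 0.5 * #null = obs) / reps - 0.5 ], in
    [-1, 1].  Values near +1 mean the two communities are less similar than
    the null expectation (dispersal limitation acting with drift); values
    near -1 mean more similar than expected (homogenizing dispersal).
    Equality uses a 1e-12 tolerance.  Requires pseudo-count mode; the
    metacommunity is the full set of samples in `matrix` unless explicit
    `occupancy` / `mean_rel` vectors (one entry per taxon) are supplied.
    """
    if matrix.mode != "pseudocount":
        raise ValueError("raup_crick_bray requires pseudocount mode")
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples to define the metacommunity")
    counts = matrix.values
    if occupancy is None:
        occupancy = (counts > 0).sum(axis=0).astype(float)
    if mean_rel is None:
        rel = counts / counts.sum(axis=1, keepdims=True)
        mean_rel = rel.mean(axis=0)
    occupancy = np.asarray(occupancy, dtype=float)
    mean_rel = np.asarray(mean_rel, dtype=float)
    if occupancy.shape != (matrix.n_taxa,) or mean_rel.shape != (matrix.n_taxa,):
        raise ValueError("occupancy/mean_rel must have one entry per taxon")
    richness = (counts > 0).sum(axis=1)
    depth = counts.sum(axis=1).astype(int)

    rows = []
    nulls: dict[tuple[str, str], NullDistribution] = {}
    for ia, ib in _sample_pairs(matrix.sample_ids, pairs):
        obs = _bray_curtis(counts[ia], counts[ib])
        rng = _pair_rng(seed, _OP_RC, ia, ib)
        null = np.empty(reps)
        for r in range(reps):
            xa = _draw_null_community(rng, int(richness[ia]), depth[ia], occupancy, mean_rel)
            xb = _draw_null_community(rng, int(richness[ib]), depth[ib], occupancy, mean_rel)
            null[r] = _bray_curtis(xa, xb)
        less = (null < obs - 1e-12).sum()
        ties = (np.abs(null - obs) <= 1e-12).sum()
        rc = 2.0 * ((less + 0.5 * ties) / reps - 0.5)
        a, b = matrix.sample_ids[ia], matrix.sample_ids[ib]
        rows.append((a, b, float(obs), float(rc)))
        if keep_nulls:
            nulls[(a, b)] = NullDistribution("bray_curtis", null, reps, seed)
    out = pd.DataFrame(rows, columns=["sample_a", "sample_b", "bray_curtis_obs", "rc_bray"])
    return (out, nulls) if keep_nulls else out


def classify_process(beta_nti: float, rc_bray: float | None = None) -> str:
    """Five-way assembly-process label from (betaNTI, RCbray).

    betaNTI > +2 -> variable selection; betaNTI < -2 -> homogeneous
    selection.  Otherwise assembly is stochastic and RCbray partitions it:
    > +0.95 dispersal limitation, < -0.95 homogenizing dispersal, else
    undominated.  Boundary values (|betaNTI| = 2, |RCbray| = 0.95) count as
    the weaker category.
    """
    beta_nti = float(beta_nti)
    if not np.isfinite(beta_nti):
        raise ValueError("non-finite betaNTI")
    if beta_nti > 2.0:
        return "variable_selection"
    if beta_nti < -2.0:
        return "homogeneous_selection"
    if rc_bray is None or not np.isfinite(rc_bray):
        raise ValueError("finite RCbray required when |betaNTI| <= 2")
    rc_bray = float(rc_bray)
    if not -1.0 - 1e-9 <= rc_bray <= 1.0 + 1e-9:
        raise ValueError("RCbray outside [-1, 1]")
    if rc_bray > 0.95:
        return "dispersal_limitation"
    if rc_bray < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def infer_assembly(
    rel_matrix: CommunityMatrix,
    count_matrix: CommunityMatrix,
    dist: DistanceMatrix,
    reps: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """betaNTI + RCbray + process label for every sample pair.

    `rel_matrix` (relative abundances, harmonized with `dist`) drives the
    phylogenetic null; `count_matrix` (pseudo-counts over the same samples)
    drives the Raup-Crick null.

    Pairs whose betaNTI null is degenerate (the observed betaMNTD equals
    every shuffled value, as happens when two samples contain exactly the
    same taxa) carry no evidence of selection either way; they keep a NaN
    betaNTI and are partitioned by RCbray alone.
    """
    bn = beta_nti(rel_matrix, dist, reps=reps, seed=seed, pairs=pairs, on_degenerate="nan")
    rc = raup_crick_bray(count_matrix, reps=reps, seed=seed, pairs=pairs)
    out = bn.merge(rc, on=["sample_a", "sample_b"], validate="one_to_one")
    out["process"] = [
        classify_process(0.0 if np.isnan(b) else b, r)
        for b, r in zip(out["beta_nti"], out["rc_bray"])
    ]
    return out


def phase_pair_summary(results: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-pair assembly results over phase pairs.

    For each unordered pair of distinct phases, all cross-phase sample pairs
    (9 for 3 digesters with one sample per phase) are collected and the mean
    and median betaNTI, mean RCbray, per-pair label counts, and a consensus
    label classified from the mean betaNTI and mean RCbray are reported.
    Within-phase pairs are excluded from the aggregates.
    """
    if "phase" not in sample_meta.columns:
        raise ValueError("sample_meta needs a 'phase' column")
    phases = sorted(sample_meta["phase"].unique())
    counts = sample_meta["phase"].value_counts()
    empty = [p for p in phases if counts.get(p, 0) == 0]
    if empty or len(phases) < 2:
        raise ValueError("each phase needs at least one sample")
    res = results.copy()
    res["phase_a"] = res["sample_a"].map(sample_meta["phase"])
    res["phase_b"] = res["sample_b"].map(sample_meta["phase"])
    if res[["phase_a", "phase_b"]].isna().any().any():
        raise ValueError("results contain samples missing from sample_meta")

    rows = []
    for pa, pb in itertools.combinations(phases, 2):
        mask = ((res["phase_a"] == pa) & (res["phase_b"] == pb)) | (
            (res["phase_a"] == pb) & (res["phase_b"] == pa)
        )
        sub = res[mask]
        if sub.empty:
            raise ValueError(f"no cross-phase sample pairs for ({pa}, {pb})")
        mean_bnti = float(sub["beta_nti"].mean())
        mean_rc = float(sub["rc_bray"].mean())
        rows.append(
            {
                "phase_a": pa,
                "phase_b": pb,
                "n_pairs": int(len(sub)),
                "mean_beta_nti": mean_bnti,
                "median_beta_nti": float(sub["beta_nti"].median()),
                "mean_rc_bray": mean_rc,
                "labels": {k: int(v) for k, v in sub["process"].value_counts().items()},
                "consensus": classify_process(mean_bnti, mean_rc),
            }
        )
    return pd.DataFrame(rows)
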