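"""End-to-end validation experiments for the assembly-inference stack.

These routines answer three questions a practitioner should ask before
trusting null-model inference on real data:

1. *Is the betaNTI null calibrated?*  When the observed configuration is
   itself a draw from the taxon-shuffle null, |betaNTI| >= 2 should fire at
   roughly its nominal ~5% rate.
2. *Is the Raup-Crick index self-centered?*  Communities generated by the
   RC null procedure itself should score near 0 on average.
3. *Does inference recover known processes?*  Communities simulated under a
   named assembly regime should be classified as that regime for most
   sample pairs (parameter recovery).

They are used by the test suite and by the reproduction script, and are
ordinary library functions so they can be rerun at other sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assembly import (
    PROCESS_LABELS,
    _draw_null_community,
    beta_nti,
    infer_assembly,
    raup_crick_bray,
)
from .data_io import CommunityMatrix
from .phylo import cophenetic_distances, permute_taxa
from .succession import group_significance
from .synthetic import generate_scenario
from .turnover import bray_curtis_matrix

__all__ = [
    "bnti_null_calibration",
    "rc_self_calibration",
    "regime_recovery",
    "permutation_type_i",
]


def _relative(matrix: CommunityMatrix) -> CommunityMatrix:
    rel = matrix.data.div(matrix.data.sum(axis=1), axis=0)
    return CommunityMatrix(rel, mode="relative", sample_meta=matrix.sample_meta)


def bnti_null_calibration(
    n_instances: int = 100,
    n_taxa: int = 150,
    reps: int = 999,
    seed: int = 0,
) -> dict:
    """betaNTI distribution when the data are themselves a null draw.

    Each instance takes a structured two-sample community (variable
    selection regime) and applies one random taxon-label shuffle to the
    cophenetic matrix before inference, so the observed configuration is a
    draw from the very null betaNTI tests against.  Returns the betaNTI
    values and the fraction with |betaNTI| >= 2 (nominal rate ~5%).
    """
    values = []
    for i in range(n_instances):
        bundle = generate_scenario(
            "variable_selection", seed=(int(seed) * 100_003 + i) % 2_147_483_647, n_taxa=n_taxa, n_samples=2
        )
        dm = cophenetic_distances(bundle.tree)
        dm = permute_taxa(dm, seed=np.random.default_rng([seed, 7, i]))
        res = beta_nti(_relative(bundle.matrix), dm, reps=reps, seed=i)
        values.append(float(res["beta_nti"].iloc[0]))
    values = np.asarray(values)
    return {
        "beta_nti": values,
        "fraction_significant": float(np.mean(np.abs(values) >= 2.0)),
    }


def rc_self_calibration(
    n_instances: int = 100,
    n_taxa: int = 150,
    reps: int = 999,
    seed: int = 0,
) -> dict:
    """RCbray scored on pairs generated by the RC null procedure itself.

    A reference metacommunity (occupancy and mean relative abundance) is
    taken from a six-sample simulated scenario; each instance draws a fresh
    pair of null communities from that metacommunity and scores it with the
    same null.  RCbray should then be centered near 0.
    """
    bundle = generate_scenario("undominated", seed=seed, n_taxa=n_taxa, n_samples=6)
    counts = bundle.matrix.values
    occupancy = (counts > 0).sum(axis=0).astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    richness = int((counts[0] > 0).sum())
    depth = int(counts[0].sum())

    values = []
    for i in range(n_instances):
        rng = np.random.default_rng([seed, 11, i])
        xa = _draw_null_community(rng, richness, depth, occupancy, mean_rel)
        xb = _draw_null_community(rng, richness, depth, occupancy, mean_rel)
        pair = CommunityMatrix(
            pd.DataFrame(
                np.vstack([xa, xb]), index=["A", "B"], columns=bundle.matrix.taxon_ids
            ),
            mode="pseudocount",
        )
        res = raup_crick_bray(
            pair, reps=reps, seed=i, occupancy=occupancy, mean_rel=mean_rel
        )
        values.append(float(res["rc_bray"].iloc[0]))
    values = np.asarray(values)
    return {"rc_bray": values, "mean": float(values.mean())}


def regime_recovery(
    regimes=PROCESS_LABELS,
    n_pairs: int = 20,
    reps: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter recovery: simulate under each regime, infer, compare.

    For every regime, `n_pairs` independent two-sample scenarios are
    generated at the regime defaults and pushed through the full inference
    chain (betaNTI + RCbray + classification).  A pair whose inference
    fails (degenerate null from complete taxon overlap) counts as not
    recovered.  Returns one row per regime with the recovered fraction and
    the modal label.
    """
    rows = []
    for regime in regimes:
        labels = []
        for i in range(n_pairs):
            bundle = generate_scenario(regime, seed=(int(seed) * 100_003 + i) % 2_147_483_647, n_samples=2)
            dm = cophenetic_distances(bundle.tree)
            try:
                res = infer_assembly(
                    _relative(bundle.matrix), bundle.matrix, dm, reps=reps, seed=i
                )
                labels.append(res["process"].iloc[0])
            except ValueError:
                labels.append("inference_error")
        counts = pd.Series(labels).value_counts()
        rows.append(
            {
                "regime": regime,
                "n_pairs": n_pairs,
                "recovered_fraction": float(np.mean([l == regime for l in labels])),
                "modal_label": counts.index[0],
                "labels": dict(counts),
            }
        )
    return pd.DataFrame(rows)


def permutation_type_i(
    n_runs: int = 200,
    n_samples: int = 8,
    n_taxa: int = 40,
    alpha: float = 0.05,
    permutations: int = 999,
    method: str = "permanova",
    seed: int = 0,
) -> dict:
    """Type-I error of the permutation group tests on structureless data.

    Each run draws all samples from one common abundance profile (no group
    structure), assigns two equal groups at random, and records whether the
    permutation p-value falls below `alpha`.  The rejection rate should be
    close to the nominal level.
    """
    rng = np.random.default_rng([seed, 13])
    hits = 0
    for i in range(n_runs):
        base = rng.lognormal(0.0, 1.0, size=n_taxa)
        p = base / base.sum()
        counts = rng.multinomial(2000, p, size=n_samples)
        mat = CommunityMatrix(
            pd.DataFrame(
                counts, index=[f"S{k}" for k in range(n_samples)],
                columns=[f"t{k}" for k in range(n_taxa)],
            ),
            mode="pseudocount",
        )
        dist = bray_curtis_matrix(mat)
        labels = np.array(["a", "b"]).repeat(n_samples // 2)
        rng.shuffle(labels)
        res = group_significance(
            dist, labels, method=method, permutations=permutations, seed=i
        )
        hits += res["p"] <= alpha
    return {"rejection_rate": hits / n_runs, "n_runs": n_runs, "alpha": alpha}
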