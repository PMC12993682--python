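import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from skbio import DistanceMatrix

from ecoassembly.data_io import CommunityMatrix
from ecoassembly.succession import (
    alpha_diversity,
    bh_adjust,
    group_significance,
    one_way_anova,
    pcoa,
    percent_reduction,
    phase_peak_test,
    round_half_up,
    tukey_hsd,
    upgma_cluster,
)
from ecoassembly.turnover import bray_curtis_matrix


class TestAlphaDiversity:
    def test_uniform_closed_form(self):
        d = alpha_diversity([100, 100, 100, 100])
        assert d["shannon"] == pytest.approx(np.log(4))
        assert d["simpson"] == pytest.approx(0.25)
        assert d["inv_simpson"] == pytest.approx(4.0)

    def test_single_taxon(self):
        d = alpha_diversity([50])
        assert d["shannon"] == pytest.approx(0.0)
        assert d["simpson"] == pytest.approx(1.0)
        assert d["inv_simpson"] == pytest.approx(1.0)

    def test_fisher_alpha_root(self):
        # unique alpha solving S = alpha ln(1 + N/alpha) for S=10, N=100,
        # value frozen from an independent bisection on the defining equation
        counts = [91] + [1] * 9  # S=10, N=100
        d = alpha_diversity(counts)
        assert d["fisher_alpha"] == pytest.approx(2.7662896, abs=1e-4)
        a = d["fisher_alpha"]
        assert abs(a * np.log1p(100 / a) - 10) < 1e-9

    def test_fisher_alpha_undefined_when_all_singletons(self):
        d = alpha_diversity([1])
        assert np.isnan(d["fisher_alpha"])

    def test_entropy_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 50, size=rng.integers(2, 20))
            d = alpha_diversity(counts)
            s = (counts > 0).sum()
            assert d["shannon"] <= np.log(s) + 1e-12
            assert d["inv_simpson"] <= s + 1e-12

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])


class TestOneWayAnova:
    def test_hand_computed_f(self):
        res = one_way_anova([[0, 1], [2, 3], [4, 5]])
        assert res["F"] == pytest.approx(16.0)
        assert res["df_between"] == 2
        assert res["df_within"] == 3

    def test_identical_groups(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res["F"] == pytest.approx(0.0)

    def test_all_values_identical(self):
        res = one_way_anova([[2, 2], [2, 2]])
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_zero_within_variance(self):
        res = one_way_anova([[1, 1], [2, 2]])
        assert np.isinf(res["F"]) and res["p"] == 0.0

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=8)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert res["F"] == pytest.approx(t * t)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(2, 8)) for _ in range(3)]
            res = one_way_anova(groups)
            ref = sps.f_oneway(*groups)
            assert res["F"] == pytest.approx(ref.statistic, abs=1e-10)
            assert res["p"] == pytest.approx(ref.pvalue, abs=1e-10)


class TestTukeyHsd:
    def test_identical_groups_not_significant(self):
        res = tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert np.allclose(res["p_adj"], 1.0)
        assert not res["significant"].any()

    def test_largest_mean_difference_has_largest_q(self):
        res = tukey_hsd([[0, 1], [2, 3], [4, 5]], labels=["g1", "g2", "g3"])
        top = res.loc[res["q"].idxmax()]
        assert {top["group_a"], top["group_b"]} == {"g1", "g3"}

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, size=6) for m in (0, 1, 3)]
        res = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for _, row in res.iterrows():
            i, j = int(row["group_a"]), int(row["group_b"])
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-8)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert np.allclose(adj, [0.04, 0.04, 0.05333333, 0.8])

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPhasePeakTest:
    @staticmethod
    def _matrix(values, n_features_noise=10, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"{d}{p}" for p in ("P1", "P2", "P3") for d in ("D1", "D2", "D3")]
        meta = pd.DataFrame(
            {"digester": [s[:2] for s in samples], "phase": [s[2:] for s in samples]},
            index=samples,
        )
        data = {"signal": values}
        for i in range(n_features_noise):
            data[f"noise{i}"] = rng.uniform(0.5, 1.5, size=9)
        df = pd.DataFrame(data, index=samples)
        df = df.div(df.sum(axis=1), axis=0)
        return CommunityMatrix(df, mode="relative", sample_meta=meta)

    def test_separated_feature_is_significant(self):
        m = self._matrix([10, 10, 10, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
        res = phase_peak_test(m).set_index("feature")
        assert res.loc["signal", "peak_phase"] == "P1"
        assert res.loc["signal", "significant"]

    def test_constant_feature_never_significant(self):
        samples = [f"{d}{p}" for p in ("P1", "P2", "P3") for d in ("D1", "D2", "D3")]
        meta = pd.DataFrame({"phase": [s[2:] for s in samples]}, index=samples)
        df = pd.DataFrame({"flat": [0.5] * 9, "other": [0.5] * 9}, index=samples)
        m = CommunityMatrix(df, mode="relative", sample_meta=meta)
        res = phase_peak_test(m, transform="none").set_index("feature")
        assert res.loc["flat", "p_raw"] == 1.0
        assert not res.loc["flat", "significant"]

    def test_fdr_control_on_pure_noise(self):
        # label-free noise: the fraction of significant features should not
        # exceed the nominal FDR by more than sampling slack
        fractions = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            samples = [f"S{i}" for i in range(9)]
            meta = pd.DataFrame({"phase": ["P1", "P2", "P3"] * 3}, index=samples)
            df = pd.DataFrame(
                rng.uniform(0.5, 1.5, size=(9, 30)),
                index=samples,
                columns=[f"f{i}" for i in range(30)],
            )
            df = df.div(df.sum(axis=1), axis=0)
            m = CommunityMatrix(df, mode="relative", sample_meta=meta)
            res = phase_peak_test(m, fdr_q=0.05)
            fractions.append(res["significant"].mean())
        assert np.mean(fractions) <= 0.05 + 0.05


class TestGroupSignificance:
    def test_perfect_separation(self):
        n = 10
        data = np.ones((n, n)) - np.eye(n)
        data[: n // 2, : n // 2] = 0.01
        data[n // 2:, n // 2:] = 0.01
        np.fill_diagonal(data, 0)
        dm = DistanceMatrix(data, ids=[f"S{i}" for i in range(n)])
        labels = ["a"] * (n // 2) + ["b"] * (n // 2)
        res = group_significance(dm, labels, method="anosim", permutations=999, seed=0)
        assert res["statistic"] == pytest.approx(1.0)
        # smallest p attainable given C(10,5)/2 = 126 distinct groupings
        assert res["p"] <= 0.02

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"S{i}" for i in range(8)]
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        dm = DistanceMatrix(d, ids=ids)
        r1 = group_significance(dm, labels[list(dm.ids)], seed=1)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        r2 = group_significance(dm2, labels[list(dm2.ids)], seed=1)
        assert r1["statistic"] == pytest.approx(r2["statistic"])

    def test_singleton_group_errors(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.raises(ValueError):
            group_significance(dm, ["x", "x", "y"])


class TestPcoa:
    def test_collinear_points_recovered(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(rec, d, atol=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_identical_samples_zero_eigenvalues(self):
        res = pcoa(np.zeros((4, 4)))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_input_is_psd_and_exact(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(d)
        assert (res.eigenvalues >= -1e-9).all()
        coords = res.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(rec - d).max() < 1e-8

    def test_matches_skbio_on_bray_curtis(self, count_matrix):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        bc = bray_curtis_matrix(count_matrix)
        ours = pcoa(bc)
        ref = skbio_pcoa(bc, method="eigh", warn_neg_eigval=False)
        n = min(ours.coordinates.shape[1], 2)
        for k in range(n):
            a = ours.coordinates.iloc[:, k].to_numpy()
            b = ref.samples.iloc[:, k].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_asymmetric_input_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0, 1], [2, 0]], dtype=float))


class TestUpgma:
    def test_hand_agglomeration(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=list("ABC"))
        dendro = upgma_cluster(dm)
        heights = dendro.linkage[:, 2]
        assert heights[0] == pytest.approx(2.0)  # (A,B) merge at raw distance 2
        assert heights[1] == pytest.approx(4.0)

    def test_ultrametric_fixed_point(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=list("ABC"))
        cr = upgma_cluster(dm).cophenetic()
        assert np.allclose(cr.data, dm.data)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = list("ABCDEF")
        h1 = np.sort(upgma_cluster(DistanceMatrix(d, ids=ids)).linkage[:, 2])
        perm = rng.permutation(6)
        h2 = np.sort(
            upgma_cluster(
                DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
            ).linkage[:, 2]
        )
        assert np.allclose(h1, h2)

    def test_newick_round_trip_depths(self):
        from ecoassembly.data_io import read_newick

        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=list("ABC"))
        tree = read_newick(upgma_cluster(dm).to_newick())
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]


class TestPercentReduction:
    @pytest.mark.parametrize(
        ("start", "end", "rounded"),
        [(27595.16, 3959.78, 86), (25457.29, 4316.09, 83)],
    )
    def test_chemical_oxygen_demand_summaries(self, start, end, rounded):
        assert round_half_up(percent_reduction(start, end)) == rounded

    def test_identity_and_errors(self):
        assert percent_reduction(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)
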