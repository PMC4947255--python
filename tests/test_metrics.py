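"""Evaluation metrics: hand oracles, nulls, and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, linregress

from famnorm.datatypes import BetaMatrix, GenotypeTable, KinshipMatrix, MValueMatrix
from famnorm.metrics import (
    age_ewas_lambda,
    cluster_batch_agreement,
    density_summary,
    dmrse,
    ibs_kinship,
    mds_coordinates,
    meqtl_association,
    pc_anova,
    replicate_mad,
)


def _beta(values, probes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


class TestDensitySummary:
    def test_mass_concentrated_and_normalised(self, qc_dataset):
        grid, dens, ks = density_summary(BetaMatrix(qc_dataset.beta), qc_dataset.annotation)
        for j in range(dens.shape[1]):
            area = np.trapezoid(dens.iloc[:, j].to_numpy(), grid)
            assert area == pytest.approx(1.0, abs=0.01)
        assert 0 <= ks <= 1

    def test_equal_type_distributions_zero_ks(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.1, 0.9, size=(40, 1))
        beta = _beta(np.vstack([vals, vals]))
        from conftest import toy_dataset

        ds = toy_dataset(np.full((80, 1), 1000.0), np.full((80, 1), 1000.0),
                         design=["I"] * 40 + ["II"] * 40)
        _, _, ks = density_summary(beta, ds.annotation)
        assert ks < 1e-12


class TestMds:
    def test_3_4_5_triangle(self):
        # samples at (0,0), (3,0), (0,4): pairwise distances 3, 4, 5
        m = pd.DataFrame(
            {"a": [0.0, 0.0], "b": [3.0, 0.0], "c": [0.0, 4.0]},
            index=["p1", "p2"],
        )
        coords, _ = mds_coordinates(m, k=2)
        d = lambda x, y: np.linalg.norm(coords.loc[x] - coords.loc[y])
        assert d("a", "b") == pytest.approx(3.0, abs=1e-6)
        assert d("a", "c") == pytest.approx(4.0, abs=1e-6)
        assert d("b", "c") == pytest.approx(5.0, abs=1e-6)

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        m["d"] = m["a"]
        coords, _ = mds_coordinates(m, k=30)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["d"], atol=1e-8)

    def test_permutation_invariant_up_to_sign(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        c1, _ = mds_coordinates(m, k=25)
        c2, _ = mds_coordinates(m[list("fedcba")], k=25)
        for axis in ("mds1", "mds2"):
            direct = c2[axis].reindex(c1.index)
            same = np.allclose(direct, c1[axis], atol=1e-8)
            flipped = np.allclose(-direct, c1[axis], atol=1e-8)
            assert same or flipped


class TestPcAnova:
    def test_strong_shift_detected(self):
        rng = np.random.default_rng(4)
        n, s = 300, 30
        labels = np.array(["A"] * 15 + ["B"] * 15)
        x = rng.normal(size=(n, s))
        x[:, labels == "B"] += 5.0
        assert pc_anova(_beta(1 / (1 + np.exp(-x))), labels, k=200) < 1e-6

    def test_random_labels_uniform_null(self):
        # fresh iid data per repetition so the F-test's normality assumption
        # holds marginally and the null p-values are exactly uniform
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            beta = _beta(1 / (1 + np.exp(-rng.normal(size=(60, 24)))))
            labels = rng.permutation(["A"] * 12 + ["B"] * 12)
            pvals.append(pc_anova(beta, labels, k=60))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_equal_groups(self):
        beta = _beta(np.full((5, 4), 0.5))
        assert pc_anova(beta, ["A", "A", "B", "B"], k=5) == 1.0

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            pc_anova(_beta(np.random.rand(5, 4)), ["A"] * 4, k=5)


class TestReplicateMad:
    def test_hand_computation(self):
        m = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [1.5, 2.0, 2.5]})
        out = replicate_mad(m, {"g": ["r1", "r2"]})
        assert out["g"] == pytest.approx(0.5)

    def test_identical_replicates_zero(self):
        m = pd.DataFrame({"r1": [1.0, 2.0], "r2": [1.0, 2.0]})
        assert replicate_mad(m, {"g": ["r1", "r2"]})["g"] == 0.0

    def test_bruteforce_median_oracle(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=101), rng.normal(size=101)
        m = pd.DataFrame({"r1": a, "r2": b})
        expected = np.sort(np.abs(a - b))[50]
        assert replicate_mad(m, {"g": ["r1", "r2"]})["g"] == pytest.approx(expected)

    def test_missing_member_skipped_with_warning(self):
        m = pd.DataFrame({"r1": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="missing"):
            out = replicate_mad(m, {"g": ["r1", "gone"]})
        assert out == {}

    def test_triplet_evaluated_pairwise(self):
        m = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [3.0]})
        out = replicate_mad(m, {"g": ["a", "b", "c"]})
        assert len(out) == 3


class TestDmrse:
    def test_all_half_gives_zero(self):
        beta = _beta(np.full((5, 4), 0.5))
        assert dmrse(beta, [True] * 5) == 0.0

    def test_hand_computation_single_probe(self):
        beta = _beta([[0.4, 0.6]])
        assert dmrse(beta, [True]) == pytest.approx(np.std([-0.1, 0.1], ddof=1), abs=1e-12)
        assert dmrse(beta, [True]) == pytest.approx(0.14142135, abs=1e-6)

    def test_linearity_in_deviations(self):
        base = np.array([[0.5, 0.5], [0.45, 0.55]])
        doubled = np.array([[0.5, 0.5], [0.40, 0.60]])
        assert dmrse(_beta(doubled), [True, True]) == pytest.approx(
            2 * dmrse(_beta(base), [True, True])
        )

    def test_requires_idmr_probes(self):
        with pytest.raises(ValueError):
            dmrse(_beta(np.full((3, 3), 0.5)), [False, False, False])


class TestClusterBatchAgreement:
    def test_perfect_separation_ari_one(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 12))
        labels = ["A"] * 6 + ["B"] * 6
        x[:, 6:] += 20.0
        m = pd.DataFrame(x, columns=[f"s{j}" for j in range(12)])
        _, ari = cluster_batch_agreement(m, labels)
        assert ari == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(60, 14)))
        aris = []
        for _ in range(100):
            labels = rng.permutation(["A"] * 7 + ["B"] * 7)
            aris.append(cluster_batch_agreement(x, labels)[1])
        assert abs(np.mean(aris)) < 0.05


class TestIbsKinship:
    def test_identical_and_opposite_vectors(self):
        g = pd.DataFrame(
            {"a": [0, 2, 1, 0] * 5, "b": [0, 2, 1, 0] * 5, "c": [2, 0, 1, 2] * 5},
            index=[f"rs{i}" for i in range(20)],
            dtype=float,
        )
        pos = pd.DataFrame({"chromosome": "chr1", "position": range(20)}, index=g.index)
        k = ibs_kinship(GenotypeTable(g=g, positions=pos)).k
        assert k.loc["a", "b"] == pytest.approx(1.0)
        # a vs c: identical at het sites, opposite otherwise
        expected = np.mean([(2 - abs(x - y)) / 2 for x, y in zip(g["a"], g["c"])])
        assert k.loc["a", "c"] == pytest.approx(expected)

    def test_bruteforce_oracle_random(self):
        rng = np.random.default_rng(9)
        g = pd.DataFrame(
            rng.integers(0, 3, size=(1000, 4)).astype(float),
            index=[f"rs{i}" for i in range(1000)],
            columns=list("abcd"),
        )
        pos = pd.DataFrame({"chromosome": "chr1", "position": range(1000)}, index=g.index)
        k = ibs_kinship(GenotypeTable(g=g, positions=pos)).k
        brute = np.mean((2 - np.abs(g["a"] - g["b"])) / 2)
        assert k.loc["a", "b"] == pytest.approx(brute)


class TestMeqtlAssociation:
    def _geno(self, g):
        gdf = pd.DataFrame(g, index=[f"rs{i}" for i in range(len(g))],
                           columns=[f"s{j}" for j in range(len(g[0]))], dtype=float)
        pos = pd.DataFrame({"chromosome": "chr1", "position": range(len(g))}, index=gdf.index)
        return GenotypeTable(g=gdf, positions=pos)

    def test_identity_kinship_reduces_to_plain_regression(self):
        rng = np.random.default_rng(10)
        n = 30
        g = rng.integers(0, 3, size=(12, n)).astype(float)
        y = 0.5 * g[3] + rng.normal(0, 1, n)
        geno = self._geno(g)
        kin = KinshipMatrix(pd.DataFrame(np.eye(n) * 0.5, index=geno.sample_ids, columns=geno.sample_ids))
        table, _ = meqtl_association(pd.Series(y, index=geno.sample_ids), geno, kin)
        direct = [linregress(g[i], y - y.mean()).pvalue for i in range(12)]
        np.testing.assert_allclose(table["p"].to_numpy(), direct, rtol=1e-6)

    def test_perfect_association_recovered(self):
        rng = np.random.default_rng(11)
        n = 24
        g = rng.integers(0, 3, size=(11, n)).astype(float)
        y = 0.7 * g[5]
        geno = self._geno(g)
        kin = KinshipMatrix(pd.DataFrame(np.eye(n) * 0.5, index=geno.sample_ids, columns=geno.sample_ids))
        table, min_p = meqtl_association(pd.Series(y, index=geno.sample_ids), geno, kin)
        assert table.loc["rs5", "beta"] == pytest.approx(0.7, abs=1e-8)
        assert table.loc["rs5", "p"] < 1e-20
        assert min_p < 1e-18

    def test_monomorphic_snp_reported_as_one(self):
        rng = np.random.default_rng(12)
        n = 20
        g = rng.integers(0, 3, size=(5, n)).astype(float)
        g[2] = 1.0
        geno = self._geno(g)
        kin = KinshipMatrix(pd.DataFrame(np.eye(n) * 0.5, index=geno.sample_ids, columns=geno.sample_ids))
        table, _ = meqtl_association(pd.Series(rng.normal(size=n), index=geno.sample_ids), geno, kin)
        assert table.loc["rs2", "p_bonferroni"] == 1.0


class TestAgeEwasLambda:
    def test_definitional_lambda_one_for_uniform_pvalues(self):
        # when the regression p-values land exactly on the expected uniform
        # quantiles, lambda is 1 by definition; approximate via a large null
        rng = np.random.default_rng(13)
        ages = rng.uniform(23, 89, 40)
        x = rng.normal(size=(4000, 40))
        _, lam = age_ewas_lambda(pd.DataFrame(x), ages)
        assert lam == pytest.approx(1.0, abs=0.1)

    def test_five_percent_strong_signals_matches_mixture_median(self):
        # with a fraction f of probes carrying overwhelming signal, the
        # median observed p solves (1-f)*p + f = 0.5, hence
        # lambda -> log10(0.5/(1-f) - f/(1-f)... ) computed below
        rng = np.random.default_rng(14)
        f = 0.05
        n, s = 8000, 40
        ages = rng.uniform(23, 89, s)
        x = rng.normal(size=(n, s))
        k = int(f * n)
        x[:k] += np.outer(np.ones(k), (ages - ages.mean())) * 1.0  # overwhelming slopes
        _, lam = age_ewas_lambda(pd.DataFrame(x), ages)
        p_median = (0.5 - f) / (1 - f)
        expected = np.log10(p_median) / np.log10(0.5)
        assert expected == pytest.approx(1.0779, abs=1e-3)
        assert lam == pytest.approx(expected, abs=0.05)

    def test_constant_probe_gets_p_one(self):
        ages = np.array([30.0, 40.0, 50.0, 60.0])
        x = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [0.1, 0.4, 0.2, 0.9]])
        pvals, _ = age_ewas_lambda(x, ages)
        assert pvals.iloc[0] == 1.0

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError):
            age_ewas_lambda(pd.DataFrame(np.random.rand(5, 4)), [30, 30, 30, 30])
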