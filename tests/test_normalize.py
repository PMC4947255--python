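"""Normalisation methods: kernels, fixed points, recovery, and oracles."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from famnorm.datatypes import BetaMatrix, IntensityMatrix, MethylDataset
from famnorm.normalize import (
    BMIQNormalizer,
    ComBat,
    DasenNormalizer,
    FunnormNormalizer,
    NoobCorrector,
    combat,
    norm_bmiq,
    norm_dasen,
    norm_funnorm,
    norm_noob,
    norm_qn,
    norm_stratified_qn,
    norm_swan,
    normexp_signal,
    quantile_normalize,
)
from famnorm.qc import run_qc
from famnorm.simulate import simulate_dataset

from conftest import small_config, toy_dataset


def _type_ks(dataset):
    design = dataset.annotation.design_type.to_numpy()
    v = dataset.beta.to_numpy()
    return ks_2samp(v[design == "I"].ravel(), v[design == "II"].ravel()).statistic


# ---------------------------------------------------------------------------
# quantile normalisation kernel


class TestQuantileNormalize:
    def test_hand_oracle_two_columns(self):
        x = np.array([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]])
        out = quantile_normalize(x)
        np.testing.assert_allclose(out[:, 0], [1.5, 3.5, 5.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.5, 5.5])

    def test_identical_columns_fixed_point(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
        np.testing.assert_allclose(quantile_normalize(x), x)

    def test_tie_rule_mean_of_rank_range(self):
        # reference = mean of sorted columns: [(1+2)/2, (1+4)/2, (3+6)/2]
        x = np.array([[1.0, 2.0], [1.0, 4.0], [3.0, 6.0]])
        out = quantile_normalize(x)
        np.testing.assert_allclose(out[:, 0], [2.0, 2.0, 4.5])  # ties share mean(1.5, 2.5)
        np.testing.assert_allclose(out[:, 1], [1.5, 2.5, 4.5])

    def test_single_column_identity_with_warning(self):
        x = np.array([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single column"):
            out = quantile_normalize(x)
        np.testing.assert_allclose(out, x)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 5))
        out = quantile_normalize(x)
        for j in range(5):
            assert (np.argsort(out[:, j]) == np.argsort(x[:, j], kind="stable")).all()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 5):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-9)


def test_norm_qn_postconditions(qc_dataset):
    out = norm_qn(qc_dataset)
    meth = out.intensities.meth.to_numpy()
    sorted_cols = np.sort(meth, axis=0)
    assert np.abs(sorted_cols - sorted_cols[:, [0]]).max() < 1e-9
    assert out.provenance[-1] == "qn"
    # between-sample KS distance of intensity distributions is zero
    assert ks_2samp(meth[:, 0], meth[:, 1]).statistic < 1e-12
    assert out.beta.to_numpy().min() >= 0 and out.beta.to_numpy().max() <= 1


class TestStratifiedQN:
    def test_single_stratum_type2_only_equals_qn(self):
        rng = np.random.default_rng(3)
        meth = rng.uniform(100, 5000, size=(50, 6))
        unmeth = rng.uniform(100, 5000, size=(50, 6))
        ds = toy_dataset(meth, unmeth)
        a = norm_stratified_qn(ds)
        b = norm_qn(ds)
        np.testing.assert_allclose(
            a.intensities.meth.to_numpy(), b.intensities.meth.to_numpy(), atol=1e-9
        )

    def test_disjoint_strata_mean_difference_preserved(self):
        rng = np.random.default_rng(4)
        n = 200
        stratum = ["island"] * (n // 2) + ["open_sea"] * (n // 2)
        meth = np.vstack(
            [rng.uniform(500, 1500, size=(n // 2, 8)), rng.uniform(4000, 6000, size=(n // 2, 8))]
        )
        meth += rng.normal(0, 50, size=(8,))[None, :]  # per-sample shifts
        unmeth = meth[::-1].copy()
        ds = toy_dataset(meth, unmeth, stratum=stratum)
        out = norm_stratified_qn(ds)
        pre = meth[: n // 2].mean() - meth[n // 2 :].mean()
        post_m = out.intensities.meth.to_numpy()
        post = post_m[: n // 2].mean() - post_m[n // 2 :].mean()
        assert abs(post - pre) / abs(pre) < 0.05

    def test_type2_sorted_equality_within_stratum(self, qc_dataset):
        out = norm_stratified_qn(qc_dataset)
        ann = out.annotation
        for s in ann.region_stratum.unique():
            mask = (ann.region_stratum == s) & (ann.design_type == "II")
            sub = out.intensities.meth.loc[mask[mask].index].to_numpy()
            sorted_cols = np.sort(sub, axis=0)
            assert np.abs(sorted_cols - sorted_cols[:, [0]]).max() < 1e-9


class TestSwan:
    def test_identical_type_distributions_near_fixed_point(self):
        rng = np.random.default_rng(6)
        half = rng.uniform(200, 4000, size=(40, 4))
        meth = np.vstack([half, half])  # type I values duplicate type II exactly
        unmeth = np.vstack([half[::-1], half[::-1]])
        design = ["I"] * 40 + ["II"] * 40
        ds = toy_dataset(meth, unmeth, design=design)
        out = norm_swan(ds, seed=0)
        np.testing.assert_allclose(
            out.intensities.meth.to_numpy(), meth, atol=1e-5
        )

    def test_deterministic_in_seed(self, qc_dataset):
        a = norm_swan(qc_dataset, seed=1)
        b = norm_swan(qc_dataset, seed=1)
        c = norm_swan(qc_dataset, seed=2)
        assert a.intensities.meth.equals(b.intensities.meth)
        assert not a.intensities.meth.equals(c.intensities.meth)

    def test_reduces_type_ks_on_compressed_simulation(self, qc_dataset):
        out = norm_swan(qc_dataset, seed=0)
        assert _type_ks(out) < _type_ks(qc_dataset)


class TestBmiq:
    def test_near_fixed_point_when_types_match(self):
        # type I and II beta values drawn from the same crisp 3-state mixture
        rng = np.random.default_rng(1)
        n_half = 4000

        def draw(n):
            state = rng.choice(3, size=n, p=[0.4, 0.15, 0.45])
            vals = np.empty(n)
            vals[state == 0] = rng.beta(4, 30, (state == 0).sum())
            vals[state == 1] = rng.beta(40, 40, (state == 1).sum())
            vals[state == 2] = rng.beta(30, 4, (state == 2).sum())
            return vals

        beta_vals = np.concatenate([draw(n_half), draw(n_half)])[:, None] * np.ones((1, 3))
        ds = toy_dataset(
            np.full((2 * n_half, 3), 1000.0),
            np.full((2 * n_half, 3), 1000.0),
            design=["I"] * n_half + ["II"] * n_half,
        )
        ds = MethylDataset(
            beta=pd.DataFrame(beta_vals, index=ds.probe_ids, columns=ds.sample_ids),
            annotation=ds.annotation,
            samples=ds.samples,
        )
        out = norm_bmiq(ds)
        design = ds.annotation.design_type.to_numpy()
        change = np.abs(
            out.beta.to_numpy()[design == "II"] - ds.beta.to_numpy()[design == "II"]
        )
        assert change.mean() < 0.01

    def test_reduces_type_ks_and_stays_in_unit_interval(self, qc_dataset):
        out = norm_bmiq(qc_dataset)
        assert _type_ks(out) < _type_ks(qc_dataset)
        v = out.beta.to_numpy()
        assert v.min() >= 0 and v.max() <= 1

    def test_transform_monotone_per_sample(self, qc_dataset):
        out = norm_bmiq(qc_dataset)
        design = qc_dataset.annotation.design_type.to_numpy()
        x = qc_dataset.beta.to_numpy()[design == "II", 0]
        y = out.beta.to_numpy()[design == "II", 0]
        order = np.argsort(x)
        dy = np.diff(y[order])
        assert (dy >= -1e-6).all()

    def test_requires_both_types(self):
        ds = toy_dataset(np.random.default_rng(0).uniform(100, 2000, (20, 4)), np.full((20, 4), 500.0))
        with pytest.raises(ValueError, match="both probe types"):
            BMIQNormalizer().fit(ds)


class TestNoob:
    def test_parameter_recovery(self):
        ds, _ = simulate_dataset(
            small_config(n_probes=4000, bg_batch_sd=0.0, bg_sample_sd=0.0, n_samples=9,
                         n_replicate_pairs=2, n_families=3),
            seed=2,
        )
        fits = NoobCorrector().fit(ds).fits_
        for per_channel in fits.values():
            for f in per_channel.values():
                assert abs(f.mu - 500.0) / 500.0 < 0.10
                assert abs(f.sigma - 100.0) / 100.0 < 0.15

    def test_deconvolution_limit(self):
        # vanishing background noise, strong signal: corrected ~ x - mu
        x = np.array([5000.0, 8000.0])
        out = normexp_signal(x, mu=500.0, sigma=1e-3, theta=3000.0)
        np.testing.assert_allclose(out, x - 500.0, rtol=1e-6)

    def test_outputs_strictly_positive(self, qc_dataset):
        out = norm_noob(qc_dataset)
        assert (out.intensities.meth.to_numpy() > 0).all()
        assert (out.intensities.unmeth.to_numpy() > 0).all()

    def test_rejects_few_oob(self, qc_dataset):
        i = qc_dataset.intensities
        tiny = IntensityMatrix(
            meth=i.meth, unmeth=i.unmeth,
            oob_meth=i.oob_meth.iloc[:10], oob_unmeth=i.oob_unmeth.iloc[:10],
            controls=i.controls,
        )
        from dataclasses import replace

        ds = replace(qc_dataset, intensities=tiny)
        with pytest.raises(ValueError, match="out-of-band"):
            NoobCorrector().fit(ds)


class TestDasen:
    def test_single_type_equal_background_reduces_to_qn(self):
        rng = np.random.default_rng(8)
        meth = rng.uniform(100, 4000, (60, 5))
        unmeth = rng.uniform(100, 4000, (60, 5))
        ds = toy_dataset(meth, unmeth)  # all type II
        a = norm_dasen(ds)
        b = norm_qn(ds)
        np.testing.assert_allclose(
            a.intensities.meth.to_numpy(), b.intensities.meth.to_numpy(), atol=1e-9
        )

    def test_planted_type1_offset_realigned(self, qc_dataset):
        from famnorm.transforms import beta_from_intensities

        i = qc_dataset.intensities
        design = qc_dataset.annotation.design_type.to_numpy()
        meth = i.meth.copy()
        unmeth = i.unmeth.copy()
        meth.iloc[design == "I", :] += 300.0
        unmeth.iloc[design == "I", :] += 300.0
        shifted_i = IntensityMatrix(meth=meth, unmeth=unmeth, oob_meth=i.oob_meth,
                                    oob_unmeth=i.oob_unmeth, controls=i.controls)
        shifted = MethylDataset(
            beta=beta_from_intensities(shifted_i).beta,
            annotation=qc_dataset.annotation, samples=qc_dataset.samples,
            intensities=shifted_i,
        )
        out = norm_dasen(shifted)
        residual = DasenNormalizer().fit(out).background_shift_
        assert np.abs(residual["meth"]).max() < 50.0
        assert np.abs(residual["unmeth"]).max() < 50.0

    def test_sorted_equality_within_probe_type(self, qc_dataset):
        out = norm_dasen(qc_dataset)
        design = out.annotation.design_type.to_numpy()
        for mask in (design == "I", design == "II"):
            sub = out.intensities.meth.to_numpy()[mask]
            sorted_cols = np.sort(sub, axis=0)
            assert np.abs(sorted_cols - sorted_cols[:, [0]]).max() < 1e-9


class TestFunnorm:
    def test_zero_pcs_is_identity(self, qc_dataset):
        out = norm_funnorm(qc_dataset, n_pcs=0)
        np.testing.assert_allclose(
            out.intensities.meth.to_numpy(), qc_dataset.intensities.meth.to_numpy()
        )

    def test_control_driven_variation_removed(self, qc_dataset):
        # plant per-sample intensity shifts that the negative controls track
        from dataclasses import replace

        rng = np.random.default_rng(15)
        i = qc_dataset.intensities
        shifts = rng.normal(0, 150, size=len(i.sample_ids))
        controls = i.controls.copy()
        controls.loc["negative"] = (controls.loc["negative"] + shifts[None, :]).clip(lower=0).to_numpy()
        planted_i = IntensityMatrix(
            meth=(i.meth + shifts[None, :]).clip(lower=0),
            unmeth=(i.unmeth + shifts[None, :]).clip(lower=0),
            oob_meth=i.oob_meth,
            oob_unmeth=i.oob_unmeth,
            controls=controls,
        )
        planted = replace(qc_dataset, intensities=planted_i)
        out = norm_funnorm(planted)

        def midq_var(d):
            v = d.intensities.meth.to_numpy()
            return np.var(np.quantile(v, 0.5, axis=0))

        assert midq_var(out) < 0.5 * midq_var(planted)

    def test_rejects_constant_controls(self, qc_dataset):
        from dataclasses import replace

        i = qc_dataset.intensities
        const = i.controls.copy()
        const.iloc[:, :] = 100.0
        flat = IntensityMatrix(meth=i.meth, unmeth=i.unmeth, oob_meth=None,
                               oob_unmeth=None, controls=const)
        ds = replace(qc_dataset, intensities=flat)
        with pytest.raises(ValueError, match="constant"):
            FunnormNormalizer().fit(ds)


class TestCombat:
    def _toy(self, seed=0, n=120, s=12):
        rng = np.random.default_rng(seed)
        batch = np.array([f"B{j % 3}" for j in range(s)])
        gamma = rng.normal(0, 1, (n, 3))
        X = rng.normal(0, 0.5, (n, s)) + gamma[:, [int(b[1]) for b in batch]]
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(n)], columns=[f"s{j}" for j in range(s)])
        return df, batch

    def test_single_batch_identity_with_warning(self):
        df, _ = self._toy()
        with pytest.warns(UserWarning, match="single batch"):
            adj, fit = combat(df, ["B1"] * df.shape[1])
        np.testing.assert_allclose(adj.m.to_numpy(), df.to_numpy(), atol=1e-6)

    def test_singleton_batch_rejected(self):
        df, _ = self._toy(s=5)
        with pytest.raises(ValueError, match="single sample"):
            combat(df, ["A", "A", "B", "B", "C"])

    def test_batch_location_recovery(self):
        rng = np.random.default_rng(3)
        n, s = 500, 50
        batch = np.array([f"B{j % 3}" for j in range(s)])
        gamma = rng.normal(0, 1, (n, 3))
        X = rng.normal(0, 0.5, (n, s)) + gamma[:, [int(b[1]) for b in batch]]
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(n)], columns=[f"s{j}" for j in range(s)])
        pre = np.concatenate(
            [X[:, batch == b].mean(axis=1) - X.mean(axis=1) for b in np.unique(batch)]
        )
        adj, fit = combat(df, batch)
        A = adj.m.to_numpy()
        post = np.concatenate(
            [A[:, batch == b].mean(axis=1) - A.mean(axis=1) for b in np.unique(batch)]
        )
        assert pre.std() > 0.5
        assert post.std() < 0.15
        assert (fit.delta_star.to_numpy() > 0).all()

    def test_grand_mean_preserved_without_shrinkage(self):
        df, batch = self._toy(seed=5)
        est = ComBat(parametric=False).fit(df, batch)
        adj = est.transform(df, batch)
        counts = pd.Series(batch).value_counts()
        weighted = sum(
            adj.loc[:, batch == b].mean(axis=1) * (counts[b] / len(batch)) for b in counts.index
        )
        orig = sum(
            df.loc[:, batch == b].mean(axis=1) * (counts[b] / len(batch)) for b in counts.index
        )
        np.testing.assert_allclose(weighted.to_numpy(), orig.to_numpy(), atol=1e-6)

    def test_grand_mean_approximately_preserved_with_shrinkage(self):
        df, batch = self._toy(seed=6)
        adj, _ = combat(df, batch)
        shift = (adj.m.mean(axis=1) - df.mean(axis=1)).abs().mean()
        assert shift < 0.1 * df.to_numpy().std()

    def test_matches_r_sva_reference(self, tmp_path):
        """Dual-route check against the Bioconductor sva implementation."""
        df, batch = self._toy(seed=42, n=80, s=12)
        df.to_csv(tmp_path / "in.tsv", sep="\t")
        (tmp_path / "batch.txt").write_text("\n".join(batch) + "\n")
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            'X <- as.matrix(read.delim("in.tsv", row.names=1))\n'
            'batch <- readLines("batch.txt")\n'
            'out <- ComBat(dat=X, batch=batch, mod=NULL, par.prior=TRUE)\n'
            'write.table(out, "out.tsv", sep="\\t", quote=FALSE)\n'
        )
        proc = subprocess.run(
            ["Rscript", "combat.R"], cwd=tmp_path, capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        ours, _ = combat(df, batch)
        np.testing.assert_allclose(ours.m.to_numpy(), ref.to_numpy(), atol=1e-4)


def test_every_method_yields_valid_dataset(qc_dataset):
    methods = {
        "qn": norm_qn,
        "stratified_qn": norm_stratified_qn,
        "swan": lambda d: norm_swan(d, seed=0),
        "bmiq": norm_bmiq,
        "noob": norm_noob,
        "dasen": norm_dasen,
        "funnorm": norm_funnorm,
    }
    for name, fn in methods.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = fn(qc_dataset)
        v = out.beta.to_numpy()
        assert np.isfinite(v).all(), name
        assert v.min() >= 0 and v.max() <= 1, name
        assert np.isfinite(out.mvalues().to_numpy()).all(), name
        assert out.provenance[-1].startswith(name.split("_")[0]) or name in out.provenance[-1], name
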