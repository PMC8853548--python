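import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mbnoise import (
    BatchDesign,
    FeatureTableError,
    SampleMetadata,
    bmc,
    clr_transform,
    combat,
    dcc,
    fit_pca,
    linear_batch_removal,
    pca_correct_fixed,
    pca_correct_tuned,
    percentile_normalize,
    to_relative_abundance,
)

from conftest import make_table


def meta_from(columns, sample_ids, types, phenotype=None, batch=None):
    return SampleMetadata(
        data=pd.DataFrame(columns, index=sample_ids),
        column_types=types,
        phenotype_col=phenotype,
        batch_col=batch,
    )


class TestBMC:
    def test_hand_example(self):
        t = make_table([[1.0], [3.0], [10.0], [20.0]])
        design = BatchDesign.from_labels(["A", "A", "B", "B"])
        out = bmc(t, design).corrected.values.ravel()
        np.testing.assert_allclose(out, [-1, 1, -5, 5])

    def test_within_batch_means_are_zero(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(size=(30, 8)))
        labels = rng.choice(["A", "B", "C"], size=30)
        out = bmc(t, BatchDesign.from_labels(labels)).corrected.values
        for lv in "ABC":
            assert np.abs(out[labels == lv].mean(axis=0)).max() < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.normal(size=(12, 4)))
        design = BatchDesign.from_labels(["A"] * 6 + ["B"] * 6)
        once = bmc(t, design).corrected
        twice = bmc(once, design).corrected
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_single_batch_requires_flag(self):
        with pytest.raises(FeatureTableError):
            BatchDesign.from_labels(["A", "A", "A"])
        design = BatchDesign.from_labels(["A", "A", "A"], allow_single_batch=True)
        t = make_table([[1.0], [2.0], [3.0]])
        out = bmc(t, design).corrected.values
        np.testing.assert_allclose(out.ravel(), [-1, 0, 1])


class TestDCC:
    def test_equals_bmc_on_50_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(8, 20))
            f = int(rng.integers(2, 10))
            vals = rng.normal(size=(n, f))
            labels = rng.choice(["A", "B", "C"][: int(rng.integers(2, 4))], size=n)
            while len(np.unique(labels)) < 2:
                labels = rng.choice(["A", "B"], size=n)
            t = make_table(vals)
            meta = meta_from({"batch": labels}, t.sample_ids, {"batch": "categorical"})
            a = dcc(t, meta, ["batch"]).corrected.values
            b = bmc(t, BatchDesign.from_labels(labels)).corrected.values
            assert np.abs(a - b).max() < 1e-9

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(8)
        t = make_table(rng.normal(size=(20, 5)))
        meta = meta_from(
            {"g": rng.choice(["x", "y"], 20), "age": rng.normal(size=20)},
            t.sample_ids, {"g": "categorical", "age": "continuous"},
        )
        res = dcc(t, meta, ["g", "age"])
        design = np.column_stack([
            np.ones(20),
            (meta.data["g"] == meta.data["g"].iloc[0]).to_numpy(float),
            meta.data["age"].to_numpy(),
        ])
        assert np.abs(design.T @ res.corrected.values).max() < 1e-8

    def test_orthogonal_covariate_returns_mean_centered(self):
        # 6-sample toy: covariate explicitly orthogonalized against the
        # centered feature, so OLS fits a zero slope and leaves centering
        feature = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        fc = feature - feature.mean()
        cov = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        cov = cov - cov.mean()
        cov = cov - (cov @ fc) / (fc @ fc) * fc
        t = make_table(feature[:, None])
        meta = meta_from({"c": cov}, t.sample_ids, {"c": "continuous"})
        out = dcc(t, meta, ["c"]).corrected.values.ravel()
        np.testing.assert_allclose(out, fc, atol=1e-9)

    def test_constant_feature_residual_zero(self):
        t = make_table(np.full((8, 1), 3.14))
        meta = meta_from({"b": ["A"] * 4 + ["B"] * 4}, t.sample_ids, {"b": "categorical"})
        out = dcc(t, meta, ["b"]).corrected.values
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_rank_deficient_design_lists_aliased(self):
        t = make_table(np.random.default_rng(0).normal(size=(8, 2)))
        meta = meta_from(
            {"b": ["A"] * 4 + ["B"] * 4, "b2": ["A"] * 4 + ["B"] * 4},
            t.sample_ids, {"b": "categorical", "b2": "categorical"},
        )
        with pytest.raises(FeatureTableError, match="aliased"):
            dcc(t, meta, ["b", "b2"])


class TestLinearBatchRemoval:
    def test_protect_none_equals_dcc(self):
        rng = np.random.default_rng(9)
        t = make_table(rng.normal(size=(16, 6)))
        labels = ["A"] * 8 + ["B"] * 8
        meta = meta_from({"batch": labels}, t.sample_ids, {"batch": "categorical"})
        a = linear_batch_removal(t, BatchDesign.from_labels(labels)).corrected.values
        b = dcc(t, meta, ["batch"]).corrected.values
        assert np.abs(a - b).max() < 1e-9

    def test_planted_offset_removed(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(40, 20))
        vals[20:] += 2.0
        labels = ["A"] * 20 + ["B"] * 20
        out = linear_batch_removal(
            make_table(vals), BatchDesign.from_labels(labels)
        ).corrected.values
        gap = np.abs(out[:20].mean(axis=0) - out[20:].mean(axis=0))
        assert gap.max() < 1e-9

    def test_phenotype_confounded_with_batch_errors(self):
        t = make_table(np.random.default_rng(1).normal(size=(10, 3)))
        labels = ["A"] * 5 + ["B"] * 5
        meta = meta_from(
            {"pheno": ["case"] * 5 + ["ctrl"] * 5}, t.sample_ids,
            {"pheno": "categorical"},
        )
        with pytest.raises(FeatureTableError, match="aliased"):
            linear_batch_removal(t, BatchDesign.from_labels(labels), meta, protect="pheno")

    def test_protected_phenotype_signal_survives(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(40, 10))
        pheno = np.tile(["case", "ctrl"], 20)
        vals[pheno == "case"] += 1.5        # phenotype effect
        vals[20:] += 3.0                    # batch offset
        labels = ["A"] * 20 + ["B"] * 20
        t = make_table(vals)
        meta = meta_from({"pheno": pheno}, t.sample_ids, {"pheno": "categorical"})
        out = linear_batch_removal(
            t, BatchDesign.from_labels(labels), meta, protect="pheno"
        ).corrected.values
        pheno_gap = out[pheno == "case"].mean() - out[pheno == "ctrl"].mean()
        batch_gap = abs(out[:20].mean() - out[20:].mean())
        assert pheno_gap > 1.0 and batch_gap < 0.2


class TestComBat:
    def _shifted_table(self, seed=3):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, (40, 50))
        vals[20:] += 3.0
        return make_table(vals), BatchDesign.from_labels(["A"] * 20 + ["B"] * 20)

    def test_identical_batches_identity(self):
        rng = np.random.default_rng(4)
        block = rng.normal(size=(15, 20))
        t = make_table(np.vstack([block, block]))
        design = BatchDesign.from_labels(["A"] * 15 + ["B"] * 15)
        out = combat(t, design).corrected.values
        assert np.abs(out - t.values).max() < 1e-8

    def test_location_shift_removed(self):
        t, design = self._shifted_table()
        out = combat(t, design).corrected.values
        before = np.abs(t.values[:20].mean(0) - t.values[20:].mean(0)).mean()
        after = np.abs(out[:20].mean(0) - out[20:].mean(0)).mean()
        assert after <= 0.1 * before

    def test_single_feature_degenerates_to_own_estimates(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(30, 1))
        vals[15:] += 2.0
        design = BatchDesign.from_labels(["A"] * 15 + ["B"] * 15)
        out = combat(make_table(vals), design).corrected.values
        assert abs(out[:15].mean() - out[15:].mean()) < 1e-6

    def test_small_batch_rejected(self):
        t = make_table(np.random.default_rng(0).normal(size=(5, 4)))
        design = BatchDesign.from_labels(["A", "A", "A", "B", "B"])
        with pytest.raises(FeatureTableError, match=">= 3"):
            combat(t, design)

    def test_matches_sva_combat_oracle(self, tmp_path):
        """Cross-check against Bioconductor sva::ComBat on a 100x30 fixture.

        sva estimates per-batch scales with the n-1 divisor whereas this
        implementation matches the pooled-variance divisor (n), so exact
        agreement is not expected; algorithmic errors would produce O(1)
        deviations, far above the asserted band.
        """
        rng = np.random.default_rng(42)
        vals = rng.normal(0, 1, (100, 30)) * rng.uniform(0.5, 2, 30)
        vals[50:] += rng.normal(1.0, 0.5, 30)
        vals[50:] *= rng.uniform(0.8, 1.5, 30)
        t = make_table(vals)
        out = combat(t, BatchDesign.from_labels(["A"] * 50 + ["B"] * 50)).corrected.values
        in_csv, r_csv = tmp_path / "in.csv", tmp_path / "out.csv"
        pd.DataFrame(vals).to_csv(in_csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- t(as.matrix(read.csv('{in_csv}')))
            out <- ComBat(dat=x, batch=c(rep('A',50), rep('B',50)))
            write.csv(t(out), '{r_csv}', row.names=FALSE)
        """)
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(r_csv).to_numpy()
        assert np.abs(out - ref).max() < 0.06
        assert np.corrcoef(out.ravel(), ref.ravel())[0, 1] > 0.9999


class TestPercentileNormalize:
    def test_hand_examples(self):
        # batch controls [1,2,3,4]; case value 2.5 -> 50; control value 2 -> 37.5
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [2.5]])
        design = BatchDesign.from_labels(["A"] * 5, allow_single_batch=True)
        ctrl = np.array([True, True, True, True, False])
        out = percentile_normalize(make_table(vals), design, ctrl).corrected.values.ravel()
        np.testing.assert_allclose(out, [12.5, 37.5, 62.5, 87.5, 50.0])

    def test_all_equal_controls_give_midrank_50(self):
        vals = np.array([[2.0], [2.0], [2.0], [2.0]])
        design = BatchDesign.from_labels(["A"] * 4, allow_single_batch=True)
        ctrl = np.array([True, True, True, False])
        out = percentile_normalize(make_table(vals), design, ctrl).corrected.values
        assert out[3, 0] == pytest.approx(50.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(20, 5))
        labels = ["A"] * 10 + ["B"] * 10
        ctrl = np.tile([True, False], 10)
        design = BatchDesign.from_labels(labels)
        a = percentile_normalize(make_table(vals), design, ctrl).corrected.values
        b = percentile_normalize(make_table(np.exp(vals)), design, ctrl).corrected.values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_batch_without_controls_errors(self):
        vals = np.zeros((4, 2))
        design = BatchDesign.from_labels(["A", "A", "B", "B"])
        with pytest.raises(FeatureTableError, match="no control"):
            percentile_normalize(make_table(vals), design, [True, False, False, False])


class TestPCA:
    def test_loadings_orthonormal_and_fractions_ordered(self):
        rng = np.random.default_rng(12)
        t = make_table(rng.normal(size=(30, 10)))
        model = fit_pca(t, 6)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(6), atol=1e-8)
        assert np.all(np.diff(model.variance_fraction) <= 1e-12)
        assert model.variance_fraction.sum() <= 1 + 1e-8

    def test_rank_one_data(self):
        direction = np.array([1.0, 2.0, -1.0])
        scores = np.linspace(-2, 2, 8)
        t = make_table(np.outer(scores, direction) + 5.0)
        model = fit_pca(t, 2)
        assert model.variance_fraction[0] == pytest.approx(1.0)
        assert model.variance_fraction[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_fractions_sum_to_one(self):
        rng = np.random.default_rng(13)
        t = make_table(rng.normal(size=(9, 5)))
        model = fit_pca(t, 5)
        assert model.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(14)
        row = rng.normal(size=5)
        vals = np.vstack([row, row, rng.normal(size=(6, 5))])
        model = fit_pca(make_table(vals), 3)
        np.testing.assert_allclose(model.scores[0], model.scores[1], atol=1e-10)


class TestPCACorrection:
    def test_p_zero_is_identity(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(size=(10, 6))
        vals -= vals.mean(axis=1, keepdims=True)
        t = make_table(vals, space="clr")
        out = pca_correct_fixed(t, 0).corrected
        np.testing.assert_allclose(out.values, t.values, atol=1e-12)

    def test_rank_one_collapses_to_feature_means(self):
        direction = np.array([1.0, -1.0, 0.0])
        scores = np.linspace(-1, 1, 6)
        vals = np.outer(scores, direction)
        t = make_table(vals, space="clr")
        out = pca_correct_fixed(t, 1).corrected
        np.testing.assert_allclose(out.values, np.tile(vals.mean(0), (6, 1)), atol=1e-10)

    def test_removed_loadings_orthogonal_and_variance_removed(self):
        rng = np.random.default_rng(16)
        vals = rng.normal(size=(20, 10))
        vals -= vals.mean(axis=1, keepdims=True)
        t = make_table(vals, space="clr")
        res = pca_correct_fixed(t, 3)
        model = res.removed_components
        centered = res.corrected.values - model.feature_means
        proj = centered @ model.loadings[:, :3]
        assert np.abs(proj).max() < 1e-8
        total = ((t.values - t.values.mean(0)) ** 2).sum()
        removed = total * model.variance_fraction[:3].sum()
        remaining = (centered**2).sum()
        assert abs((total - remaining) - removed) / total < 1e-8


class TestTunedPCA:
    def _clr_table(self, rng, n, f, prefix=("s", "f")):
        vals = rng.normal(size=(n, f))
        vals -= vals.mean(axis=1, keepdims=True)
        return make_table(vals, space="clr", prefix=prefix)

    def test_tie_break_picks_smallest_p(self):
        class ConstantClassifier:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                return self

            def predict_proba(self, X):
                return np.tile([0.5, 0.5], (len(X), 1))

        rng = np.random.default_rng(17)
        train = self._clr_table(rng, 30, 10)
        val = self._clr_table(rng, 10, 10, prefix=("v", "f"))
        pheno = ["case", "ctrl"] * 15 + ["case", "ctrl"] * 5
        meta = meta_from(
            {"phenotype": pheno}, train.sample_ids + val.sample_ids,
            {"phenotype": "categorical"}, phenotype="phenotype",
        )
        res = pca_correct_tuned(train, val, meta, p_grid=[2, 3, 5],
                                estimator=ConstantClassifier())
        assert res.chosen_p == 2
        assert len(set(res.metrics.values())) == 1

    def test_chosen_p_attains_max_metric(self):
        rng = np.random.default_rng(18)
        train = self._clr_table(rng, 40, 12)
        val = self._clr_table(rng, 16, 12, prefix=("v", "f"))
        pheno = list(np.where(np.arange(56) % 2 == 0, "case", "ctrl"))
        meta = meta_from(
            {"phenotype": pheno}, train.sample_ids + val.sample_ids,
            {"phenotype": "categorical"}, phenotype="phenotype",
        )
        res = pca_correct_tuned(train, val, meta, p_grid=[1, 2, 4], random_state=0)
        assert res.metrics[res.chosen_p] == max(res.metrics.values())

    def test_overlapping_samples_rejected(self):
        rng = np.random.default_rng(19)
        t = self._clr_table(rng, 10, 5)
        meta = meta_from({"phenotype": ["a", "b"] * 5}, t.sample_ids,
                         {"phenotype": "categorical"}, phenotype="phenotype")
        with pytest.raises(FeatureTableError, match="overlap"):
            pca_correct_tuned(t, t, meta)


class TestBackTransform:
    def test_log_space_hand_example(self):
        t = make_table([[0.0, np.log(3.0)]], space="log")
        out = to_relative_abundance(t)
        np.testing.assert_allclose(out.values, [[0.25, 0.75]], atol=1e-12)

    def test_clr_roundtrip_recovers_composition(self):
        rng = np.random.default_rng(20)
        comp = rng.dirichlet(np.ones(8), size=10)
        clr = clr_transform(make_table(comp, space="relative"))
        out = to_relative_abundance(clr)
        np.testing.assert_allclose(out.values, comp, atol=1e-12)

    def test_generic_without_declared_transform_errors(self):
        t = make_table([[1.0, 2.0]])
        with pytest.raises(FeatureTableError, match="back-transform"):
            to_relative_abundance(t)
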