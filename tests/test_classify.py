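import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import mxraman as mx
from mxraman.errors import (
    InvalidConfigError,
    InvalidInputError,
    SchemaError,
)


def _gaussian_dataset(n_per_class=100, delta=10.0, n_vars=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_vars))
    b = rng.normal(delta, 1.0, size=(n_per_class, n_vars))
    matrix = np.vstack([a, b])
    n = 2 * n_per_class
    row_meta = pd.DataFrame(
        {
            "class_label": ["a"] * n_per_class + ["b"] * n_per_class,
            "sample_id": [f"s{i}" for i in range(n)],
            "acquisition_index": [0] * n,
        }
    )
    col_meta = pd.DataFrame(
        {"channel": ["c"] * n_vars, "wavenumber": np.arange(n_vars, dtype=float)}
    )
    return mx.SpectralDataset(matrix, row_meta, col_meta)


class TestMakeSplits:
    def test_paper_counts(self, small_study):
        # reduced fixture: 15 samples x 6 spectra -> 45 test / 45 train
        d = small_study["mx"].dataset
        splits = mx.make_splits(d)
        assert len(splits.repeats) == 3
        for train, test in splits.repeats:
            assert len(test) == 45
            assert len(train) == d.n_spectra - 45

    def test_positions_first_middle_final(self):
        rows = []
        for a in range(10):
            rows.append(np.full(4, float(a)))
        d = mx.SpectralDataset(
            np.vstack(rows),
            pd.DataFrame(
                {
                    "class_label": ["x"] * 10,
                    "sample_id": ["s"] * 10,
                    "acquisition_index": list(range(10)),
                }
            ),
            pd.DataFrame(
                {"channel": ["c"] * 4, "wavenumber": np.arange(4.0)}
            ),
        )
        splits = mx.make_splits(d)
        tests = [sorted(d.row_meta["acquisition_index"].to_numpy()[t]) for _, t in splits.repeats]
        assert tests[0] == [0, 1, 2]
        assert tests[1] == [4, 5, 6]  # m=10: positions m//2-1..m//2+1
        assert tests[2] == [7, 8, 9]

    def test_partition_property(self, small_study):
        d = small_study["mx"].dataset
        for train, test in mx.make_splits(d).repeats:
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == d.n_spectra

    def test_unequal_counts_rejected(self, small_study):
        d = small_study["mx"].dataset.subset_rows(range(d0 := small_study["mx"].dataset.n_spectra - 1))
        with pytest.raises(InvalidInputError):
            mx.make_splits(d)

    def test_m_equal_3_rejected(self):
        d = mx.SpectralDataset(
            np.ones((3, 4)),
            pd.DataFrame(
                {
                    "class_label": ["x"] * 3,
                    "sample_id": ["s"] * 3,
                    "acquisition_index": [0, 1, 2],
                }
            ),
            pd.DataFrame({"channel": ["c"] * 4, "wavenumber": np.arange(4.0)}),
        )
        with pytest.raises(InvalidConfigError):
            mx.make_splits(d)


class TestLDA:
    def test_separable_classes_perfect_cv(self):
        d = _gaussian_dataset(delta=10.0)
        model, cv = mx.train_lda(d, folds=5, seed=1)
        assert cv.overall_accuracy == 100.0
        assert all(v == 100.0 for v in cv.per_class_accuracy.values())

    def test_shuffled_labels_near_chance(self):
        d = _gaussian_dataset(delta=10.0, seed=2)
        rng = np.random.default_rng(3)
        d.row_meta = d.row_meta.assign(class_label=rng.permutation(d.labels))
        _, cv = mx.train_lda(d, folds=5, seed=4)
        # binomial null: 200 predictions at p=1/2
        sd = 100.0 * np.sqrt(0.25 / 200)
        assert abs(cv.overall_accuracy - 50.0) < 3 * sd + 1e-9

    def test_matches_sklearn_on_full_rank_problem(self):
        d = _gaussian_dataset(n_per_class=60, delta=1.0, n_vars=4, seed=5)
        model = mx.LDAModel().fit(d.matrix, d.labels)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(d.matrix, d.labels)
        rng = np.random.default_rng(6)
        x = rng.normal(0.5, 2.0, size=(200, 4))
        assert np.array_equal(model.predict(x), ref.predict(x))

    def test_pseudo_inverse_regime_runs(self):
        # p >> n: pooled covariance singular, pseudo-inverse behavior
        d = _gaussian_dataset(n_per_class=10, delta=4.0, n_vars=100, seed=7)
        model, cv = mx.train_lda(d, folds=5, seed=8)
        assert cv.overall_accuracy > 90.0

    def test_duplicated_block_same_predictions(self):
        d = _gaussian_dataset(n_per_class=30, delta=1.0, n_vars=6, seed=9)
        dup = d.copy()
        dup.matrix = np.hstack([d.matrix, d.matrix])
        dup.col_meta = pd.concat([d.col_meta] * 2, ignore_index=True)
        m1 = mx.LDAModel().fit(d.matrix, d.labels)
        m2 = mx.LDAModel().fit(dup.matrix, dup.labels)
        rng = np.random.default_rng(10)
        x = rng.normal(0.5, 1.0, size=(100, 6))
        assert np.array_equal(m1.predict(x), m2.predict(np.hstack([x, x])))

    def test_small_class_rejected(self):
        d = _gaussian_dataset(n_per_class=3)
        with pytest.raises(InvalidConfigError):
            mx.train_lda(d, folds=5)


class TestEvaluate:
    def test_perfect_model_diagonal_confusion(self):
        d = _gaussian_dataset(delta=10.0, seed=11)
        model, _ = mx.train_lda(d, folds=5, seed=1)
        acc, conf = mx.evaluate(model, d)
        assert all(v == 100.0 for v in acc.values())
        assert conf.to_numpy().trace() == d.n_spectra

    def test_confusion_rows_sum_to_test_counts(self, small_study):
        d = small_study["mx"].dataset
        splits = mx.make_splits(d)
        train_idx, test_idx = splits.repeats[0]
        train, test = d.subset_rows(train_idx), d.subset_rows(test_idx)
        model, _ = mx.train_lda(train, seed=0)
        acc, conf = mx.evaluate(model, test)
        counts = test.row_meta.groupby("class_label").size()
        for cls in counts.index:
            assert conf.loc[cls].sum() == counts[cls] == 9  # 3 samples x 3 spectra

    def test_column_map_mismatch_rejected(self, small_study):
        d = small_study["mx"].dataset
        model, _ = mx.train_lda(d, seed=0)
        other = d.select_columns(range(d.n_variables - 1))
        with pytest.raises(SchemaError):
            mx.evaluate(model, other)


class TestProtocol:
    def test_identical_configs_identical_reports(self, small_study):
        fp1 = small_study["fingerprints"]["532nm"]
        rep = mx.run_protocol({"a": fp1, "b": fp1.copy()}, seed=5)
        assert rep.per_config["a"]["values"] == rep.per_config["b"]["values"]
        assert rep.comparisons["omnibus_p"] == 1.0

    def test_fifteen_values_per_config(self, small_study):
        fp1 = small_study["fingerprints"]["532nm"]
        rep = mx.run_protocol({"a": fp1}, seed=5)
        assert len(rep.per_config["a"]["values"]) == 15  # 5 classes x 3 repeats

    def test_determinism_under_seed(self, small_study):
        fp1 = small_study["fingerprints"]["532nm"]
        r1 = mx.run_protocol({"a": fp1}, seed=7)
        r2 = mx.run_protocol({"a": fp1}, seed=7)
        assert r1.per_config["a"]["values"] == r2.per_config["a"]["values"]

    def test_comparison_note_preserved(self, small_study):
        fp1 = small_study["fingerprints"]["532nm"]
        rep = mx.run_protocol({"a": fp1}, seed=1)
        assert "configuration comparison" in rep.note
        assert "configuration comparison" in rep.to_dict()["note"]


class TestCompareConfigs:
    def test_identical_sets_h_zero(self):
        sets = {"a": [80.0] * 15, "b": [80.0] * 15}
        out = mx.compare_configs(sets)
        assert out["omnibus_H"] == 0.0
        assert out["omnibus_p"] == 1.0

    def test_disjoint_sets_strongly_significant(self):
        rng = np.random.default_rng(12)
        lo = list(rng.uniform(10, 20, 15))
        hi = list(rng.uniform(80, 90, 15))
        out = mx.compare_configs({"lo": lo, "hi": hi})
        assert out["pairwise"][("lo", "hi")]["p_raw"] < 0.001

    def test_pairwise_matches_rank_sum_oracle(self):
        # Dunn z-test on two groups reduces to the normal rank-sum test
        rng = np.random.default_rng(13)
        a = list(rng.normal(50, 5, 15))
        b = list(rng.normal(60, 5, 15))
        out = mx.compare_configs({"a": a, "b": b})
        z_exp = stats.norm.isf(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False).pvalue / 2
        )
        assert abs(out["pairwise"][("a", "b")]["z"]) == pytest.approx(z_exp, rel=1e-6)

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(14)
        sets = {k: list(rng.normal(50, 5, 15)) for k in "abcd"}
        out = mx.compare_configs(sets)
        n_pairs = 6
        for rec in out["pairwise"].values():
            assert rec["p_bonferroni"] == pytest.approx(
                min(1.0, rec["p_raw"] * n_pairs)
            )

    def test_unequal_sizes_rejected(self):
        with pytest.raises(InvalidInputError):
            mx.compare_configs({"a": [1.0] * 15, "b": [1.0] * 14})
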