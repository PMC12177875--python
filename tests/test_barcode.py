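import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mxraman as mx
from mxraman.errors import InvalidConfigError, LabelError, MappingError


def brute_force_utest(x, y):
    """Exhaustive permutation oracle: two-sided rank-sum p with midranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    na = len(x)
    u_obs = float(np.sum(ranks[:na]) - na * (na + 1) / 2.0)
    u_all = []
    for comb in itertools.combinations(range(len(pooled)), na):
        u_all.append(float(np.sum(ranks[list(comb)]) - na * (na + 1) / 2.0))
    u_all = np.asarray(u_all)
    p_hi = np.mean(u_all >= u_obs - 1e-12)
    p_lo = np.mean(u_all <= u_obs + 1e-12)
    return u_obs, min(1.0, 2.0 * min(p_hi, p_lo))


def _two_class_dataset(a_rows, b_rows):
    a_rows = np.atleast_2d(np.asarray(a_rows, dtype=float))
    b_rows = np.atleast_2d(np.asarray(b_rows, dtype=float))
    matrix = np.vstack([a_rows, b_rows])
    n_a, n_b = a_rows.shape[0], b_rows.shape[0]
    v = matrix.shape[1]
    row_meta = pd.DataFrame(
        {
            "class_label": ["A"] * n_a + ["B"] * n_b,
            "sample_id": [f"A{i}" for i in range(n_a)]
            + [f"B{i}" for i in range(n_b)],
            "acquisition_index": [0] * (n_a + n_b),
        }
    )
    col_meta = pd.DataFrame(
        {"channel": ["c"] * v, "wavenumber": np.arange(v, dtype=float)}
    )
    return mx.SpectralDataset(matrix, row_meta, col_meta)


class TestRankUTest:
    def test_matches_exact_oracle_small_groups(self):
        rng = np.random.default_rng(0)
        for trial in range(8):
            na, nb = rng.integers(3, 9, size=2)
            a = rng.normal(0, 1, size=(na, 3))
            b = rng.normal(0.8, 1, size=(nb, 3))
            if trial % 2:  # force ties in half the trials
                a = np.round(a)
                b = np.round(b)
            d = _two_class_dataset(a, b)
            r = mx.rank_utest(d, "A", "B")
            for j in range(3):
                u_exp, p_exp = brute_force_utest(a[:, j], b[:, j])
                assert r.p[j] == pytest.approx(p_exp, abs=1e-9)

    def test_complete_separation_column_ranks_first(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(10, 4))
        b = rng.normal(0, 1, size=(10, 4))
        a[:, 2] = 0.0
        b[:, 2] = 1.0
        d = _two_class_dataset(a, b)
        r = mx.rank_utest(d, "A", "B")
        _, p_exp = brute_force_utest(a[:, 2], b[:, 2])
        assert r.p[2] == pytest.approx(p_exp, abs=1e-9)
        assert r.rank[2] == 1

    def test_identical_distributions_give_p_one(self):
        a = np.tile(np.arange(6.0), (5, 1))
        d = _two_class_dataset(a, a)
        r = mx.rank_utest(d, "A", "B")
        assert np.all(r.p == 1.0)

    def test_direction_is_sign_of_median_difference(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(12, 5))
        b = rng.normal(0, 1, size=(12, 5)) + np.array([2, -2, 0, 1, -1])
        d = _two_class_dataset(a, b)
        r = mx.rank_utest(d, "A", "B")
        expected = np.sign(np.median(b, axis=0) - np.median(a, axis=0))
        assert np.array_equal(r.direction, expected.astype(int))

    def test_rank_is_permutation(self, small_study):
        d = small_study["mx"].dataset
        r = mx.rank_utest(d, "control", "diseaseA")
        assert sorted(r.rank) == list(range(1, d.n_variables + 1))
        assert np.all((r.p >= 0) & (r.p <= 1))

    def test_missing_class_rejected(self, tiny_dataset):
        with pytest.raises(LabelError):
            mx.rank_utest(tiny_dataset, "control", "nope")


class TestSelectRegions:
    def _ranked_dataset(self, p_values, top_order):
        v = len(p_values)
        d = _two_class_dataset(np.zeros((3, v)), np.ones((3, v)))
        rank = np.empty(v, dtype=int)
        rank[np.asarray(top_order)] = np.arange(1, v + 1)
        r = mx.FeatureRanking(
            class_a="A",
            class_b="B",
            u=np.zeros(v),
            p=np.asarray(p_values, dtype=float),
            median_diff=np.ones(v),
            direction=np.ones(v, dtype=int),
            rank=rank,
        )
        return r, d

    def test_enumerated_runs(self):
        # significance mask [0,1,1,1,0,1,0]: runs [1..3] and [5..5]
        p = np.array([0.5, 0.01, 0.02, 0.03, 0.5, 0.04, 0.5])
        r, d = self._ranked_dataset(p, top_order=[2, 5, 1, 3, 0, 4, 6])
        regions = mx.select_regions(r, d, n_regions=3)
        assert [(g.start, g.end) for g in regions] == [(1, 3), (5, 5)]
        assert regions[0].seed == 2

    def test_two_top_variables_in_one_run(self):
        # both best-ranked variables sit in run [1..3]; second region
        # comes from the best-ranked variable outside it
        p = np.array([0.5, 0.01, 0.005, 0.03, 0.5, 0.04, 0.5])
        r, d = self._ranked_dataset(p, top_order=[2, 1, 3, 5, 0, 4, 6])
        regions = mx.select_regions(r, d, n_regions=2)
        assert [(g.start, g.end) for g in regions] == [(1, 3), (5, 5)]
        starts_ends = {(g.start, g.end) for g in regions}
        assert len(starts_ends) == 2  # disjoint

    def test_nothing_significant_returns_empty(self):
        p = np.full(5, 0.9)
        r, d = self._ranked_dataset(p, top_order=[0, 1, 2, 3, 4])
        assert mx.select_regions(r, d) == []

    def test_runs_do_not_cross_channel_blocks(self):
        p = np.array([0.01, 0.01, 0.01, 0.01])
        r, d = self._ranked_dataset(p, top_order=[0, 1, 2, 3])
        d.col_meta["channel"] = ["c1", "c1", "c2", "c2"]
        regions = mx.select_regions(r, d, n_regions=2)
        assert [(g.start, g.end) for g in regions] == [(0, 1), (2, 3)]

    def test_maximality(self, small_study):
        d = small_study["mx"].dataset
        r = mx.rank_utest(d, "control", "diseaseA")
        for g in mx.select_regions(r, d):
            blocks = {
                tag: sl for tag, sl in d.channel_blocks()
            }
            sl = blocks[g.channel]
            assert np.all(r.p[g.start : g.end + 1] < 0.05)
            if g.start > sl.start:
                assert r.p[g.start - 1] >= 0.05
            if g.end < sl.stop - 1:
                assert r.p[g.end + 1] >= 0.05


class TestDiseaseBarcode:
    def test_single_channel_class_draws_single_channel(self, small_study):
        d = small_study["mx"].dataset
        b = mx.disease_barcode(d, "control", "diseaseA")
        assert b.size > 0
        assert b.channels() == {"532nm"}
        b2 = mx.disease_barcode(d, "control", "diseaseB")
        assert b2.channels() == {"785nm"}

    def test_planted_increase_flagged_black(self, small_study):
        d = small_study["mx"].dataset
        truth = small_study["result"].truth_for("diseaseA")
        b = mx.disease_barcode(d, "control", "diseaseA")
        planted_cols = {
            int(c) for t in truth for c in t.window_columns
        }  # channel 1 occupies columns [0, n)
        hits = [v for v in b.variables if v.column in planted_cols]
        assert hits, "barcode misses every planted window"
        assert all(v.direction == +1 for v in hits)

    def test_disease_equals_control_gives_empty(self, small_study):
        d = small_study["mx"].dataset
        b = mx.disease_barcode(d, "control", "control")
        assert b.size == 0


class TestMRMR:
    def test_k_equals_candidates_returns_all(self, tiny_dataset):
        out = mx.mrmr_select(tiny_dataset, [0, 1, 2], k=3)
        assert sorted(out) == [0, 1, 2]

    def test_single_candidate(self, tiny_dataset):
        assert mx.mrmr_select(tiny_dataset, [4], k=1) == [4]

    def test_duplicate_column_not_picked_twice_early(self):
        rng = np.random.default_rng(3)
        n = 40
        informative = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        informative = informative + rng.normal(0, 0.05, n)
        weaker = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        weaker = weaker + rng.normal(0, 0.4, n)
        matrix = np.column_stack([informative, informative.copy(), weaker])
        row_meta = pd.DataFrame(
            {
                "class_label": ["A"] * (n // 2) + ["B"] * (n // 2),
                "sample_id": [f"s{i}" for i in range(n)],
                "acquisition_index": [0] * n,
            }
        )
        col_meta = pd.DataFrame(
            {"channel": ["c"] * 3, "wavenumber": [1.0, 2.0, 3.0]}
        )
        d = mx.SpectralDataset(matrix, row_meta, col_meta)
        out = mx.mrmr_select(d, [0, 1, 2], k=2)
        assert out[0] == 0  # max relevance, tie broken to lower index
        assert out[1] == 2  # duplicate penalized by full redundancy

    def test_deterministic(self, small_study):
        d = small_study["mx"].dataset
        cand = list(range(0, 60, 3))
        assert mx.mrmr_select(d, cand, 5) == mx.mrmr_select(d, cand, 5)

    def test_k_too_large_rejected(self, tiny_dataset):
        with pytest.raises(InvalidConfigError):
            mx.mrmr_select(tiny_dataset, [0, 1], k=3)


class TestUniversalBarcode:
    def test_exact_sizes(self, small_study):
        d = small_study["mx"].dataset
        assert mx.universal_barcode(d, 30).size == 30
        assert mx.universal_barcode(d, 10).size == 10
        assert mx.universal_barcode(d, 100).size == 100

    def test_full_and_half(self, small_study):
        d = small_study["mx"].dataset
        assert mx.universal_barcode(d, "full").size == d.n_variables
        assert mx.universal_barcode(d, "half").size == d.n_variables // 2

    def test_ten_pairwise_tests_for_five_classes(self, small_study):
        d = small_study["mx"].dataset
        b = mx.universal_barcode(d, 10)
        tests = {
            v.provenance.split(";")[0] for v in b.variables
        }
        # 10 variables, one seeded by each of the 10 pairwise tests
        assert len(tests) <= 10
        assert all(t.startswith("utest:") for t in tests)

    def test_no_duplicates(self, small_study):
        d = small_study["mx"].dataset
        for size in (10, 30, 100):
            b = mx.universal_barcode(d, size)
            assert len({v.column for v in b.variables}) == b.size


class TestAnovaControl:
    def test_constant_column_selected(self, small_study):
        d = small_study["mx"].dataset.copy()
        d.matrix[:, 5] = 0.42
        b = mx.lowest_ranked_anova(d, k=10)
        assert 5 in {v.column for v in b.variables}

    def test_planted_column_never_lowest(self, small_study):
        d = small_study["mx"].dataset
        truth = small_study["result"].truth
        planted = {int(t.center_column) for t in truth if t.channel == "532nm"}
        b = mx.lowest_ranked_anova(d, k=10)
        assert planted.isdisjoint({v.column for v in b.variables})

    def test_k_equals_all(self, tiny_dataset):
        b = mx.lowest_ranked_anova(tiny_dataset, k=tiny_dataset.n_variables)
        assert b.size == tiny_dataset.n_variables


class TestApplyBarcode:
    def test_subsetting(self, small_study):
        d = small_study["mx"].dataset
        b = mx.universal_barcode(d, 10)
        out = mx.apply_barcode(d, b)
        assert out.matrix.shape == (d.n_spectra, 10)
        assert out.row_meta.equals(d.row_meta)
        assert np.array_equal(out.matrix, d.matrix[:, b.columns])

    def test_identity_barcode(self, small_study):
        d = small_study["mx"].dataset
        b = mx.universal_barcode(d, "full")
        out = mx.apply_barcode(d, b)
        assert out.n_variables == d.n_variables

    def test_empty_barcode_rejected(self, small_study):
        with pytest.raises(MappingError):
            mx.apply_barcode(small_study["mx"].dataset, mx.Barcode("empty"))

    def test_unknown_variable_rejected(self, small_study):
        d = small_study["mx"].dataset
        b = mx.universal_barcode(d, 10)
        b.variables[0].wavenumber += 5.0
        with pytest.raises(MappingError):
            mx.apply_barcode(d, b)
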