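"""Filters, TMM normalization, log-CPM and the Blom transformation."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import ndtr

from mirsurv.preprocess import (CountMatrix, blom_from_reference,
                                blom_transform, filter_mirnas, filter_samples,
                                fold_normalization, normalize_counts,
                                preprocess_counts, tmm_normalization_factors)


def cm(arr, prefix="f"):
    arr = np.asarray(arr)
    return CountMatrix(pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])]))


def sorted_quantile(values, q):
    """Independent quantile oracle: linear interpolation of sorted order
    statistics, computed from first principles."""
    v = sorted(values)
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestFilterMirnas:
    def test_all_zero_feature_removed(self):
        m = cm([[0, 0, 0, 0], [10, 12, 9, 11]])
        kept = filter_mirnas(m)
        assert kept.feature_ids == ["f1"]

    def test_boundary_q3_exactly_five_retained(self):
        # "fewer than five" excludes, so Q3 == 5 stays
        m = cm([[5, 5, 5, 5], [4, 4, 4, 4]])
        kept = filter_mirnas(m)
        assert kept.feature_ids == ["f0"]

    @pytest.mark.parametrize("row", [
        (0, 0, 0, 0, 12, 40),
        (0, 1, 2, 3, 4, 5),
        (5, 5, 5, 0, 0, 0),
        (7, 0, 0, 0, 0, 0),
    ])
    def test_agrees_with_sorting_oracle(self, row):
        m = cm([list(row)])
        kept = filter_mirnas(m)
        expected = sorted_quantile(row, 0.75) >= 5
        assert (len(kept.feature_ids) == 1) == expected

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        m = cm(rng.integers(0, 50, (30, 8)))
        kept = filter_mirnas(m)
        orig = [f for f in m.feature_ids if f in set(kept.feature_ids)]
        assert kept.feature_ids == orig


class TestFilterSamples:
    def test_all_positive_sample_retained(self):
        m = cm(np.ones((10, 3), dtype=int))
        assert filter_samples(m).sample_ids == ["s0", "s1", "s2"]

    def test_mostly_zero_sample_removed(self):
        arr = np.ones((8, 2), dtype=int) * 5
        arr[:6, 1] = 0  # 75% zeros -> Q1 == 0
        kept = filter_samples(cm(arr))
        assert kept.sample_ids == ["s0"]

    def test_half_zero_sample_median_oracle(self):
        # 10 features, exactly 5 zeros: median interpolates between 0 and
        # the smallest positive count, so the sample survives
        col = np.array([0, 0, 0, 0, 0, 3, 4, 5, 6, 7])
        med = sorted_quantile(col, 0.5)
        arr = np.column_stack([np.arange(1, 11), col])
        kept = filter_samples(cm(arr))
        assert ("s1" in kept.sample_ids) == (med != 0 and sorted_quantile(col, 0.25) != 0)
        assert "s1" not in kept.sample_ids  # Q1 is 0 here

    def test_filters_idempotent(self):
        rng = np.random.default_rng(1)
        arr = rng.negative_binomial(2, 0.3, (40, 12))
        arr[:, :3] = 0
        once = filter_samples(filter_mirnas(cm(arr)))
        twice = filter_samples(filter_mirnas(once))
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_samples_removed_raises(self):
        with pytest.raises(ValueError, match="all samples"):
            filter_samples(cm(np.zeros((4, 3), dtype=int) + [[0], [0], [0], [1]]))


def naive_tmm(arr, logratio_trim=0.3, abs_trim=0.05):
    """Independently coded reference TMM: explicit loops, rank-based
    two-sided trimming, inverse asymptotic-variance weights."""
    arr = np.asarray(arr, dtype=float)
    nf, ns = arr.shape
    lib = arr.sum(axis=0)
    f75 = np.array([sorted_quantile(arr[:, j], 0.75) for j in range(ns)]) / lib
    ref = int(np.argmin(np.abs(f75 - np.mean(f75))))
    factors = []
    for j in range(ns):
        ms, asums, ws = [], [], []
        for i in range(nf):
            o, r = arr[i, j], arr[i, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                ms.append(np.log2(po / pr))
                asums.append(0.5 * np.log2(po * pr))
                ws.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        ms, asums, ws = map(np.asarray, (ms, asums, ws))
        if ms.size == 0 or np.max(np.abs(ms)) < 1e-6:
            factors.append(1.0)
            continue
        nkeep = ms.size
        rank_m = np.argsort(np.argsort(ms)) + 1
        rank_a = np.argsort(np.argsort(asums)) + 1
        lo_l = np.floor(nkeep * logratio_trim) + 1
        hi_l = nkeep + 1 - lo_l
        lo_s = np.floor(nkeep * abs_trim) + 1
        hi_s = nkeep + 1 - lo_s
        keep = ((rank_m >= lo_l) & (rank_m <= hi_l)
                & (rank_a >= lo_s) & (rank_a <= hi_s))
        f = np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])
        factors.append(2.0 ** f)
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.random.default_rng(2).integers(1, 100, 50)
        m = cm(np.tile(col[:, None], (1, 4)))
        f = tmm_normalization_factors(m)
        assert np.allclose(f.to_numpy(), 1.0)

    def test_pure_depth_change_gives_unit_factor(self):
        col = np.random.default_rng(3).integers(1, 200, 80)
        m = cm(np.column_stack([col, 3 * col, col]))
        f = tmm_normalization_factors(m)
        assert np.allclose(f.to_numpy(), 1.0, atol=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        arr = rng.negative_binomial(3, 0.02, (100, 6))
        f = tmm_normalization_factors(cm(arr))
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(5)
        arr = rng.negative_binomial(4, 0.03, (50, 4))
        arr[:10, 1] *= 5  # inflated block
        f = tmm_normalization_factors(cm(arr))
        ref = naive_tmm(arr)
        assert np.max(np.abs(f.to_numpy() - ref)) < 1e-10

    def test_matches_edger_bioconductor(self, tmp_path):
        """Cross-check against the Bioconductor implementation."""
        rng = np.random.default_rng(7)
        arr = rng.negative_binomial(5, 0.05, (60, 5)).astype(int)
        arr[:12, 2] *= 6
        arr[rng.random(arr.shape) < 0.15] = 0
        m = cm(arr)
        path = tmp_path / "x.tsv"
        m.values.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(sprintf("%.10f\\n", calcNormFactors(x, method="TMM")))'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        ref = np.array([float(v) for v in proc.stdout.split()])
        mine = tmm_normalization_factors(m).to_numpy()
        assert np.max(np.abs(mine - ref)) < 1e-8

    def test_zero_library_raises(self):
        arr = np.ones((5, 2), dtype=int)
        arr[:, 1] = 0
        with pytest.raises(ValueError, match="zero library"):
            tmm_normalization_factors(cm(arr))


class TestLogCPM:
    def test_monotone_within_sample(self):
        rng = np.random.default_rng(8)
        arr = rng.integers(0, 500, (40, 3))
        m = cm(arr)
        f = tmm_normalization_factors(m)
        y = normalize_counts(m, f).to_numpy()
        j = 1
        order = np.argsort(arr[:, j], kind="stable")
        assert np.all(np.diff(y[order, j]) >= -1e-12)

    def test_doubling_counts_shifts_by_algebraic_amount(self):
        # log2-CPM with pseudocount c: doubling counts and library sizes
        # maps log2((x+c)/(L+1)) -> log2((2x+c)/(2L+1)); verify exactly
        arr = np.random.default_rng(9).integers(0, 300, (30, 4))
        m1, m2 = cm(arr), cm(2 * arr)
        f = pd.Series(np.ones(4), index=m1.sample_ids)
        y1 = normalize_counts(m1, f).to_numpy()
        y2 = normalize_counts(m2, f).to_numpy()
        lib = arr.sum(axis=0)
        expected = (np.log2((2 * arr + 0.5) / (2 * lib + 1.0)[None, :] * 1e6))
        assert np.allclose(y2, expected)
        # and rank structure is untouched
        assert np.allclose(np.argsort(y1, axis=0), np.argsort(y2, axis=0))

    def test_zero_count_maps_to_pseudocount_floor(self):
        arr = np.array([[0, 0], [100, 100]])
        m = cm(arr)
        f = pd.Series(np.ones(2), index=m.sample_ids)
        y = normalize_counts(m, f).to_numpy()
        assert np.allclose(y[0], np.log2(0.5 / (arr.sum(0) + 1.0) * 1e6))


def independent_normal_quantile(p):
    """Invert the normal CDF numerically (independent of ndtri)."""
    return brentq(lambda x: ndtr(x) - p, -10, 10, xtol=1e-13)


class TestBlom:
    def test_constant_vector_maps_to_zero(self):
        assert np.allclose(blom_transform(np.full(7, 3.3)), 0.0)

    def test_three_distinct_values_closed_form(self):
        out = blom_transform(np.array([10.0, -2.0, 5.0]))
        expected = np.array([
            independent_normal_quantile((3 - 0.375) / 3.25),
            independent_normal_quantile((1 - 0.375) / 3.25),
            independent_normal_quantile((2 - 0.375) / 3.25),
        ])
        assert np.allclose(out, expected, atol=1e-10)
        assert np.allclose(out, [0.8694, -0.8694, 0.0], atol=1e-3)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40, unique=True))
    def test_strictly_increasing_input_gives_increasing_output(self, values):
        v = np.sort(np.array(values))
        out = blom_transform(v)
        assert np.all(np.diff(out) > 0)

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=30, unique=True))
    def test_invariant_to_monotone_transform(self, values):
        v = np.array(values, dtype=float)
        assert np.allclose(blom_transform(v), blom_transform(np.exp(v / 500)))

    def test_short_vector_raises(self):
        with pytest.raises(ValueError):
            blom_transform(np.array([1.0]))

    def test_reference_mapping_matches_plugin_rank(self):
        rng = np.random.default_rng(12)
        train = rng.normal(size=50)
        new = rng.normal(size=10)
        out = blom_from_reference(train, new)
        # midrank of a far-below-minimum value maps near the lower tail
        lo = blom_from_reference(train, np.array([train.min() - 10]))
        assert np.isfinite(out).all() and lo < out.min()


class TestFullPipeline:
    def test_blom_rows_mean_zero(self):
        rng = np.random.default_rng(13)
        arr = rng.negative_binomial(5, 0.05, (60, 20))
        expr = preprocess_counts(cm(arr))
        means = expr.values.to_numpy().mean(axis=1)
        assert np.max(np.abs(means)) < 0.05  # ties among zeros may offset slightly

    def test_provenance_tallies(self):
        rng = np.random.default_rng(14)
        arr = rng.negative_binomial(5, 0.05, (80, 15))
        arr[:30] = 0
        expr = preprocess_counts(cm(arr))
        assert expr.provenance["n_mirnas_in"] == 80
        assert expr.provenance["n_mirnas_retained"] == expr.values.shape[0]
        assert expr.provenance["n_samples_retained"] == expr.values.shape[1]

    def test_fold_normalization_shapes_and_determinism(self):
        rng = np.random.default_rng(15)
        arr = rng.negative_binomial(5, 0.05, (40, 12))
        m = cm(arr)
        tr = CountMatrix(m.values.iloc[:, :8])
        te = CountMatrix(m.values.iloc[:, 8:])
        e_tr, e_te = fold_normalization(tr, te)
        e_tr2, e_te2 = fold_normalization(tr, te)
        pd.testing.assert_frame_equal(e_tr, e_tr2)
        pd.testing.assert_frame_equal(e_te, e_te2)
        assert e_tr.shape == (40, 8) and e_te.shape == (40, 4)
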