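"""Hi-C analytic scores vs independent scalar reference implementations."""

import math

import numpy as np
import pytest

from trackstack import (
    BinAxis,
    ContactMatrix,
    GenomeRange,
    diff_matrix,
    directionality_index,
    insulation_score,
    parse_region,
    virtual_4c,
    zscore_by_distance,
)


def square(values, res=1000):
    values = np.asarray(values, dtype=float)
    axis = BinAxis(GenomeRange("chr1", 1, values.shape[0] * res), res)
    return ContactMatrix(axis, axis, values, res)


# ------------------------------------------------------------ scalar oracles
# Plain-Python, index-at-a-time re-derivations of each score, kept free of
# any code shared with the implementation.

def oracle_di(m, w):
    n = len(m)
    out = [float("nan")] * n
    for i in range(w, n - w):
        a = sum(m[i][i - k] for k in range(1, w + 1))
        b = sum(m[i][i + k] for k in range(1, w + 1))
        e = (a + b) / 2
        if a == b or e == 0:
            out[i] = 0.0
        else:
            chi = (a - e) ** 2 / e + (b - e) ** 2 / e
            out[i] = math.copysign(chi, b - a)
    return out


def oracle_insulation(m, w):
    n = len(m)
    raw = [float("nan")] * n
    for i in range(w, n - w + 1):
        vals = [m[r][c] for r in range(i - w, i) for c in range(i, i + w)]
        vals = [v for v in vals if not math.isnan(v)]
        if vals:
            raw[i] = sum(vals) / len(vals)
    valid = [r for r in raw if not math.isnan(r)]
    mean = sum(valid) / len(valid)
    return [math.log2(r / mean) if not math.isnan(r) else r for r in raw]


def oracle_zscore_by_distance(m):
    n = len(m)
    out = [[float("nan")] * n for _ in range(n)]
    for d in range(n):
        cells = [(i, i + d) for i in range(n - d)]
        vals = [m[i][j] for i, j in cells if not math.isnan(m[i][j])]
        for i, j in cells:
            x = m[i][j]
            if math.isnan(x):
                z = float("nan")
            elif len(vals) < 2:
                z = 0.0
            else:
                mu = sum(vals) / len(vals)
                var = sum((v - mu) ** 2 for v in vals) / len(vals)
                z = 0.0 if var == 0 else (x - mu) / math.sqrt(var)
            out[i][j] = z
            out[j][i] = z
    return out


def random_square(rng, n=40):
    upper = np.triu(rng.uniform(0.0, 20.0, size=(n, n)))
    return square(upper + np.triu(upper, 1).T)


# ---------------------------------------------------------------- virtual 4C

class TestVirtual4C:
    def test_single_bin_anchor_extracts_row(self):
        cm = square([[4, 2, 0], [2, 4, 2], [0, 2, 4]])
        prof = virtual_4c(cm, parse_region("chr1:1001-2000"))
        assert prof.values.tolist() == [2, 4, 2]

    def test_multi_bin_anchor_is_row_mean(self):
        cm = square([[4, 2, 0], [2, 4, 2], [0, 2, 4]])
        prof = virtual_4c(cm, parse_region("chr1:1-2000"))
        assert prof.values.tolist() == [3, 3, 1]

    def test_whole_range_anchor_is_column_means(self):
        rng = np.random.default_rng(5)
        cm = random_square(rng, 15)
        prof = virtual_4c(cm, cm.axis.range)
        np.testing.assert_allclose(prof.values, cm.values.mean(axis=0), rtol=1e-12)

    def test_all_nan_anchor_row_gives_nan_profile(self):
        vals = np.ones((3, 3))
        vals[0, :] = np.nan
        prof = virtual_4c(square(vals), parse_region("chr1:1-1000"))
        assert np.isnan(prof.values).all()

    def test_anchor_outside_matrix_errors(self):
        cm = square(np.ones((3, 3)))
        with pytest.raises(ValueError, match="anchor"):
            virtual_4c(cm, parse_region("chr2:1-1000"))


# ---------------------------------------------------------------- DI

class TestDirectionalityIndex:
    def test_scalar_case(self):
        # one upstream bin 2, one downstream bin 8: E=5, DI=+3.6
        m = np.zeros((3, 3))
        m[1, 0], m[1, 2] = 2, 8
        m[0, 1], m[2, 1] = 2, 8
        di = directionality_index(square(m), 1)
        assert di.values[1] == pytest.approx(3.6, abs=1e-12)

    def test_antisymmetric_under_swap(self):
        m = np.zeros((3, 3))
        m[1, 0], m[1, 2] = 8, 2
        di = directionality_index(square(m), 1)
        assert di.values[1] == pytest.approx(-3.6, abs=1e-12)

    def test_balanced_row_gives_zero(self):
        cm = square(np.full((7, 7), 3.0))
        di = directionality_index(cm, 2)
        interior = di.values[2:-2]
        assert (interior == 0).all()

    def test_edges_are_nan(self):
        cm = square(np.ones((9, 9)))
        di = directionality_index(cm, 3)
        assert np.isnan(di.values[:3]).all() and np.isnan(di.values[-3:]).all()

    def test_window_too_large_errors(self):
        with pytest.raises(ValueError):
            directionality_index(square(np.ones((4, 4))), 4)

    def test_matches_scalar_oracle_on_random_matrices(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            cm = random_square(rng)
            w = int(rng.integers(1, 8))
            got = directionality_index(cm, w).values
            expected = oracle_di(cm.values.tolist(), w)
            np.testing.assert_allclose(got, expected, atol=1e-9, equal_nan=True)

    def test_scales_with_uniform_scaling(self):
        # DI is NOT scale-invariant: scaling the matrix by c scales DI by c
        rng = np.random.default_rng(8)
        cm = random_square(rng, 20)
        base = directionality_index(cm, 3).values
        scaled = directionality_index(cm.with_values(cm.values * 5), 3).values
        np.testing.assert_allclose(scaled, base * 5, atol=1e-9, equal_nan=True)
        assert not np.allclose(np.nan_to_num(scaled), np.nan_to_num(base))


# ---------------------------------------------------------------- insulation

class TestInsulationScore:
    def test_constant_matrix_scores_zero(self):
        cm = square(np.full((11, 11), 7.0))
        score = insulation_score(cm, 2)
        valid = score.values[np.isfinite(score.values)]
        assert valid.size > 0
        assert np.allclose(valid, 0.0, atol=1e-12)

    def test_w1_two_value_case(self):
        # interior diamonds see {2, 8}: scores log2(2/5), log2(8/5)
        m = np.full((4, 4), np.nan)
        m[0, 1], m[1, 0] = 2, 2
        m[1, 2], m[2, 1] = 2, 2
        m[2, 3], m[3, 2] = 8, 8
        np.fill_diagonal(m, 1)
        score = insulation_score(square(m), 1)
        got = score.values[np.isfinite(score.values)]
        raws = np.array([2.0, 2.0, 8.0])
        expected = np.log2(raws / raws.mean())
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_matches_scalar_oracle_on_random_matrices(self):
        rng = np.random.default_rng(78)
        for _ in range(50):
            cm = random_square(rng)
            w = int(rng.integers(1, 10))
            got = insulation_score(cm, w).values
            expected = oracle_insulation(cm.values.tolist(), w)
            np.testing.assert_allclose(got, expected, atol=1e-9, equal_nan=True)

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(9)
        cm = random_square(rng, 24)
        base = insulation_score(cm, 3).values
        scaled = insulation_score(cm.with_values(cm.values * 11), 3).values
        np.testing.assert_allclose(scaled, base, atol=1e-9, equal_nan=True)

    def test_all_nan_matrix_errors(self):
        with pytest.raises(ValueError):
            insulation_score(square(np.full((9, 9), np.nan)), 2)


# ---------------------------------------------------------------- z-score

class TestZscoreByDistance:
    def test_two_value_diagonal(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1
        m[1, 2] = m[2, 1] = 3
        z = zscore_by_distance(square(m)).values
        assert z[0, 1] == pytest.approx(-1.0)
        assert z[1, 2] == pytest.approx(1.0)

    def test_constant_diagonal_is_zero(self):
        z = zscore_by_distance(square(np.full((5, 5), 4.0))).values
        assert np.allclose(z, 0.0)

    def test_per_diagonal_mean_is_zero(self):
        rng = np.random.default_rng(79)
        z = zscore_by_distance(random_square(rng)).values
        n = z.shape[0]
        for d in range(n - 2):
            diag = np.diagonal(z, offset=d)
            sd = np.diagonal(random_square(np.random.default_rng(79)).values, d).std()
            if sd > 0:
                assert abs(diag.mean()) < 1e-9

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(80)
        for _ in range(50):
            cm = random_square(rng, 40)
            got = zscore_by_distance(cm).values
            expected = oracle_zscore_by_distance(cm.values.tolist())
            np.testing.assert_allclose(got, expected, atol=1e-9, equal_nan=True)

    def test_output_symmetric(self):
        rng = np.random.default_rng(81)
        z = zscore_by_distance(random_square(rng)).values
        np.testing.assert_allclose(z, z.T, atol=0)


# ---------------------------------------------------------------- diff

class TestDiffMatrix:
    def test_self_difference_is_zero(self):
        rng = np.random.default_rng(82)
        cm = random_square(rng)
        d = diff_matrix(cm, cm).values
        assert np.allclose(np.nan_to_num(d), 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(83)
        a, b = random_square(rng), random_square(rng)
        ab = diff_matrix(a, b).values
        ba = diff_matrix(b, a).values
        np.testing.assert_allclose(ab, -ba, atol=1e-9, equal_nan=True)

    def test_axis_mismatch_names_both_axes(self):
        a = square(np.ones((4, 4)), res=1000)
        b = square(np.ones((5, 5)), res=1000)
        with pytest.raises(ValueError, match="axes differ"):
            diff_matrix(a, b)

    def test_enriched_block_is_positive(self):
        rng = np.random.default_rng(84)
        base = random_square(rng, 30)
        bumped = base.values.copy()
        bumped[10:14, 20:24] += 40
        bumped[20:24, 10:14] += 40
        d = diff_matrix(base.with_values(bumped), base).values
        assert (d[10:14, 20:24] > 0).all()

    def test_nan_propagates(self):
        vals = np.ones((4, 4)) * np.arange(4)
        vals = (vals + vals.T) / 2
        vals[0, 3] = vals[3, 0] = np.nan
        a = square(vals)
        d = diff_matrix(a, a).values
        assert np.isnan(d[0, 3]) and np.isnan(d[3, 0])

    def test_global_variant_selectable(self):
        rng = np.random.default_rng(85)
        a, b = random_square(rng, 20), random_square(rng, 20)
        per = diff_matrix(a, b, method="per_distance").values
        glob = diff_matrix(a, b, method="global").values
        assert per.shape == glob.shape
        assert not np.allclose(np.nan_to_num(per), np.nan_to_num(glob))
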