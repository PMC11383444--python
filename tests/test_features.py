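"""Feature-derivation oracles: Pearson FC, intrinsic timescale, SC
normalization, scaling, Spearman structure-function coupling."""

import numpy as np
import pytest

from neuromask.features import (
    AnatomicalTable,
    ConnectivityMatrix,
    GmVolumes,
    RoiTimeSeries,
    assemble_as,
    compute_coupling,
    compute_fc,
    compute_int,
    minmax_scale,
    minmax_scale_offdiag,
    normalize_sc,
    scale_anatomical,
)


# -- independent oracles ----------------------------------------------------

def pearson_oracle(x):
    """Double-loop Pearson correlation, straight from the formula."""
    t, q = x.shape
    out = np.eye(q)
    for i in range(q):
        for j in range(q):
            xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
            out[i, j] = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
    return out


def int_oracle(y, tr):
    """Brute-force INT: explicit double-loop autocorrelation, summed over
    its initial positive phase, max lag T-2."""
    t = len(y)
    ybar = y.mean()
    denom = np.sum((y - ybar) ** 2)
    r = []
    for k in range(1, t - 1):
        num = sum((y[s] - ybar) * (y[s - k] - ybar) for s in range(k, t))
        r.append(num / denom)
    total = 0.0
    for rk in r:
        if rk < 0:
            break
        total += rk
    return tr * total


def spearman_oracle(a, b):
    """Rank (average ranks for ties) then Pearson."""
    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = avg_rank(np.asarray(a, float)), avg_rank(np.asarray(b, float))
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return np.sum(ra * rb) / np.sqrt(np.sum(ra**2) * np.sum(rb**2))


# -- functional connectivity ------------------------------------------------

class TestComputeFc:
    def test_identical_and_negated_columns(self, rng):
        base = rng.normal(size=50)
        x = np.column_stack([base, base, -base])
        fc = compute_fc(RoiTimeSeries(x, tr=1.0)).values
        assert fc[0, 1] == pytest.approx(1.0)
        assert fc[0, 2] == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(200, 5))
        fc = compute_fc(RoiTimeSeries(x, tr=1.0)).values
        np.testing.assert_allclose(fc, pearson_oracle(x), atol=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(size=(80, 4))
        y = x.copy()
        y[:, 2] = 5.0 * y[:, 2] - 3.0
        a = compute_fc(RoiTimeSeries(x, tr=1.0)).values
        b = compute_fc(RoiTimeSeries(y, tr=1.0)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_variance_column_names_roi(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        x[:, 1] = 2.0
        with pytest.raises(ValueError, match="ROI001"):
            compute_fc(RoiTimeSeries(x, tr=1.0))


# -- intrinsic neural timescale --------------------------------------------

class TestComputeInt:
    def test_alternating_signal_is_zero(self):
        y = np.tile([1.0, -1.0], 25)
        x = np.column_stack([y, np.random.default_rng(1).normal(size=50)])
        out = compute_int(RoiTimeSeries(x, tr=1.0))
        assert out[0] == 0.0

    def test_linear_in_tr(self, rng):
        x = rng.normal(size=(120, 3)).cumsum(axis=0)  # smooth-ish signals
        a = compute_int(RoiTimeSeries(x, tr=0.7))
        b = compute_int(RoiTimeSeries(x, tr=1.4))
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-12)

    def test_matches_brute_force_oracle_on_ar1(self):
        rng = np.random.default_rng(42)
        phi, t = 0.5, 1000
        e = rng.normal(size=t)
        y = np.empty(t)
        y[0] = e[0]
        for i in range(1, t):
            y[i] = phi * y[i - 1] + e[i]
        x = y[:, None]
        got = compute_int(RoiTimeSeries(x, tr=0.8))[0]
        assert got == pytest.approx(int_oracle(y, 0.8), abs=1e-10)

    def test_no_sign_change_fallback(self):
        # [1, 0, -1]: r(1) = 0 (not negative) and T-2 = 1 is the last lag,
        # so the sum runs to the fallback limit; INT = TR * 0
        x = np.array([[1.0], [0.0], [-1.0]])
        assert compute_int(RoiTimeSeries(x, tr=2.0))[0] == 0.0

    def test_scale_invariance(self, rng):
        y = rng.normal(size=200).cumsum()
        a = compute_int(RoiTimeSeries(y[:, None], tr=1.0))[0]
        b = compute_int(RoiTimeSeries((3.0 * y + 7.0)[:, None], tr=1.0))[0]
        assert b == pytest.approx(a, rel=1e-12)

    def test_constant_column_raises(self):
        x = np.ones((30, 1))
        with pytest.raises(ValueError, match="constant"):
            compute_int(RoiTimeSeries(x, tr=1.0))


# -- scaling ----------------------------------------------------------------

class TestMinMax:
    def test_basic(self):
        np.testing.assert_allclose(minmax_scale(np.array([2.0, 4.0, 6.0])),
                                   [0.0, 0.5, 1.0])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(minmax_scale(np.full(5, 3.3)), np.zeros(5))

    def test_range_is_exact(self, rng):
        out = minmax_scale(rng.normal(size=(6, 7)))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            minmax_scale(np.array([1.0, np.inf]))


# -- SC normalization -------------------------------------------------------

class TestNormalizeSc:
    def test_volume_correction_value(self):
        # raw(0,1)=6 with volumes 4 and 9: pre-scaling value 6/sqrt(36) = 1,
        # visible because min-max with a single distinct positive entry
        # maps it to 1 and zeros stay 0
        raw = np.zeros((3, 3))
        raw[0, 1] = raw[1, 0] = 6.0
        sc = normalize_sc(ConnectivityMatrix(raw, "SC"),
                          GmVolumes(np.array([4.0, 9.0, 1.0])))
        assert sc.values[0, 1] == pytest.approx(1.0)
        assert sc.values[0, 2] == 0.0

    def test_all_zero_input_stays_zero(self):
        sc = normalize_sc(ConnectivityMatrix(np.zeros((4, 4)), "SC"),
                          GmVolumes(np.ones(4)))
        np.testing.assert_array_equal(sc.values, np.zeros((4, 4)))

    def test_matches_elementwise_oracle(self, rng):
        raw = np.triu(rng.poisson(5.0, size=(6, 6)).astype(float), 1)
        raw = raw + raw.T
        vol = rng.uniform(1.0, 10.0, size=6)
        got = normalize_sc(ConnectivityMatrix(raw, "SC"), GmVolumes(vol)).values

        pre = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j:
                    pre[i, j] = raw[i, j] / np.sqrt(vol[i] * vol[j])
        off = [pre[i, j] for i in range(6) for j in range(6) if i != j]
        lo, hi = min(off), max(off)
        expect = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j:
                    expect[i, j] = (pre[i, j] - lo) / (hi - lo)
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_preserves_zeros_and_symmetry(self, rng):
        raw = np.triu(rng.poisson(1.0, size=(8, 8)).astype(float), 1)
        raw = raw + raw.T
        vol = rng.uniform(0.5, 3.0, size=8)
        out = normalize_sc(ConnectivityMatrix(raw, "SC"), GmVolumes(vol)).values
        np.testing.assert_array_equal(out == 0, raw == 0)
        np.testing.assert_allclose(out, out.T, atol=1e-15)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            GmVolumes(np.array([1.0, 0.0]))


# -- anatomical scaling -----------------------------------------------------

class TestScaleAnatomical:
    def test_rank_preserving_per_column(self, rng):
        raw = AnatomicalTable(rng.uniform(0.1, 100.0, size=(15, 4)),
                              [f"c{i}" for i in range(4)])
        out = scale_anatomical(raw)
        for c in range(4):
            assert np.array_equal(np.argsort(raw.values[:, c]),
                                  np.argsort(out.values[:, c]))
        assert out.values.min() >= 0 and out.values.max() <= 1

    def test_constant_column_is_zero(self):
        raw = AnatomicalTable(np.column_stack([np.full(5, 2.0),
                                               np.arange(5.0)]), ["a", "b"])
        out = scale_anatomical(raw)
        np.testing.assert_array_equal(out.values[:, 0], np.zeros(5))

    def test_plain_log_requires_positive(self):
        raw = AnatomicalTable(np.array([[0.0], [1.0]]), ["a"])
        with pytest.raises(ValueError, match="positive"):
            scale_anatomical(raw, log="log")


# -- structure-function coupling --------------------------------------------

class TestCoupling:
    @staticmethod
    def _mats(sc_vals, fc_vals):
        return (ConnectivityMatrix(sc_vals, "SC", normalized=True),
                ConnectivityMatrix(fc_vals, "FC"))

    def test_monotone_and_antimonotone(self):
        q = 5
        sc = np.zeros((q, q))
        fc = np.eye(q)
        sc[0, 1:] = [1.0, 2.0, 3.0, 4.0]
        sc[1:, 0] = sc[0, 1:]
        fc[0, 1:] = [0.1, 0.2, 0.3, 0.4]
        fc[1:, 0] = fc[0, 1:]
        scm, fcm = self._mats(sc, fc)
        assert compute_coupling(scm, fcm)[0] == pytest.approx(1.0)
        fc2 = fc.copy()
        fc2[0, 1:] = fc2[0, 1:][::-1]
        fc2[1:, 0] = fc2[0, 1:]
        scm2, fcm2 = self._mats(sc, fc2)
        assert compute_coupling(scm2, fcm2)[0] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        q = 12
        sc = np.triu(rng.integers(0, 4, size=(q, q)).astype(float), 1)
        sc = sc + sc.T
        fc = np.triu(np.round(rng.uniform(-1, 1, size=(q, q)), 1), 1)
        fc = fc + fc.T + np.eye(q)
        scm, fcm = self._mats(sc, fc)
        got = compute_coupling(scm, fcm)
        for i in range(q):
            support = [j for j in range(q) if j != i and sc[i, j] > 0]
            if len(support) < 3:
                assert got[i] == 0.0
                continue
            a = np.array([sc[i, j] for j in support])
            b = np.array([fc[i, j] for j in support])
            if np.all(a == a[0]) or np.all(b == b[0]):
                assert got[i] == 0.0
                continue
            assert got[i] == pytest.approx(spearman_oracle(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        q = 8
        sc = np.triu(rng.uniform(0.1, 1, size=(q, q)), 1)
        sc = sc + sc.T
        fc = np.triu(rng.uniform(-0.5, 0.9, size=(q, q)), 1)
        fc = fc + fc.T + np.eye(q)
        scm, fcm = self._mats(sc, fc)
        base = compute_coupling(scm, fcm)
        fc_t = np.tanh(2.0 * fc)  # strictly monotone transform
        np.fill_diagonal(fc_t, 1.0)
        scm2, fcm2 = self._mats(sc, fc_t)
        np.testing.assert_allclose(compute_coupling(scm2, fcm2), base, atol=1e-12)

    def test_sparse_row_imputed_zero(self):
        q = 5
        sc = np.zeros((q, q))
        sc[0, 1] = sc[1, 0] = 1.0  # ROI 0 has a single connection
        sc[2, 3] = sc[3, 2] = 1.0
        sc[2, 4] = sc[4, 2] = 2.0
        sc[3, 4] = sc[4, 3] = 3.0
        fc = np.eye(q)
        scm, fcm = self._mats(sc, fc)
        assert compute_coupling(scm, fcm)[0] == 0.0

    def test_all_zero_sc_raises(self):
        scm, fcm = self._mats(np.zeros((4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="all-zero"):
            compute_coupling(scm, fcm)


# -- AS assembly ------------------------------------------------------------

class TestAssembleAs:
    def test_nine_plus_two_columns(self, rng):
        morph = AnatomicalTable(rng.uniform(1, 10, size=(6, 9)),
                                [f"m{i}" for i in range(9)])
        out = assemble_as(morph, rng.uniform(0, 5, 6), rng.uniform(-1, 1, 6))
        assert out.n_columns == 11
        assert out.column_names[-2:] == ["int_s", "coupling"]
        assert out.scaled

    def test_empty_morphology_allowed(self, rng):
        morph = AnatomicalTable(np.zeros((6, 0)), [])
        out = assemble_as(morph, rng.uniform(0, 5, 6), rng.uniform(-1, 1, 6))
        assert out.n_columns == 2

    def test_roi_count_mismatch(self, rng):
        morph = AnatomicalTable(rng.uniform(1, 2, size=(6, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            assemble_as(morph, np.zeros(5), np.zeros(6))
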