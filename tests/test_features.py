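"""LLD extraction oracles, HLD functionals and change-score identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimil.features import (
    MODALITIES,
    FeatureBag,
    baseline_score,
    change_score_bag,
    change_scores,
    compute_eda_lld,
    hld_functionals,
    instantaneous_hr,
    instantaneous_rsp,
    raw_feature_bag,
    window_hlds,
)
from mimil.preprocess import N_SEGMENTS

from conftest import make_window

FS = 1250.0


def synthetic_ecg(rr_s, fs=FS, total_s=30.0):
    """Spike-train ECG with the given repeating R-R interval pattern."""
    n = int(total_s * fs)
    ecg = np.zeros(n)
    t, k = 1.0, 0
    while t < total_s - 0.1:
        i = int(t * fs)
        ecg[i] = 1.0
        t += rr_s[k % len(rr_s)]
        k += 1
    return ecg


class TestHeartRate:
    @pytest.mark.parametrize("rr,bpm", [(1.0, 60.0), (0.5, 120.0)])
    def test_constant_rr(self, rr, bpm):
        hr, ok = instantaneous_hr(synthetic_ecg([rr]), FS)
        assert ok
        mid = slice(int(5 * FS), int(25 * FS))
        assert np.allclose(hr[mid], bpm, rtol=0.02)

    def test_alternating_rr_time_weighted_mean(self):
        # R-R alternating 0.8/1.0 s: HR steps between 75 and 60; the mean over
        # a long stretch is the time-weighted mean (0.8*75 + 1.0*60) / 1.8
        hr, ok = instantaneous_hr(synthetic_ecg([0.8, 1.0]), FS)
        assert ok
        mid = hr[int(5 * FS) : int(25 * FS)]
        expected = (0.8 * 75 + 1.0 * 60) / 1.8
        assert np.mean(mid) == pytest.approx(expected, rel=0.02)

    def test_no_peaks_falls_back(self):
        flat = np.zeros(int(10 * FS))
        hr, ok = instantaneous_hr(flat, FS, fallback_bpm=90.0)
        assert not ok
        assert np.allclose(hr, 90.0)


class TestRespiration:
    def test_rate_and_amplitude_from_sinusoid(self):
        f, A = 0.333, 1.7
        t = np.arange(int(40 * FS)) / FS
        rsp = A * np.sin(2 * np.pi * f * t)
        rate, amp, ok = instantaneous_rsp(rsp, FS)
        assert ok
        mid = slice(int(10 * FS), int(30 * FS))
        assert np.allclose(rate[mid], 60 * f, rtol=0.05)
        assert np.allclose(amp[mid], 2 * A, rtol=0.05)

    def test_rate_scales_with_frequency(self):
        t = np.arange(int(40 * FS)) / FS
        r1, _, _ = instantaneous_rsp(np.sin(2 * np.pi * 0.25 * t), FS)
        r2, _, _ = instantaneous_rsp(np.sin(2 * np.pi * 0.5 * t), FS)
        mid = slice(int(10 * FS), int(30 * FS))
        assert np.mean(r2[mid]) == pytest.approx(2 * np.mean(r1[mid]), rel=0.05)


class TestEdaLld:
    def test_identity_passthrough(self):
        x = np.random.default_rng(0).normal(size=2500)
        assert np.array_equal(compute_eda_lld(x), x)
        assert len(compute_eda_lld(x)) == 2500


class TestHldFunctionals:
    def test_constant(self):
        assert np.allclose(hld_functionals(np.full(100, 2.5)), [2.5, 2.5, 0, 0, 2.5, 2.5])

    def test_hand_case(self):
        v = hld_functionals(np.array([1.0, 2.0, 3.0, 4.0]))
        # population convention: var = mean((x - mean)^2) = 1.25
        assert np.allclose(v, [1, 4, np.sqrt(1.25), 1.25, 2.5, 2.5])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hld_functionals(np.array([]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=50),
        st.floats(-100, 100),
    )
    def test_translation_invariance_and_oracle(self, values, shift):
        """Shift moves min/max/mean/median; std/var unchanged; sort/sum oracle."""
        x = np.array(values)
        v = hld_functionals(x)
        # brute-force oracle from sorted values and explicit sums
        s = np.sort(x)
        n = len(x)
        mean = sum(x) / n
        var = sum((xi - mean) ** 2 for xi in x) / n
        med = (s[(n - 1) // 2] + s[n // 2]) / 2
        assert np.allclose(v, [s[0], s[-1], np.sqrt(var), var, mean, med], atol=1e-8)
        w = hld_functionals(x + shift)
        assert np.allclose(w[[0, 1, 4, 5]], v[[0, 1, 4, 5]] + shift, atol=1e-6)
        assert np.allclose(w[2:4], v[2:4], atol=1e-6)

    def test_var_equals_std_squared(self):
        x = np.random.default_rng(1).normal(size=1000)
        v = hld_functionals(x)
        assert v[3] == pytest.approx(v[2] ** 2, abs=1e-12)


class TestBags:
    def test_raw_bag_shape_and_flatten(self):
        bag = raw_feature_bag(make_window())
        for m in MODALITIES:
            assert bag.matrices[m].shape == (19, 6)
        flat = bag.flatten()
        assert flat.shape == (19, 24)
        assert flat.size == 456

    def test_constant_channels_zero_spread(self):
        channels = {c: np.full(25000, v) for c, v in [("ecg", 0.0), ("eda", 2.0), ("rsp", 0.0)]}
        bag = raw_feature_bag(make_window(channels=channels))
        eda = bag.matrices["eda"]
        assert np.allclose(eda[:, 2], 0)  # std
        assert np.allclose(eda[:, 3], 0)  # var
        assert np.allclose(eda[:, 4], 2.0)  # mean

    def test_row_locality_under_segment_permutation(self):
        """Swapping two non-overlapping segments permutes only those HLD rows."""
        w = make_window(seed=3)
        base = window_hlds(w)["eda"]
        swapped = w.channels["eda"].copy()
        # segments 2 and 6 occupy samples [2500,5000) and [7500,10000)
        a, b = slice(2500, 5000), slice(7500, 10000)
        swapped[a], swapped[b] = w.channels["eda"][b].copy(), w.channels["eda"][a].copy()
        w2 = make_window(channels={**w.channels, "eda": swapped}, seed=3)
        perm = window_hlds(w2)["eda"]
        assert np.allclose(perm[2], base[6])
        assert np.allclose(perm[6], base[2])
        for i in (0, 10, 18):
            assert np.allclose(perm[i], base[i])


class TestBaselineAndChangeScores:
    def test_single_window_baseline_is_mean_of_its_segments(self):
        h = window_hlds(make_window())
        b = baseline_score([h])
        for m in MODALITIES:
            assert np.allclose(b[m], h[m].mean(axis=0))

    def test_two_windows_average(self):
        h1, h2 = window_hlds(make_window(seed=1)), window_hlds(make_window(seed=2))
        b = baseline_score([h1, h2])
        for m in MODALITIES:
            stacked = np.concatenate([h1[m], h2[m]])
            assert np.allclose(b[m], stacked.mean(axis=0))

    def test_counting_oracle_fifteen_windows(self):
        hlds = [window_hlds(make_window(seed=s)) for s in range(15)]
        b = baseline_score(hlds)
        m = "hr"
        stacked = np.concatenate([h[m] for h in hlds])
        assert stacked.shape == (15 * 19, 6)
        assert np.allclose(b[m], stacked.sum(axis=0) / 285)

    def test_no_baseline_rejected(self):
        with pytest.raises(ValueError):
            baseline_score([])

    def test_identical_vectors(self):
        v = np.array([1.0, -2.0, 3.0, 0.5, 2.0, 1.0])
        e, c = change_scores(v, v)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_three_four_five(self):
        e, c = change_scores(np.array([3.0, 4.0, 0, 0, 0, 0]), np.zeros(6))
        assert e == pytest.approx(5.0)
        assert c == 0.0  # zero-norm baseline flagged to 0

    def test_colinear_vectors(self):
        b = np.array([1.0, 2.0, 2.0, 0.0, 0.0, 0.0])
        e, c = change_scores(2 * b, b)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert e == pytest.approx(np.linalg.norm(b))

    def test_direct_definition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.normal(size=6), rng.normal(size=6)
            e, c = change_scores(a, b)
            assert e == pytest.approx(np.sqrt(np.sum((a - b) ** 2)), abs=1e-12)
            assert c == pytest.approx(
                np.dot(a, b) / (np.sqrt(a @ a) * np.sqrt(b @ b)), abs=1e-12
            )

    def test_change_score_bag_shape(self):
        w = make_window()
        b = baseline_score([window_hlds(w)])
        bag = change_score_bag(w, b)
        flat = bag.flatten()
        assert flat.shape == (19, 8)
        assert flat.size == 152
        for m in MODALITIES:
            assert np.all(bag.matrices[m][:, 0] >= 0)  # euclidean
            assert np.all(np.abs(bag.matrices[m][:, 1]) <= 1 + 1e-12)  # cosine

    def test_offset_invariance_with_matching_baseline(self):
        """A constant offset present in both task and baseline windows leaves
        the EDA change-scores unchanged in the mean/median dimensions'
        contribution: shifting baseline and post by the same constant shifts
        both Y_t and Y_b equally in min/max/mean/median, so Y_t - Y_b is
        unchanged and the Euclidean change-score is identical."""
        w = make_window(seed=5)
        hl = window_hlds(w)
        base = baseline_score([hl])
        shift = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 1.0]) * 3.3  # effect of +c offset
        hl_shift = {m: (hl[m] + shift if m == "eda" else hl[m]) for m in MODALITIES}
        base_shift = {m: (base[m] + shift if m == "eda" else base[m]) for m in MODALITIES}
        bag = change_score_bag(w, base, hlds=hl)
        bag_shift = change_score_bag(w, base_shift, hlds=hl_shift)
        assert np.allclose(
            bag.matrices["eda"][:, 0], bag_shift.matrices["eda"][:, 0], atol=1e-9
        )
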