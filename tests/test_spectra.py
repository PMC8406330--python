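"""Spectral filters and modified-cosine similarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocomet.spectra import (
    Ms2Spectrum,
    Polarity,
    SimilarityResult,
    ToleranceConfig,
    filter_spectrum,
    modified_cosine,
    remove_precursor_region,
    window_filter_top_k,
)

from conftest import brute_force_modified_cosine, make_spectrum, random_spectrum


class TestSpectrumValidation:
    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValueError, match="ascending"):
            Ms2Spectrum("x", 300.0, Polarity.POSITIVE, 1.0,
                        np.array([100.0, 90.0]), np.array([1.0, 1.0]))

    def test_rejects_nonpositive_precursor(self):
        with pytest.raises(ValueError, match="precursor"):
            Ms2Spectrum("x", 0.0, Polarity.POSITIVE, 1.0, np.array([100.0]), np.array([1.0]))

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError, match="non-negative"):
            Ms2Spectrum("x", 300.0, Polarity.POSITIVE, 1.0, np.array([100.0]), np.array([-1.0]))


class TestRemovePrecursorRegion:
    @pytest.mark.parametrize(
        "peaks, precursor, window, kept",
        [
            # peaks near the precursor go, distant ones stay
            ([(100.0, 1), (284.0, 1), (290.0, 1)], 300.0, 17.0, [100.0]),
            # all peaks far from the precursor: unchanged
            ([(100.0, 1), (150.0, 1)], 300.0, 17.0, [100.0, 150.0]),
            # boundary |delta| == window is removed (inclusive removal)
            ([(283.0, 1)], 300.0, 17.0, []),
            # peaks above the precursor are removed symmetrically
            ([(316.0, 1), (320.0, 1)], 300.0, 17.0, [320.0]),
        ],
    )
    def test_examples(self, peaks, precursor, window, kept):
        s = make_spectrum(peaks, precursor=precursor)
        out = remove_precursor_region(s, window)
        assert out.mz.tolist() == kept

    def test_input_unmodified(self):
        s = make_spectrum([(290.0, 1.0)], precursor=300.0)
        remove_precursor_region(s, 17.0)
        assert s.mz.tolist() == [290.0]


class TestWindowFilterTopK:
    def test_few_peaks_unchanged(self):
        s = make_spectrum([(100.0 + 10 * i, i + 1.0) for i in range(6)])
        assert window_filter_top_k(s, 50.0, 6).mz.tolist() == s.mz.tolist()

    def test_dense_cluster_keeps_top_k(self):
        # 8 peaks within 10 Da: only the 6 most intense survive
        peaks = [(100.0 + i, float(i + 1)) for i in range(8)]
        out = window_filter_top_k(make_spectrum(peaks), 50.0, 6)
        assert out.mz.tolist() == [102.0 + i for i in range(6)]

    def test_distant_clusters_filtered_independently(self):
        peaks = [(100.0 + i, float(i + 1)) for i in range(7)]
        peaks += [(300.0 + i, float(i + 1)) for i in range(7)]
        out = window_filter_top_k(make_spectrum(peaks), 50.0, 6)
        assert len(out) == 12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 25))
    def test_both_filters_idempotent(self, seed, n_peaks):
        rng = np.random.default_rng(seed)
        s = random_spectrum(rng, n_peaks)
        tol = ToleranceConfig()
        f1 = remove_precursor_region(s, tol.precursor_window_da)
        assert remove_precursor_region(f1, tol.precursor_window_da).mz.tolist() == f1.mz.tolist()
        f2 = window_filter_top_k(f1, tol.window_da, tol.window_top_k)
        f3 = window_filter_top_k(f2, tol.window_da, tol.window_top_k)
        assert f3.mz.tolist() == f2.mz.tolist()
        assert f3.intensity.tolist() == f2.intensity.tolist()


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        s = filter_spectrum(random_spectrum(rng, 8))
        res = modified_cosine(s, s)
        assert res.score == pytest.approx(1.0, abs=1e-12)
        assert res.n_matched == len(s)

    def test_hand_computed_two_peak_example(self):
        # sqrt intensities a=(2,3)/sqrt13, b=(1,2)/sqrt5 -> score 8/sqrt65
        a = make_spectrum([(50.0, 4.0), (100.0, 9.0)], precursor=200.0)
        b = make_spectrum([(50.0, 1.0), (100.0, 4.0)], precursor=200.0)
        res = modified_cosine(a, b)
        assert res.score == pytest.approx(8 / math.sqrt(65), abs=1e-12)
        assert res.n_matched == 2

    def test_precursor_shift_match(self):
        # peaks differ exactly by the precursor mass difference
        a = make_spectrum([(100.0, 5.0)], precursor=200.0)
        b = make_spectrum([(114.0157, 5.0)], precursor=214.0157)
        res = modified_cosine(a, b)
        assert res.n_matched == 1
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_empty_spectrum_scores_zero(self):
        a = make_spectrum([], precursor=200.0)
        b = make_spectrum([(100.0, 5.0)], precursor=200.0)
        res = modified_cosine(a, b)
        assert res == SimilarityResult(0.0, 0)

    def test_no_match_outside_tolerance(self):
        a = make_spectrum([(100.0, 5.0)], precursor=200.0)
        b = make_spectrum([(100.2, 5.0)], precursor=200.0)
        assert modified_cosine(a, b).n_matched == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_bounds_and_match_count(self, seed):
        rng = np.random.default_rng(seed)
        a = filter_spectrum(random_spectrum(rng, int(rng.integers(1, 15)), "a"))
        b = filter_spectrum(random_spectrum(rng, int(rng.integers(1, 15)), "b"))
        ab = modified_cosine(a, b)
        ba = modified_cosine(b, a)
        assert ab.score == pytest.approx(ba.score, abs=1e-9)
        assert ab.n_matched == ba.n_matched
        assert -1e-9 <= ab.score <= 1 + 1e-9
        assert ab.n_matched <= min(len(a), len(b))

    def test_greedy_never_beats_exhaustive_optimum(self):
        rng = np.random.default_rng(11)
        checked_equal = 0
        for _ in range(200):
            a = random_spectrum(rng, int(rng.integers(1, 7)), "a")
            b = random_spectrum(rng, int(rng.integers(1, 7)), "b",
                                precursor=a.precursor_mz + float(rng.uniform(-30, 30)))
            res = modified_cosine(a, b)
            best, best_nm, n_opt = brute_force_modified_cosine(a, b)
            assert res.score <= best + 1e-9
            if n_opt == 1:
                assert res.score == pytest.approx(best, abs=1e-9)
                checked_equal += 1
        assert checked_equal > 50  # the equality branch is actually exercised

    def test_matches_matchms_on_unambiguous_spectra(self):
        """Independent cross-check against matchms' ModifiedCosine on
        spectra whose peaks are >= 1 Da apart (unique optimal pairing).

        matchms scores raw intensities, so it receives the sqrt of ours;
        the resulting score equals our sqrt-then-L2 convention.
        """
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        sim = ModifiedCosine(tolerance=0.05)
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = random_spectrum(rng, int(rng.integers(2, 9)), "a", grid=True, precursor=400.0)
            b = random_spectrum(rng, int(rng.integers(2, 9)), "b", grid=True,
                                precursor=400.0 + float(rng.integers(0, 20)))
            res = modified_cosine(a, b)
            ma = matchms.Spectrum(mz=a.mz, intensities=np.sqrt(a.intensity),
                                  metadata={"precursor_mz": a.precursor_mz})
            mb = matchms.Spectrum(mz=b.mz, intensities=np.sqrt(b.intensity),
                                  metadata={"precursor_mz": b.precursor_mz})
            out = sim.pair(ma, mb)
            assert res.score == pytest.approx(float(out["score"]), abs=1e-6)
            assert res.n_matched == int(out["matches"])
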