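"""SSA, EMD and permutation-entropy behaviour against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emdeepsd import (
    embed,
    emd_decompose,
    permutation_entropy,
    regroup_by_pe,
    sift_emd,
    ssa_decompose,
)


def naive_ssa(series, L, grouping):
    """Textbook SSA written independently: explicit Hankel build, eigen
    decomposition of X X^T, rank-1 reconstruction, loop-based diagonal
    averaging."""
    series = np.asarray(series, float)
    n = series.size
    K = n - L + 1
    X = np.empty((L, K))
    for i in range(L):
        for j in range(K):
            X[i, j] = series[i + j]
    S = X @ X.T
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    out = []
    for group in grouping:
        Xg = np.zeros_like(X)
        for comp in group:
            u = eigvec[:, comp - 1]
            Xg += np.outer(u, u) @ X
        rec = np.zeros(n)
        for pos in range(n):
            vals = [Xg[i, pos - i] for i in range(L) if 0 <= pos - i < K]
            rec[pos] = np.mean(vals)
        out.append(rec)
    return out


class TestEmbed:
    def test_small_example(self):
        np.testing.assert_array_equal(
            embed(np.array([1.0, 2, 3, 4, 5]), 2),
            [[1, 2, 3, 4], [2, 3, 4, 5]],
        )

    def test_profile_shape(self):
        assert embed(np.zeros(256), 8).shape == (8, 249)

    def test_window_out_of_range(self):
        with pytest.raises(ValueError, match="N/2"):
            embed(np.zeros(256), 200)


class TestSSA:
    def test_additive_completeness(self, rng):
        x = rng.standard_normal(256)
        dec = ssa_decompose(x)
        np.testing.assert_allclose(sum(dec.subsequences), x, atol=1e-8)

    def test_constant_series_is_pure_trend(self):
        x = np.full(64, 3.5)
        dec = ssa_decompose(x)
        np.testing.assert_allclose(dec.subsequences[0], x, atol=1e-8)
        assert np.abs(dec.subsequences[1]).max() < 1e-8
        assert np.abs(dec.subsequences[2]).max() < 1e-8

    def test_trend_and_tone_separation_matches_naive_oracle(self):
        # tone period 8 fits inside the L=8 window, so the leading triple
        # captures the trend and the next pair captures the oscillation
        t = np.arange(256.0)
        trend = 0.02 * t
        tone = 0.5 * np.sin(2 * np.pi * t / 8)
        x = trend + tone
        dec = ssa_decompose(x)
        oracle = naive_ssa(x, 8, ((1,), (2, 3), tuple(range(4, 9))))
        for mine, ref in zip(dec.subsequences, oracle):
            np.testing.assert_allclose(mine, ref, atol=1e-8)
        assert np.corrcoef(dec.subsequences[0], trend)[0, 1] > 0.99
        assert np.corrcoef(dec.subsequences[1], tone)[0, 1] > 0.99

    def test_singular_values_sorted_and_energy(self, rng):
        x = rng.standard_normal(128)
        dec = ssa_decompose(x)
        s = dec.singular_values
        assert (np.diff(s) <= 1e-10).all() and (s >= 0).all()
        # eigenvalues of the lag-covariance XX^T carry the trajectory energy
        assert np.sum(s**2) == pytest.approx(
            np.linalg.norm(embed(x, 8), "fro") ** 2, rel=1e-10
        )

    def test_non_partition_grouping_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            ssa_decompose(np.arange(64.0), grouping=((1,), (2, 3), (4, 5)))

    @settings(max_examples=25, deadline=None)
    @given(arrays(float, 64, elements=st.floats(-10, 10)))
    def test_reconstruction_property(self, x):
        dec = ssa_decompose(x, L=8)
        np.testing.assert_allclose(sum(dec.subsequences), x, atol=1e-8)


class TestEMD:
    def test_monotonic_ramp_has_no_imfs(self):
        ramp = np.linspace(0.0, 1.0, 256)
        imfs, residual = sift_emd(ramp)
        assert imfs == []
        np.testing.assert_allclose(residual, ramp)

    def test_telescoping_reconstruction(self, rng):
        x = rng.standard_normal(256)
        imfs, residual = sift_emd(x)
        np.testing.assert_allclose(sum(imfs) + residual, x, atol=1e-10)
        assert len(imfs) >= 1

    def test_pure_tone_is_first_imf(self):
        t = np.arange(256.0)
        tone = np.sin(2 * np.pi * t / 16)
        imfs, _ = sift_emd(tone)
        assert np.corrcoef(imfs[0], tone)[0, 1] > 0.99

    def test_imf_criteria_hold(self, rng):
        from emdeepsd.decomposition import _count_zero_crossings, _local_extrema

        x = rng.standard_normal(256)
        imfs, _ = sift_emd(x)
        assert len(imfs) >= 2
        for imf in imfs:
            maxima, minima = _local_extrema(imf)
            n_ext = maxima.size + minima.size
            assert abs(n_ext - _count_zero_crossings(imf)) <= 1

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="too short"):
            sift_emd(np.arange(5.0))


class TestPermutationEntropy:
    def test_monotone_series_zero(self):
        assert permutation_entropy(np.arange(100.0)) == 0.0

    def test_constant_series_zero_under_stable_ties(self):
        assert permutation_entropy(np.zeros(100)) == 0.0

    def test_iid_noise_near_one_matches_bruteforce(self, rng):
        x = rng.uniform(size=10_000)
        pe = permutation_entropy(x, m=4, tau=1)
        assert pe > 0.99
        # brute-force ordinal pattern count
        from collections import Counter

        patterns = Counter(
            tuple(np.argsort(x[i : i + 4], kind="stable"))
            for i in range(x.size - 3)
        )
        p = np.array(list(patterns.values()), float)
        p /= p.sum()
        ref = -np.sum(p * np.log(p)) / math.log(math.factorial(4))
        assert pe == pytest.approx(ref, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            permutation_entropy(np.arange(3.0))

    @settings(max_examples=25, deadline=None)
    @given(arrays(float, 50, elements=st.floats(-5, 5)))
    def test_bounded(self, x):
        assert 0.0 <= permutation_entropy(x) <= 1.0


class TestRegroupByPE:
    def test_smooth_signal_all_low_pe(self):
        t = np.arange(256.0)
        x = np.sin(2 * np.pi * t / 128) + 0.01 * t
        imfs, residual = sift_emd(x)
        e1, e2, pe = regroup_by_pe(imfs, residual)
        if (pe < 0.8).all():
            np.testing.assert_allclose(e1, 0.0, atol=1e-12)
            np.testing.assert_allclose(e2, x, atol=1e-8)

    def test_completeness(self, rng):
        x = rng.standard_normal(256)
        imfs, residual = sift_emd(x)
        e1, e2, _ = regroup_by_pe(imfs, residual)
        np.testing.assert_allclose(e1 + e2, x, atol=1e-10)

    def test_noise_plus_trend_split(self, rng):
        # known components: an irregular oscillation (itself the leading
        # mode of a white-noise series, PE ~0.95) plus a smooth trend;
        # regrouping should route the former to E1 and the latter to E2
        t = np.arange(256.0)
        trend = 0.05 * t
        fast = sift_emd(rng.standard_normal(256))[0][0]
        assert permutation_entropy(fast) >= 0.8
        dec = emd_decompose(trend + fast)
        e1, e2 = dec.subsequences
        assert np.corrcoef(e1, fast)[0, 1] > 0.9
        assert np.corrcoef(e2, trend)[0, 1] > 0.9

    def test_exactly_two_outputs_on_profiles(self, cohort):
        dec = emd_decompose(cohort.values[0])
        assert len(dec.subsequences) == 2
        assert ((dec.pe_values >= 0) & (dec.pe_values <= 1)).all()
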