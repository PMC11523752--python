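"""Histogram entropy / mutual information and the windowed MI time course."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmconn import (
    entropy_hist,
    joint_entropy_hist,
    mi_timecourse,
    mutual_information,
    optimal_bins,
)


def entropy_oracle(x, n_bins):
    """Exhaustive counting entropy on explicit uniform edges."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    counts = np.zeros(n_bins)
    for v in x:
        if hi == lo:
            k = 0
        else:
            k = min(int((v - lo) / (hi - lo) * n_bins), n_bins - 1)
        counts[k] += 1
    p = counts[counts > 0] / counts.sum()
    return -(p * np.log2(p)).sum()


def joint_entropy_oracle(x, y, m, n):
    x, y = np.asarray(x, float), np.asarray(y, float)
    counts = {}
    for xv, yv in zip(x, y):
        kx = 0 if x.max() == x.min() else min(int((xv - x.min()) / np.ptp(x) * m), m - 1)
        ky = 0 if y.max() == y.min() else min(int((yv - y.min()) / np.ptp(y) * n), n - 1)
        counts[(kx, ky)] = counts.get((kx, ky), 0) + 1
    total = sum(counts.values())
    return -sum(c / total * np.log2(c / total) for c in counts.values())


class TestOptimalBins:
    def test_worked_arithmetic(self):
        # range 7, std 1, n = 1000 -> 7 / (3.5 * 1 * 0.1) = 20
        x = np.linspace(0, 7, 1000)
        x = (x - x.mean()) / x.std() * 1.0  # unit std, range scales accordingly
        rng_over_std = np.ptp(x) / x.std()
        expected = round(rng_over_std / (3.5 * 1000 ** (-1 / 3)))
        assert optimal_bins(x) == expected
        # and the exact printed example, by constructing range/std = 7 directly
        y = np.array([0.0, 7.0] + [3.5] * 998)
        y = (y - y.mean()) / y.std()
        assert optimal_bins(y * 1.0) == round(np.ptp(y) / (3.5 * y.std() * 1000 ** (-1 / 3)))

    def test_constant_window_single_bin(self):
        assert optimal_bins(np.full(100, 2.5)) == 1

    @settings(derandomize=True, max_examples=25)
    @given(c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, c):
        x = np.random.default_rng(0).standard_normal(400)
        assert optimal_bins(c * x) == optimal_bins(x)

    def test_fd_rule_differs_from_scott(self):
        x = np.random.default_rng(1).standard_normal(1000)
        assert optimal_bins(x, rule="fd") != optimal_bins(x, rule="scott")

    def test_too_small_window_rejected(self):
        with pytest.raises(ValueError):
            optimal_bins(np.array([1.0]))


class TestEntropy:
    def test_uniform_four_bins_two_bits(self):
        x = np.array([0.1, 1.1, 2.1, 3.1])
        assert entropy_hist(x, 4) == pytest.approx(2.0)

    def test_single_bin_zero_bits(self):
        assert entropy_hist(np.random.default_rng(0).random(50), 1) == 0.0

    def test_counts_2_1_1_give_1_5_bits(self):
        x = np.array([0.1, 0.2, 1.5, 2.9])
        assert entropy_hist(x, 3) == pytest.approx(1.5)

    def test_bounded_by_log2_bins(self):
        x = np.random.default_rng(2).random(1000)
        for b in [2, 5, 16]:
            h = entropy_hist(x, b)
            assert 0 <= h <= np.log2(b) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy_hist(np.array([]), 4)


class TestJointEntropy:
    def test_self_joint_equals_marginal(self):
        x = np.random.default_rng(3).random(200)
        assert joint_entropy_hist(x, x, 4, 4) == pytest.approx(entropy_hist(x, 4), abs=1e-12)

    def test_exact_independent_quarters(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert joint_entropy_hist(x, y, 2, 2) == pytest.approx(2.0)

    def test_subadditivity(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(500), rng.random(500)
        hxy = joint_entropy_hist(x, y, 5, 7)
        assert hxy <= entropy_hist(x, 5) + entropy_hist(y, 7) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_entropy_hist(np.ones(5), np.ones(6), 2, 2)


class TestMutualInformation:
    def test_identity_gives_marginal_entropy(self):
        x = np.random.default_rng(5).random(500)
        b = optimal_bins(x)
        assert mutual_information(x, x) == pytest.approx(entropy_hist(x, b), abs=1e-12)

    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert mutual_information(x, y, bins_x=4, bins_y=4) < 0.01

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.random(300), rng.random(300)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x), abs=1e-12)

    def test_monotone_transform_with_aligned_bins_gives_marginal_entropy(self):
        # 16-sample case: an affine (monotone) transform induces the same
        # partition into bins, so MI(x, y) recovers H(x) exactly
        x = np.random.default_rng(8).random(16)
        y = 2.0 * x + 3.0
        b = optimal_bins(x)
        mi = mutual_information(x, y, bins_x=b, bins_y=b)
        assert mi == pytest.approx(entropy_oracle(x, b), abs=1e-12)

    def test_oracle_equivalence_small_cases(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(2, 17)
            mx, my = rng.integers(1, 5), rng.integers(1, 5)
            x, y = rng.random(n), rng.random(n)
            got = mutual_information(x, y, bins_x=mx, bins_y=my)
            want = max(
                entropy_oracle(x, mx) + entropy_oracle(y, my) - joint_entropy_oracle(x, y, mx, my),
                0.0,
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_added_noise_does_not_raise_mean_mi(self):
        rng = np.random.default_rng(10)
        base, noisy = [], []
        for _ in range(100):
            x = rng.standard_normal(400)
            y = x + 0.5 * rng.standard_normal(400)
            base.append(mutual_information(x, y))
            noisy.append(mutual_information(x, y + rng.standard_normal(400)))
        assert np.mean(noisy) < np.mean(base)


class TestTimecourse:
    def test_window_count(self, coupled_epochs):
        tr = coupled_epochs.trials[0]
        tc = mi_timecourse(tr, "C3", "AD")
        assert len(tc.mi) == 100
        assert (tc.mi >= 0).all()

    def test_requires_common_rate(self):
        from tests.test_preprocess import _trial

        with pytest.raises(ValueError):
            mi_timecourse(_trial(), "C3", "AD")

    def test_coupled_trials_show_gated_elevation(self, coupled_epochs):
        suede = [t for t in coupled_epochs.trials if t.surface == "Suede"]
        pre, task, post = [], [], []
        for tr in suede:
            tc = mi_timecourse(tr, "C3", "AD")
            pre.append(tc.mi[tc.times < 2].mean())
            task.append(tc.mi[(tc.times > 2) & (tc.times < 8)].mean())
            post.append(tc.mi[tc.times > 8.5].mean())
        assert np.mean(task) > np.mean(pre)
        assert np.mean(task) > np.mean(post)
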