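"""Power-Based Connectivity: grids, normalization, Spearman, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cmconn import (
    BANDS,
    SEMG_GRID,
    BandDefinition,
    matched_resolution,
    minmax_normalize,
    normality_check,
    pbc_aggregate,
    pbc_records,
    pbc_spearman,
    regrid_psd,
    welch_psd,
)


def spearman_oracle(x, y):
    """Brute-force rank (average ties) + Pearson correlation."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    return np.corrcoef(rx, ry)[0, 1]


class TestMatchedResolution:
    def test_semg_grid_has_44_points(self):
        assert len(SEMG_GRID) == 44
        assert SEMG_GRID[0] == 20 and SEMG_GRID[-1] == 149

    def test_beta_resolution_is_16_over_43(self):
        grid = matched_resolution(BANDS["beta"])
        assert grid.ebl == 17 and grid.mbl == 44
        assert grid.fr == pytest.approx(16 / 43)
        assert grid.fr_display == 0.37
        assert grid.points[0] == 14.0
        assert grid.points[-1] == pytest.approx(14 + 16)
        assert len(grid.points) == 44

    def test_mu_resolution_follows_formula_not_printed_value(self):
        grid = matched_resolution(BANDS["mu"])
        assert grid.fr == pytest.approx(5 / 43)  # 0.116..., not 0.16

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("x", 20, 20)
        with pytest.raises(ValueError):
            matched_resolution(BandDefinition("x", 20.5, 30))

    def test_band_outside_filtered_range_rejected(self):
        with pytest.raises(ValueError):
            matched_resolution(BandDefinition("x", 2, 10))


class TestWelch:
    def test_sine_peak(self):
        fs = 4000.0
        t = np.arange(int(6 * fs)) / fs
        f, p = welch_psd(np.sin(2 * np.pi * 20 * t), fs)
        assert f[np.argmax(p)] == pytest.approx(20.0, abs=0.5)

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8000)
        _, p1 = welch_psd(x, 4000.0)
        _, p2 = welch_psd(2 * x, 4000.0)
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-9)

    def test_overlap_reduces_estimator_variance(self):
        rng = np.random.default_rng(1)
        fs = 500.0
        v_overlap, v_none = [], []
        for _ in range(60):
            x = rng.standard_normal(int(8 * fs))
            _, p_o = welch_psd(x, fs, overlap=0.5)
            _, p_n = welch_psd(x, fs, overlap=0.0)
            v_overlap.append(p_o[10:200])
            v_none.append(p_n[10:200])
        assert np.var(v_overlap, axis=0).mean() < np.var(v_none, axis=0).mean()


class TestRegrid:
    def test_identity_on_native_grid(self):
        f = np.arange(10.0, 60.0)
        p = np.random.default_rng(2).random(50)
        np.testing.assert_allclose(regrid_psd(f, p, f), p)

    def test_affine_function_reproduced_exactly(self):
        f = np.arange(0.0, 200.0)
        p = 3.0 * f + 7.0
        pts = np.linspace(20, 149, 44)
        np.testing.assert_allclose(regrid_psd(f, p, pts), 3.0 * pts + 7.0, rtol=1e-12)

    def test_output_length_is_grid_length(self):
        f = np.arange(0.0, 2001.0)
        p = np.random.default_rng(3).random(len(f))
        assert len(regrid_psd(f, p, SEMG_GRID)) == 44

    def test_grid_outside_support_rejected(self):
        with pytest.raises(ValueError):
            regrid_psd(np.arange(30.0, 100.0), np.ones(70), SEMG_GRID)


class TestMinMax:
    def test_reference_vector(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_unit_range(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(minmax_normalize(x), x)

    def test_constant_vector_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize([5.0, 5.0, 5.0])
        np.testing.assert_array_equal(out, [0.0, 0.0, 0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([])


class TestSpearman:
    def test_identical_vectors(self):
        x = np.random.default_rng(4).random(44)
        rho, p, flagged = pbc_spearman(x, x)
        assert rho == pytest.approx(1.0) and not flagged

    def test_reversed_ranks(self):
        x = np.arange(44.0)
        rho, _, _ = pbc_spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_worked_example(self):
        rho, _, _ = pbc_spearman(np.array([1, 2, 3, 4, 5.0]), np.array([3, 1, 2, 5, 4.0]))
        assert rho == pytest.approx(0.6)

    def test_matches_oracle_and_monotone_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x, y = rng.random(44), rng.random(44)
            rho, _, _ = pbc_spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)
            # strictly monotone transforms leave the rank correlation fixed
            rho2, _, _ = pbc_spearman(np.exp(3 * x), y**3 + 2 * y)
            assert rho2 == pytest.approx(rho, abs=1e-12)

    def test_tied_vector_flagged(self):
        rho, p, flagged = pbc_spearman(np.ones(44), np.arange(44.0))
        assert flagged and np.isnan(rho)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pbc_spearman(np.ones(10), np.ones(11))


class TestNormalityCheck:
    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(6).exponential(size=500)
        report = normality_check(x)
        assert report.loc[0, "p"] < 0.01
        assert report.attrs["recommend_rank_correlation"]

    def test_gaussian_sample_mostly_passes(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            normality_check(rng.standard_normal(500)).loc[0, "p"] < 0.05 for _ in range(40)
        )
        assert rejections <= 8  # near the nominal 5% rate

    def test_constant_degenerate_flagged(self):
        report = normality_check(np.ones(30))
        assert report.loc[0, "degenerate"].item()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_check(np.ones(5))


class TestAggregate:
    def _records(self):
        rows = []
        for ch in ["C3", "Cz", "C4"]:
            for i, m in enumerate(["AD", "B", "FD", "CED", "FDI"]):
                for band in ["mu", "beta", "gamma", "all"]:
                    rows.append({"subject": "S01", "trial_id": "T1", "surface": "Suede",
                                 "eeg_channel": ch, "muscle": m, "band": band,
                                 "rho": 0.2 * (i + 1)})
        return pd.DataFrame(rows)

    def test_per_channel_mean_over_muscles(self):
        agg = pbc_aggregate(self._records(), "per_channel")
        row = agg[(agg.band == "beta") & (agg.eeg_channel == "C3")]
        assert row.rho.iloc[0] == pytest.approx(0.6)

    def test_per_pair_row_count(self):
        agg = pbc_aggregate(self._records(), "per_pair")
        assert len(agg) == 15  # 3 channels x 5 muscles, one surface

    def test_single_record_aggregates_to_itself(self):
        df = self._records().iloc[[0]]
        agg = pbc_aggregate(df, "per_channel")
        assert len(agg) == 1 and agg.rho.iloc[0] == df.rho.iloc[0]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pbc_aggregate(self._records(), "per_subject")


def test_feature_vectors_are_normalized_and_sized(coupled_epochs):
    df = pbc_records(coupled_epochs)
    assert set(df.band) == {"mu", "beta", "gamma", "all"}
    assert df.rho.abs().max() <= 1.0
    assert ((df.p >= 0) & (df.p <= 1)).all()
    n = len(coupled_epochs.trials)
    assert len(df) == n * 3 * 5 * 4
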