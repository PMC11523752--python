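"""Relative power and event-related desynchronization (ERD) maps.

Relative power is the percentage change of task power A against baseline
power B, ``(A - B) / B * 100``; negative values denote desynchronization.
ERD maps are Morlet-wavelet (5 cycles) time-frequency representations on a
1 Hz grid from 8 to 50 Hz with a 50 ms stride, expressed as relative power
against the pre-cue baseline interval, and masked for significance with a
bootstrap-t confidence interval on the across-trial mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "BandDefinition",
    "BANDS",
    "ERDMap",
    "psd_hanning",
    "relative_power",
    "band_power",
    "erd_time_frequency",
    "bootstrap_significance",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency band with inclusive integer-Hz edges."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("band requires f_lo < f_hi")


#: canonical bands: mu 8-13, beta 14-30, gamma 30-50, All 8-50 Hz
BANDS: dict[str, BandDefinition] = {
    "mu": BandDefinition("mu", 8, 13),
    "beta": BandDefinition("beta", 14, 30),
    "gamma": BandDefinition("gamma", 30, 50),
    "all": BandDefinition("all", 8, 50),
}


@dataclass
class ERDMap:
    times: np.ndarray  # window centers, s
    freqs: np.ndarray  # Hz
    values: np.ndarray  # (n_freqs, n_times) mean relative power, %
    per_trial: np.ndarray  # (n_trials, n_freqs, n_times)
    sig_mask: np.ndarray | None = None
    alpha: float = 0.05


def psd_hanning(
    x: np.ndarray, fs: float, window_s: float = 1.0, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram PSD with a Hann window at 50% overlap (1 Hz step)."""
    x = np.asarray(x, dtype=float)
    nperseg = round(window_s * fs)
    if x.shape[-1] < nperseg:
        raise ValueError("segment shorter than one analysis window")
    return _sig.welch(x, fs=fs, window="hann", nperseg=nperseg,
                      noverlap=round(nperseg * overlap), axis=-1)


def relative_power(a: float | np.ndarray, b: float | np.ndarray) -> float | np.ndarray:
    """Percent change of task power ``a`` relative to baseline power ``b``."""
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr <= 0):
        raise ValueError("baseline power must be strictly positive")
    out = (np.asarray(a, dtype=float) - b_arr) / b_arr * 100.0
    return float(out) if out.ndim == 0 else out


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> float | np.ndarray:
    """Integrated PSD over ``band`` (trapezoid on the native grid)."""
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if mask.sum() < 2:
        raise ValueError("band spans fewer than two frequency bins")
    return np.trapezoid(np.asarray(psd)[..., mask], freqs[mask], axis=-1)


def erd_time_frequency(
    epochs: np.ndarray,
    fs: float,
    baseline: tuple[float, float] = (0.0, 2.0),
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
    stride_s: float = 0.05,
    per_trial_baseline: bool = False,
    edge_trim_s: float = 0.25,
) -> ERDMap:
    """Morlet ERD map for trials aligned to t = 0.

    Parameters
    ----------
    epochs : (n_trials, n_samples) array of one channel's trials.
    per_trial_baseline : divide each trial by its own mean baseline power
        instead of the trial-average baseline power.  The trial-average is
        the default: a narrowband per-trial baseline carries few degrees of
        freedom, and dividing by it biases the power ratio upward.
    edge_trim_s : margin excluded from the start of the baseline window so
        that boundary transients (wavelet support and filter edges crossing
        t = 0) do not contaminate the baseline statistic.
    """
    from mne.time_frequency import tfr_array_morlet

    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if freqs is None:
        freqs = np.arange(8.0, 51.0, 1.0)
    n_base = round(baseline[1] * fs)
    if epochs.shape[1] < n_base:
        raise ValueError("trials shorter than the baseline window")
    decim = max(round(stride_s * fs), 1)
    power = tfr_array_morlet(
        epochs[:, None, :], sfreq=fs, freqs=freqs, n_cycles=n_cycles,
        output="power", decim=decim, zero_mean=True, verbose="error",
    )[:, 0]  # (n_trials, n_freqs, n_times)
    times = np.arange(power.shape[-1]) * decim / fs
    base_cols = (times >= max(baseline[0], edge_trim_s)) & (times < baseline[1])
    base = power[:, :, base_cols].mean(axis=-1, keepdims=True)
    if not per_trial_baseline:
        base = base.mean(axis=0, keepdims=True)
    per_trial = (power - base) / base * 100.0
    return ERDMap(times=times, freqs=np.asarray(freqs), values=per_trial.mean(axis=0),
                  per_trial=per_trial)


def bootstrap_significance(
    per_trial: np.ndarray,
    alpha: float = 0.05,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Bootstrap-t mask: True where the two-sided CI for the mean excludes 0.

    Trials are resampled with replacement; the same resamples are used for
    every cell, which leaves each cell's marginal bootstrap distribution
    intact while keeping the map computation vectorized.
    """
    per_trial = np.asarray(per_trial, dtype=float)
    n = per_trial.shape[0]
    if n < 5:
        raise ValueError("need at least 5 trials for the bootstrap")
    if n_boot < 200:
        raise ValueError("need at least 200 bootstrap resamples")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cells = per_trial.reshape(n, -1)
    mean = cells.mean(axis=0)
    se = cells.std(axis=0, ddof=1) / np.sqrt(n)

    idx = rng.integers(0, n, size=(n_boot, n))
    counts = np.zeros((n_boot, n))
    for b in range(n_boot):  # bincount per resample; cheap versus the matmuls
        counts[b] = np.bincount(idx[b], minlength=n)
    w = counts / n
    m_b = w @ cells
    q_b = w @ (cells**2)
    var_b = np.clip((q_b - m_b**2) * n / (n - 1), 0.0, None)
    se_b = np.sqrt(var_b / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_b = np.where(se_b > 0, (m_b - mean) / se_b, 0.0)
    t_lo = np.quantile(t_b, alpha / 2, axis=0)
    t_hi = np.quantile(t_b, 1 - alpha / 2, axis=0)
    ci_lo = mean - t_hi * se
    ci_hi = mean - t_lo * se
    sig = (ci_lo > 0) | (ci_hi < 0)
    # degenerate cells (zero spread) are significant iff their mean is nonzero
    sig[se == 0] = mean[se == 0] != 0
    return sig.reshape(per_trial.shape[1:])
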