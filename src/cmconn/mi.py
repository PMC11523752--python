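"""Windowed histogram mutual information between EEG and sEMG.

Within each adjacent 100 ms window the two signals are discretized into
histograms whose bin count follows the std-based rule

    bins = (max(x) - min(x)) / (3.5 * std(x) * n^(-1/3)),

rounded to the nearest integer (floor 1, cap 256).  Entropies are in bits;
mutual information is MI = H(X) + H(Y) - H(X, Y), with the marginal
entropies taken from the joint histogram's margins so that MI >= 0 holds by
construction.  No lag scan is performed: windows are compared at zero delay.

An IQR-based Freedman-Diaconis bin rule is available behind ``rule="fd"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .synth import TrialRecording

__all__ = [
    "MITimecourse",
    "optimal_bins",
    "entropy_hist",
    "joint_entropy_hist",
    "mutual_information",
    "mi_timecourse",
    "mi_table",
]

MAX_BINS = 256


@dataclass
class MITimecourse:
    times: np.ndarray  # window centers, s
    mi: np.ndarray  # bits, one value per window
    eeg_channel: str = ""
    muscle: str = ""

    def __post_init__(self) -> None:
        if np.any(self.mi < 0):
            raise ValueError("mutual information cannot be negative")


def optimal_bins(x: np.ndarray, rule: str = "scott") -> int:
    """Histogram bin count for one window.

    ``rule="scott"`` (default) uses the std-based width 3.5*std*n^(-1/3);
    ``rule="fd"`` uses the Freedman-Diaconis IQR-based width 2*IQR*n^(-1/3).
    Degenerate windows (zero spread) get a single bin.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples to choose a bin count")
    rng = np.ptp(x)
    if rule == "scott":
        width = 3.5 * x.std() * n ** (-1.0 / 3.0)
    elif rule == "fd":
        q75, q25 = np.percentile(x, [75, 25])
        width = 2.0 * (q75 - q25) * n ** (-1.0 / 3.0)
    else:
        raise ValueError(f"unknown bin rule {rule!r}")
    if width == 0 or rng == 0:
        return 1
    return int(np.clip(round(rng / width), 1, MAX_BINS))


def _probabilities(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return counts[counts > 0] / total


def entropy_hist(x: np.ndarray, n_bins: int) -> float:
    """Shannon entropy (bits) of the histogram of ``x`` with ``n_bins`` bins."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    counts, _ = np.histogram(x, bins=n_bins)
    p = _probabilities(counts)
    return float(-(p * np.log2(p)).sum())


def joint_entropy_hist(x: np.ndarray, y: np.ndarray, m_bins: int, n_bins: int) -> float:
    """Joint entropy (bits) on an m x n histogram with per-signal edges."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    counts, _, _ = np.histogram2d(x, y, bins=[m_bins, n_bins])
    p = _probabilities(counts)
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    bins_x: int | None = None,
    bins_y: int | None = None,
    rule: str = "scott",
) -> float:
    """MI(X, Y) = H(X) + H(Y) - H(X, Y) in bits (zero lag).

    Bin counts default to :func:`optimal_bins` per signal.  Marginal entropies
    are computed from the joint histogram's margins, which is algebraically
    identical to separate histograms on the same edges and guarantees a
    non-negative result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    mx = bins_x if bins_x is not None else optimal_bins(x, rule)
    ny = bins_y if bins_y is not None else optimal_bins(y, rule)
    joint, _, _ = np.histogram2d(x, y, bins=[mx, ny])
    px = _probabilities(joint.sum(axis=1))
    py = _probabilities(joint.sum(axis=0))
    pxy = _probabilities(joint)
    hx = -(px * np.log2(px)).sum()
    hy = -(py * np.log2(py)).sum()
    hxy = -(pxy * np.log2(pxy)).sum()
    return float(max(hx + hy - hxy, 0.0))


def mi_timecourse(
    trial: TrialRecording,
    eeg_channel: str,
    muscle: str,
    window_s: float = 0.1,
    rule: str = "scott",
) -> MITimecourse:
    """MI per adjacent ``window_s`` window over the whole trial (zero overlap).

    Requires both modalities at a common sampling rate (post-preprocessing).
    """
    if trial.fs_eeg != trial.fs_emg:
        raise ValueError("EEG and sEMG must share a sampling rate; preprocess first")
    fs = trial.fs_eeg
    x = trial.eeg_channel(eeg_channel)
    y = trial.emg_channel(muscle)
    w = round(window_s * fs)
    n = min(x.size, y.size)
    if n < w:
        raise ValueError("trial shorter than one MI window")
    n_win = n // w
    mi = np.empty(n_win)
    for k in range(n_win):
        sl = slice(k * w, (k + 1) * w)
        mi[k] = mutual_information(x[sl], y[sl], rule=rule)
    times = (np.arange(n_win) + 0.5) * w / fs
    return MITimecourse(times=times, mi=mi, eeg_channel=eeg_channel, muscle=muscle)


def mi_table(
    epochs: EpochSet,
    window_s: float = 0.1,
    analysis_channels: tuple[str, ...] | None = None,
    rule: str = "scott",
) -> pd.DataFrame:
    """Tidy per-window MI for every (trial, channel, muscle) combination."""
    rows = []
    for tr in epochs.trials:
        channels = analysis_channels or tuple(
            c for c in tr.eeg_channels if not c.startswith("REF")
        )
        for ch in channels:
            for m in tr.muscles:
                tc = mi_timecourse(tr, ch, m, window_s=window_s, rule=rule)
                for t, v in zip(tc.times, tc.mi):
                    rows.append(
                        {
                            "subject": tr.subject_id,
                            "trial_id": tr.trial_id,
                            "surface": tr.surface,
                            "eeg_channel": ch,
                            "muscle": m,
                            "time": float(t),
                            "mi": float(v),
                        }
                    )
    return pd.DataFrame(rows)
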