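"""Muscle-activation summaries from sEMG root-mean-square envelopes.

The envelope is the RMS over a 300 ms sliding window with 50% overlap,
computed on the band-filtered task segment.  Activation is compared across
contact surfaces per muscle with the group-comparison machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet, split_epochs
from .stats import GroupComparisonResult, compare_groups

__all__ = ["EnvelopeSeries", "rms_envelope", "activation_table", "summarize_activation"]


@dataclass
class EnvelopeSeries:
    times: np.ndarray  # window centers, s
    rms: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.rms < 0):
            raise ValueError("RMS values cannot be negative")


def rms_envelope(
    x: np.ndarray, fs: float, window_s: float = 0.3, overlap: float = 0.5
) -> EnvelopeSeries:
    """RMS over sliding windows; incomplete trailing windows are dropped."""
    x = np.asarray(x, dtype=float)
    w = round(window_s * fs)
    if x.shape[-1] < w:
        raise ValueError("signal shorter than one RMS window")
    hop = max(round(w * (1.0 - overlap)), 1)
    n_win = (x.shape[-1] - w) // hop + 1
    starts = np.arange(n_win) * hop
    vals = np.array([np.sqrt(np.mean(x[s : s + w] ** 2)) for s in starts])
    times = (starts + w / 2) / fs
    return EnvelopeSeries(times=times, rms=vals)


def activation_table(epochs: EpochSet, window_s: float = 0.3, overlap: float = 0.5) -> pd.DataFrame:
    """Tidy per-trial activation: mean task-segment RMS per muscle."""
    rows = []
    for tr in epochs.trials:
        _, task = split_epochs(tr)
        for m in tr.muscles:
            env = rms_envelope(task.emg_channel(m), tr.fs_emg, window_s, overlap)
            rows.append(
                {
                    "subject": tr.subject_id,
                    "trial_id": tr.trial_id,
                    "surface": tr.surface,
                    "muscle": m,
                    "mean_rms": float(env.rms.mean()),
                }
            )
    return pd.DataFrame(rows)


def summarize_activation(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, GroupComparisonResult]]:
    """Per-muscle mean RMS per surface plus a surface comparison per muscle.

    Expects the tidy table from :func:`activation_table`.  Subject-level means
    (over trials) are the unit of analysis for the group test.
    """
    if table["surface"].nunique() < 2:
        raise ValueError("need at least two surfaces to compare")
    summary = (
        table.groupby(["muscle", "surface"])["mean_rms"].agg(["mean", "std", "count"]).reset_index()
    )
    tests: dict[str, GroupComparisonResult] = {}
    subj = table.groupby(["muscle", "surface", "subject"])["mean_rms"].mean().reset_index()
    for muscle, grp in subj.groupby("muscle"):
        tests[str(muscle)] = compare_groups(
            grp["mean_rms"].to_numpy(), grp["surface"].to_numpy(), factor="surface"
        )
    return summary, tests
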