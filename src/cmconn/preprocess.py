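"""Signal conditioning and trial rejection.

Fixed stage order: resample EEG to the sEMG rate -> common average reference
-> zero-phase Butterworth band-pass (EEG 6-50 Hz, sEMG 20-150 Hz) -> 50 Hz
notch -> amplitude-based trial rejection -> baseline/task epoch split.

"Eighth-order zero-phase" is realized as a 4th-order Butterworth applied
forward-backward, i.e. an 8th-order zero-phase magnitude response; set
``literal_order=True`` to instead run the stated order twice (16th-order
effective).
"""

from __future__ import annotations

import copy

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synth import TrialRecording

__all__ = [
    "PreprocessConfig",
    "EpochSet",
    "resample_eeg",
    "apply_car",
    "filter_signal",
    "reject_trials",
    "split_epochs",
    "preprocess_trial",
    "preprocess_session",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 4000.0
    eeg_band: tuple[float, float] = (6.0, 50.0)
    emg_band: tuple[float, float] = (20.0, 150.0)
    notch_freq: float = 50.0
    notch_q: float = 25.0
    reject_threshold_uv: float = 350.0
    max_reject_fraction: float = 0.10
    filter_order: int = 8  # effective zero-phase order
    literal_order: bool = False
    reject_on_filtered: bool = True

    def __post_init__(self) -> None:
        for band in (self.eeg_band, self.emg_band):
            if not (0 < band[0] < band[1] < self.target_fs / 2):
                raise ValueError(f"band {band} must satisfy 0 < lo < hi < Nyquist")
        if self.reject_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")


@dataclass
class EpochSet:
    """Retained analysis-ready trials plus the rejection audit trail."""

    trials: list[TrialRecording]
    rejected_trial_ids: list[str]
    subject_flagged: bool
    report: pd.DataFrame
    baseline_window: tuple[float, float] = (0.0, 2.0)


def resample_eeg(trial: TrialRecording, target_fs: float) -> TrialRecording:
    """Polyphase-resample the EEG to ``target_fs`` (rational ratio required)."""
    if target_fs < trial.fs_eeg:
        raise ValueError("target rate must not be below the original EEG rate")
    ratio = target_fs / trial.fs_eeg
    num, den = _as_small_fraction(ratio)
    # sharp kaiser anti-imaging filter: round-trip error well below 1e-6
    eeg = signal.resample_poly(trial.eeg, num, den, axis=1, window=("kaiser", 14.0))
    out = copy.copy(trial)
    out.eeg = eeg
    out.fs_eeg = float(target_fs)
    return out


def _as_small_fraction(x: float, max_den: int = 1000) -> tuple[int, int]:
    from fractions import Fraction

    fr = Fraction(x).limit_denominator(max_den)
    if abs(float(fr) - x) > 1e-9:
        raise ValueError(f"resampling ratio {x} is not a small rational number")
    return fr.numerator, fr.denominator


def apply_car(eeg: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the per-sample cross-channel mean."""
    eeg = np.asarray(eeg)
    if eeg.ndim != 2 or eeg.shape[0] < 2:
        raise ValueError("CAR needs at least two channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


def filter_signal(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] | float,
    order: int = 8,
    kind: str = "bandpass",
    notch_q: float = 25.0,
    literal_order: bool = False,
) -> np.ndarray:
    """Zero-phase band-pass or notch filtering along the last axis."""
    x = np.asarray(x, dtype=float)
    if kind == "bandpass":
        lo, hi = band  # type: ignore[misc]
        if not (0 < lo < hi < fs / 2):
            raise ValueError("band edges must lie strictly inside (0, Nyquist)")
        design_order = order if literal_order else max(order // 2, 1)
        sos = signal.butter(design_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        return signal.sosfiltfilt(sos, x, axis=-1)
    if kind == "notch":
        f0 = band if np.isscalar(band) else band[0]  # type: ignore[assignment]
        if not (0 < f0 < fs / 2):
            raise ValueError("notch frequency must lie below Nyquist")
        b, a = signal.iirnotch(f0, notch_q, fs=fs)
        return signal.filtfilt(b, a, x, axis=-1)
    raise ValueError(f"unknown filter kind {kind!r}")


def reject_trials(
    trials: list[TrialRecording],
    threshold_uv: float = 350.0,
    max_fraction: float = 0.10,
) -> EpochSet:
    """Drop any trial whose EEG exceeds +/-threshold on any channel.

    Rejection removes the trial from EEG and sEMG alike.  When the rejected
    fraction exceeds ``max_fraction`` the subject flag is raised.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if not trials:
        raise ValueError("no trials to screen")
    rows = []
    kept: list[TrialRecording] = []
    rejected: list[str] = []
    for tr in trials:
        peak = float(np.abs(tr.eeg).max())
        bad = peak > threshold_uv
        rows.append({"trial_id": tr.trial_id, "max_abs_uv": peak, "rejected": bad})
        if bad:
            rejected.append(tr.trial_id)
        else:
            kept.append(tr)
    frac = len(rejected) / len(trials)
    report = pd.DataFrame(rows)
    cue = trials[0].cue_time_s
    return EpochSet(
        trials=kept,
        rejected_trial_ids=rejected,
        subject_flagged=frac > max_fraction,
        report=report,
        baseline_window=(0.0, cue),
    )


def split_epochs(trial: TrialRecording) -> tuple[TrialRecording, TrialRecording]:
    """Split into baseline [0, cue) and task [cue, end] segments (no shared sample)."""
    cue = trial.cue_time_s
    if trial.duration_s <= cue:
        raise ValueError("trial shorter than the baseline window")
    i_eeg = round(cue * trial.fs_eeg)
    i_emg = round(cue * trial.fs_emg)
    baseline = copy.copy(trial)
    task = copy.copy(trial)
    baseline.eeg, task.eeg = trial.eeg[:, :i_eeg], trial.eeg[:, i_eeg:]
    baseline.emg, task.emg = trial.emg[:, :i_emg], trial.emg[:, i_emg:]
    return baseline, task


def preprocess_trial(trial: TrialRecording, cfg: PreprocessConfig | None = None) -> TrialRecording:
    """Resample -> CAR -> band-pass -> notch for one trial (both modalities).

    Reference-only channels (labels starting with ``REF``) take part in the
    common average and are then dropped: only analysis channels are filtered,
    screened and carried downstream.
    """
    cfg = cfg or PreprocessConfig()
    out = resample_eeg(trial, cfg.target_fs) if trial.fs_eeg != cfg.target_fs else copy.copy(trial)
    eeg = apply_car(out.eeg)
    keep = [i for i, c in enumerate(out.eeg_channels) if not c.startswith("REF")]
    if len(keep) < len(out.eeg_channels):
        eeg = eeg[keep]
        out.eeg_channels = tuple(out.eeg_channels[i] for i in keep)
    eeg = filter_signal(eeg, cfg.target_fs, cfg.eeg_band, cfg.filter_order, "bandpass",
                        literal_order=cfg.literal_order)
    eeg = filter_signal(eeg, cfg.target_fs, cfg.notch_freq, kind="notch", notch_q=cfg.notch_q)
    emg = filter_signal(out.emg, trial.fs_emg, cfg.emg_band, cfg.filter_order, "bandpass",
                        literal_order=cfg.literal_order)
    emg = filter_signal(emg, trial.fs_emg, cfg.notch_freq, kind="notch", notch_q=cfg.notch_q)
    out.eeg, out.emg = eeg, emg
    return out


def preprocess_session(
    trials: list[TrialRecording], cfg: PreprocessConfig | None = None
) -> EpochSet:
    """Full conditioning of a trial list, then amplitude-based rejection.

    With ``reject_on_filtered=False`` the threshold is applied to the raw EEG
    instead of the referenced/filtered EEG.
    """
    cfg = cfg or PreprocessConfig()
    processed = [preprocess_trial(tr, cfg) for tr in trials]
    if cfg.reject_on_filtered:
        epochs = reject_trials(processed, cfg.reject_threshold_uv, cfg.max_reject_fraction)
    else:
        raw_screen = reject_trials(trials, cfg.reject_threshold_uv, cfg.max_reject_fraction)
        keep_ids = {t.trial_id for t in raw_screen.trials}
        epochs = EpochSet(
            trials=[t for t in processed if t.trial_id in keep_ids],
            rejected_trial_ids=raw_screen.rejected_trial_ids,
            subject_flagged=raw_screen.subject_flagged,
            report=raw_screen.report,
            baseline_window=raw_screen.baseline_window,
        )
    return epochs
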