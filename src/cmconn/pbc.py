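"""Power-Based Connectivity (PBC).

PBC rank-correlates length-matched, min-max-normalized Welch PSD feature
vectors of an EEG band and a muscle's 20-150 Hz sEMG spectrum.  The sEMG
feature grid is fixed at 20, 23, ..., 149 Hz (3 Hz resolution, MBL = 44
points); each EEG band is re-gridded from its native 1 Hz resolution onto 44
points spaced FR = (EBL - 1)/(MBL - 1) Hz apart, where EBL counts the band's
integer frequencies inclusive.  For the beta band (14-30 Hz) this gives
FR = 16/43 ~= 0.37 Hz.

Because the normalized PSD features are generally non-normal (checked with a
one-sample Kolmogorov-Smirnov test), the correlation is Spearman's rank
coefficient, tested one-sided for connectivity greater than zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as sps

from .preprocess import EpochSet
from .spectral import BANDS, BandDefinition

__all__ = [
    "SEMG_GRID",
    "FrequencyGrid",
    "ConnectivityRecord",
    "welch_psd",
    "matched_resolution",
    "regrid_psd",
    "minmax_normalize",
    "psd_feature_vector",
    "pbc_spearman",
    "normality_check",
    "pbc_records",
    "pbc_aggregate",
]

#: sEMG feature frequencies: 20 to 150 Hz exclusive in 3 Hz steps -> 44 points
SEMG_GRID: np.ndarray = np.arange(20.0, 150.0, 3.0)
MBL: int = len(SEMG_GRID)  # 44


@dataclass(frozen=True)
class FrequencyGrid:
    """Matched-resolution EEG feature grid for one band."""

    band: BandDefinition
    ebl: int
    mbl: int
    fr: float
    points: np.ndarray

    @property
    def fr_display(self) -> float:
        """The resolution rounded to two decimals, as conventionally reported."""
        return round(self.fr, 2)


@dataclass
class ConnectivityRecord:
    eeg_channel: str
    muscle: str
    band: str
    surface: str
    subject: str
    trial_id: str
    rho: float
    p: float
    flagged: bool = False


def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD: Hamming-windowed 1 s segments at 50% overlap (1 Hz spacing)."""
    x = np.asarray(x, dtype=float)
    nperseg = round(segment_s * fs)
    if x.shape[-1] < nperseg:
        raise ValueError("segment shorter than one Welch window")
    return _sig.welch(x, fs=fs, window=window, nperseg=nperseg,
                      noverlap=round(nperseg * overlap), axis=-1)


def matched_resolution(band: BandDefinition) -> FrequencyGrid:
    """Matched EEG resolution FR = (EBL - 1)/(MBL - 1) and its feature grid."""
    f_lo, f_hi = band.f_lo, band.f_hi
    if f_lo != int(f_lo) or f_hi != int(f_hi):
        raise ValueError("band edges must be integers (native 1 Hz resolution)")
    if not (8 <= f_lo < f_hi <= 50):
        raise ValueError("EEG band must lie within the filtered 8-50 Hz range")
    ebl = int(f_hi) - int(f_lo) + 1
    if ebl < 2:
        raise ValueError("degenerate band: matched resolution would be zero")
    fr = (ebl - 1) / (MBL - 1)
    points = f_lo + fr * np.arange(MBL)
    return FrequencyGrid(band=band, ebl=ebl, mbl=MBL, fr=fr, points=points)


def regrid_psd(freqs: np.ndarray, psd: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Linear interpolation of a native PSD onto target frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    points = np.asarray(points, dtype=float)
    if points.min() < freqs.min() - 1e-9 or points.max() > freqs.max() + 1e-9:
        raise ValueError("target grid lies outside the native frequency support")
    return np.interp(points, freqs, psd)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max scaling to [0, 1]; a constant vector maps to zeros with a warning."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant feature vector: min-max normalization returns zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def psd_feature_vector(
    x: np.ndarray, fs: float, points: np.ndarray
) -> np.ndarray:
    """Welch PSD -> linear regrid onto ``points`` -> min-max normalization."""
    freqs, psd = welch_psd(x, fs)
    return minmax_normalize(regrid_psd(freqs, psd, points))


def pbc_spearman(eeg_features: np.ndarray, emg_features: np.ndarray) -> tuple[float, float, bool]:
    """Spearman rho between matched feature vectors; one-sided p for rho > 0.

    Returns ``(rho, p, flagged)``; ``flagged`` marks degenerate (all-tied)
    inputs where the coefficient is undefined.
    """
    eeg_features = np.asarray(eeg_features, dtype=float)
    emg_features = np.asarray(emg_features, dtype=float)
    if eeg_features.shape != emg_features.shape:
        raise ValueError("feature vectors must have equal length")
    if np.ptp(eeg_features) == 0 or np.ptp(emg_features) == 0:
        return float("nan"), float("nan"), True
    res = sps.spearmanr(eeg_features, emg_features, alternative="greater")
    return float(res.statistic), float(res.pvalue), False


def normality_check(features: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """One-sample KS normality screen across feature sets.

    ``features`` is (n_samples, n_sets) or 1-D; each column is tested against
    a moment-fitted normal.  The report carries a per-set recommendation and
    implies rank correlation when any set rejects normality.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 1:
        features = features.T
    if features.shape[0] < 20:
        raise ValueError("need at least 20 samples per feature set")
    rows = []
    for j in range(features.shape[1]):
        x = features[:, j]
        sd = x.std(ddof=1)
        if sd == 0:
            rows.append({"feature_set": j, "ks_stat": np.nan, "p": np.nan,
                         "normal": False, "degenerate": True})
            continue
        res = sps.kstest(x, "norm", args=(x.mean(), sd))
        rows.append({"feature_set": j, "ks_stat": float(res.statistic),
                     "p": float(res.pvalue), "normal": res.pvalue > alpha,
                     "degenerate": False})
    report = pd.DataFrame(rows)
    report.attrs["recommend_rank_correlation"] = bool((~report["normal"]).any())
    return report


def _spearman_block(eeg_feats: np.ndarray, emg_feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho and one-sided (rho > 0) p for all pairs.

    ``eeg_feats`` is (A, n) and ``emg_feats`` is (B, n); returns (A, B)
    matrices.  Identical to :func:`pbc_spearman` (rank then Pearson; p from
    the t approximation) but without per-pair call overhead.
    """
    n = eeg_feats.shape[-1]
    ra = sps.rankdata(eeg_feats, axis=-1)
    rb = sps.rankdata(emg_feats, axis=-1)
    ra = ra - ra.mean(axis=-1, keepdims=True)
    rb = rb - rb.mean(axis=-1, keepdims=True)
    na = np.sqrt((ra**2).sum(axis=-1))
    nb = np.sqrt((rb**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra @ rb.T) / np.outer(na, nb)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = sps.t.sf(t, n - 2)
    flagged = np.isnan(rho)
    p = np.where(flagged, np.nan, p)
    return rho, p


def pbc_records(
    epochs: EpochSet,
    bands: dict[str, BandDefinition] | None = None,
    analysis_channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-trial PBC records over all (channel, muscle, band) combinations.

    Features are computed on the movement segment [cue, replace] of each
    trial; rest-period connectivity is not estimated.
    """
    bands = bands or BANDS
    grids = {name: matched_resolution(b) for name, b in bands.items()}
    rows = []
    for tr in epochs.trials:
        channels = analysis_channels or tuple(
            c for c in tr.eeg_channels if not c.startswith("REF")
        )
        i0e = round(tr.cue_time_s * tr.fs_eeg)
        i1e = round(tr.replace_time_s * tr.fs_eeg)
        i0m = round(tr.cue_time_s * tr.fs_emg)
        i1m = round(tr.replace_time_s * tr.fs_emg)
        emg_feats = np.stack([
            psd_feature_vector(tr.emg_channel(m)[i0m:i1m], tr.fs_emg, SEMG_GRID)
            for m in tr.muscles
        ])
        eeg_feats = []
        combos = []
        for ch in channels:
            seg = tr.eeg_channel(ch)[i0e:i1e]
            freqs, psd = welch_psd(seg, tr.fs_eeg)
            for bname, grid in grids.items():
                eeg_feats.append(minmax_normalize(regrid_psd(freqs, psd, grid.points)))
                combos.append((ch, bname))
        rho, p = _spearman_block(np.stack(eeg_feats), emg_feats)
        for i, (ch, bname) in enumerate(combos):
            for j, m in enumerate(tr.muscles):
                rows.append(
                    {
                        "subject": tr.subject_id,
                        "trial_id": tr.trial_id,
                        "surface": tr.surface,
                        "eeg_channel": ch,
                        "muscle": m,
                        "band": bname,
                        "rho": rho[i, j],
                        "p": p[i, j],
                        "flagged": bool(np.isnan(rho[i, j])),
                    }
                )
    return pd.DataFrame(rows)


def pbc_aggregate(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Aggregate per-trial records to subject-level means.

    * ``per_channel``: mean rho over muscles and trials per
      (subject, surface, band, eeg_channel);
    * ``per_muscle``: mean over EEG channels and trials per
      (subject, surface, band, muscle);
    * ``per_pair``: mean over trials per (subject, surface, channel, muscle)
      in the broadband 8-50 Hz ("all") band.
    """
    if not len(records):
        raise ValueError("no connectivity records to aggregate")
    if mode == "per_channel":
        keys = ["subject", "surface", "band", "eeg_channel"]
        df = records
    elif mode == "per_muscle":
        keys = ["subject", "surface", "band", "muscle"]
        df = records
    elif mode == "per_pair":
        keys = ["subject", "surface", "eeg_channel", "muscle"]
        df = records[records["band"] == "all"]
        if not len(df):
            raise ValueError("per_pair aggregation needs 'all'-band records")
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return df.groupby(keys, as_index=False)["rho"].mean()
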