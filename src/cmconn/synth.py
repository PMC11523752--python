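"""Trial-structured synthetic EEG + sEMG sessions with known ground truth.

The generator emulates a cued reach-grasp-lift-replace paradigm: 2 s of rest,
a visual cue, object manipulation until ~8 s, then replacement.  Each trial
carries

* per-channel cortical background (1/f noise) plus narrow-band mu (10 Hz) and
  beta (20 Hz) oscillations; the mu amplitude is multiplied by
  ``erd_amplitude_factor`` from the cue onward, so event-related
  desynchronization depth is a known quantity;
* movement-gated surface EMG: band-limited (20-150 Hz) noise whose envelope
  ramps up between cue and replace, with per-muscle activation scales;
* a shared band-limited latent drive ``D(t)`` (14-30 Hz by default), gated to
  the movement interval, mixed into every EEG channel and (resampled to the
  EMG rate) into every muscle with gain ``kappa * g``.  ``kappa`` is the
  per-surface coupling gain that downstream connectivity estimators should
  recover.

Extra "reference-only" EEG channels containing pure background are generated
so that common-average referencing does not cancel the shared drive the way
it would in a 3-channel montage; they are never analyzed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.fft import irfft, rfft, rfftfreq
from scipy.signal import resample_poly

__all__ = [
    "SessionSpec",
    "TrialRecording",
    "GroundTruthRecord",
    "generate_trial",
    "generate_session",
    "export_ground_truth",
    "load_ground_truth",
    "save_session",
    "load_session",
]

DEFAULT_SURFACES = ("Sandpaper", "Suede", "Silk")
DEFAULT_KAPPA = {"Sandpaper": 0.6, "Suede": 1.0, "Silk": 0.3}
DEFAULT_EEG_CHANNELS = ("C3", "Cz", "C4")
DEFAULT_MUSCLES = ("AD", "B", "FD", "CED", "FDI")
#: mixing gain of the latent drive into each analysis EEG channel
DEFAULT_CHANNEL_DRIVE_GAIN = {"C3": 1.1, "Cz": 1.0, "C4": 0.9}
#: coupling gain of the drive into each muscle, proportional to the muscle's
#: activation amplitude so that the drive's *share* of each muscle's variance
#: is comparable; AD carries twice the relative coupling of every other muscle
DEFAULT_MUSCLE_DRIVE_GAIN = {"AD": 3.2, "B": 1.1, "FD": 0.7, "CED": 1.3, "FDI": 0.9}
#: tonic-to-peak activation scale per muscle (AD > CED > B > FDI > FD)
DEFAULT_MUSCLE_AMPLITUDE = {"AD": 1.6, "B": 1.1, "FD": 0.7, "CED": 1.3, "FDI": 0.9}


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic recording campaign."""

    n_subjects: int = 12
    n_trials_per_surface: int = 11
    surfaces: tuple[str, ...] = DEFAULT_SURFACES
    coupling_gain_per_surface: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KAPPA)
    )
    erd_amplitude_factor: float = 0.5
    trial_duration_s: float = 10.0
    cue_time_s: float = 2.0
    replace_time_s: float = 8.0
    fs_eeg: int = 500
    fs_emg: int = 4000
    eeg_channels: tuple[str, ...] = DEFAULT_EEG_CHANNELS
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    noise_sd: float = 0.4
    mu_amplitude: float = 1.0
    beta_amplitude: float = 0.3
    gamma_floor_sd: float = 2.0
    drive_band: tuple[float, float] = (14.0, 30.0)
    channel_drive_gain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_DRIVE_GAIN)
    )
    muscle_drive_gain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUSCLE_DRIVE_GAIN)
    )
    muscle_amplitude: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUSCLE_AMPLITUDE)
    )
    n_reference_channels: int = 5
    subject_kappa_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cue_time_s < self.replace_time_s < self.trial_duration_s):
            raise ValueError("need cue_time_s < replace_time_s < trial_duration_s")
        if self.n_trials_per_surface < 1:
            raise ValueError("n_trials_per_surface must be >= 1")
        if not (0 < self.erd_amplitude_factor <= 1):
            raise ValueError("erd_amplitude_factor must lie in (0, 1]")
        if self.fs_emg % self.fs_eeg != 0:
            raise ValueError("fs_emg must be an integer multiple of fs_eeg")
        for s in self.surfaces:
            k = self.coupling_gain_per_surface.get(s)
            if k is None or k < 0:
                raise ValueError(f"coupling gain for surface {s!r} must be >= 0")

    @property
    def all_eeg_channels(self) -> tuple[str, ...]:
        refs = tuple(f"REF{i + 1}" for i in range(self.n_reference_channels))
        return self.eeg_channels + refs


@dataclass
class TrialRecording:
    """One trial's synchronized EEG and sEMG arrays."""

    eeg: np.ndarray  # (n_eeg_channels, n_samples_eeg), microvolts
    emg: np.ndarray  # (n_muscles, n_samples_emg), arbitrary units
    fs_eeg: float
    fs_emg: float
    eeg_channels: tuple[str, ...]
    muscles: tuple[str, ...]
    cue_time_s: float
    replace_time_s: float
    surface: str
    subject_id: str
    trial_id: str

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.fs_eeg

    def eeg_channel(self, name: str) -> np.ndarray:
        return self.eeg[self.eeg_channels.index(name)]

    def emg_channel(self, name: str) -> np.ndarray:
        return self.emg[self.muscles.index(name)]


@dataclass(frozen=True)
class GroundTruthRecord:
    subject_id: str
    trial_id: str
    surface: str
    kappa_nominal: float
    kappa_effective: float
    erd_amplitude_factor: float
    cue_time_s: float
    replace_time_s: float


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f (power) noise; spectrum flattened below 1 Hz."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, 1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    spec *= scale
    spec[0] = 0.0
    x = irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_limited_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    slope: float = 0.0,
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band``.

    ``slope`` is the amplitude exponent of an in-band 1/f^slope tilt; the
    latent drive uses a steep slope (power ~ f^-4) so its power concentrates
    at the low band edge, a spectral signature that survives in both the EEG
    band features and the sEMG features.  The cortical rhythms use a flat
    in-band spectrum, which keeps them Gaussian narrowband processes.
    """
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, 1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    shaped = np.zeros_like(spec)
    shaped[mask] = spec[mask] / np.maximum(f[mask], 1.0) ** slope
    x = irfft(shaped, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _cosine_gate(t: np.ndarray, on: float, off: float, ramp: float) -> np.ndarray:
    """0/1 gate over [on, off] with raised-cosine ramps of width ``ramp``."""
    g = np.zeros_like(t)
    rise = (t >= on) & (t < on + ramp)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp))
    g[(t >= on + ramp) & (t <= off - ramp)] = 1.0
    fall = (t > off - ramp) & (t <= off)
    g[fall] = 0.5 * (1 - np.cos(np.pi * (off - t[fall]) / ramp))
    return g


def generate_trial(
    spec: SessionSpec,
    surface: str,
    rng: np.random.Generator,
    *,
    kappa_scale: float = 1.0,
    subject_id: str = "S01",
    trial_id: str = "T001",
) -> TrialRecording:
    """Generate one trial; deterministic given ``rng`` state.

    ``kappa_scale`` multiplies the nominal per-surface coupling gain (used by
    :func:`generate_session` to add between-subject variability).
    """
    if surface not in spec.surfaces:
        raise ValueError(f"unknown surface {surface!r}; expected one of {spec.surfaces}")
    if spec.trial_duration_s <= 0:
        raise ValueError("trial duration must be positive")

    n_eeg = round(spec.trial_duration_s * spec.fs_eeg)
    n_emg = round(spec.trial_duration_s * spec.fs_emg)
    t_eeg = np.arange(n_eeg) / spec.fs_eeg
    t_emg = np.arange(n_emg) / spec.fs_emg

    kappa = spec.coupling_gain_per_surface[surface] * kappa_scale

    # Shared latent drive, generated at the EEG rate and gated to the movement.
    drive = _band_limited_noise(rng, n_eeg, spec.fs_eeg, spec.drive_band, slope=2.0)
    gate = _cosine_gate(t_eeg, spec.cue_time_s, spec.replace_time_s, 0.1)
    gated = drive * gate
    on = gate > 0.5
    sd_on = gated[on].std() if on.any() else 0.0
    if sd_on > 0:
        gated = gated / sd_on
    up = spec.fs_emg // spec.fs_eeg
    drive_emg = resample_poly(gated, up, 1)[:n_emg]

    # mu suppression envelope: baseline amplitude 1, erd_amplitude_factor after cue
    mu_env = np.where(t_eeg >= spec.cue_time_s, spec.erd_amplitude_factor, 1.0)

    channels = spec.all_eeg_channels
    eeg = np.empty((len(channels), n_eeg))
    for i, ch in enumerate(channels):
        x = spec.noise_sd * _pink_noise(rng, n_eeg, spec.fs_eeg)
        if ch in spec.eeg_channels:
            # narrowband Gaussian rhythms: mu at 8-12 Hz, beta at 16-24 Hz;
            # "amplitude" follows sine conventions (variance = amp^2 / 2).
            # A stationary broadband gamma floor (30-50 Hz) keeps the
            # short-window sample statistics stable across the cue.
            mu = _band_limited_noise(rng, n_eeg, spec.fs_eeg, (8.0, 12.0))
            beta = _band_limited_noise(rng, n_eeg, spec.fs_eeg, (16.0, 24.0))
            floor = _band_limited_noise(rng, n_eeg, spec.fs_eeg, (30.0, 50.0))
            x = x + spec.mu_amplitude / np.sqrt(2) * mu_env * mu
            x = x + spec.beta_amplitude / np.sqrt(2) * beta
            x = x + spec.gamma_floor_sd * floor
            x = x + kappa * spec.channel_drive_gain.get(ch, 1.0) * gated
        eeg[i] = x

    # movement-gated EMG envelope: tonic 0.1 at rest, 1.0 during the movement
    env = 0.1 + 0.9 * _cosine_gate(t_emg, spec.cue_time_s, spec.replace_time_s + 0.5, 0.3)
    emg = np.empty((len(spec.muscles), n_emg))
    for j, m in enumerate(spec.muscles):
        noise = _emg_background(rng, n_emg, spec.fs_emg)
        amp = spec.muscle_amplitude.get(m, 1.0)
        g = spec.muscle_drive_gain.get(m, 1.0)
        emg[j] = amp * env * noise + kappa * g * drive_emg

    return TrialRecording(
        eeg=eeg,
        emg=emg,
        fs_eeg=float(spec.fs_eeg),
        fs_emg=float(spec.fs_emg),
        eeg_channels=channels,
        muscles=spec.muscles,
        cue_time_s=spec.cue_time_s,
        replace_time_s=spec.replace_time_s,
        surface=surface,
        subject_id=subject_id,
        trial_id=trial_id,
    )


_EMG_SHAPE_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _emg_shaping(n: int, fs: float) -> np.ndarray:
    """Amplitude shaping of the EMG carrier across rFFT frequencies.

    The carrier is confined to 20-149.5 Hz and pre-emphasized by the inverse
    of a zero-phase 4th-order Butterworth 20-150 Hz response, so that after
    standard conditioning the expected muscle-noise spectrum is flat across
    the whole analysis band (a textbook white-carrier assumption; without it
    the filter's edge roll-off would imprint a deterministic rank pattern on
    every muscle's feature vector).
    """
    key = (n, fs)
    if key not in _EMG_SHAPE_CACHE:
        from scipy.signal import butter, freqz, iirnotch, sosfreqz

        f = rfftfreq(n, 1.0 / fs)
        w = 2 * np.pi * f / fs
        sos = butter(4, [20.0, 150.0], btype="bandpass", fs=fs, output="sos")
        _, h_bp = sosfreqz(sos, worN=w)
        b, a = iirnotch(50.0, 25.0, fs=fs)
        _, h_notch = freqz(b, a, worN=w)
        mag_zp = (np.abs(h_bp) * np.abs(h_notch)) ** 2  # forward-backward magnitude
        amp = np.zeros_like(f)
        band = (f >= 16.0) & (f <= 160.0)
        amp[band] = 1.0 / np.maximum(mag_zp[band], 0.05)
        _EMG_SHAPE_CACHE[key] = amp
    return _EMG_SHAPE_CACHE[key]


def _emg_background(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise for the 20-150 Hz EMG carrier band (pre-emphasized)."""
    white = rng.standard_normal(n)
    spec = rfft(white) * _emg_shaping(n, fs)
    x = irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_session(
    spec: SessionSpec,
) -> tuple[list[TrialRecording], list[GroundTruthRecord]]:
    """Generate ``n_subjects x |surfaces| x n_trials_per_surface`` trials.

    A per-subject multiplicative jitter (uniform within
    ``1 +/- subject_kappa_jitter``) is applied to all coupling gains so that
    group-level statistics see between-subject variance.  Identical spec
    (including ``seed``) yields bit-identical output.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    trials: list[TrialRecording] = []
    truth: list[GroundTruthRecord] = []
    for si in range(spec.n_subjects):
        subject_id = f"S{si + 1:02d}"
        sub_ss = subject_seeds[si]
        jitter_rng = np.random.default_rng(sub_ss)
        j = spec.subject_kappa_jitter
        kappa_scale = float(jitter_rng.uniform(1 - j, 1 + j)) if j > 0 else 1.0
        trial_seeds = sub_ss.spawn(len(spec.surfaces) * spec.n_trials_per_surface)
        idx = 0
        for surface in spec.surfaces:
            for ti in range(spec.n_trials_per_surface):
                trial_id = f"{subject_id}_{surface}_{ti + 1:03d}"
                rng = np.random.default_rng(trial_seeds[idx])
                idx += 1
                trial = generate_trial(
                    spec,
                    surface,
                    rng,
                    kappa_scale=kappa_scale,
                    subject_id=subject_id,
                    trial_id=trial_id,
                )
                trials.append(trial)
                truth.append(
                    GroundTruthRecord(
                        subject_id=subject_id,
                        trial_id=trial_id,
                        surface=surface,
                        kappa_nominal=spec.coupling_gain_per_surface[surface],
                        kappa_effective=spec.coupling_gain_per_surface[surface]
                        * kappa_scale,
                        erd_amplitude_factor=spec.erd_amplitude_factor,
                        cue_time_s=spec.cue_time_s,
                        replace_time_s=spec.replace_time_s,
                    )
                )
    return trials, truth


def export_ground_truth(records: list[GroundTruthRecord], path: str | Path) -> Path:
    """Write ground-truth records as a CSV table, one row per trial."""
    if not records:
        raise ValueError("no ground-truth records to export")
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_session(trials: list[TrialRecording], directory: str | Path) -> list[Path]:
    """Write one NPZ container per subject (arrays + labels + trial metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[TrialRecording]] = {}
    for tr in trials:
        by_subject.setdefault(tr.subject_id, []).append(tr)
    paths = []
    for subject_id, sub_trials in by_subject.items():
        payload: dict[str, np.ndarray] = {}
        meta = []
        for k, tr in enumerate(sub_trials):
            payload[f"eeg_{k}"] = tr.eeg
            payload[f"emg_{k}"] = tr.emg
            meta.append(
                (tr.trial_id, tr.surface, tr.cue_time_s, tr.replace_time_s, tr.fs_eeg, tr.fs_emg)
            )
        payload["trial_meta"] = np.array(meta, dtype=object)
        payload["eeg_channels"] = np.array(sub_trials[0].eeg_channels)
        payload["muscles"] = np.array(sub_trials[0].muscles)
        p = directory / f"{subject_id}.npz"
        np.savez(p, **payload, allow_pickle=True)
        paths.append(p)
    return paths


def load_session(directory: str | Path) -> list[TrialRecording]:
    directory = Path(directory)
    trials: list[TrialRecording] = []
    for p in sorted(directory.glob("S*.npz")):
        with np.load(p, allow_pickle=True) as z:
            channels = tuple(z["eeg_channels"])
            muscles = tuple(z["muscles"])
            meta = z["trial_meta"]
            for k, (trial_id, surface, cue, replace, fs_eeg, fs_emg) in enumerate(meta):
                trials.append(
                    TrialRecording(
                        eeg=z[f"eeg_{k}"],
                        emg=z[f"emg_{k}"],
                        fs_eeg=float(fs_eeg),
                        fs_emg=float(fs_emg),
                        eeg_channels=channels,
                        muscles=muscles,
                        cue_time_s=float(cue),
                        replace_time_s=float(replace),
                        surface=str(surface),
                        subject_id=p.stem,
                        trial_id=str(trial_id),
                    )
                )
    return trials
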