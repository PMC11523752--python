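"""End-to-end orchestration: simulate -> preprocess -> ERD/EMG -> PBC -> MI
-> group statistics, from one config, with a manifest for traceability.

A single global seed fans out to per-stage seeds derived from it, so stages
are individually reproducible.  Rerunning an identical config reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emg as emg_mod
from . import mi as mi_mod
from . import pbc as pbc_mod
from . import spectral, stats
from .preprocess import PreprocessConfig, preprocess_session
from .synth import SessionSpec, export_ground_truth, generate_session

log = logging.getLogger("cmconn")

ALL_STAGES = ("simulate", "preprocess", "erd", "emg", "pbc", "mi", "stats")
STAGE_DEPS = {
    "preprocess": ("simulate",),
    "erd": ("preprocess",),
    "emg": ("preprocess",),
    "pbc": ("preprocess",),
    "mi": ("preprocess",),
    "stats": ("preprocess",),  # needs pbc and/or mi outputs, checked at run time
}


@dataclass
class PipelineConfig:
    session: SessionSpec = field(default_factory=SessionSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    out_dir: Path = Path("cmconn_out")
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    erd_channel: str = "C3"
    n_boot: int = 1000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sess_kw = dict(raw.get("session", {}))
        for key in ("surfaces", "eeg_channels", "muscles"):
            if key in sess_kw:
                sess_kw[key] = tuple(sess_kw[key])
        session = SessionSpec(**sess_kw)
        pre = PreprocessConfig(**raw.get("preprocess", {}))
        kw = {k: v for k, v in raw.items() if k not in ("session", "preprocess")}
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        if "out_dir" in kw:
            kw["out_dir"] = Path(kw["out_dir"])
        return cls(session=session, preprocess=pre, **kw)


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    payload = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the output manifest."""
    stages = tuple(cfg.stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")
        for dep in STAGE_DEPS.get(s, ()):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r} to be enabled")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # derive the session seed from the global pipeline seed
    session = dataclasses.replace(cfg.session, seed=int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31)))
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "artifacts": [],
    }

    def record(stage: str, path: Path, **params) -> None:
        manifest["artifacts"].append(
            {"stage": stage, "path": str(path), "seed": cfg.seed, **params}
        )

    trials = truth = epochs = None
    pbc_df = mi_df = None

    if "simulate" in stages:
        t0 = time.time()
        trials, truth = generate_session(session)
        p = export_ground_truth(truth, out / "ground_truth.csv")
        record("simulate", p, n_trials=len(trials), session_seed=session.seed)
        log.info("simulated %d trials in %.1fs", len(trials), time.time() - t0)

    if "preprocess" in stages:
        t0 = time.time()
        epochs = preprocess_session(trials, cfg.preprocess)
        p = _write(epochs.report, out / "rejection_report.csv")
        record("preprocess", p, n_retained=len(epochs.trials),
               n_rejected=len(epochs.rejected_trial_ids),
               subject_flagged=epochs.subject_flagged)
        log.info("preprocessed %d trials (%d rejected) in %.1fs",
                 len(epochs.trials), len(epochs.rejected_trial_ids), time.time() - t0)

    if "erd" in stages:
        t0 = time.time()
        ch = cfg.erd_channel
        data = np.stack([tr.eeg_channel(ch) for tr in epochs.trials])
        emap = spectral.erd_time_frequency(data, epochs.trials[0].fs_eeg)
        emap.sig_mask = spectral.bootstrap_significance(
            emap.per_trial, alpha=cfg.alpha, n_boot=cfg.n_boot,
            rng=np.random.default_rng(cfg.seed + 1),
        )
        np.savez(out / "erd_map.npz", times=emap.times, freqs=emap.freqs,
                 values=emap.values, sig_mask=emap.sig_mask)
        df = pd.DataFrame({
            "freq": np.repeat(emap.freqs, emap.times.size),
            "time": np.tile(emap.times, emap.freqs.size),
            "erd_percent": emap.values.ravel(),
            "significant": emap.sig_mask.ravel(),
        })
        p = _write(df, out / "erd_map.csv")
        record("erd", p, channel=ch, n_boot=cfg.n_boot, alpha=cfg.alpha)
        log.info("ERD map for %s in %.1fs", ch, time.time() - t0)

    if "emg" in stages:
        t0 = time.time()
        table = emg_mod.activation_table(epochs)
        p = _write(table, out / "emg_activation.csv")
        record("emg", p, n_rows=len(table))
        if table["surface"].nunique() >= 2:
            summary, _tests = emg_mod.summarize_activation(table)
            p = _write(summary, out / "emg_activation_summary.csv")
            record("emg", p)
        log.info("EMG activation in %.1fs", time.time() - t0)

    if "pbc" in stages:
        t0 = time.time()
        pbc_df = pbc_mod.pbc_records(epochs)
        p = _write(pbc_df, out / "pbc_records.csv")
        record("pbc", p, n_records=len(pbc_df))
        log.info("PBC (%d records) in %.1fs", len(pbc_df), time.time() - t0)

    if "mi" in stages:
        t0 = time.time()
        mi_df = mi_mod.mi_table(epochs)
        p = _write(mi_df, out / "mi_timecourses.csv")
        record("mi", p, n_rows=len(mi_df))
        log.info("MI (%d rows) in %.1fs", len(mi_df), time.time() - t0)

    if "stats" in stages:
        if pbc_df is None and mi_df is None:
            raise ValueError("stage 'stats' requires stage 'pbc' or 'mi' to be enabled")
        t0 = time.time()
        studies = stats.run_studies(pbc_df, mi_df)
        for name, df in studies.items():
            p = _write(df, out / f"{name}.csv")
            record("stats", p, study=name)
        log.info("group statistics in %.1fs", time.time() - t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
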