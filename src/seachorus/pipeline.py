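"""End-to-end orchestration: analyze recordings, detect and evaluate.

The unit of analysis is the hourly window: ``analyze`` turns calibrated
audio into one row per window per measure (H, C, ACI, ADI, BI and the two
band SPLs) in tidy long format; ``evaluate`` normalizes each measure over
the deployment, applies the 0.5 detection threshold, scores detections
against annotated chorus presence, and reports Pearson correlations of
every index against the chorus-masked 500-2500 Hz SPL and the 50-200 Hz
noise-band SPL.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import global_complexity, limit_curves
from .detection import (
    DEFAULT_CHORUS_HOURS,
    chorus_masked_spl,
    confusion_matrix,
    correlation_frame,
    detect,
    detect_ch,
    min_max_normalize,
    pearson_by_group,
)
from .indices import IndexConfig, aci, adi, bi
from .ordinal import OrdinalConfig
from .spectral import CalibratedAudio, band_spl, read_wav, welch_spectrogram

log = logging.getLogger("seachorus")

MEASURES = ("H", "C", "ACI", "ADI", "BI", "SPL_chorus", "SPL_noise")
DETECTOR_MEASURES = ("H", "C", "ACI", "ADI", "BI")


@dataclass
class RunConfig:
    """Defaults mirror the field study: d = 6, τ = 1, SPL bands 50-200 and
    500-2500 Hz, detection threshold 0.5, sensitivity -164.5 dB re 1 µPa."""

    d: int = 6
    tau: int = 1
    chorus_band: tuple[float, float] = (500.0, 2500.0)
    noise_band: tuple[float, float] = (50.0, 200.0)
    sensitivity: float = -164.5
    spl_nfft: int = 1024
    seconds_per_hour: float | None = None  # None: each file is one window
    indices: IndexConfig | None = None     # None: scaled to the audio at hand
    chorus_hours: tuple[int, ...] = DEFAULT_CHORUS_HOURS
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "d": self.d, "tau": self.tau,
            "chorus_band": list(self.chorus_band), "noise_band": list(self.noise_band),
            "sensitivity": self.sensitivity, "spl_nfft": self.spl_nfft,
            "seconds_per_hour": self.seconds_per_hour,
            "chorus_hours": list(self.chorus_hours), "seed": self.seed,
        }


def analyze_window(
    seg: CalibratedAudio, cfg: RunConfig, icfg: IndexConfig, window_id: str, clock_hour: int
) -> list[dict]:
    """All seven measures of one hourly window, as tidy rows."""
    window_seconds = seg.duration
    pt = global_complexity(seg.samples, OrdinalConfig(cfg.d, cfg.tau))
    spec = welch_spectrogram(
        seg, nfft=cfg.spl_nfft,
        seg_seconds=min(1.0, window_seconds),
        avg_seconds=window_seconds,
    )
    values = {
        "H": pt.H,
        "C": pt.C,
        "ACI": aci(seg, icfg.aci).value,
        "ADI": adi(seg, icfg.adi).value,
        "BI": bi(seg, icfg.bi).value,
        "SPL_chorus": float(band_spl(spec, cfg.chorus_band)[0]),
        "SPL_noise": float(band_spl(spec, cfg.noise_band)[0]),
    }
    return [
        {"window_id": window_id, "clock_hour": clock_hour, "measure": m, "value": v}
        for m, v in values.items()
    ]


def analyze_audio(audio: CalibratedAudio, cfg: RunConfig, stem: str = "scene") -> pd.DataFrame:
    """Split calibrated audio into hourly windows and analyze each.

    With ``cfg.seconds_per_hour`` unset the whole signal is one window.
    Window k gets id ``"{stem}:{k:04d}"`` and clock hour ``k % 24``.
    """
    sph = cfg.seconds_per_hour or audio.duration
    n_win = int(round(sph * audio.rate))
    n_windows = max(audio.samples.shape[0] // n_win, 1)
    icfg = cfg.indices or IndexConfig.scaled(audio.rate, sph)
    rows = []
    for k in range(n_windows):
        seg = CalibratedAudio(
            audio.samples[k * n_win : (k + 1) * n_win], audio.rate, audio.sensitivity
        )
        rows.extend(analyze_window(seg, cfg, icfg, f"{stem}:{k:04d}", k % 24))
    return pd.DataFrame(rows)


def analyze_files(paths, cfg: RunConfig, out_csv=None, resume: bool = True) -> pd.DataFrame:
    """Analyze WAV files into one tidy table; unreadable files are skipped.

    When ``out_csv`` exists and ``resume`` is set, files already present in
    it are not recomputed.  Returns the full (merged) table.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    done: pd.DataFrame | None = None
    done_stems: set[str] = set()
    if out_csv is not None and resume and Path(out_csv).exists():
        done = pd.read_csv(out_csv)
        done_stems = {w.split(":")[0] for w in done["window_id"].astype(str)}
    frames = [] if done is None else [done]
    n_failed = 0
    for p in paths:
        if p.stem in done_stems:
            log.info("skipping %s (already analyzed)", p.name)
            continue
        t0 = time.monotonic()
        try:
            audio = read_wav(p, sensitivity=cfg.sensitivity)
            frames.append(analyze_audio(audio, cfg, stem=p.stem))
        except Exception as exc:  # corrupt/unreadable input must not kill the run
            log.error("failed on %s: %s", p.name, exc)
            n_failed += 1
            continue
        log.info("analyzed %s in %.1f s", p.name, time.monotonic() - t0)
    if not frames:
        raise RuntimeError("no file could be analyzed")
    result = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        result.to_csv(out_csv, index=False)
    if n_failed:
        log.warning("%d file(s) failed", n_failed)
    return result


def _wide(results: pd.DataFrame) -> pd.DataFrame:
    wide = results.pivot_table(
        index=["window_id", "clock_hour"], columns="measure", values="value", sort=False
    ).reset_index()
    return wide.sort_values("window_id", kind="stable").reset_index(drop=True)


def detect_run(results: pd.DataFrame, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Deployment-normalized binary detections per window and measure.

    Columns: window_id, clock_hour, one 0/1 column per index plus the joint
    ``CH`` detector (H dip or C peak).
    """
    wide = _wide(results)
    out = wide[["window_id", "clock_hour"]].copy()
    norm = {}
    for m in DETECTOR_MEASURES:
        ns = min_max_normalize(wide[m].to_numpy(), wide["window_id"].to_numpy())
        norm[m] = ns
        out[m] = detect(ns, m)
    out["CH"] = detect_ch(norm["H"], norm["C"])
    return out


def evaluate_run(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> dict:
    """Score a deployment against its ground truth.

    ``truth`` needs columns ``window_id`` (or the same row order) and
    ``chorus_present``.  Returns a JSON-ready report with one confusion
    matrix per index (H, C, ACI, ADI, BI) plus the joint C-H detector, the
    correlation table, and the C-H plane coordinates with their
    limit-curve containment check.
    """
    cfg = cfg or RunConfig()
    wide = _wide(results)
    detections = detect_run(results, cfg)
    if "window_id" in truth.columns:
        tmap = dict(zip(truth["window_id"].astype(str), truth["chorus_present"]))
        missing = [w for w in wide["window_id"].astype(str) if w not in tmap]
        if missing:
            raise ValueError(f"truth is missing window_ids: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        y = np.array([tmap[w] for w in wide["window_id"].astype(str)], dtype=int)
    else:
        if len(truth) != len(wide):
            raise ValueError("truth and results have different numbers of windows")
        y = truth["chorus_present"].to_numpy(dtype=int)

    confusions = {}
    for m in list(DETECTOR_MEASURES) + ["CH"]:
        confusions[m] = confusion_matrix(y, detections[m].to_numpy()).as_dict()

    clock = wide["clock_hour"].to_numpy(dtype=int)
    masked = chorus_masked_spl(wide["SPL_chorus"].to_numpy(), clock, cfg.chorus_hours)
    reports = []
    for m in DETECTOR_MEASURES:
        reports.extend(
            pearson_by_group(wide[m].to_numpy(), masked, clock, index_name=m, band=cfg.chorus_band)
        )
        reports.extend(
            pearson_by_group(
                wide[m].to_numpy(), wide["SPL_noise"].to_numpy(), clock,
                index_name=m, band=cfg.noise_band, groups={},
            )
        )
    correlations = correlation_frame(reports)

    ref = limit_curves(cfg.d, n_grid=2000)
    pts = wide[["H", "C"]].to_numpy(dtype=float)
    contained = ref.contains(pts, tol=5e-3)
    plane = wide[["window_id", "clock_hour", "H", "C"]].copy()
    plane["within_limit_curves"] = contained

    # json.loads(to_json(...)) strips numpy scalar types for a JSON-safe report
    return {
        "n_windows": int(len(wide)),
        "confusion_matrices": confusions,
        "correlations": json.loads(correlations.to_json(orient="records")),
        "ch_plane": json.loads(plane.to_json(orient="records")),
        "all_points_within_limit_curves": bool(contained.all()),
        "config": cfg.to_dict(),
    }
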