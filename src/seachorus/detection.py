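"""Chorus detection and evaluation: normalization, thresholding, confusion
matrices and correlation against band SPL.

Hourly index series (H, C, ACI, ADI, BI and SPLs) are min-max normalized
over the deployment, thresholded at 0.5 (inverted for H, whose value dips
during choruses), and scored against annotated chorus presence with a
confusion matrix; Pearson correlations against the chorus-band SPL, overall
and by time-of-day group, quantify how faithfully each index tracks the
chorusing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizedSeries",
    "DetectionTable",
    "CorrelationReport",
    "HIGH_IS_CHORUS",
    "DEFAULT_CHORUS_HOURS",
    "DEFAULT_GROUPS",
    "min_max_normalize",
    "detect",
    "detect_ch",
    "confusion_matrix",
    "chorus_masked_spl",
    "pearson_by_group",
]

# detection polarity: value > 0.5 signals a chorus for these indices, < 0.5 for H
HIGH_IS_CHORUS = {"C": True, "ACI": True, "ADI": True, "BI": True, "H": False, "SPL": True}

# chorus-hour mask and time-of-day correlation groups (clock hours, inclusive)
DEFAULT_CHORUS_HOURS = tuple(range(0, 6)) + tuple(range(18, 24))
DEFAULT_GROUPS = {"Dawn": tuple(range(0, 6)), "Dusk": tuple(range(18, 24)), "Midday": tuple(range(6, 18))}


@dataclass
class NormalizedSeries:
    window_ids: np.ndarray
    raw: np.ndarray
    norm: np.ndarray
    constant: bool = False  # degenerate input: all values equal, norm all zero


@dataclass
class DetectionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def error_rate(self) -> float:
        return (self.fn + self.fp) / self.n if self.n else float("nan")

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "error_rate": self.error_rate,
        }


@dataclass
class CorrelationReport:
    index: str
    band: tuple[float, float]
    group: str
    r: float
    p: float
    n: int


def min_max_normalize(series, window_ids=None) -> NormalizedSeries:
    """(x - min) / (max - min); constant input maps to all zeros, flagged."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty series")
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    ids = np.asarray(window_ids) if window_ids is not None else np.arange(x.size)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return NormalizedSeries(ids, x, np.zeros_like(x), constant=True)
    return NormalizedSeries(ids, x, (x - lo) / (hi - lo))


def detect(series, index_name: str) -> np.ndarray:
    """Binary detections from a normalized series.

    Strict thresholds: detected iff value > 0.5 for C/ACI/ADI/BI (and SPL),
    iff value < 0.5 for H.  A value of exactly 0.5 is never a detection.
    """
    x = series.norm if isinstance(series, NormalizedSeries) else np.asarray(series, dtype=float)
    key = index_name.upper()
    if key not in HIGH_IS_CHORUS:
        raise ValueError(f"unknown index {index_name!r}; expected one of {sorted(HIGH_IS_CHORUS)}")
    if HIGH_IS_CHORUS[key]:
        return (x > 0.5).astype(int)
    return (x < 0.5).astype(int)


def detect_ch(h_series, c_series) -> np.ndarray:
    """Joint C-H detector: chorus iff H dips below 0.5 OR C rises above 0.5.

    Both quantifiers flag the same physical signature — movement toward the
    deterministic (low-H, high-C) corner of the complexity-entropy plane —
    so either coordinate crossing its threshold counts as a detection.
    """
    return (detect(h_series, "H") | detect(c_series, "C")).astype(int)


def confusion_matrix(truth, detected) -> DetectionTable:
    """TP/FP/TN/FN counts with accuracy = (TP+TN)/n, error rate = (FN+FP)/n."""
    t = np.asarray(truth, dtype=int)
    d = np.asarray(detected, dtype=int)
    if t.shape != d.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs detected {d.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(d, (0, 1)).all()):
        raise ValueError("truth and detections must be binary")
    return DetectionTable(
        tp=int(((t == 1) & (d == 1)).sum()),
        fp=int(((t == 0) & (d == 1)).sum()),
        tn=int(((t == 0) & (d == 0)).sum()),
        fn=int(((t == 1) & (d == 0)).sum()),
    )


def chorus_masked_spl(spl_series, clock_hours, chorus_hours=DEFAULT_CHORUS_HOURS) -> np.ndarray:
    """Keep SPL during chorus hours, zero elsewhere.

    The masked series is a cleaner proxy of chorusing than the raw band SPL,
    which may also pick up noise outside the chorusing hours.
    """
    s = np.asarray(spl_series, dtype=float)
    h = np.asarray(clock_hours)
    if h.shape != s.shape:
        raise ValueError("spl_series and clock_hours must have equal length")
    if h.size and not np.issubdtype(h.dtype, np.number):
        raise ValueError("clock labels must be numeric hours 0-23")
    keep = np.isin(h.astype(int), np.asarray(chorus_hours, dtype=int))
    return np.where(keep, s, 0.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_by_group(
    index_series,
    spl_series,
    clock_hours,
    index_name: str = "",
    band: tuple[float, float] = (500.0, 2500.0),
    groups: dict | None = None,
) -> list[CorrelationReport]:
    """Pearson r and two-sided p, overall and per time-of-day group.

    Groups with fewer than 3 paired values, or zero variance in either
    series, report r = NaN.
    """
    x = np.asarray(index_series, dtype=float)
    y = np.asarray(spl_series, dtype=float)
    h = np.asarray(clock_hours, dtype=int)
    if not (x.shape == y.shape == h.shape):
        raise ValueError("index, SPL and clock series must have equal length")
    groups = groups if groups is not None else DEFAULT_GROUPS
    reports = []
    r, p = _pearson(x, y) if x.size >= 3 else (float("nan"), float("nan"))
    reports.append(CorrelationReport(index_name, band, "all", r, p, int(x.size)))
    for name, hours in groups.items():
        sel = np.isin(h, np.asarray(hours, dtype=int))
        if sel.sum() < 3:
            reports.append(CorrelationReport(index_name, band, name, float("nan"), float("nan"), int(sel.sum())))
            continue
        r, p = _pearson(x[sel], y[sel])
        reports.append(CorrelationReport(index_name, band, name, r, p, int(sel.sum())))
    return reports


def correlation_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"index": r.index, "band_lo": r.band[0], "band_hi": r.band[1],
             "group": r.group, "r": r.r, "p": r.p, "n": r.n}
            for r in reports
        ]
    )
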