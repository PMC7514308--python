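"""Calibrated spectrograms, Welch PSD and band sound-pressure levels.

Hydrophone recordings arrive as PCM samples in [-1, 1] plus a single
end-to-end sensitivity S (dB re 1 µPa), so pressure = sample · 10^(-S/20).
PSDs are computed per short segment with the Welch method and averaged to a
coarser resolution; band SPLs integrate the calibrated one-sided PSD over a
frequency band and are reported in dB re 1 µPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "CalibratedAudio",
    "SpectrogramMatrix",
    "BandSPLStats",
    "read_wav",
    "write_wav",
    "welch_spectrogram",
    "band_spl",
    "spl_statistics",
    "hourly_mean_spl",
]

DB_FLOOR = -200.0  # dB value substituted for zero power (digital silence)


@dataclass
class CalibratedAudio:
    """PCM samples in [-1, 1] with sample rate and end-to-end sensitivity."""

    samples: np.ndarray
    rate: float
    sensitivity: float = -164.5  # dB re 1 µPa

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.isfinite(self.sensitivity):
            raise ValueError("sensitivity must be finite")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.rate

    @property
    def pressure(self) -> np.ndarray:
        """Samples converted to instantaneous pressure in µPa."""
        return self.samples * 10.0 ** (-self.sensitivity / 20.0)


@dataclass
class SpectrogramMatrix:
    """Time × frequency PSD in linear µPa²/Hz with a dB view."""

    times: np.ndarray  # window centers, s
    freqs: np.ndarray  # bin centers, Hz
    power: np.ndarray  # shape (n_times, n_freqs), µPa²/Hz
    rate: float
    nfft: int

    @property
    def df(self) -> float:
        return self.rate / self.nfft

    @property
    def db(self) -> np.ndarray:
        """PSD in dB re 1 µPa²/Hz; zero power floors at DB_FLOOR."""
        with np.errstate(divide="ignore"):
            out = 10.0 * np.log10(self.power)
        return np.where(np.isfinite(out), out, DB_FLOOR)


@dataclass
class BandSPLStats:
    """Summary statistics of a band SPL series (all dB re 1 µPa)."""

    band: tuple[float, float]
    mean_rms: float
    median: float
    p95: float
    series: np.ndarray = field(default_factory=lambda: np.array([]))


_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


def read_wav(path, sensitivity: float = -164.5) -> CalibratedAudio:
    """Read a PCM or float WAV file; multi-channel input keeps channel 0."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    elif data.dtype in (np.int16, np.int32):
        x = data.astype(float) / float(_PCM_SCALE[np.dtype(data.dtype)])
    else:
        x = data.astype(float)
    return CalibratedAudio(samples=x, rate=float(rate), sensitivity=sensitivity)


def write_wav(path, audio: CalibratedAudio) -> None:
    """Write audio as float32 WAV (lossless for the simulator's dynamic range)."""
    wavfile.write(path, int(audio.rate), audio.samples.astype(np.float32))


def welch_spectrogram(
    audio: CalibratedAudio,
    nfft: int = 1024,
    seg_seconds: float = 1.0,
    avg_seconds: float = 60.0,
    window: str = "hann",
    overlap: float = 0.5,
) -> SpectrogramMatrix:
    """Welch PSD per short segment, averaged to coarse time resolution.

    Each ``seg_seconds`` chunk gets a one-sided Welch PSD (default Hann,
    50% overlap, ``nfft`` points); linear PSDs are then arithmetically
    averaged over each ``avg_seconds`` block.  Calibration multiplies the
    digital PSD by 10^(-S/10) so the result is in µPa²/Hz.
    """
    x = audio.samples
    fs = audio.rate
    n_seg = int(round(seg_seconds * fs))
    n_avg = int(round(avg_seconds * fs))
    if nfft > n_seg:
        raise ValueError(f"nfft={nfft} exceeds segment length {n_seg} samples")
    if x.shape[0] < n_seg:
        raise ValueError("audio shorter than one analysis segment")
    cal = 10.0 ** (-audio.sensitivity / 10.0)

    n_blocks = x.shape[0] // n_avg
    if n_blocks == 0:  # shorter than one averaging block: single partial block
        n_blocks, n_avg = 1, x.shape[0]
    times = np.empty(n_blocks)
    rows = []
    freqs = None
    for b in range(n_blocks):
        block = x[b * n_avg : (b + 1) * n_avg]
        psds = []
        for s in range(0, block.shape[0] - n_seg + 1, n_seg):
            seg = block[s : s + n_seg]
            f, pxx = signal.welch(
                seg,
                fs=fs,
                window=window,
                nperseg=nfft,
                noverlap=int(round(nfft * overlap)),
                detrend=False,
                scaling="density",
            )
            psds.append(pxx)
        freqs = f
        rows.append(np.mean(psds, axis=0) * cal)
        times[b] = (b + 0.5) * n_avg / fs
    power = np.vstack(rows)
    if np.all(power == 0):
        warnings.warn("spectrogram is digital silence; dB values floor at DB_FLOOR")
    return SpectrogramMatrix(times=times, freqs=freqs, power=power, rate=fs, nfft=nfft)


def band_spl(spec: SpectrogramMatrix, band: tuple[float, float]) -> np.ndarray:
    """Per-window SPL (dB re 1 µPa): 10·log10(Σ_band PSD·df).

    Bins whose centers lie in [f_lo, f_hi], both ends inclusive.
    """
    f_lo, f_hi = band
    if f_hi > spec.rate / 2 + 1e-9:
        raise ValueError(f"band {band} exceeds Nyquist ({spec.rate / 2} Hz)")
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    p_band = spec.power[:, mask].sum(axis=1) * spec.df
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(p_band)
    return np.where(np.isfinite(out), out, DB_FLOOR)


def spl_statistics(series_db, band: tuple[float, float] = (0.0, 0.0)) -> BandSPLStats:
    """Mean (RMS sense), median and 95th percentile of an SPL series.

    The mean is taken on linear power then converted back to dB; median and
    p95 are order statistics of the dB values themselves.
    """
    s = np.asarray(series_db, dtype=float)
    if s.size == 0:
        raise ValueError("empty SPL series")
    mean_rms = 10.0 * np.log10(np.mean(10.0 ** (s / 10.0)))
    return BandSPLStats(
        band=tuple(band),
        mean_rms=float(mean_rms),
        median=float(np.median(s)),
        p95=float(np.percentile(s, 95)),
        series=s,
    )


def hourly_mean_spl(series_db, clock_hours, mean_of_db: bool = False) -> pd.DataFrame:
    """Mean SPL ± SD per clock hour (0-23) across a deployment.

    By default the mean is computed on linear power and converted to dB (an
    RMS level); ``mean_of_db=True`` averages the dB values instead.  The SD
    is always the standard deviation of the dB values within the hour.
    """
    s = np.asarray(series_db, dtype=float)
    h = np.asarray(clock_hours, dtype=int)
    if s.shape != h.shape:
        raise ValueError("series and clock_hours must have equal length")
    df = pd.DataFrame({"hour": h, "spl": s})

    def _agg(g: pd.Series) -> float:
        if mean_of_db:
            return float(g.mean())
        return float(10.0 * np.log10(np.mean(10.0 ** (g / 10.0))))

    out = df.groupby("hour")["spl"].agg(mean_spl=_agg, sd="std", n="count").reset_index()
    return out
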