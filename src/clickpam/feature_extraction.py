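"""The eight per-click acoustic parameters.

Each selected click is reduced to a 32-sample rectangular window centered
on the peak of its analytic-signal envelope.  The -10 dB duration is read
off the 10x linearly interpolated envelope; the seven spectral parameters
come from a 32-point Hanning power spectrum interpolated by a factor of
10 with a low-pass (polyphase FIR) interpolator, giving a 1.8 kHz bin
spacing at the nominal 576 kHz sampling rate.  Spectral sums are
restricted to the 10-200 kHz analysis band of the preprocessing filter.

Parameters (all per click):

==========  =====================================================
d10_us      -10 dB duration of the envelope, microseconds
fp_khz      peak frequency: bin of maximum spectral power
fc_khz      centroid frequency: power-weighted mean frequency
fl3_khz     lower edge of the -3 dB band
fl10_khz    lower edge of the -10 dB band
bw3_khz     -3 dB (half-power) bandwidth
bw10_khz    -10 dB bandwidth
bwrms_khz   RMS bandwidth: power-weighted spectral std. deviation
==========  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import hilbert, periodogram

from .audio_io import AudioRecording
from .click_detection import ClickCandidate

__all__ = [
    "ClickWindow",
    "ClickSpectrum",
    "ClickFeatures",
    "envelope",
    "extract_window",
    "duration_minus10dB",
    "click_spectrum",
    "peak_frequency",
    "centroid_frequency",
    "rms_bandwidth",
    "db_bandwidth",
    "extract_features",
    "features_to_frame",
    "to_s1_table",
    "from_s1_table",
    "PARAMS",
    "S1_COLUMNS",
]

WINDOW_SIZE = 32
INTERP_FACTOR = 10
ANALYSIS_BAND = (10_000.0, 200_000.0)  # Hz, matches the preprocessing filter

#: Internal short names of the eight parameters, in canonical order.
PARAMS = ["d10_us", "fp_khz", "fc_khz", "fl3_khz", "fl10_khz", "bw3_khz", "bw10_khz", "bwrms_khz"]

#: Export column labels (per-click feature table).
S1_COLUMNS = {
    "species": "species",
    "file_name": "file name",
    "d10_us": "-10 dB duration (us)",
    "fp_khz": "peak frequency (kHz)",
    "fc_khz": "centroid frequency (kHz)",
    "fl3_khz": "lower -3 dB frequency (kHz)",
    "fl10_khz": "lower -10 dB frequency (kHz)",
    "bw3_khz": "-3 dB bandwidth (kHz)",
    "bw10_khz": "-10 dB bandwidth (kHz)",
    "bwrms_khz": "RMS bandwidth (kHz)",
}


@dataclass
class ClickWindow:
    """32 raw samples centered on the envelope peak (index 16)."""

    samples: np.ndarray
    sample_rate: float
    center_index: int = WINDOW_SIZE // 2

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size != WINDOW_SIZE:
            raise ValueError(f"ClickWindow requires exactly {WINDOW_SIZE} samples")


@dataclass
class ClickSpectrum:
    """Interpolated one-sided power spectrum of a click window."""

    frequencies: np.ndarray  # Hz, spacing sample_rate / (32 * 10)
    power: np.ndarray        # linear power, >= 0

    @property
    def amplitude(self) -> np.ndarray:
        return np.sqrt(self.power)

    @property
    def bin_spacing(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class ClickFeatures:
    """The eight per-click parameters plus provenance."""

    species: str
    file_name: str
    d10_us: float
    fp_khz: float
    fc_khz: float
    fl3_khz: float
    fl10_khz: float
    bw3_khz: float
    bw10_khz: float
    bwrms_khz: float
    session_id: str = ""
    train_id: str = ""


class BandEdges(NamedTuple):
    bandwidth_khz: float
    lower_khz: float
    flagged: bool


def envelope(waveform: np.ndarray) -> np.ndarray:
    """Analytic-signal (Hilbert) envelope, same length as the input."""
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size < 8:
        raise ValueError("waveform too short for envelope estimation")
    return np.abs(hilbert(waveform))


def extract_window(rec: AudioRecording, time_index: int) -> ClickWindow:
    """Cut 32 samples around an envelope peak, zero-padding at the edges.

    The peak lands at window index 16 (0-based); the short window keeps
    surface/bottom reflections and surrounding noise out of the spectra.
    """
    if not 0 <= time_index < rec.n_samples:
        raise ValueError("time_index outside the recording")
    half = WINDOW_SIZE // 2
    out = np.zeros(WINDOW_SIZE)
    lo = time_index - half
    hi = time_index + half
    src_lo = max(lo, 0)
    src_hi = min(hi, rec.n_samples)
    out[src_lo - lo : src_hi - lo] = rec.samples[src_lo:src_hi]
    return ClickWindow(out, rec.sample_rate)


def duration_minus10dB(win: ClickWindow) -> float:
    """-10 dB envelope duration in microseconds.

    The envelope is linearly interpolated by a factor of 10; the duration
    is the time between the first and the last crossing of one tenth
    power (10^(-10/20) of the peak envelope amplitude).  Invariant under
    amplitude scaling.
    """
    env = envelope(win.samples)
    peak = env.max()
    if peak <= 0.0:
        raise ValueError("all-zero click window has no duration")
    t = np.arange(env.size) / win.sample_rate
    fine_t = np.linspace(t[0], t[-1], (env.size - 1) * INTERP_FACTOR + 1)
    fine = np.interp(fine_t, t, env)
    thr = peak * 10.0 ** (-10.0 / 20.0)
    above = np.flatnonzero(fine >= thr)
    first, last = above[0], above[-1]
    t_first = fine_t[first]
    if first > 0:  # sub-sample crossing refinement on the fine grid
        e0, e1 = fine[first - 1], fine[first]
        t_first = fine_t[first - 1] + (thr - e0) / (e1 - e0) * (fine_t[first] - fine_t[first - 1])
    t_last = fine_t[last]
    if last < fine.size - 1:
        e0, e1 = fine[last], fine[last + 1]
        t_last = fine_t[last] + (e0 - thr) / (e0 - e1) * (fine_t[last + 1] - fine_t[last])
    return float((t_last - t_first) * 1e6)


def click_spectrum(win: ClickWindow) -> ClickSpectrum:
    """Interpolated power spectrum of a 32-sample click window.

    A single 32-point Hanning frame (the degenerate Welch case) gives a
    17-bin one-sided spectrum with sample_rate/32 spacing.  The spectrum
    is refined by a factor of 10 through zero-padding the windowed
    waveform to 320 points — the classical low-pass interpolation of a
    spectrum — for a bin spacing of sample_rate/320: 1.8 kHz at the
    nominal 576 kHz rate.
    """
    freqs, pxx = periodogram(
        win.samples,
        fs=win.sample_rate,
        window="hann",
        nfft=WINDOW_SIZE * INTERP_FACTOR,
        detrend=False,
        scaling="density",
    )
    return ClickSpectrum(freqs, pxx)


def _band_mask(spec: ClickSpectrum, band: tuple[float, float]) -> np.ndarray:
    mask = (spec.frequencies >= band[0]) & (spec.frequencies <= band[1])
    if not mask.any():
        raise ValueError("analysis band contains no spectral bins")
    return mask


def peak_frequency(spec: ClickSpectrum, band: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Frequency (kHz) of maximum spectral power; ties go to the lowest bin."""
    mask = _band_mask(spec, band)
    f = spec.frequencies[mask]
    p = spec.power[mask]
    if p.max() <= 0.0:
        raise ValueError("zero spectrum has no peak frequency")
    return float(f[int(np.argmax(p))] / 1e3)


def centroid_frequency(spec: ClickSpectrum, band: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Power-weighted mean frequency (kHz) over the analysis band."""
    mask = _band_mask(spec, band)
    f = spec.frequencies[mask]
    p = spec.power[mask]
    total = p.sum()
    if total <= 0.0:
        raise ValueError("zero total power; centroid undefined")
    return float((f * p).sum() / total / 1e3)


def rms_bandwidth(spec: ClickSpectrum, band: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Power-weighted standard deviation of frequency (kHz) about the centroid."""
    mask = _band_mask(spec, band)
    f = spec.frequencies[mask]
    p = spec.power[mask]
    total = p.sum()
    if total <= 0.0:
        raise ValueError("zero total power; RMS bandwidth undefined")
    fc = (f * p).sum() / total
    return float(np.sqrt(((f - fc) ** 2 * p).sum() / total) / 1e3)


def db_bandwidth(
    spec: ClickSpectrum,
    drop: float,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> BandEdges:
    """Bandwidth and lower edge (kHz) at ``drop`` dB below the spectral peak.

    Thresholds are applied to the power spectrum: -3 dB is the half-power
    (1/sqrt(2) amplitude) point, -10 dB one-tenth power.  Edges are the
    outermost threshold crossings within the analysis band, with linear
    interpolation between bins; if the spectrum never falls below the
    threshold inside the band the result covers the full band and is
    flagged.
    """
    mask = _band_mask(spec, band)
    f = spec.frequencies[mask]
    p = spec.power[mask]
    if p.max() <= 0.0:
        raise ValueError("zero spectrum has no bandwidth")
    thr = p.max() * 10.0 ** (-drop / 10.0)
    above = np.flatnonzero(p >= thr)
    imin, imax = above[0], above[-1]
    flagged = imin == 0 and imax == p.size - 1
    if imin > 0:
        f_lo = f[imin - 1] + (thr - p[imin - 1]) / (p[imin] - p[imin - 1]) * (f[imin] - f[imin - 1])
    else:
        f_lo = f[0]
    if imax < p.size - 1:
        f_hi = f[imax] + (p[imax] - thr) / (p[imax] - p[imax + 1]) * (f[imax + 1] - f[imax])
    else:
        f_hi = f[-1]
    return BandEdges(float((f_hi - f_lo) / 1e3), float(f_lo / 1e3), bool(flagged))


def extract_features(
    click: ClickCandidate,
    rec: AudioRecording,
    species: str = "",
    file_name: str = "",
    session_id: str = "",
    train_id: str = "",
) -> ClickFeatures:
    """All eight parameters of one retained click, with provenance."""
    win = extract_window(rec, click.time_index)
    d10 = duration_minus10dB(win)
    spec = click_spectrum(win)
    bw3 = db_bandwidth(spec, 3.0)
    bw10 = db_bandwidth(spec, 10.0)
    return ClickFeatures(
        species=species,
        file_name=file_name or rec.source_id,
        d10_us=d10,
        fp_khz=peak_frequency(spec),
        fc_khz=centroid_frequency(spec),
        fl3_khz=bw3.lower_khz,
        fl10_khz=bw10.lower_khz,
        bw3_khz=bw3.bandwidth_khz,
        bw10_khz=bw10.bandwidth_khz,
        bwrms_khz=rms_bandwidth(spec),
        session_id=session_id,
        train_id=train_id,
    )


def features_to_frame(features: list[ClickFeatures]) -> pd.DataFrame:
    """Tidy per-click feature table with internal (short) column names."""
    return pd.DataFrame(
        [
            {
                "species": ft.species,
                "file_name": ft.file_name,
                "session_id": ft.session_id,
                "train_id": ft.train_id,
                **{p: getattr(ft, p) for p in PARAMS},
            }
            for ft in features
        ]
    )


def to_s1_table(df: pd.DataFrame) -> pd.DataFrame:
    """Rename internal columns to the export labels (per-click table)."""
    return df[list(S1_COLUMNS)].rename(columns=S1_COLUMNS)


def from_s1_table(df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_s1_table`; tolerant of column order."""
    inverse = {v: k for k, v in S1_COLUMNS.items()}
    return df.rename(columns=inverse)
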