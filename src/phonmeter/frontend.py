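"""Spectral front end: calibrated audio to 61-band dB spectra.

Audio is analysed with a 1024-point DFT at 16 kHz and the bins are grouped
into 61 bands with centre frequencies up to 8 kHz: one bin per band for
centre frequencies up to about 0.2 kHz, and 1/9-octave-wide bands above
that.  The per-band levels in dB SPL are the common input representation
for both the reference loudness model (the "teacher") and the neural
network that is distilled from it (the "student").

Digital amplitudes are tied to sound pressure level by a calibration
constant: a waveform with unit RMS amplitude corresponds to
``calibration_db`` dB SPL (94 dB by default, the usual microphone
reference of 1 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal.windows import hann

SAMPLE_RATE = 16000
DFT_SIZE = 1024
F_MAX = 8000.0
N_BANDS = 61
HOP_CORPUS = 560      # frame shift used when building training corpora
HOP_TRACE = 16        # 1-ms frame shift for loudness traces
DEFAULT_CALIBRATION_DB = 94.0   # dB SPL of a unit-RMS digital signal
SILENCE_FLOOR_DB = -30.0        # per-band level floor

# Periodic Hann analysis window; band powers are normalised by the window
# energy so that a steady sinusoid's banded level equals its calibrated SPL.
ANALYSIS_WINDOW = hann(DFT_SIZE, sym=False)
_WINDOW_POWER_NORM = 2.0 / (DFT_SIZE * np.sum(ANALYSIS_WINDOW**2))


@dataclass
class AudioSignal:
    """Mono waveform with a digital-to-SPL calibration.

    ``samples`` are dimensionless amplitudes; an RMS of 1.0 corresponds to
    ``calibration_db`` dB SPL.
    """

    samples: np.ndarray
    sample_rate: int = SAMPLE_RATE
    calibration_db: float = DEFAULT_CALIBRATION_DB

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D samples)")
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError(
                f"sample_rate must be {SAMPLE_RATE} Hz, got {self.sample_rate}"
            )
        if not np.isfinite(self.calibration_db):
            raise ValueError("calibration must be finite")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def rms_db(self) -> float:
        """RMS level of the waveform in dB SPL under the calibration."""
        rms = float(np.sqrt(np.mean(self.samples**2)))
        if rms == 0.0:
            raise ValueError("all-zero signal has no RMS level")
        return self.calibration_db + 20.0 * np.log10(rms)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class BandDefinition:
    """Grouping of DFT bins into the 61 analysis bands."""

    bin_slices: list          # per band: (first_bin, last_bin) inclusive
    centers_hz: np.ndarray    # per band: centre frequency
    dft_size: int
    sample_rate: int
    f_max: float

    @property
    def n_bands(self) -> int:
        return len(self.bin_slices)


@dataclass
class BandSpectrum:
    """Per-band levels in dB SPL for one analysis frame."""

    levels: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.levels.shape != (N_BANDS,):
            raise ValueError(f"expected {N_BANDS} band levels")


def design_bands(
    dft_size: int = DFT_SIZE,
    sample_rate: int = SAMPLE_RATE,
    f_max: float = F_MAX,
) -> BandDefinition:
    """Group DFT bins into 61 bands (single bins low, 1/9 octave above).

    The DC bin is excluded.  Bins with centre frequency below 200 Hz each
    form their own band.  From the upper edge of the last single-bin band
    onward, band edges are spaced exactly a ninth of an octave apart
    (successive edges multiplied by ``2**(1/9)``); a bin belongs to the
    band whose (lower, upper] edge interval contains its frequency, and
    the final band is truncated at ``f_max``.  For the canonical
    1024-point / 16-kHz configuration this yields 12 single-bin bands plus
    49 ninth-octave bands = 61 bands, the first ninth-octave band holding
    the single bin centred at 203 Hz.
    """
    if dft_size % 2 != 0:
        raise ValueError("dft_size must be even")
    if f_max > sample_rate / 2:
        raise ValueError("f_max exceeds the Nyquist frequency")

    bin_hz = sample_rate / dft_size
    n_pos = dft_size // 2                      # bins 1..n_pos, DC excluded
    freqs = bin_hz * np.arange(1, n_pos + 1)

    bin_slices: list[tuple[int, int]] = []
    centers: list[float] = []

    # Single-bin bands: every bin with centre frequency below 200 Hz.
    k = 1
    while k * bin_hz < 200.0:
        bin_slices.append((k, k))
        centers.append(k * bin_hz)
        k += 1
    low_edge = (k - 1) * bin_hz + bin_hz / 2.0  # upper edge of last single bin

    # 1/9-octave bands: edges low_edge * 2^(m/9); a band owns the bins in
    # (edge_lo, edge_hi], with the last band truncated at f_max.
    m = 0
    while True:
        e_lo = low_edge * 2.0 ** (m / 9.0)
        if e_lo >= f_max:
            break
        e_hi = min(low_edge * 2.0 ** ((m + 1) / 9.0), f_max)
        center = np.sqrt(e_lo * e_hi)
        first = int(np.ceil(e_lo / bin_hz + 1e-9))
        if first * bin_hz <= e_lo:
            first += 1
        last = int(np.floor(e_hi / bin_hz + 1e-9))
        if last < first:
            raise AssertionError("empty analysis band in the design")
        bin_slices.append((first, last))
        centers.append(center)
        m += 1

    bd = BandDefinition(
        bin_slices=bin_slices,
        centers_hz=np.asarray(centers),
        dft_size=dft_size,
        sample_rate=sample_rate,
        f_max=f_max,
    )
    # structural sanity: contiguous, non-overlapping coverage of (0, f_max]
    covered = [k for lo, hi in bin_slices for k in range(lo, hi + 1)]
    expected = [k for k in range(1, n_pos + 1) if freqs[k - 1] <= f_max]
    if covered != expected:
        raise AssertionError("band design does not partition the DFT bins")
    if np.any(np.diff(bd.centers_hz) <= 0):
        raise AssertionError("band centres must increase strictly")
    return bd


def frame_signal(
    signal: AudioSignal, window_len: int = DFT_SIZE, hop: int = HOP_CORPUS
) -> np.ndarray:
    """Slice a signal into overlapping Hann-windowed frames.

    Returns an array of shape ``(n_frames, window_len)`` where
    ``n_frames = floor((n_samples - window_len) / hop) + 1``.
    """
    x = signal.samples
    if len(x) < window_len:
        raise ValueError("signal shorter than the analysis window")
    n_frames = (len(x) - window_len) // hop + 1
    idx = hop * np.arange(n_frames)[:, None] + np.arange(window_len)[None, :]
    if window_len == DFT_SIZE:
        window = ANALYSIS_WINDOW
    else:
        window = hann(window_len, sym=False)
    return x[idx] * window[None, :]


def _banded_power(frames: np.ndarray, bands: BandDefinition) -> np.ndarray:
    """Per-band power (RMS^2 units) for windowed frames, shape (n, n_bands)."""
    spec = np.fft.rfft(frames, axis=-1)
    power = np.abs(spec) ** 2
    out = np.empty((frames.shape[0], bands.n_bands))
    for b, (lo, hi) in enumerate(bands.bin_slices):
        out[:, b] = power[:, lo : hi + 1].sum(axis=-1)
    return out * _WINDOW_POWER_NORM


def band_spectrum(
    frame: np.ndarray,
    bands: BandDefinition,
    calibration_db: float = DEFAULT_CALIBRATION_DB,
    frame_time: float = 0.0,
) -> BandSpectrum:
    """Band levels in dB SPL for one windowed frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (bands.dft_size,):
        raise ValueError("frame length does not match the band design")
    power = _banded_power(frame[None, :], bands)[0]
    with np.errstate(divide="ignore"):
        levels = calibration_db + 10.0 * np.log10(power)
    levels = np.maximum(levels, SILENCE_FLOOR_DB)
    return BandSpectrum(levels=levels, frame_time=frame_time)


def band_spectra(
    signal: AudioSignal,
    bands: BandDefinition,
    hop: int = HOP_CORPUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-level time series for a whole signal.

    Returns ``(times, levels)`` with ``times`` the frame-centre instants in
    seconds and ``levels`` of shape ``(n_frames, 61)`` in dB SPL.
    """
    frames = frame_signal(signal, bands.dft_size, hop)
    power = _banded_power(frames, bands)
    with np.errstate(divide="ignore"):
        levels = signal.calibration_db + 10.0 * np.log10(power)
    levels = np.maximum(levels, SILENCE_FLOOR_DB)
    n = frames.shape[0]
    times = (hop * np.arange(n) + bands.dft_size / 2.0) / signal.sample_rate
    return times, levels


def scale_to_rms_level(signal: AudioSignal, target_db: float) -> AudioSignal:
    """Scale a waveform so its RMS maps to ``target_db`` dB SPL."""
    gain = 10.0 ** ((target_db - signal.rms_db) / 20.0)
    return AudioSignal(
        samples=signal.samples * gain,
        sample_rate=signal.sample_rate,
        calibration_db=signal.calibration_db,
    )


def read_wav(path, calibration_db: float = DEFAULT_CALIBRATION_DB) -> AudioSignal:
    """Read a mono 16-kHz RIFF WAV (PCM16 or float) as an AudioSignal."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if rate != SAMPLE_RATE:
        raise ValueError(f"unsupported sample rate {rate}; expected {SAMPLE_RATE}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return AudioSignal(samples=samples, calibration_db=calibration_db)


def write_wav(path, signal: AudioSignal) -> None:
    """Write an AudioSignal as a float32 WAV."""
    wavfile.write(path, signal.sample_rate, signal.samples.astype(np.float32))


def spectra_to_frame(times: np.ndarray, levels: np.ndarray) -> pd.DataFrame:
    """Band-level series as a DataFrame (frame_time_s, band_01..band_61)."""
    cols = {f"band_{b + 1:02d}": levels[:, b] for b in range(levels.shape[1])}
    return pd.DataFrame({"frame_time_s": times, **cols})


def spectra_to_csv(path, times: np.ndarray, levels: np.ndarray) -> None:
    spectra_to_frame(times, levels).to_csv(path, index=False)
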