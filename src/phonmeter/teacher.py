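"""Reference time-varying loudness model (the distillation "teacher").

Implements the classic loudness-model cascade of Glasberg and Moore for a
61-band short-term spectrum:

1. outer-ear (free field to eardrum, frontal incidence) and middle-ear
   transfer applied to the band levels;
2. an excitation pattern computed from the effective spectrum with
   level-dependent rounded-exponential (roex) auditory filters, evaluated
   at 150 channels spaced 0.25 Cam apart from 1.75 to 39 Cam on the
   ERB_N-number scale;
3. a compressive transform of excitation into specific loudness
   (sones per Cam);
4. summation of specific loudness across channels into instantaneous
   loudness in sones, converted to loudness level in phons through a
   mapping calibrated on 1-kHz pure tones;
5. asymmetric attack/release smoothing of the instantaneous loudness into
   short-term and long-term loudness; the maximum of the long-term trace
   is the overall loudness.

Each band of the input spectrum is treated as a single sinusoidal
component at the band centre.  The phon mapping is built by running the
complete model end to end on 1-kHz tones, so the phon scale satisfies its
definition (a 1-kHz tone at L dB SPL has loudness level L phons) by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frontend import (
    ANALYSIS_WINDOW,
    BandDefinition,
    BandSpectrum,
    AudioSignal,
    DEFAULT_CALIBRATION_DB,
    DFT_SIZE,
    HOP_TRACE,
    SAMPLE_RATE,
    SILENCE_FLOOR_DB,
    band_spectra,
    design_bands,
)

# ---------------------------------------------------------------------------
# ERB_N-number (Cam) scale
# ---------------------------------------------------------------------------

_CAM_A = 21.4
_CAM_B = 4.37  # per kHz


def cam_from_frequency(f_hz):
    """ERB_N-number (in Cams) at frequency ``f_hz``.

    Uses the standard formula ``21.4 * log10(4.37 * f_kHz + 1)``; strictly
    increasing with frequency and zero at 0 Hz.
    """
    f = np.asarray(f_hz, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = _CAM_A * np.log10(_CAM_B * f / 1000.0 + 1.0)
    return float(out) if np.isscalar(f_hz) else out


def frequency_from_cam(cam):
    """Inverse of :func:`cam_from_frequency` (Hz)."""
    c = np.asarray(cam, dtype=np.float64)
    out = (10.0 ** (c / _CAM_A) - 1.0) / _CAM_B * 1000.0
    return float(out) if np.isscalar(cam) else out


def erb_at(f_hz):
    """Equivalent rectangular bandwidth (Hz) of the auditory filter at f."""
    f = np.asarray(f_hz, dtype=np.float64)
    out = 24.7 * (_CAM_B * f / 1000.0 + 1.0)
    return float(out) if np.isscalar(f_hz) else out


# Specific-loudness channels: Cam 1.75 to 39.00 in 0.25 steps (150 channels).
CHANNEL_CAMS = np.arange(1.75, 39.0 + 1e-9, 0.25)
CHANNEL_FREQS = frequency_from_cam(CHANNEL_CAMS)
CAM_STEP = 0.25
N_CHANNELS = len(CHANNEL_CAMS)

# ---------------------------------------------------------------------------
# Outer/middle-ear transfer
# ---------------------------------------------------------------------------

# Free-field-to-eardrum transfer for frontal incidence, dB gain re free
# field.  The broad maximum near 3 kHz is the ear-canal resonance.
FREE_FIELD_TO_EARDRUM = np.array([
    [15.0, 0.0], [20.0, 0.0], [50.0, 0.0], [100.0, 0.0], [200.0, 0.5], [315.0, 1.4],
    [400.0, 1.6], [500.0, 1.7], [630.0, 2.5], [800.0, 2.6], [1000.0, 2.6],
    [1250.0, 3.2], [1600.0, 6.6], [2000.0, 12.0], [2500.0, 16.8],
    [3000.0, 15.3], [3150.0, 15.2], [4000.0, 14.2], [5000.0, 10.7],
    [6000.0, 7.1], [6300.0, 6.4], [8000.0, 1.8],
])

# Effective middle-ear transfer, dB.  Low frequencies are attenuated by the
# stiffness of the middle ear; a shallow dip appears above 1 kHz.
MIDDLE_EAR = np.array([
    [15.0, -45.0], [20.0, -39.6], [25.0, -32.0], [31.5, -25.9], [40.0, -21.4],
    [50.0, -18.5], [63.0, -15.9], [80.0, -14.1], [100.0, -12.4],
    [125.0, -11.0], [160.0, -9.6], [200.0, -8.3], [250.0, -7.4],
    [315.0, -6.2], [400.0, -4.8], [500.0, -3.8], [630.0, -3.3],
    [800.0, -2.6], [1000.0, -2.6], [1250.0, -4.5], [1600.0, -6.1],
    [2000.0, -8.5], [2500.0, -10.4], [3000.0, -7.3], [3150.0, -7.0],
    [4000.0, -6.7], [5000.0, -8.2], [6000.0, -11.2], [6300.0, -10.9],
    [8000.0, -10.1],
])


@dataclass
class EarTransfer:
    """Outer- and middle-ear gain tables (dB vs frequency)."""

    outer: np.ndarray
    middle: np.ndarray

    def combined_gain(self, f_hz: np.ndarray) -> np.ndarray:
        """Total outer+middle ear gain, interpolated on a log-f axis."""
        f = np.atleast_1d(np.asarray(f_hz, dtype=np.float64))
        for table in (self.outer, self.middle):
            if np.any(f < table[0, 0] - 1e-9) or np.any(f > table[-1, 0] + 1e-9):
                raise ValueError("frequency outside the ear-transfer tables")
        logf = np.log10(f)
        g_outer = np.interp(logf, np.log10(self.outer[:, 0]), self.outer[:, 1])
        g_middle = np.interp(logf, np.log10(self.middle[:, 0]), self.middle[:, 1])
        return g_outer + g_middle


DEFAULT_EAR = EarTransfer(outer=FREE_FIELD_TO_EARDRUM, middle=MIDDLE_EAR)


def ear_filter(spectrum: BandSpectrum, bands: BandDefinition,
               transfer: EarTransfer = DEFAULT_EAR) -> BandSpectrum:
    """Apply outer+middle-ear gain at the band centres; keep the floor."""
    gain = transfer.combined_gain(bands.centers_hz)
    levels = np.maximum(spectrum.levels + gain, SILENCE_FLOOR_DB)
    return BandSpectrum(levels=levels, frame_time=spectrum.frame_time)


# ---------------------------------------------------------------------------
# Excitation patterns (level-dependent roex filters)
# ---------------------------------------------------------------------------

_P51_1K = 4.0 * 1000.0 / erb_at(1000.0)   # roex slope at 1 kHz, 51 dB


def excitation_pattern(levels_db: np.ndarray,
                       component_freqs: np.ndarray) -> np.ndarray:
    """Excitation (dB) at the 150 channels for one or more spectra.

    ``levels_db``: component levels at the eardrum, shape (..., n_comp);
    ``component_freqs``: component frequencies, shape (n_comp,).
    Each component passes through a roex(p) filter centred on each channel:
    ``W(g) = (1 + p|g|) exp(-p|g|)`` with ``g`` the normalised frequency
    deviation.  The lower-side slope flattens with component level at
    0.35 dB per dB (relative to its value at 51 dB), which produces the
    upward spread of excitation; the upper-side slope is level-invariant.
    Component intensities are summed in power at each channel.
    """
    X = np.atleast_2d(np.asarray(levels_db, dtype=np.float64))
    fc = np.asarray(component_freqs, dtype=np.float64)

    p51 = 4.0 * CHANNEL_FREQS / erb_at(CHANNEL_FREQS)          # (150,)
    g = (fc[:, None] - CHANNEL_FREQS[None, :]) / CHANNEL_FREQS[None, :]
    abs_g = np.abs(g)                                          # (n_comp, 150)

    # level-dependent lower slope, clamped to stay a decaying filter
    Xc = np.clip(X, 0.0, 110.0)                                # (n, n_comp)
    p_l = p51[None, None, :] - 0.35 * (p51[None, None, :] / _P51_1K) * (
        Xc[:, :, None] - 51.0
    )
    p_l = np.maximum(p_l, 0.1)
    p = np.where(g[None, :, :] < 0.0, p_l, p51[None, None, :])

    pg = p * abs_g[None, :, :]
    W = (1.0 + pg) * np.exp(-pg)
    intensity = 10.0 ** (X / 10.0)                             # (n, n_comp)
    E = np.einsum("ncj,nc->nj", W, intensity)

    out = 10.0 * np.log10(np.maximum(E, 1e-10))
    if np.asarray(levels_db).ndim == 1:
        return out[0]
    return out


# ---------------------------------------------------------------------------
# Specific loudness
# ---------------------------------------------------------------------------

# Excitation level at the threshold of hearing in quiet (dB) versus channel
# frequency.  Constant at 3.63 dB from 500 Hz upward; rises toward low
# frequencies as the cochlear active mechanism applies less gain.
_ETHRQ_TABLE = np.array([
    [20.0, 38.0], [50.0, 28.18], [63.0, 23.9], [80.0, 19.2], [100.0, 15.68],
    [125.0, 12.67], [160.0, 10.09], [200.0, 8.08], [250.0, 6.3],
    [315.0, 5.3], [400.0, 4.2], [500.0, 3.63], [16000.0, 3.63],
])

_SPECIFIC_LOUDNESS_C = 0.047


def _channel_constants() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel threshold, low-level gain G, and constants A and alpha.

    G is the cochlear gain relative to 500 Hz implied by the threshold
    curve; A and alpha vary smoothly with G (interpolated between the
    published anchor values alpha = 0.2, A = 4.72 at G = 0 dB and
    alpha = 0.267, A = 8.8 at G = -25 dB).
    """
    ethrq_db = np.interp(
        np.log10(CHANNEL_FREQS), np.log10(_ETHRQ_TABLE[:, 0]), _ETHRQ_TABLE[:, 1]
    )
    g_db = 3.63 - ethrq_db                 # <= 0
    G = 10.0 ** (g_db / 10.0)
    alpha = np.interp(g_db, [-25.0, 0.0], [0.26692, 0.2])
    A = np.interp(g_db, [-25.0, 0.0], [8.8, 4.72])
    ethrq = 10.0 ** (ethrq_db / 10.0)
    return ethrq, G, A, alpha


_ETHRQ, _G, _A, _ALPHA = _channel_constants()


def specific_loudness(excitation_db: np.ndarray) -> np.ndarray:
    """Specific loudness N' (sones per Cam) from excitation in dB.

    Piecewise compressive transform: below the threshold excitation the
    output shrinks rapidly but continuously; in the mid range
    ``N' = C[(G E + A)^alpha - A^alpha]`` with alpha < 1 (cochlear
    compression); above E = 1e10 a square-root branch takes over.
    """
    exc = np.asarray(excitation_db, dtype=np.float64)
    E = 10.0 ** (exc / 10.0)
    C = _SPECIFIC_LOUDNESS_C

    core = C * ((_G * E + _A) ** _ALPHA - _A**_ALPHA)
    low = core * (2.0 * E / (E + _ETHRQ)) ** 1.5
    high = C * (E / 1.04e6) ** 0.5

    n_prime = np.where(E <= _ETHRQ, low, core)
    n_prime = np.where(E > 1e10, high, n_prime)
    return np.maximum(n_prime, 0.0)


def instantaneous_sones(n_prime: np.ndarray) -> np.ndarray:
    """Sum specific loudness over channels (rectangle rule, 0.25-Cam steps)."""
    return CAM_STEP * np.asarray(n_prime).sum(axis=-1)


# ---------------------------------------------------------------------------
# Temporal smoothing
# ---------------------------------------------------------------------------


@dataclass
class SmootherConfig:
    """Attack/release coefficients per 1-ms step for the two smoothing stages.

    The published values of the time-varying loudness model: the short-term
    stage tracks word-sized events (attack 0.045, release 0.02) and the
    long-term stage tracks sentence-sized events (attack 0.01,
    release 0.0005).  Attack exceeds release in each stage, so loudness
    builds up faster than it decays.
    """

    short_attack: float = 0.045
    short_release: float = 0.02
    long_attack: float = 0.01
    long_release: float = 0.0005

    def __post_init__(self) -> None:
        for a, r in ((self.short_attack, self.short_release),
                     (self.long_attack, self.long_release)):
            if not (0.0 < r < a < 1.0):
                raise ValueError(
                    "coefficients must satisfy 0 < release < attack < 1"
                )


DEFAULT_SMOOTHER = SmootherConfig()


def _asymmetric_smooth(x: np.ndarray, attack: float, release: float) -> np.ndarray:
    """One-pole smoother with separate attack and release coefficients."""
    y = np.empty_like(x)
    state = 0.0
    for i, v in enumerate(x):
        a = attack if v > state else release
        state = state + a * (v - state)
        y[i] = state
    return y


@dataclass
class LoudnessTrace:
    """Instantaneous / short-term / long-term loudness level over time."""

    times: np.ndarray
    instantaneous: np.ndarray
    short_term: np.ndarray
    long_term: np.ndarray

    @property
    def overall(self) -> float:
        """Overall loudness: the maximum of the long-term loudness."""
        return overall_loudness(self)


def overall_loudness(trace: LoudnessTrace) -> float:
    if len(trace.long_term) == 0:
        raise ValueError("empty loudness trace")
    return float(np.max(trace.long_term))


# ---------------------------------------------------------------------------
# The assembled teacher
# ---------------------------------------------------------------------------


class Teacher:
    """End-to-end reference loudness model over the 61-band front end.

    Builds its sone-to-phon mapping on first use by running itself on
    1-kHz pure tones from 0 to 110 dB SPL in 0.25-dB steps (synthesised
    through the same front end), then inverting the resulting
    level-to-sone curve.  This makes the phon output exact by definition
    at 1 kHz.
    """

    def __init__(self, bands: BandDefinition | None = None,
                 ear: EarTransfer = DEFAULT_EAR,
                 smoother: SmootherConfig = DEFAULT_SMOOTHER,
                 chunk: int = 64):
        self.bands = bands if bands is not None else design_bands()
        self.ear = ear
        self.smoother = smoother
        self.chunk = chunk
        self._ear_gain = ear.combined_gain(self.bands.centers_hz)
        self._cal_levels: np.ndarray | None = None
        self._cal_log_sones: np.ndarray | None = None

    # -- core spectrum-to-loudness path ------------------------------------

    def sones_from_levels(self, levels: np.ndarray) -> np.ndarray:
        """Instantaneous loudness in sones for band-level rows (..., 61)."""
        L = np.atleast_2d(np.asarray(levels, dtype=np.float64))
        out = np.empty(L.shape[0])
        for start in range(0, L.shape[0], self.chunk):
            block = L[start : start + self.chunk]
            eff = np.maximum(block + self._ear_gain[None, :], SILENCE_FLOOR_DB)
            exc = excitation_pattern(eff, self.bands.centers_hz)
            n_prime = specific_loudness(exc)
            out[start : start + block.shape[0]] = instantaneous_sones(n_prime)
        if np.asarray(levels).ndim == 1:
            return out[0]
        return out

    # -- phon calibration ---------------------------------------------------

    def _build_calibration(self) -> None:
        levels = np.arange(0.0, 110.0 + 1e-9, 0.25)
        n = np.arange(DFT_SIZE)
        # 1 kHz is exactly bin 64 at 16 kHz / 1024 points
        tone = np.sin(2.0 * np.pi * 1000.0 * n / SAMPLE_RATE)
        frame = tone * ANALYSIS_WINDOW
        amps = np.sqrt(2.0) * 10.0 ** ((levels - DEFAULT_CALIBRATION_DB) / 20.0)
        frames = amps[:, None] * frame[None, :]
        from .frontend import _banded_power

        power = _banded_power(frames, self.bands)
        with np.errstate(divide="ignore"):
            spec = DEFAULT_CALIBRATION_DB + 10.0 * np.log10(power)
        spec = np.maximum(spec, SILENCE_FLOOR_DB)
        sones = self.sones_from_levels(spec)
        if np.any(np.diff(sones) <= 0):
            raise RuntimeError(
                "sone-versus-level curve for 1-kHz tones is not strictly "
                "increasing; the loudness stages are inconsistent"
            )
        self._cal_levels = levels
        self._cal_log_sones = np.log10(sones)

    @property
    def calibration_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(levels dB SPL, sones) pairs of the 1-kHz calibration run."""
        if self._cal_levels is None:
            self._build_calibration()
        return self._cal_levels, 10.0**self._cal_log_sones

    def phons_from_sones(self, sones) -> np.ndarray:
        """Loudness level (phons) from loudness (sones); clipped at 0 phons."""
        if self._cal_levels is None:
            self._build_calibration()
        s = np.atleast_1d(np.asarray(sones, dtype=np.float64))
        out = np.zeros_like(s)
        pos = s > 10.0 ** self._cal_log_sones[0]
        out[pos] = np.interp(
            np.log10(s[pos]), self._cal_log_sones, self._cal_levels
        )
        return float(out[0]) if np.isscalar(sones) or np.ndim(sones) == 0 else out

    def sones_from_phons(self, phons) -> np.ndarray:
        """Inverse phon mapping (phons at or below 0 map to the floor sone)."""
        if self._cal_levels is None:
            self._build_calibration()
        p = np.atleast_1d(np.asarray(phons, dtype=np.float64))
        log_s = np.interp(p, self._cal_levels, self._cal_log_sones)
        out = 10.0**log_s
        return float(out[0]) if np.isscalar(phons) or np.ndim(phons) == 0 else out

    def phons_from_levels(self, levels: np.ndarray) -> np.ndarray:
        """Instantaneous loudness level (phons) for band-level rows."""
        return self.phons_from_sones(self.sones_from_levels(levels))

    # -- time-domain analysis ----------------------------------------------

    def smooth_trace(self, times: np.ndarray,
                     instantaneous_phons: np.ndarray) -> LoudnessTrace:
        """Short- and long-term loudness from a 1-ms instantaneous series.

        Smoothing operates in the sone domain (the loudness quantity that
        the ear integrates), then converts back to phons.
        """
        inst = np.asarray(instantaneous_phons, dtype=np.float64)
        if inst.size == 0:
            raise ValueError("empty loudness series")
        sones = np.asarray(self.sones_from_phons(inst))
        st = _asymmetric_smooth(
            sones, self.smoother.short_attack, self.smoother.short_release
        )
        lt = _asymmetric_smooth(
            st, self.smoother.long_attack, self.smoother.long_release
        )
        return LoudnessTrace(
            times=np.asarray(times),
            instantaneous=np.maximum(inst, 0.0),
            short_term=np.asarray(self.phons_from_sones(st)),
            long_term=np.asarray(self.phons_from_sones(lt)),
        )

    def analyze(self, signal: AudioSignal, hop: int = HOP_TRACE) -> LoudnessTrace:
        """Full loudness trace (1-ms hop by default) for a waveform."""
        times, levels = band_spectra(signal, self.bands, hop=hop)
        inst = self.phons_from_levels(levels)
        return self.smooth_trace(times, inst)


def trace_to_frame(trace: LoudnessTrace):
    import pandas as pd

    return pd.DataFrame({
        "time_s": trace.times,
        "instantaneous_phon": trace.instantaneous,
        "short_term_phon": trace.short_term,
        "long_term_phon": trace.long_term,
    })
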