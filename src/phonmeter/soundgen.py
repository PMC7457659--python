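"""Seeded synthetic sounds and labelled training corpora.

The student network is distilled from the teacher on synthetic material
only: pure tones (15-110 dB SPL) with optional white or pink background
noise up to 10 dB below the tone, bandpass-filtered and spectrally
notched noises with varied level, bandwidth, notch width and spectral
slope, broadband white/pink noise, and a speech surrogate
(amplitude-modulated harmonic complexes with moving formant-like
resonances and silent gaps) standing in for a real speech corpus.

Every sound is generated from an explicit integer seed, so corpora are
bit-reproducible.  ``build_corpus`` frames each sound, computes 61-band
spectra and labels every frame with the teacher's instantaneous loudness
level in phons, then assigns a seeded 90/10 train/validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .frontend import (
    AudioSignal,
    BandDefinition,
    HOP_CORPUS,
    SAMPLE_RATE,
    band_spectra,
    scale_to_rms_level,
)
from .teacher import Teacher

KINDS = (
    "tone",
    "tone_in_noise",
    "bandpass_noise",
    "notched_noise",
    "white_noise",
    "pink_noise",
    "speech_surrogate",
)

_BROADBAND_LO = 15.0     # lower edge of broadband noises, Hz
_BROADBAND_HI = 8000.0


@dataclass
class SoundSpec:
    """Recipe for one synthetic sound."""

    kind: str
    level_db: float               # RMS level of the primary component
    duration: float = 1.0         # seconds
    seed: int = 0
    frequency: float = 1000.0     # tone frequency / noise centre, Hz
    noise_color: str = "white"    # background colour for tone_in_noise
    noise_level_db: float | None = None   # background level, dB SPL
    bandwidth_oct: float = 1.0    # bandpass noise width, octaves
    notch_oct: float = 1.0        # notch width, octaves
    slope_db_oct: float = 0.0     # spectral slope within the passband

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown sound kind {self.kind!r}")
        if not (0.0 <= self.level_db <= 110.0):
            raise ValueError("level must lie within 0-110 dB SPL")
        if self.kind in ("tone", "tone_in_noise") and not (
            20.0 <= self.frequency <= 8000.0
        ):
            raise ValueError("tone frequency must lie within 20-8000 Hz")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "tone_in_noise":
            if self.noise_level_db is None:
                raise ValueError("tone_in_noise requires noise_level_db")
            if self.noise_level_db > self.level_db - 10.0:
                raise ValueError(
                    "background noise must stay at least 10 dB below the tone"
                )
            if self.noise_color not in ("white", "pink"):
                raise ValueError("noise colour must be white or pink")
        if self.kind == "bandpass_noise" and self.bandwidth_oct <= 0:
            raise ValueError("bandwidth must be positive")
        if self.kind == "notched_noise" and self.notch_oct < 0:
            raise ValueError("notch width must be non-negative")


def _shaped_noise(
    rng: np.random.Generator,
    n: int,
    f_lo: float,
    f_hi: float,
    slope_db_oct: float = 0.0,
    slope_ref: float | None = None,
    notch: tuple[float, float] | None = None,
) -> np.ndarray:
    """Gaussian noise spectrally shaped in the DFT domain (unit-ish RMS)."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / SAMPLE_RATE)
    amp = np.zeros_like(f)
    in_band = (f >= f_lo) & (f <= f_hi)
    amp[in_band] = 1.0
    if slope_db_oct != 0.0:
        ref = slope_ref if slope_ref is not None else np.sqrt(f_lo * f_hi)
        with np.errstate(divide="ignore"):
            octaves = np.log2(np.maximum(f, 1e-6) / ref)
        amp *= 10.0 ** (slope_db_oct * octaves / 20.0)
    if notch is not None:
        amp[(f >= notch[0]) & (f <= notch[1])] = 0.0
    y = np.fft.irfft(spec * amp, n=n)
    rms = np.sqrt(np.mean(y**2))
    if rms == 0.0:
        raise ValueError("spectral shaping removed all energy")
    return y / rms


def synthesize(spec: SoundSpec) -> AudioSignal:
    """Render a SoundSpec to a calibrated waveform (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE

    if spec.kind == "speech_surrogate":
        return speech_surrogate(spec.seed, spec.duration, spec.level_db)

    if spec.kind in ("tone", "tone_in_noise"):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = np.sqrt(2.0) * np.sin(2.0 * np.pi * spec.frequency * t + phase)
        sig = scale_to_rms_level(AudioSignal(x), spec.level_db)
        if spec.kind == "tone_in_noise":
            if spec.noise_color == "pink":
                noise = _shaped_noise(
                    rng, n, _BROADBAND_LO, _BROADBAND_HI, -3.0, slope_ref=1000.0
                )
            else:
                noise = _shaped_noise(rng, n, _BROADBAND_LO, _BROADBAND_HI)
            noise_sig = scale_to_rms_level(AudioSignal(noise), spec.noise_level_db)
            sig = AudioSignal(sig.samples + noise_sig.samples)
        return sig

    if spec.kind == "white_noise":
        x = _shaped_noise(rng, n, _BROADBAND_LO, _BROADBAND_HI)
    elif spec.kind == "pink_noise":
        x = _shaped_noise(
            rng, n, _BROADBAND_LO, _BROADBAND_HI, -3.0, slope_ref=1000.0
        )
    elif spec.kind == "bandpass_noise":
        half = spec.bandwidth_oct / 2.0
        f_lo = max(spec.frequency * 2.0**-half, 1.0)
        f_hi = min(spec.frequency * 2.0**half, _BROADBAND_HI)
        # a vanishing bandwidth degenerates to a tone at the centre frequency
        if f_hi - f_lo < SAMPLE_RATE / n:
            x = np.sqrt(2.0) * np.sin(2.0 * np.pi * spec.frequency * t)
        else:
            x = _shaped_noise(rng, n, f_lo, f_hi, spec.slope_db_oct)
    elif spec.kind == "notched_noise":
        half = spec.notch_oct / 2.0
        notch = (spec.frequency * 2.0**-half, spec.frequency * 2.0**half)
        x = _shaped_noise(
            rng, n, 50.0, _BROADBAND_HI, spec.slope_db_oct,
            slope_ref=1000.0, notch=notch if spec.notch_oct > 0 else None,
        )
    else:  # pragma: no cover - guarded by SoundSpec validation
        raise ValueError(spec.kind)

    return scale_to_rms_level(AudioSignal(x), spec.level_db)


def _smooth_walk(rng, n, cutoff_hz, lo, hi):
    """Slowly varying random track in [lo, hi] (log-domain random walk)."""
    steps = max(int(n * cutoff_hz / SAMPLE_RATE) * 2 + 3, 4)
    knots = rng.uniform(0.0, 1.0, steps)
    x = np.interp(np.linspace(0, steps - 1, n), np.arange(steps), knots)
    return lo * (hi / lo) ** x


def speech_surrogate(seed: int, duration: float, level_db: float) -> AudioSignal:
    """Speech-like test signal: voiced harmonics + formants + pauses.

    A harmonic complex with a wandering fundamental (80-280 Hz) is shaped
    by three slowly moving formant-like resonances, modulated at a
    syllabic rate, interrupted by silent gaps, and mixed with weak gated
    high-frequency noise bursts (fricative-like).  The result has a
    broadband long-term spectrum below 8 kHz and an instantaneous-loudness
    distribution spanning tens of phons, including near-silence.
    """
    if duration < 0.5:
        raise ValueError("speech surrogate requires at least 0.5 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE

    f0 = _smooth_walk(rng, n, 3.0, 80.0, 280.0)
    phase = 2.0 * np.pi * np.cumsum(f0) / SAMPLE_RATE

    formants = [
        _smooth_walk(rng, n, 2.0, 300.0, 900.0),
        _smooth_walk(rng, n, 2.0, 900.0, 2400.0),
        _smooth_walk(rng, n, 1.5, 2400.0, 3400.0),
    ]
    bws = (120.0, 180.0, 260.0)

    max_harmonics = int(7800.0 // 80.0)
    x = np.zeros(n)
    for h in range(1, max_harmonics + 1):
        fh = h * f0
        active = fh < 7800.0
        if not np.any(active):
            break
        envelope = sum(
            1.0 / (1.0 + ((fh - F) / B) ** 2) for F, B in zip(formants, bws)
        )
        envelope = envelope * (fh / 500.0) ** -0.3   # gentle spectral tilt
        x += np.where(active, envelope, 0.0) * np.sin(h * phase)

    # syllabic modulation with true silent gaps
    syll = _smooth_walk(rng, n, 5.0, 0.05, 1.0)
    gate = (_smooth_walk(rng, n, 1.5, 0.1, 1.0) > 0.22).astype(float)
    # soften gate edges to avoid clicks
    from scipy.ndimage import uniform_filter1d

    gate = uniform_filter1d(gate, size=161)
    x *= syll * gate

    # weak fricative-like bursts
    frico = _shaped_noise(rng, n, 2000.0, 7800.0)
    burst = (_smooth_walk(rng, n, 4.0, 0.05, 1.0) > 0.75).astype(float)
    burst = uniform_filter1d(burst, size=161)
    x += 0.15 * np.sqrt(np.mean(x**2)) / max(np.sqrt(np.mean(frico**2)), 1e-12) \
        * frico * burst * 3.0

    return scale_to_rms_level(AudioSignal(x), level_db)


# ---------------------------------------------------------------------------
# Corpus manifests
# ---------------------------------------------------------------------------


@dataclass
class CorpusManifest:
    """Seeded description of a synthetic training/evaluation set."""

    specs: list
    seed: int = 0
    train_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")

    @property
    def class_counts(self) -> dict:
        counts: dict[str, int] = {}
        for s in self.specs:
            counts[s.kind] = counts.get(s.kind, 0) + 1
        return counts

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "train_fraction": self.train_fraction,
                "specs": [asdict(s) for s in self.specs],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CorpusManifest":
        obj = json.loads(text)
        specs = [SoundSpec(**d) for d in obj["specs"]]
        return cls(
            specs=specs,
            seed=obj["seed"],
            train_fraction=obj["train_fraction"],
        )


def _rows_per_sound(duration: float, hop: int) -> int:
    n = int(round(duration * SAMPLE_RATE))
    return (n - 1024) // hop + 1


def _random_artificial_spec(
    rng: np.random.Generator, seed: int, duration: float = 0.064
) -> SoundSpec:
    """One tones-and-noises sound with the default parameter distributions.

    Tone levels cover 15-110 dB SPL; noise levels 20-100 dB SPL; bandwidth
    log-uniform over 0.1-5 octaves; notch width uniform 0-2 octaves;
    spectral slope uniform -6 to +6 dB/octave; background noise for tones
    from far below up to 10 dB below the tone.
    """
    kind = rng.choice(
        ["tone", "tone_in_noise", "bandpass_noise", "notched_noise",
         "white_noise", "pink_noise"],
        p=[0.21, 0.21, 0.21, 0.21, 0.08, 0.08],
    )
    freq = float(np.exp(rng.uniform(np.log(50.0), np.log(7500.0))))
    if kind in ("tone", "tone_in_noise"):
        level = float(rng.uniform(15.0, 110.0))
        freq = min(max(freq, 20.0), 8000.0)
    else:
        level = float(rng.uniform(20.0, 100.0))
    kwargs = dict(kind=kind, level_db=level, frequency=freq, seed=seed,
                  duration=duration)
    if kind == "tone_in_noise":
        kwargs["noise_color"] = str(rng.choice(["white", "pink"]))
        kwargs["noise_level_db"] = float(
            rng.uniform(max(level - 60.0, 0.0), level - 10.0)
        )
    elif kind == "bandpass_noise":
        kwargs["bandwidth_oct"] = float(
            np.exp(rng.uniform(np.log(0.1), np.log(5.0)))
        )
        kwargs["slope_db_oct"] = float(rng.uniform(-6.0, 6.0))
    elif kind == "notched_noise":
        kwargs["notch_oct"] = float(rng.uniform(0.0, 2.0))
        kwargs["slope_db_oct"] = float(rng.uniform(-6.0, 6.0))
    return SoundSpec(**kwargs)


def standard_manifest(
    profile: str,
    n_rows: int,
    seed: int,
    hop: int = HOP_CORPUS,
    duration: float = 0.064,
    speech_duration: float = 3.0,
) -> CorpusManifest:
    """Build a manifest of roughly ``n_rows`` labelled frames.

    Profiles: ``"tones_noises"`` (artificial sounds only), ``"speech"``
    (surrogate speech at 60 dB SPL only, mirroring the fixed-level speech
    corpus), and ``"mixed"`` (about 30% speech-surrogate rows and 70%
    artificial rows, the proportion of the full-scale training material).

    Artificial sounds default to a single analysis frame each (0.064 s),
    so a corpus of n rows contains n independently drawn artificial
    spectra — each generated tone or noise contributes one spectrum, as
    in the full-scale training material.  Speech surrogates are longer
    and contribute a frame sequence per utterance.
    """
    if profile not in ("tones_noises", "speech", "mixed"):
        raise ValueError(f"unknown corpus profile {profile!r}")
    rng = np.random.default_rng(seed)
    specs: list[SoundSpec] = []
    rows_art = _rows_per_sound(duration, hop)
    rows_speech = _rows_per_sound(speech_duration, hop)

    speech_rows = {"tones_noises": 0, "speech": n_rows,
                   "mixed": int(0.3 * n_rows)}[profile]
    art_rows = n_rows - speech_rows

    n_speech = int(np.ceil(speech_rows / rows_speech)) if speech_rows else 0
    n_art = int(np.ceil(art_rows / rows_art)) if art_rows else 0

    for _ in range(n_art):
        specs.append(
            _random_artificial_spec(
                rng, seed=int(rng.integers(0, 2**31 - 1)), duration=duration
            )
        )
    for _ in range(n_speech):
        specs.append(
            SoundSpec(
                kind="speech_surrogate",
                level_db=60.0,
                duration=speech_duration,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    if not specs:
        raise ValueError("manifest would be empty")
    return CorpusManifest(specs=specs, seed=seed)


# ---------------------------------------------------------------------------
# Labelled datasets
# ---------------------------------------------------------------------------


@dataclass
class LabelledDataset:
    """Band-spectrum rows with teacher phon labels and a train/val split."""

    inputs: np.ndarray        # (n, 61) dB SPL
    labels: np.ndarray        # (n,) phons
    train_mask: np.ndarray    # (n,) bool
    sound_id: np.ndarray      # (n,) int, index into manifest.specs
    manifest: CorpusManifest

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (
            self.inputs.shape == (n, 61)
            and self.train_mask.shape == (n,)
            and self.sound_id.shape == (n,)
        ):
            raise ValueError("dataset arrays are inconsistent")
        if not np.all(np.isfinite(self.labels)):
            raise ValueError("labels must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[self.train_mask], self.labels[self.train_mask]

    @property
    def validation(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[~self.train_mask], self.labels[~self.train_mask]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["format"] = "phonmeter-dataset-1"
            # manifests can exceed the HDF5 attribute size limit
            f.create_dataset("manifest_json", data=self.manifest.to_json())
            f.create_dataset("inputs", data=self.inputs)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("train_mask", data=self.train_mask)
            f.create_dataset("sound_id", data=self.sound_id)

    @classmethod
    def load(cls, path) -> "LabelledDataset":
        import h5py

        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "phonmeter-dataset-1":
                raise ValueError("not a phonmeter dataset file")
            return cls(
                inputs=f["inputs"][()],
                labels=f["labels"][()],
                train_mask=f["train_mask"][()].astype(bool),
                sound_id=f["sound_id"][()],
                manifest=CorpusManifest.from_json(
                    f["manifest_json"][()].decode()
                ),
            )


def build_corpus(
    manifest: CorpusManifest,
    teacher: Teacher,
    hop: int = HOP_CORPUS,
) -> LabelledDataset:
    """Synthesize, frame, and label every sound in a manifest.

    Frames are labelled with the teacher's instantaneous loudness level;
    the train/validation assignment is a seeded random shuffle of rows
    with ``train_fraction`` of them marked for training.
    """
    if not manifest.specs:
        raise ValueError("empty manifest")
    rows = []
    ids = []
    for i, spec in enumerate(manifest.specs):
        sig = synthesize(spec)
        _, levels = band_spectra(sig, teacher.bands, hop=hop)
        rows.append(levels)
        ids.append(np.full(levels.shape[0], i))
    inputs = np.concatenate(rows, axis=0)
    sound_id = np.concatenate(ids)
    labels = np.asarray(teacher.phons_from_levels(inputs))

    n = len(labels)
    rng = np.random.default_rng(manifest.seed)
    order = rng.permutation(n)
    n_train = int(round(manifest.train_fraction * n))
    train_mask = np.zeros(n, dtype=bool)
    train_mask[order[:n_train]] = True
    return LabelledDataset(
        inputs=inputs,
        labels=labels,
        train_mask=train_mask,
        sound_id=sound_id,
        manifest=manifest,
    )
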