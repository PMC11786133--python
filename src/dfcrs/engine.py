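"""DFCRS band prescription and dual-band +10 dB music enhancement.

The Digital Frequency Customized Relieving Sound (DFCRS) takes a patient's
matched tinnitus pitch and boosts, on a relieving-music carrier, the two
third-octave frequency bands that flank the pitch. The prescription is four
frequency endpoints: with pitch p and an optional guard gap of g octaves,

    lower band = (p * 2**(-g - 1/3),  p * 2**(-g))
    upper band = (p * 2**(+g),        p * 2**(+g + 1/3))

so each band spans exactly one third of an octave (edge ratio 2**(1/3)) and
the bands abut the pitch symmetrically in log frequency when g = 0.

The boost is applied frame-wise in a short-time Fourier transform: every
analysis frame has its in-band bins multiplied by 10**(gain_db/20), with
raised-cosine tapers (1/24 octave) centered on the band edges, then the
frames are overlap-added back. Because the multiplier is constant, the
absolute boost tracks whatever in-band content the music has at that moment
— a constant *relative* +10 dB — while content away from the bands passes
through unchanged. A soft peak limiter with 1 dB of headroom guards against
values leaving [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT, resample_poly, welch
from scipy.signal.windows import hann

__all__ = [
    "BandSpec",
    "AudioSignal",
    "EngineConfig",
    "NyquistError",
    "UndefinedGainError",
    "compute_band_endpoints",
    "apply_dfcrs",
    "measure_band_gain",
    "process_file",
    "read_wav",
    "write_wav",
]

THIRD_OCTAVE = 1.0 / 3.0

REPORT_SCHEMA_VERSION = "1"


class NyquistError(ValueError):
    """The sample rate cannot represent a prescribed band endpoint."""


class UndefinedGainError(ValueError):
    """Band gain is undefined because the reference band power is zero."""


@dataclass(frozen=True)
class BandSpec:
    """A DFCRS prescription: the four band endpoints plus the gain.

    ``lower_band`` and ``upper_band`` are (f_lo, f_hi) pairs in Hz; the four
    numbers f1_lo < f1_hi <= pitch <= f2_lo < f2_hi are the endpoints of the
    modulation range. Each band spans exactly 1/3 octave.
    """

    pitch_hz: float
    lower_band: tuple[float, float]
    upper_band: tuple[float, float]
    gain_db: float = 10.0
    guard_octaves: float = 0.0

    def __post_init__(self) -> None:
        f1_lo, f1_hi = self.lower_band
        f2_lo, f2_hi = self.upper_band
        if not (f1_lo < f1_hi <= self.pitch_hz <= f2_lo < f2_hi):
            raise ValueError(
                "band endpoints must satisfy "
                f"f1_lo < f1_hi <= pitch <= f2_lo < f2_hi, got {self}"
            )
        for lo, hi in (self.lower_band, self.upper_band):
            if abs(math.log2(hi / lo) - THIRD_OCTAVE) > 1e-9:
                raise ValueError(
                    f"band ({lo}, {hi}) does not span 1/3 octave"
                )

    @property
    def endpoints(self) -> tuple[float, float, float, float]:
        """The four endpoints (f1_lo, f1_hi, f2_lo, f2_hi) in Hz."""
        return (*self.lower_band, *self.upper_band)


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform: float samples in [-1, 1], shape (n,) or (n, 2)."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        if x.ndim != 2 or x.shape[1] not in (1, 2):
            raise ValueError(
                f"samples must be mono or stereo, got shape {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", x)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class EngineConfig:
    """Tunables of the STFT boost stage.

    window_samples_at_44k1 is rescaled to the actual sample rate so the
    analysis window keeps a constant duration (~46 ms) and hence constant
    frequency resolution in Hz-per-octave terms.
    """

    gain_db: float = 10.0
    guard_octaves: float = 0.0
    window_samples_at_44k1: int = 2048
    overlap: float = 0.75
    taper_octaves: float = 1.0 / 24.0
    limiter_headroom_db: float = 1.0
    allow_resample: bool = False

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown engine config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_band_endpoints(
    pitch_hz: float,
    guard_octaves: float = 0.0,
    gain_db: float = 10.0,
) -> BandSpec:
    """Compute the four DFCRS band endpoints flanking a tinnitus pitch.

    Parameters
    ----------
    pitch_hz : float
        Matched tinnitus pitch in Hz, > 0.
    guard_octaves : float
        Optional symmetric gap (octaves) between the pitch and each band;
        0 makes the bands abut the pitch.
    gain_db : float
        Boost applied to each band, default +10 dB.
    """
    if not pitch_hz > 0:
        raise ValueError(f"pitch_hz must be > 0, got {pitch_hz}")
    if guard_octaves < 0:
        raise ValueError("guard_octaves must be >= 0")
    g = float(guard_octaves)
    lower = (pitch_hz * 2.0 ** (-g - THIRD_OCTAVE), pitch_hz * 2.0 ** (-g))
    upper = (pitch_hz * 2.0 ** (g), pitch_hz * 2.0 ** (g + THIRD_OCTAVE))
    return BandSpec(
        pitch_hz=float(pitch_hz),
        lower_band=lower,
        upper_band=upper,
        gain_db=float(gain_db),
        guard_octaves=g,
    )


# ---------------------------------------------------------------------------
# STFT boost
# ---------------------------------------------------------------------------

def _band_weight(freqs: np.ndarray, lo: float, hi: float, taper_oct: float) -> np.ndarray:
    """Raised-cosine band window in log frequency: 1 on the band interior,
    with ``taper_oct``-octave cosine transitions centered on the band edges
    (weight 0.5 exactly at each edge)."""
    w = np.zeros_like(freqs)
    pos = freqs > 0
    x = np.full_like(freqs, -np.inf)
    x[pos] = np.log2(freqs[pos])
    llo, lhi = math.log2(lo), math.log2(hi)
    t = min(taper_oct, (lhi - llo) / 2.0)
    h = t / 2.0
    w[(x >= llo + h) & (x <= lhi - h)] = 1.0
    if t > 0:
        rise = (x >= llo - h) & (x < llo + h)
        w[rise] = 0.5 - 0.5 * np.cos(np.pi * (x[rise] - llo + h) / t)
        fall = (x > lhi - h) & (x <= lhi + h)
        w[fall] = 0.5 - 0.5 * np.cos(np.pi * (lhi + h - x[fall]) / t)
    return w


def _gain_mask(freqs: np.ndarray, spec: BandSpec, taper_oct: float) -> np.ndarray:
    boost = 10.0 ** (spec.gain_db / 20.0) - 1.0
    w = _band_weight(freqs, *spec.lower_band, taper_oct) + _band_weight(
        freqs, *spec.upper_band, taper_oct
    )
    return 1.0 + boost * np.clip(w, 0.0, 1.0)


def _soft_limit(x: np.ndarray, headroom_db: float) -> np.ndarray:
    """Identity below the threshold 10**(-headroom/20); tanh soft knee above,
    asymptoting at full scale. Leaves signals under the threshold untouched."""
    thr = 10.0 ** (-headroom_db / 20.0)
    over = np.abs(x) > thr
    if not np.any(over):
        return x
    y = x.copy()
    span = 1.0 - thr
    y[over] = np.sign(x[over]) * (
        thr + span * np.tanh((np.abs(x[over]) - thr) / span)
    )
    return y


def _check_nyquist(sample_rate: float, spec: BandSpec) -> None:
    f2_hi = spec.upper_band[1]
    if sample_rate <= 2.0 * f2_hi:
        raise NyquistError(
            f"upper band endpoint f2_hi = {f2_hi:.1f} Hz requires a sample "
            f"rate above {2.0 * f2_hi:.1f} Hz; got {sample_rate:g} Hz"
        )


def apply_dfcrs(
    audio: AudioSignal,
    spec: BandSpec,
    config: EngineConfig | None = None,
) -> AudioSignal:
    """Boost the two prescribed flanking bands of ``audio`` by ``spec.gain_db``.

    Returns a signal of identical length, rate and channel count. Stereo
    channels are processed independently with identical filters.

    Raises
    ------
    NyquistError
        If the sample rate cannot represent the upper band edge.
    ValueError
        On empty audio.
    """
    cfg = config or EngineConfig()
    if audio.n_samples == 0:
        raise ValueError("cannot process empty audio")
    _check_nyquist(audio.sample_rate, spec)

    nwin = int(round(cfg.window_samples_at_44k1 * audio.sample_rate / 44100.0))
    nwin = max(256, 1 << (nwin - 1).bit_length())  # power of two, >= 256
    hop = max(1, int(round(nwin * (1.0 - cfg.overlap))))
    win = hann(nwin, sym=False)
    sft = ShortTimeFFT(win, hop=hop, fs=audio.sample_rate, fft_mode="onesided")
    mask = _gain_mask(sft.f, spec, cfg.taper_octaves)

    out = np.empty_like(audio.samples)
    n = audio.n_samples
    npad = max(n, nwin)  # STFT needs at least one full window of input
    for ch in range(audio.channels):
        x = audio.samples[:, ch]
        if npad > n:
            x = np.pad(x, (0, npad - n))
        S = sft.stft(x)
        S *= mask[:, None]
        y = sft.istft(S, k1=npad)
        out[:, ch] = _soft_limit(np.real(y[:n]), cfg.limiter_headroom_db)
    res = AudioSignal(out if audio.channels > 1 else out[:, 0], audio.sample_rate)
    return res


def measure_band_gain(
    original: AudioSignal,
    processed: AudioSignal,
    f_lo: float,
    f_hi: float,
) -> float:
    """Band-limited power ratio processed/original in dB.

    Integrates Welch power spectral densities over [f_lo, f_hi] and returns
    10*log10 of the ratio. Used as the verification oracle for the boost.
    """
    if original.n_samples != processed.n_samples:
        raise ValueError("signals must have equal length")
    if original.sample_rate != processed.sample_rate:
        raise ValueError("signals must share a sample rate")
    fs = original.sample_rate
    nper = min(8192, original.n_samples)
    x = original.samples.mean(axis=1)
    y = processed.samples.mean(axis=1)
    f, pxx = welch(x, fs=fs, nperseg=nper)
    _, pyy = welch(y, fs=fs, nperseg=nper)
    sel = (f >= f_lo) & (f <= f_hi)
    p_orig = float(np.trapezoid(pxx[sel], f[sel])) if sel.sum() > 1 else float(pxx[sel].sum())
    p_proc = float(np.trapezoid(pyy[sel], f[sel])) if sel.sum() > 1 else float(pyy[sel].sum())
    if p_orig <= 0.0 or not np.isfinite(p_orig):
        raise UndefinedGainError(
            f"original signal has no power in [{f_lo:g}, {f_hi:g}] Hz"
        )
    return 10.0 * math.log10(p_proc / p_orig)


# ---------------------------------------------------------------------------
# WAV plumbing
# ---------------------------------------------------------------------------

_INT_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path) -> tuple[AudioSignal, str]:
    """Read a WAV file into float [-1, 1]; returns (signal, source_format).

    Supports PCM16, PCM24/32 (both arrive as int32) and float32/float64.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise ValueError(f"unreadable or unsupported WAV file {path}: {exc}") from exc
    if data.dtype in _INT_SCALES:
        fmt = "pcm16" if data.dtype == np.int16 else "pcm32"
        x = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        fmt = "pcm8"
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        fmt = "float32"
        x = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return AudioSignal(x, float(rate)), fmt


def write_wav(path, audio: AudioSignal, fmt: str = "float32") -> None:
    """Write a signal as PCM16 or float32 WAV (other inputs fall back to float32)."""
    x = audio.samples if audio.channels > 1 else audio.samples[:, 0]
    if fmt == "pcm16":
        data = np.clip(np.round(x * 2**15), -(2**15), 2**15 - 1).astype(np.int16)
    else:
        data = x.astype(np.float32)
    wavfile.write(path, int(audio.sample_rate), data)


def process_file(
    in_wav,
    pitch_hz: float,
    out_wav,
    config: EngineConfig | None = None,
) -> dict:
    """End-to-end: read WAV, prescribe bands for ``pitch_hz``, boost, write,
    and return a verification report (band endpoints, measured per-band gains,
    peak level, duration)."""
    cfg = config or EngineConfig()
    audio, fmt = read_wav(in_wav)
    spec = compute_band_endpoints(pitch_hz, cfg.guard_octaves, cfg.gain_db)
    if cfg.allow_resample and audio.sample_rate <= 2.0 * spec.upper_band[1]:
        for target in (44100, 48000, 96000, 192000):
            if target > 2.0 * spec.upper_band[1]:
                break
        up, down = target, int(audio.sample_rate)
        g = math.gcd(up, down)
        y = resample_poly(audio.samples, up // g, down // g, axis=0)
        audio = AudioSignal(y, float(target))
    processed = apply_dfcrs(audio, spec, cfg)
    write_wav(out_wav, processed, "pcm16" if fmt == "pcm16" else "float32")
    gains = {
        "lower_band_db": measure_band_gain(audio, processed, *spec.lower_band),
        "upper_band_db": measure_band_gain(audio, processed, *spec.upper_band),
    }
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "pitch_hz": spec.pitch_hz,
        "band_endpoints_hz": list(spec.endpoints),
        "gain_db": spec.gain_db,
        "measured_gain_db": gains,
        "peak_level": float(np.max(np.abs(processed.samples))),
        "duration_s": processed.duration_s,
        "sample_rate_hz": processed.sample_rate,
        "channels": processed.channels,
        "source_format": fmt,
    }
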