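"""Audio loading and Mel + PCEN feature extraction.

The detector consumes log-free Mel-band energy patches. Recordings are
resampled to a common 22.05 kHz rate, converted to a 128-band Mel power
spectrogram (1024-point FFT, 256-sample hop, centered frames with reflect
padding) and passed through per-channel energy normalization (PCEN), an
adaptive-gain + root-compression transform that flattens stationary
background noise and channel gain differences — important for field
recordings where the noise floor varies between devices and sites.

Frames are then grouped into short fixed-size patches (``seg_len_s`` seconds
long, advancing by ``seg_hop_s``) which are the unit the encoder embeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, lfilter, resample_poly

DEFAULT_SAMPLE_RATE = 22050


@dataclass
class Waveform:
    """Mono audio in [-1, 1] at a known sample rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class MelConfig:
    """Mel spectrogram parameters.

    ``hop_mel`` (in samples) sets the STFT/Mel frame hop; ``seg_len_s`` and
    ``seg_hop_s`` (in seconds) set how frames are grouped into encoder
    patches. ``eps`` is the floor applied to Mel energies so downstream
    logarithms never see zero.
    """

    sample_rate: int = DEFAULT_SAMPLE_RATE
    n_fft: int = 1024
    n_mel: int = 128
    hop_mel: int = 256
    seg_len_s: float = 0.04
    seg_hop_s: float = 0.02
    eps: float = 2.2204e-16
    center: bool = True

    def __post_init__(self) -> None:
        if self.n_fft < self.hop_mel:
            raise ValueError("n_fft must be >= hop_mel")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @property
    def frame_hop_s(self) -> float:
        return self.hop_mel / self.sample_rate

    @property
    def patch_len(self) -> int:
        """Frames per encoder patch."""
        return math.ceil(self.seg_len_s / self.frame_hop_s)

    @property
    def patch_hop(self) -> int:
        """Frames between consecutive patch starts."""
        return max(1, math.ceil(self.seg_hop_s / self.frame_hop_s))


@dataclass
class PcenConfig:
    """PCEN parameters: out = (E/(eps+M)^alpha + delta)^r - delta^r.

    M is a per-band first-order IIR smoothing of the energy E with
    coefficient ``smoothing_coef``. Defaults are standard bioacoustics
    settings; ``eps`` here is the AGC stabilizer, distinct from the Mel
    floor.
    """

    smoothing_coef: float = 0.025
    gain_alpha: float = 0.98
    bias_delta: float = 2.0
    root_r: float = 0.5
    eps: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("smoothing_coef", "gain_alpha", "root_r", "eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bias_delta < 0:
            raise ValueError("bias_delta must be >= 0")
        if self.smoothing_coef > 1:
            raise ValueError("smoothing_coef must be in (0, 1]")
        if self.root_r > 1:
            raise ValueError("root_r must be <= 1")


@dataclass
class Spectrogram:
    """Time x frequency array with frame timing metadata.

    ``values`` has shape [n_frames, n_mel]; frame ``i`` covers the half-open
    interval [start_time_s + i*frame_hop_s, start_time_s + (i+1)*frame_hop_s).
    """

    values: np.ndarray
    frame_hop_s: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("spectrogram must be 2-D with at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_mel(self) -> int:
        return self.values.shape[1]


def load_audio(path, target_rate: int = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Read a PCM WAV file, average channels to mono and resample.

    Raises ``FileNotFoundError`` / ``ValueError`` for missing or corrupt
    files and for zero-length audio.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises ValueError on malformed files
        raise ValueError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio in {path!r}")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if data.dtype == np.uint8:
            samples = (data.astype(np.float64) - 128.0) / 128.0
        else:
            samples = data.astype(np.float64) / (float(info.max) + 1.0)
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:  # average channels before resampling
        samples = samples.mean(axis=1)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
    return Waveform(np.clip(samples, -1.0, 1.0), target_rate)


def save_audio(path, w: Waveform) -> None:
    """Write a 16-bit PCM WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.rate, (clipped * 32767.0).astype(np.int16))


def _hz_to_mel(f: np.ndarray) -> np.ndarray:
    # Slaney scale: linear below 1 kHz, logarithmic above.
    f = np.asarray(f, dtype=np.float64)
    mel = f / (200.0 / 3.0)
    log_step = np.log(6.4) / 27.0
    above = f >= 1000.0
    mel = np.where(above, 15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / log_step, mel)
    return mel


def _mel_to_hz(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    f = m * (200.0 / 3.0)
    log_step = np.log(6.4) / 27.0
    above = m >= 15.0
    return np.where(above, 1000.0 * np.exp(log_step * (m - 15.0)), f)


def mel_filterbank(sample_rate: int, n_fft: int, n_mel: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Slaney-style triangular Mel filterbank, area-normalized.

    Returns a [n_mel, n_fft//2 + 1] weight matrix mapping power-spectrum
    bins to Mel bands.
    """
    if fmax is None:
        fmax = sample_rate / 2.0
    n_bins = n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    mel_pts = np.linspace(_hz_to_mel(np.array(fmin)), _hz_to_mel(np.array(fmax)), n_mel + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mel, n_bins))
    for m in range(n_mel):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
        fb[m] *= 2.0 / (hi - lo)  # Slaney area normalization
    return fb


def mel_center_freqs(cfg: MelConfig) -> np.ndarray:
    """Center frequency (Hz) of each Mel band under ``cfg``."""
    mel_pts = np.linspace(_hz_to_mel(np.array(0.0)),
                          _hz_to_mel(np.array(cfg.sample_rate / 2.0)), cfg.n_mel + 2)
    return _mel_to_hz(mel_pts)[1:-1]


def mel_spectrogram(w: Waveform, cfg: MelConfig | None = None) -> Spectrogram:
    """Mel power spectrogram floored at ``cfg.eps``.

    Centered framing with reflect padding, so the frame count is
    ``len // hop_mel + 1``; with ``center=False`` it is
    ``(len - n_fft) // hop_mel + 1``.
    """
    cfg = cfg or MelConfig()
    x = np.asarray(w.samples, dtype=np.float64)
    if len(x) < cfg.n_fft:
        raise ValueError(
            f"waveform of {len(x)} samples is shorter than one window ({cfg.n_fft})")
    if cfg.center:
        pad = cfg.n_fft // 2
        x = np.pad(x, pad, mode="reflect")
    n_frames = (len(x) - cfg.n_fft) // cfg.hop_mel + 1
    idx = np.arange(cfg.n_fft)[None, :] + cfg.hop_mel * np.arange(n_frames)[:, None]
    frames = x[idx] * get_window("hann", cfg.n_fft, fftbins=True)[None, :]
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    fb = mel_filterbank(w.rate, cfg.n_fft, cfg.n_mel)
    mel = power @ fb.T
    return Spectrogram(np.maximum(mel, cfg.eps), cfg.frame_hop_s, 0.0)


def pcen(s: Spectrogram, cfg: PcenConfig | None = None) -> Spectrogram:
    """Per-channel energy normalization.

    The smoother is initialized at the first frame's energy so short inputs
    have no silent burn-in transient.
    """
    cfg = cfg or PcenConfig()
    E = s.values
    if not np.all(np.isfinite(E)):
        raise ValueError("PCEN input must be finite")
    if np.any(E < 0):
        raise ValueError("PCEN input must be non-negative")
    sc = cfg.smoothing_coef
    # First-order IIR: M[t] = (1-sc) M[t-1] + sc E[t], with M[0] = E[0].
    zi = (1.0 - sc) * E[0][None, :]
    M, _ = lfilter([sc], [1.0, -(1.0 - sc)], E, axis=0, zi=zi)
    out = (E / (cfg.eps + M) ** cfg.gain_alpha + cfg.bias_delta) ** cfg.root_r \
        - cfg.bias_delta ** cfg.root_r
    return Spectrogram(out, s.frame_hop_s, s.start_time_s)


def frame_time(i: int, s: Spectrogram) -> float:
    """Start time (s) of frame ``i``; frame covers [t, t + frame_hop_s)."""
    if not 0 <= i < s.n_frames:
        raise IndexError(f"frame index {i} out of range [0, {s.n_frames})")
    return s.start_time_s + i * s.frame_hop_s


def tile_to_length(patch: np.ndarray, length: int) -> np.ndarray:
    """Repeat a [frames, bands] patch along time until it reaches ``length``."""
    if patch.shape[0] == 0:
        raise ValueError("cannot tile an empty patch")
    reps = math.ceil(length / patch.shape[0])
    return np.tile(patch, (reps, 1))[:length]


def extract_patches(s: Spectrogram, cfg: MelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cut a spectrogram into fixed-size patches.

    Returns ``(patches, start_frames)`` where patches has shape
    [n_patches, patch_len, n_mel]. A spectrogram shorter than one patch
    yields a single patch tiled to full length.
    """
    P, H = cfg.patch_len, cfg.patch_hop
    if s.n_frames < P:
        return tile_to_length(s.values, P)[None, :, :], np.array([0])
    n = (s.n_frames - P) // H + 1
    starts = H * np.arange(n)
    patches = np.stack([s.values[t:t + P] for t in starts])
    return patches, starts
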