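"""SpecAugment: time masking, frequency masking and time warping.

All operators act on the spectrogram (or a raw [frames, bands] array),
preserve shape, and draw their randomness from a caller-supplied
``numpy.random.Generator`` so augmentation is reproducible per seed.
Augmentation is applied during encoder pre-training only; transductive
inference runs on clean features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import Spectrogram


@dataclass
class AugmentConfig:
    t_max: int = 2              # max time-mask width, frames
    f_max: int = 13             # max frequency-mask width, Mel bands
    n_time_masks: int = 2
    n_freq_masks: int = 2
    warp_w: int = 5             # max anchor displacement, frames
    fill_value: float = 0.0
    warp_enabled: bool = True
    time_mask_enabled: bool = True
    freq_mask_enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.t_max, self.f_max, self.warp_w,
               self.n_time_masks, self.n_freq_masks) < 0:
            raise ValueError("augment widths and counts must be >= 0")


def _wrap(s: Spectrogram | np.ndarray, values: np.ndarray):
    if isinstance(s, Spectrogram):
        return Spectrogram(values, s.frame_hop_s, s.start_time_s)
    return values


def _values(s: Spectrogram | np.ndarray) -> np.ndarray:
    return s.values if isinstance(s, Spectrogram) else np.asarray(s, dtype=np.float64)


def time_mask(s, cfg: AugmentConfig, rng: np.random.Generator):
    """Zero out (or fill) a random block of [t0, t0+t) frames, t ~ U{0..t_max}."""
    v = _values(s).copy()
    n_frames = v.shape[0]
    if cfg.t_max > n_frames:
        raise ValueError(f"t_max={cfg.t_max} exceeds n_frames={n_frames}")
    t = int(rng.integers(0, cfg.t_max + 1))
    t0 = int(rng.integers(0, n_frames - t + 1))
    v[t0:t0 + t, :] = cfg.fill_value
    return _wrap(s, v)


def freq_mask(s, cfg: AugmentConfig, rng: np.random.Generator):
    """Conceal a random band of [f0, f0+f) Mel bins, f ~ U{0..f_max}."""
    v = _values(s).copy()
    n_mel = v.shape[1]
    if cfg.f_max > n_mel:
        raise ValueError(f"f_max={cfg.f_max} exceeds n_mel={n_mel}")
    f = int(rng.integers(0, cfg.f_max + 1))
    f0 = int(rng.integers(0, n_mel - f + 1))
    v[:, f0:f0 + f] = cfg.fill_value
    return _wrap(s, v)


def time_warp(s, cfg: AugmentConfig, rng: np.random.Generator):
    """Piecewise-linear warp of the time axis.

    A random anchor frame ``a`` is displaced by ``w ~ U{-warp_w..warp_w}``;
    the two segments on either side are linearly resampled so the output
    keeps its shape and the endpoints stay fixed.
    """
    v = _values(s)
    n = v.shape[0]
    if cfg.warp_w == 0:
        return _wrap(s, v.copy())
    if cfg.warp_w >= n / 2:
        raise ValueError(f"warp_w={cfg.warp_w} must be < n_frames/2={n / 2}")
    a = int(rng.integers(cfg.warp_w, n - cfg.warp_w + 1))
    w = int(rng.integers(-cfg.warp_w, cfg.warp_w + 1))
    if w == 0 or n < 3:
        return _wrap(s, v.copy())
    # Source coordinate for each output frame: a+w maps back to a.
    src = np.interp(np.arange(n, dtype=np.float64),
                    [0.0, float(a + w), float(n - 1)],
                    [0.0, float(a), float(n - 1)])
    lo = np.clip(np.floor(src).astype(int), 0, n - 1)
    hi = np.clip(lo + 1, 0, n - 1)
    frac = (src - lo)[:, None]
    out = v[lo] * (1.0 - frac) + v[hi] * frac
    return _wrap(s, out)


def clamped(cfg: AugmentConfig, n_frames: int, n_mel: int) -> AugmentConfig:
    """Shrink mask/warp widths to fit a given patch size.

    Keeps the invariant that widths never exceed the spectrogram dimensions,
    so one config can serve patches of different shapes during training.
    """
    from dataclasses import replace
    return replace(cfg,
                   t_max=min(cfg.t_max, n_frames),
                   f_max=min(cfg.f_max, n_mel),
                   warp_w=min(cfg.warp_w, max((n_frames - 1) // 2, 0)))


def augment(s, cfg: AugmentConfig, rng: np.random.Generator):
    """Warp, then time masks, then frequency masks (fixed order)."""
    out = s
    if cfg.warp_enabled and cfg.warp_w > 0:
        out = time_warp(out, cfg, rng)
    if cfg.time_mask_enabled:
        for _ in range(cfg.n_time_masks):
            out = time_mask(out, cfg, rng)
    if cfg.freq_mask_enabled:
        for _ in range(cfg.n_freq_masks):
            out = freq_mask(out, cfg, rng)
    if out is s:
        out = _wrap(s, _values(s).copy())
    return out
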