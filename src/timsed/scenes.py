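"""Synthetic annotated bioacoustic scenes (WAV + DCASE-dialect CSV).

Stands in for field recordings of animal vocalizations: each scene is a
long background-noise bed (white or pink) over which short parametric
"calls" — tones, up/down chirps, pulse trains and noise bands — are placed
sparsely without overlap. Every placed event is annotated with onset,
offset and class, so the full detection pipeline can be exercised and
scored without external data. Event templates control frequency band,
duration and amplitude ranges; the scene controls density, SNR and the
fraction of events relabeled UNK.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .audio import DEFAULT_SAMPLE_RATE, Waveform, save_audio
from .events import Event, write_annotations

RAMP_S = 0.010          # raised-cosine onset/offset ramp
GUARD_S = 0.050         # minimum silence between placed events


@dataclass
class ClassTemplate:
    name: str
    kind: str = "tone"   # tone | chirp_up | chirp_down | pulse_train | noise_band
    f0_range: tuple[float, float] = (1000.0, 2000.0)
    duration_range: tuple[float, float] = (0.15, 0.40)
    amplitude_range: tuple[float, float] = (0.3, 0.8)
    pulse_rate_range: tuple[float, float] = (5.0, 15.0)
    bandwidth: float = 500.0

    def __post_init__(self) -> None:
        kinds = ("tone", "chirp_up", "chirp_down", "pulse_train", "noise_band")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.f0_range[1] >= DEFAULT_SAMPLE_RATE / 2:
            raise ValueError("f0 must stay below Nyquist at 22.05 kHz")
        for rng_ in (self.f0_range, self.duration_range, self.pulse_rate_range):
            if rng_[0] > rng_[1] or rng_[0] <= 0:
                raise ValueError(f"invalid range {rng_}")
        if self.amplitude_range[0] > self.amplitude_range[1] or self.amplitude_range[0] < 0:
            raise ValueError(f"invalid amplitude range {self.amplitude_range}")


@dataclass
class SceneConfig:
    duration_s: float = 20.0
    classes: list[ClassTemplate] = field(default_factory=list)
    events_per_class: int = 6
    snr_db: float = 20.0
    background: str = "white"    # white | pink
    unk_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background not in ("white", "pink"):
            raise ValueError("background must be 'white' or 'pink'")
        if not 0 <= self.unk_fraction <= 1:
            raise ValueError("unk_fraction must be in [0, 1]")


def _ramps(n: int, sr: int) -> np.ndarray:
    nr = int(round(RAMP_S * sr))
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    env[:nr] = ramp
    env[-nr:] *= ramp[::-1]
    return env


def render_event(t: ClassTemplate, rng: np.random.Generator,
                 sr: int = DEFAULT_SAMPLE_RATE) -> tuple[np.ndarray, dict]:
    """One vocalization-like snippet plus the drawn parameters."""
    dur = float(rng.uniform(*t.duration_range))
    if dur < 2 * RAMP_S:
        raise ValueError(f"duration {dur:.3f}s shorter than two {RAMP_S}s ramps")
    amp = float(rng.uniform(*t.amplitude_range))
    f0 = float(rng.uniform(*t.f0_range))
    n = int(round(dur * sr))
    tt = np.arange(n) / sr
    if t.kind == "tone":
        x = np.sin(2 * np.pi * f0 * tt + rng.uniform(0, 2 * np.pi))
    elif t.kind in ("chirp_up", "chirp_down"):
        lo, hi = t.f0_range
        f_start, f_end = (lo, hi) if t.kind == "chirp_up" else (hi, lo)
        # linear sweep across the template band
        phase = 2 * np.pi * (f_start * tt + 0.5 * (f_end - f_start) / dur * tt ** 2)
        x = np.sin(phase + rng.uniform(0, 2 * np.pi))
        f0 = f_start
    elif t.kind == "pulse_train":
        rate = float(rng.uniform(*t.pulse_rate_range))
        gate = (np.sin(2 * np.pi * rate * tt) > 0.4).astype(np.float64)
        x = np.sin(2 * np.pi * f0 * tt) * gate
    else:  # noise_band
        lo = max(f0 - t.bandwidth / 2, 10.0)
        hi = min(f0 + t.bandwidth / 2, sr / 2 - 10.0)
        sos = butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
        x = sosfilt(sos, rng.standard_normal(n))
        peak = np.max(np.abs(x))
        if peak > 0:
            x = x / peak
    x = x * _ramps(n, sr) * amp
    return x, {"duration_s": dur, "amplitude": amp, "f0": f0, "kind": t.kind}


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n)
    return x / x.std()


@dataclass
class SceneParts:
    """A generated scene split into its constituents (for diagnostics)."""

    waveform: Waveform
    events: list[Event]
    clean_signal: np.ndarray
    noise: np.ndarray


def measure_snr_db(parts: SceneParts) -> float:
    """Mean event-interval signal power over noise power, in dB."""
    sr = parts.waveform.rate
    powers = []
    for e in parts.events:
        seg = parts.clean_signal[int(e.onset_s * sr):int(e.offset_s * sr)]
        powers.append(float(np.mean(seg ** 2)))
    return 10 * math.log10(np.mean(powers) / np.mean(parts.noise ** 2))


def generate_scene(cfg: SceneConfig) -> tuple[Waveform, list[Event]]:
    w, events, _ = _generate_scene(cfg)
    return w, events


def generate_scene_parts(cfg: SceneConfig) -> SceneParts:
    w, events, (signal, noise) = _generate_scene(cfg)
    return SceneParts(w, events, signal, noise)


def _generate_scene(cfg: SceneConfig):
    """Place events without overlap, add background noise at cfg.snr_db.

    SNR is mean per-event signal power over noise power, in dB. The mix is
    peak-normalized to -1 dBFS. Same seed, same scene (bit-identical).
    """
    if not cfg.classes:
        raise ValueError("scene needs at least one class template")
    sr = DEFAULT_SAMPLE_RATE
    rng = np.random.default_rng(cfg.seed)
    n_total = int(round(cfg.duration_s * sr))
    signal = np.zeros(n_total)
    events: list[Event] = []
    occupied: list[tuple[int, int]] = []
    guard = int(GUARD_S * sr)
    n_events = cfg.events_per_class * len(cfg.classes)
    max_tries = 1000 * max(1, n_events)
    tries = 0
    powers = []
    for template in cfg.classes:
        for _ in range(cfg.events_per_class):
            snippet, _params = render_event(template, rng, sr)
            placed = False
            while tries < max_tries:
                tries += 1
                start = int(rng.integers(0, n_total - len(snippet) + 1)) \
                    if n_total > len(snippet) else 0
                stop = start + len(snippet)
                if all(stop + guard <= a or start >= b + guard
                       for a, b in occupied):
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not pack events without overlap; lower the event "
                    "density or lengthen the scene")
            signal[start:stop] += snippet
            occupied.append((start, stop))
            powers.append(float(np.mean(snippet ** 2)))
            events.append(Event(start / sr, stop / sr, label=template.name))
    mean_power = float(np.mean(powers))
    noise_power = mean_power / (10.0 ** (cfg.snr_db / 10.0))
    noise = rng.standard_normal(n_total) if cfg.background == "white" \
        else _pink_noise(n_total, rng)
    noise *= math.sqrt(noise_power)
    mix = signal + noise
    peak = np.max(np.abs(mix))
    scale = 10 ** (-1 / 20) / peak if peak > 0 else 1.0
    mix = mix * scale               # peak-normalize to -1 dBFS
    events.sort(key=lambda e: e.onset_s)
    if cfg.unk_fraction > 0:
        n_unk = int(round(cfg.unk_fraction * len(events)))
        for i in rng.choice(len(events), size=n_unk, replace=False):
            events[i].status = "UNK"
    return Waveform(mix, sr), events, (signal * scale, noise * scale)


def generate_dataset(train_cfgs: list[SceneConfig], val_cfgs: list[SceneConfig],
                     out_dir, seed: int = 0,
                     val_target_class: list[str] | None = None) -> dict:
    """Write Training_Set/ and Validation_Set/ trees of WAV + CSV pairs.

    Training CSVs are multi-class (POS/NEG per class column); validation
    CSVs are single-class (POS/UNK on the target class). Validation scenes
    must contain at least 5 POS events of their target class so the
    first-5-shots support protocol is satisfiable.
    """
    out_dir = Path(out_dir)
    manifest: dict = {"seed": seed, "train": [], "val": []}
    for split, cfgs in (("Training_Set", train_cfgs), ("Validation_Set", val_cfgs)):
        (out_dir / split).mkdir(parents=True, exist_ok=True)
    for i, cfg in enumerate(train_cfgs):
        scene_cfg = SceneConfig(**{**cfg.__dict__,
                                   "seed": (seed * 1009 + cfg.seed + i) % (2 ** 31)})
        w, evs = generate_scene(scene_cfg)
        name = f"train_{i:02d}.wav"
        save_audio(out_dir / "Training_Set" / name, w)
        classes = [t.name for t in cfg.classes]
        write_annotations(out_dir / "Training_Set" / f"train_{i:02d}.csv",
                          name, evs, classes)
        manifest["train"].append({"wav": name, "events": len(evs)})
    for i, cfg in enumerate(val_cfgs):
        target = (val_target_class[i] if val_target_class
                  else cfg.classes[0].name)
        scene_cfg = SceneConfig(**{**cfg.__dict__,
                                   "seed": (seed * 2003 + cfg.seed + i) % (2 ** 31)})
        w, evs = generate_scene(scene_cfg)
        n_pos = sum(e.status == "POS" and e.label == target for e in evs)
        if n_pos < 5:
            raise RuntimeError(
                f"validation scene {i} has only {n_pos} POS '{target}' events; "
                "raise events_per_class")
        name = f"val_{i:02d}.wav"
        save_audio(out_dir / "Validation_Set" / name, w)
        target_events = [e for e in evs if e.label == target]
        write_annotations(out_dir / "Validation_Set" / f"val_{i:02d}.csv",
                          name, target_events, [target])
        manifest["val"].append({"wav": name, "target": target,
                                "events": len(target_events)})
    return manifest
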