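"""Per-file few-shot detection: episode construction, segmentation, filters.

The detection protocol follows the few-shot annotation convention: the
first ``k_shot`` (default 5) positive events of a file's target class are
the labeled "shots". Patches inside those shots form the positive support;
an equal number of patches drawn from un-annotated gaps before the last
shot's offset form the negative support; everything after that offset is
the unlabeled query. TIM (or the prototypical baseline) yields a positive
posterior per query patch (detection defaults to L2-normalized logits:
encoder embedding norms vary with event energy, and unnormalized inner
products let the larger-norm prototype dominate every query), which is mapped back to frames, median-filtered,
thresholded and segmented into events; events shorter than a fraction
(default 60%) of the shortest shot are removed.

Annotation CSVs use the DCASE dialect: header
``Audiofilename,Starttime,Endtime,<CLASS...>`` with POS/NEG/UNK values;
prediction CSVs have ``Audiofilename,Starttime,Endtime,Score``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .audio import (MelConfig, PcenConfig, Spectrogram, extract_patches,
                    load_audio, mel_spectrogram, pcen, tile_to_length)
from .transductive import (Episode, TimConfig, prototype_posterior, tim_infer)


@dataclass
class Event:
    """One annotated or predicted time interval."""

    onset_s: float
    offset_s: float
    label: str = ""
    status: str = "POS"
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"need 0 <= onset < offset, got [{self.onset_s}, {self.offset_s}]")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class DetectionConfig:
    threshold: float = 0.5
    median_win: int = 5
    merge_gap_s: float = 0.0
    min_dur_frac: float = 0.6
    k_shot: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 <= self.min_dur_frac <= 1:
            raise ValueError("min_dur_frac must be in [0, 1]")


# -- annotation CSV dialect ---------------------------------------------

TIME_COLS = ("Audiofilename", "Starttime", "Endtime")


def read_annotations(path) -> dict[str, list[Event]]:
    """Read a DCASE-dialect CSV into {class name: [Event, ...]} (onset order)."""
    df = pd.read_csv(path)
    missing = [c for c in TIME_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    classes = [c for c in df.columns if c not in TIME_COLS]
    out: dict[str, list[Event]] = {c: [] for c in classes}
    for _, row in df.iterrows():
        for c in classes:
            status = str(row[c]).strip().upper()
            if status in ("POS", "UNK", "NEG"):
                out[c].append(Event(float(row["Starttime"]), float(row["Endtime"]),
                                    label=c, status=status))
    for c in classes:
        out[c].sort(key=lambda e: e.onset_s)
    return out


def write_annotations(path, audiofilename: str, events: list[Event],
                      classes: list[str]) -> None:
    rows = []
    for e in events:
        row = {"Audiofilename": audiofilename,
               "Starttime": round(e.onset_s, 4), "Endtime": round(e.offset_s, 4)}
        for c in classes:
            if c == e.label:
                row[c] = e.status
            else:
                row[c] = "NEG"
        rows.append(row)
    pd.DataFrame(rows, columns=[*TIME_COLS, *classes]).to_csv(path, index=False)


def write_predictions(path, rows: list[tuple[str, Event]]) -> None:
    """Rows of (audiofilename, predicted event)."""
    df = pd.DataFrame([{"Audiofilename": name,
                        "Starttime": round(e.onset_s, 4),
                        "Endtime": round(e.offset_s, 4),
                        "Score": float("nan") if e.score is None else round(e.score, 4)}
                       for name, e in rows],
                      columns=["Audiofilename", "Starttime", "Endtime", "Score"])
    df.to_csv(path, index=False)


def read_predictions(path) -> dict[str, list[Event]]:
    df = pd.read_csv(path)
    out: dict[str, list[Event]] = {}
    for _, row in df.iterrows():
        ev = Event(float(row["Starttime"]), float(row["Endtime"]),
                   score=float(row["Score"]) if not pd.isna(row["Score"]) else None)
        out.setdefault(str(row["Audiofilename"]), []).append(ev)
    return out


# -- episode construction -----------------------------------------------

def _patches_in_span(features: Spectrogram, starts: np.ndarray,
                     patches: np.ndarray, onset_s: float, offset_s: float,
                     patch_len: int) -> np.ndarray:
    """Patches fully inside [onset, offset); short events are tiled."""
    hop = features.frame_hop_s
    f0 = int(math.floor(onset_s / hop))
    f1 = int(math.ceil(offset_s / hop))
    inside = (starts >= f0) & (starts + patch_len <= f1)
    if inside.any():
        return patches[inside]
    span = features.values[max(f0, 0):max(f1, f0 + 1)]
    if span.shape[0] == 0:
        span = features.values[max(min(f0, features.n_frames - 1), 0)][None]
    return tile_to_length(span, patch_len)[None]


@dataclass
class FileEpisode:
    """Episode plus the bookkeeping needed to map posteriors back to time."""

    episode: Episode
    shots: list[Event]
    query_starts: np.ndarray    # start frame of each query patch
    query_frame0: int           # first frame at/after the k-th shot offset
    n_frames: int
    frame_hop_s: float
    patch_len: int


def build_file_episode(features: Spectrogram, annotations: list[Event],
                       enc, cfg: DetectionConfig,
                       mel_cfg: MelConfig | None = None,
                       seed: int = 0) -> FileEpisode:
    """First-K-shots support construction for one file (binary task).

    Positive support: patches inside the first ``k_shot`` POS events.
    Negative support: an equal number of patches sampled (seeded) from
    un-annotated audio before the k-th shot's offset. Query: all patches
    starting at or after that offset.
    """
    mel_cfg = mel_cfg or MelConfig()
    pos_events = [e for e in annotations if e.status == "POS"]
    pos_events.sort(key=lambda e: e.onset_s)
    if len(pos_events) < cfg.k_shot:
        raise ValueError(
            f"need >= {cfg.k_shot} POS events, annotation has {len(pos_events)}")
    shots = pos_events[:cfg.k_shot]
    support_end_s = shots[-1].offset_s
    patches, starts = extract_patches(features, mel_cfg)
    P = mel_cfg.patch_len
    hop = features.frame_hop_s

    pos_patches = np.concatenate([
        _patches_in_span(features, starts, patches, e.onset_s, e.offset_s, P)
        for e in shots])

    # negative candidates: entirely before the support end, overlapping no
    # annotated event (any status)
    end_frame = int(math.floor(support_end_s / hop))
    cand = starts + P <= end_frame
    for e in annotations:
        f0 = int(math.floor(e.onset_s / hop))
        f1 = int(math.ceil(e.offset_s / hop))
        cand &= (starts + P <= f0) | (starts >= f1)
    cand_idx = np.flatnonzero(cand)
    if len(cand_idx) == 0:
        raise ValueError(
            "no un-annotated audio before the last shot; provide longer context")
    rng = np.random.default_rng(seed)
    take = rng.choice(cand_idx, size=min(len(pos_patches), len(cand_idx)),
                      replace=len(cand_idx) < len(pos_patches))
    neg_patches = patches[np.sort(take)]

    query_mask = starts * hop >= support_end_s
    query_frame0 = int(math.ceil(support_end_s / hop))
    if not query_mask.any():
        raise ValueError("no query audio after the last shot")
    query_patches = patches[query_mask]
    sup = np.concatenate([pos_patches, neg_patches])
    sup_y = np.concatenate([np.zeros(len(pos_patches), dtype=int),
                            np.ones(len(neg_patches), dtype=int)])
    ep = Episode(enc.embed(sup), sup_y, enc.embed(query_patches), n_way=2,
                 k_shot=cfg.k_shot, support_patches=sup,
                 query_patches=query_patches)
    return FileEpisode(ep, shots, starts[query_mask], query_frame0,
                       features.n_frames, hop, P)


# -- posterior -> events -------------------------------------------------

def frames_to_events(probs: np.ndarray, hop_s: float,
                     cfg: DetectionConfig) -> list[Event]:
    """Median-filter, threshold and segment a per-frame posterior track.

    Frame i covers [i*hop_s, (i+1)*hop_s); an event spans its run of
    above-threshold frames and is scored by the mean filtered posterior
    over the run. Runs separated by gaps <= merge_gap_s are merged.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size == 0:
        return []
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    win = cfg.median_win if cfg.median_win % 2 == 1 else cfg.median_win + 1
    filt = medfilt(probs, kernel_size=win) if len(probs) >= win and win > 1 else probs
    mask = filt >= cfg.threshold
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))  # [start, stop) frame indices
    if cfg.merge_gap_s > 0 and runs:
        merged = [runs[0]]
        for a, b in runs[1:]:
            if (a - merged[-1][1]) * hop_s <= cfg.merge_gap_s:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        runs = merged
    return [Event(a * hop_s, b * hop_s, score=float(filt[a:b].mean()))
            for a, b in runs]


def filter_short_events(events: list[Event], shots: list[Event],
                        min_dur_frac: float) -> list[Event]:
    """Drop events shorter than min_dur_frac x the shortest shot duration."""
    if not shots:
        raise ValueError("shot list must be non-empty")
    cut = min_dur_frac * min(s.duration_s for s in shots)
    return [e for e in events if e.duration_s >= cut]


# -- end-to-end per-file detection ---------------------------------------

def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"detection stage '{name}' failed: {exc}") from exc


def _scores_to_frame_track(fe: FileEpisode, pos_probs: np.ndarray) -> np.ndarray:
    """Average patch posteriors over the frames each patch covers."""
    n = fe.n_frames - fe.query_frame0
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for start, p in zip(fe.query_starts, pos_probs):
        a = max(start - fe.query_frame0, 0)
        b = min(start + fe.patch_len - fe.query_frame0, n)
        acc[a:b] += p
        cnt[a:b] += 1
    track = np.zeros(n)
    covered = cnt > 0
    track[covered] = acc[covered] / cnt[covered]
    return track


def _detect(wav_path, ann_path, enc, det_cfg: DetectionConfig,
            mel_cfg: MelConfig, pcen_cfg: PcenConfig,
            tim_cfg: TimConfig | None, target_class: str | None,
            seed: int, use_tim: bool) -> list[Event]:
    w = _stage("load", load_audio, wav_path, mel_cfg.sample_rate)
    feats = _stage("features", lambda: pcen(mel_spectrogram(w, mel_cfg), pcen_cfg))
    ann = _stage("annotations", read_annotations, ann_path)
    if target_class is None:
        candidates = [c for c, evs in ann.items()
                      if sum(e.status == "POS" for e in evs) >= det_cfg.k_shot]
        if not candidates:
            raise RuntimeError(f"no class in {ann_path} has >= {det_cfg.k_shot} shots")
        target_class = candidates[0]
    fe = _stage("episode", build_file_episode, feats, ann[target_class], enc,
                det_cfg, mel_cfg, seed)
    if use_tim:
        pm, _, _ = _stage("tim", tim_infer, enc, fe.episode, tim_cfg)
    else:
        pm = _stage("prototype", prototype_posterior, fe.episode)
    track = _scores_to_frame_track(fe, pm.P[:, 0])
    events = _stage("segment", frames_to_events, track, fe.frame_hop_s, det_cfg)
    t0 = fe.query_frame0 * fe.frame_hop_s
    events = [replace(e, onset_s=e.onset_s + t0, offset_s=e.offset_s + t0,
                      label=target_class) for e in events]
    return _stage("filter", filter_short_events, events, fe.shots,
                  det_cfg.min_dur_frac)


def detect_file(wav_path, ann_path, enc, det_cfg: DetectionConfig | None = None,
                mel_cfg: MelConfig | None = None,
                pcen_cfg: PcenConfig | None = None,
                tim_cfg: TimConfig | None = None,
                target_class: str | None = None, seed: int = 0) -> list[Event]:
    """TIM-based few-shot detection over one WAV + annotation pair."""
    return _detect(wav_path, ann_path, enc, det_cfg or DetectionConfig(),
                   mel_cfg or MelConfig(), pcen_cfg or PcenConfig(),
                   tim_cfg or TimConfig(l2_normalize=True), target_class, seed,
                   use_tim=True)


def baseline_detect_file(wav_path, ann_path, enc,
                         det_cfg: DetectionConfig | None = None,
                         mel_cfg: MelConfig | None = None,
                         pcen_cfg: PcenConfig | None = None,
                         target_class: str | None = None,
                         seed: int = 0) -> list[Event]:
    """Prototype-only detection: nearest prototype, no transductive steps."""
    return _detect(wav_path, ann_path, enc, det_cfg or DetectionConfig(),
                   mel_cfg or MelConfig(), pcen_cfg or PcenConfig(),
                   None, target_class, seed, use_tim=False)


def scoring_ground_truth(annotations: list[Event], k_shot: int) -> list[Event]:
    """POS events after the k-th shot's offset plus all later UNK events.

    The first ``k_shot`` POS events are the support and are excluded from
    scoring, matching the query convention of :func:`build_file_episode`.
    """
    pos = sorted([e for e in annotations if e.status == "POS"],
                 key=lambda e: e.onset_s)
    if len(pos) < k_shot:
        raise ValueError(f"need >= {k_shot} POS events")
    t0 = pos[k_shot - 1].offset_s
    return [e for e in annotations
            if e.status in ("POS", "UNK") and e.onset_s >= t0]


# -- base dataset assembly ----------------------------------------------

def build_base_dataset(pairs: list[tuple], mel_cfg: MelConfig | None = None,
                       pcen_cfg: PcenConfig | None = None,
                       background_label: str = "_background",
                       max_background_per_file: int | None = None,
                       seed: int = 0):
    """Collect labeled patches from (wav, csv) training pairs.

    POS events of every annotated class become patches of that class;
    un-annotated gaps contribute a ``_background`` class (capped per file at
    the mean per-class patch count unless overridden).
    """
    from .backbone import BaseDataset  # local import to avoid cycle

    mel_cfg = mel_cfg or MelConfig()
    pcen_cfg = pcen_cfg or PcenConfig()
    rng = np.random.default_rng(seed)
    patch_bank: dict[str, list[np.ndarray]] = {}
    for wav_path, ann_path in pairs:
        w = load_audio(wav_path, mel_cfg.sample_rate)
        feats = pcen(mel_spectrogram(w, mel_cfg), pcen_cfg)
        ann = read_annotations(ann_path)
        patches, starts = extract_patches(feats, mel_cfg)
        P = mel_cfg.patch_len
        hop = feats.frame_hop_s
        gap_mask = np.ones(len(starts), dtype=bool)
        n_event_patches = 0
        for cls, evs in ann.items():
            for e in evs:
                f0 = int(math.floor(e.onset_s / hop))
                f1 = int(math.ceil(e.offset_s / hop))
                gap_mask &= (starts + P <= f0) | (starts >= f1)
                if e.status == "POS":
                    got = _patches_in_span(feats, starts, patches,
                                           e.onset_s, e.offset_s, P)
                    patch_bank.setdefault(cls, []).extend(got)
                    n_event_patches += len(got)
        gap_idx = np.flatnonzero(gap_mask)
        cap = max_background_per_file
        if cap is None:
            cap = max(1, n_event_patches // max(1, len(ann)))
        if len(gap_idx) > cap:
            gap_idx = np.sort(rng.choice(gap_idx, size=cap, replace=False))
        patch_bank.setdefault(background_label, []).extend(patches[gap_idx])
    names = sorted(patch_bank)
    all_patches, labels = [], []
    for i, name in enumerate(names):
        all_patches.extend(patch_bank[name])
        labels.extend([i] * len(patch_bank[name]))
    return BaseDataset(np.stack(all_patches), np.array(labels), names)
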