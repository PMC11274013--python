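"""Detection pipeline: episodes, segmentation, filters, CSV dialects."""

import numpy as np
import pytest

from timsed.audio import MelConfig, PcenConfig, Spectrogram, load_audio, mel_spectrogram, pcen
from timsed.events import (DetectionConfig, Event, baseline_detect_file,
                           build_file_episode, detect_file,
                           filter_short_events, frames_to_events,
                           read_annotations, read_predictions,
                           scoring_ground_truth, write_annotations,
                           write_predictions)
from timsed.metrics import interval_iou, match_events, pool_matches


class TestFramesToEvents:
    def test_run_extraction_convention(self):
        probs = np.array([0.1, 0.9, 0.8, 0.2, 0.9])
        cfg = DetectionConfig(median_win=1)
        evs = frames_to_events(probs, 0.02, cfg)
        assert [(round(e.onset_s, 2), round(e.offset_s, 2)) for e in evs] == \
            [(0.02, 0.06), (0.08, 0.10)]

    def test_all_below_threshold_empty(self):
        assert frames_to_events(np.full(20, 0.1), 0.02, DetectionConfig()) == []

    def test_all_above_threshold_single_event(self):
        evs = frames_to_events(np.full(30, 0.9), 0.02, DetectionConfig())
        assert len(evs) == 1
        assert np.isclose(evs[0].onset_s, 0.0)
        assert np.isclose(evs[0].offset_s, 30 * 0.02)

    def test_empty_input_empty_output(self):
        assert frames_to_events(np.array([]), 0.02, DetectionConfig()) == []

    def test_merge_gap_joins_nearby_runs(self):
        probs = np.array([0.9, 0.9, 0.1, 0.9, 0.9])
        cfg = DetectionConfig(median_win=1, merge_gap_s=0.025)
        assert len(frames_to_events(probs, 0.02, cfg)) == 1
        cfg2 = DetectionConfig(median_win=1, merge_gap_s=0.0)
        assert len(frames_to_events(probs, 0.02, cfg2)) == 2

    def test_inverse_consistency_with_frame_mask(self):
        from scipy.signal import medfilt
        rng = np.random.default_rng(5)
        probs = rng.random(200)
        cfg = DetectionConfig(median_win=5)
        evs = frames_to_events(probs, 0.01, cfg)
        mask = medfilt(probs, 5) >= cfg.threshold
        rebuilt = np.zeros(200, dtype=bool)
        for e in evs:
            rebuilt[int(round(e.onset_s / 0.01)):int(round(e.offset_s / 0.01))] = True
        assert np.array_equal(mask, rebuilt)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            frames_to_events(np.array([0.2, 1.3]), 0.02, DetectionConfig())


class TestFilterShortEvents:
    SHOTS = [Event(0, 1.0), Event(2, 3.5), Event(4, 6.0)]

    def test_sixty_percent_rule(self):
        events = [Event(0, 0.5), Event(1, 1.7)]
        kept = filter_short_events(events, self.SHOTS, 0.6)
        assert kept == [events[1]]

    def test_zero_fraction_keeps_all(self):
        events = [Event(0, 0.01), Event(1, 1.01)]
        assert filter_short_events(events, self.SHOTS, 0.0) == events

    def test_boundary_duration_kept(self):
        events = [Event(0.0, 0.6)]  # exactly 0.6 * shortest (1.0 s)
        assert filter_short_events(events, self.SHOTS, 0.6) == events

    def test_empty_shots_rejected(self):
        with pytest.raises(ValueError):
            filter_short_events([Event(0, 1)], [], 0.6)

    def test_monotone_in_fraction_and_subset(self):
        rng = np.random.default_rng(2)
        events = [Event(o, o + d) for o, d in
                  zip(rng.uniform(0, 50, 20), rng.uniform(0.05, 2.0, 20))]
        previous = events
        for frac in (0.0, 0.3, 0.6, 0.9, 1.0):
            kept = filter_short_events(events, self.SHOTS, frac)
            assert set((e.onset_s, e.offset_s) for e in kept) <= \
                set((e.onset_s, e.offset_s) for e in previous)
            previous = kept


class TestAnnotationCsv:
    def test_round_trip(self, tmp_path):
        events = [Event(0.5, 1.0, label="a", status="POS"),
                  Event(2.0, 2.4, label="b", status="POS"),
                  Event(3.0, 3.3, label="a", status="UNK")]
        path = tmp_path / "ann.csv"
        write_annotations(path, "x.wav", events, ["a", "b"])
        ann = read_annotations(path)
        assert len(ann["a"]) == len(ann["b"]) == 3  # NEG rows included
        a_pos = [e for e in ann["a"] if e.status in ("POS", "UNK")]
        assert [(e.onset_s, e.offset_s, e.status) for e in a_pos] == \
            [(0.5, 1.0, "POS"), (3.0, 3.3, "UNK")]

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("Audiofilename,Starttime\nx.wav,1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_annotations(p)

    def test_predictions_round_trip(self, tmp_path):
        rows = [("x.wav", Event(1.0, 2.0, score=0.9)),
                ("y.wav", Event(0.5, 0.8, score=0.7))]
        path = tmp_path / "pred.csv"
        write_predictions(path, rows)
        back = read_predictions(path)
        assert set(back) == {"x.wav", "y.wav"}
        assert back["x.wav"][0].score == pytest.approx(0.9)


class TestScoringGroundTruth:
    def test_excludes_support_shots(self):
        ann = [Event(i, i + 0.5) for i in range(8)]
        gt = scoring_ground_truth(ann, k_shot=5)
        assert [e.onset_s for e in gt] == [5, 6, 7]

    def test_keeps_late_unk(self):
        ann = [Event(i, i + 0.5) for i in range(5)] + \
            [Event(9.0, 9.5, status="UNK")]
        gt = scoring_ground_truth(ann, k_shot=5)
        assert [e.status for e in gt] == ["UNK"]


class TestFileEpisode:
    def _features_and_annotations(self, tiny_setup, name="val_00"):
        root = tiny_setup["root"]
        wav = root / "Validation_Set" / f"{name}.wav"
        w = load_audio(wav, 22050)
        feats = pcen(mel_spectrogram(w, tiny_setup["mel_cfg"]),
                     tiny_setup["pcen_cfg"])
        ann = read_annotations(wav.with_suffix(".csv"))
        target = next(iter(ann))
        return feats, ann[target]

    def test_protocol_structure(self, tiny_setup):
        feats, ann = self._features_and_annotations(tiny_setup)
        fe = build_file_episode(feats, ann, tiny_setup["encoder"],
                                DetectionConfig(), tiny_setup["mel_cfg"], seed=0)
        ep = fe.episode
        assert ep.n_way == 2
        assert set(ep.support_y) == {0, 1}
        assert (ep.support_y == 0).sum() == (ep.support_y == 1).sum()
        assert len(fe.shots) == 5
        support_end = fe.shots[-1].offset_s
        assert np.all(fe.query_starts * fe.frame_hop_s >= support_end - 1e-9)

    def test_deterministic_for_fixed_seed(self, tiny_setup):
        feats, ann = self._features_and_annotations(tiny_setup)
        a = build_file_episode(feats, ann, tiny_setup["encoder"],
                               DetectionConfig(), tiny_setup["mel_cfg"], seed=3)
        b = build_file_episode(feats, ann, tiny_setup["encoder"],
                               DetectionConfig(), tiny_setup["mel_cfg"], seed=3)
        assert np.array_equal(a.episode.support_z, b.episode.support_z)
        assert np.array_equal(a.episode.query_z, b.episode.query_z)

    def test_too_few_shots_rejected(self, tiny_setup):
        feats, ann = self._features_and_annotations(tiny_setup)
        pos = [e for e in ann if e.status == "POS"][:3]
        with pytest.raises(ValueError, match="POS events"):
            build_file_episode(feats, pos, tiny_setup["encoder"],
                               DetectionConfig(), tiny_setup["mel_cfg"])

    def test_no_gap_audio_rejected(self, tiny_setup):
        mel_cfg = tiny_setup["mel_cfg"]
        feats = Spectrogram(np.ones((400, 128)), mel_cfg.frame_hop_s)
        hop = mel_cfg.frame_hop_s
        # five back-to-back shots occupying all audio before the 5th offset
        ann = [Event(i * 80 * hop, (i + 1) * 80 * hop) for i in range(5)]
        with pytest.raises(ValueError, match="longer context"):
            build_file_episode(feats, ann, tiny_setup["encoder"],
                               DetectionConfig(), mel_cfg)


class TestDetectFile:
    def test_tim_detections_cover_ground_truth(self, tiny_setup):
        root = tiny_setup["root"]
        wav = root / "Validation_Set" / "val_00.wav"
        pred = detect_file(wav, wav.with_suffix(".csv"),
                           tiny_setup["encoder"], seed=0)
        ann = read_annotations(wav.with_suffix(".csv"))
        gt = scoring_ground_truth(ann[next(iter(ann))], 5)
        assert len(pred) > 0
        for g in gt:
            assert any(interval_iou(g, p) >= 0.3 for p in pred), \
                f"missed ground-truth event at {g.onset_s:.2f}s"
        dur = load_audio(wav, 22050).duration_s
        for p in pred:
            assert 0 <= p.onset_s < p.offset_s <= dur + 1e-6
            assert p.score is not None and 0 <= p.score <= 1

    def test_detection_deterministic(self, tiny_setup):
        root = tiny_setup["root"]
        wav = root / "Validation_Set" / "val_01.wav"
        a = detect_file(wav, wav.with_suffix(".csv"), tiny_setup["encoder"], seed=0)
        b = detect_file(wav, wav.with_suffix(".csv"), tiny_setup["encoder"], seed=0)
        assert [(x.onset_s, x.offset_s, x.score) for x in a] == \
            [(x.onset_s, x.offset_s, x.score) for x in b]

    def test_baseline_not_better_than_tim_when_pooled(self, tiny_setup):
        root = tiny_setup["root"]
        scores = {}
        for system, fn in (("tim", detect_file), ("baseline", baseline_detect_file)):
            results = []
            for wav in sorted((root / "Validation_Set").glob("*.wav")):
                pred = fn(wav, wav.with_suffix(".csv"), tiny_setup["encoder"], seed=0)
                ann = read_annotations(wav.with_suffix(".csv"))
                gt = scoring_ground_truth(ann[next(iter(ann))], 5)
                results.append(match_events(gt, pred))
            scores[system] = pool_matches(results).f_score
        assert scores["baseline"] <= scores["tim"] + 1e-9
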