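"""End-to-end conveniences gluing features, labels, models and scores."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .audio_io import DualChannelRecording
from .features import FeatureConfig, FeatureWindow, extract_feature_windows
from .labeling import LabelingConfig, PhoneInterval, classify_phones, nasalize_vowels, label_window
from .nasalance import ENasalanceConfig, SpeakerScore, e_nasalance, mfcc_nasalance, speaker_e_nasalance

__all__ = ["labeled_feature_windows", "score_speakers_mfcc", "score_speakers_energy", "scores_frame"]


def labeled_feature_windows(
    utterances: Sequence[tuple[DualChannelRecording, list[PhoneInterval]]],
    feature_cfg: FeatureConfig = FeatureConfig(),
    labeling_cfg: LabelingConfig = LabelingConfig(),
) -> list[FeatureWindow]:
    """Feature stacks for every window of every utterance, with rule labels."""
    out: list[FeatureWindow] = []
    for rec, intervals in utterances:
        spans = nasalize_vowels(classify_phones(intervals, labeling_cfg), labeling_cfg)
        for w in extract_feature_windows(rec, feature_cfg):
            w.label = label_window(w.start_ms, spans, labeling_cfg, feature_cfg.window_ms)
            out.append(w)
    return out


def score_speakers_mfcc(
    windows: Sequence[FeatureWindow], model
) -> list[SpeakerScore]:
    """Per-speaker mfccNasalance from (possibly unlabeled) feature windows."""
    by_speaker: dict[str, list[FeatureWindow]] = {}
    for w in windows:
        by_speaker.setdefault(w.speaker_id, []).append(w)
    return [
        mfcc_nasalance(ws, model, speaker_id=spk)
        for spk, ws in sorted(by_speaker.items())
    ]


def score_speakers_energy(
    utterances: Sequence[tuple[DualChannelRecording, object]],
    cfg: ENasalanceConfig = ENasalanceConfig(),
) -> list[SpeakerScore]:
    """Per-speaker eNasalance: utterance band-energy ratios, then the mean."""
    by_speaker: dict[str, list[float]] = {}
    for rec, _ in utterances:
        by_speaker.setdefault(rec.speaker_id, []).append(e_nasalance(rec, cfg))
    return [
        SpeakerScore(speaker_id=spk, score=speaker_e_nasalance(scores),
                     n=len(scores), kind="energy")
        for spk, scores in sorted(by_speaker.items())
    ]


def scores_frame(scores: Sequence[SpeakerScore]) -> pd.DataFrame:
    """Speaker scores as a tidy DataFrame (speaker_id, score, n, kind, level)."""
    return pd.DataFrame([
        {"speaker_id": s.speaker_id, "score": s.score, "n": s.n,
         "kind": s.kind, "level": s.level}
        for s in scores
    ])
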