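import numpy as np
import pytest

from nasalkit.audio_io import DualChannelRecording
from nasalkit.features import FeatureWindow
from nasalkit.nasalance import (
    ENasalanceConfig,
    ReferenceDistribution,
    SpeakerScore,
    e_nasalance,
    mfcc_nasalance,
    scale_transform,
    speaker_e_nasalance,
)

SR = 44_100


class StubModel:
    """Deterministic posterior source for averaging tests."""

    def __init__(self, posteriors):
        self.posteriors = np.asarray(posteriors, dtype=float)

    def nasal_posterior(self, stacks):
        return self.posteriors[: len(stacks)]


def _windows(n, speaker="s1"):
    return [FeatureWindow(stack=np.zeros((2, 3, 4)), start_ms=100.0 * i,
                          speaker_id=speaker) for i in range(n)]


def _tone(freq, sr=SR, dur=1.0, amp=0.3):
    t = np.arange(int(sr * dur)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


def test_mfcc_nasalance_is_mean_posterior():
    score = mfcc_nasalance(_windows(3), StubModel([0.2, 0.4, 0.6]))
    assert score.score == pytest.approx(0.4)
    assert score.n == 3 and score.kind == "mfcc"


def test_mfcc_nasalance_boundary_and_errors():
    assert mfcc_nasalance(_windows(4), StubModel([1, 1, 1, 1])).score == 1.0
    with pytest.raises(ValueError):
        mfcc_nasalance([], StubModel([]))
    mixed = _windows(2, "a") + _windows(2, "b")
    with pytest.raises(ValueError, match="multiple speakers"):
        mfcc_nasalance(mixed, StubModel([0, 0, 0, 0]))


def test_fold_ensemble_mean_equals_mean_of_fold_scores(rng):
    posts = rng.uniform(0, 1, size=(5, 6))

    class Ensemble:
        def nasal_posterior(self, stacks):
            return posts.mean(axis=0)[: len(stacks)]

    ensemble_score = mfcc_nasalance(_windows(6), Ensemble()).score
    fold_scores = [mfcc_nasalance(_windows(6), StubModel(p)).score for p in posts]
    assert ensemble_score == pytest.approx(np.mean(fold_scores))


def test_enasalance_silent_mouth_is_100():
    rec = DualChannelRecording(nose=_tone(600), mouth=np.zeros(SR), sample_rate=SR)
    assert e_nasalance(rec) == pytest.approx(100.0, abs=0.5)


def test_enasalance_identical_channels_is_50():
    x = _tone(600) + _tone(520, amp=0.1)
    rec = DualChannelRecording(nose=x, mouth=x.copy(), sample_rate=SR)
    assert e_nasalance(rec) == pytest.approx(50.0, abs=1e-9)


def test_enasalance_channel_swap_complement(rng):
    nose = rng.standard_normal(SR) * 0.1
    mouth = rng.standard_normal(SR) * 0.1
    rec = DualChannelRecording(nose=nose, mouth=mouth, sample_rate=SR)
    e = e_nasalance(rec)
    assert e_nasalance(rec.swapped()) == pytest.approx(100.0 - e, abs=1e-9)


def test_enasalance_band_selectivity():
    # nose energy far outside 450-750 Hz, mouth inside: score near 0
    rec = DualChannelRecording(nose=_tone(3000), mouth=_tone(600), sample_rate=SR)
    assert e_nasalance(rec) < 0.5
    assert e_nasalance(rec.swapped()) > 99.5


def test_enasalance_gain_invariance_and_errors(rng):
    nose = _tone(600)
    mouth = _tone(700, amp=0.2)
    rec = DualChannelRecording(nose=nose, mouth=mouth, sample_rate=SR)
    scaled = DualChannelRecording(nose=0.05 * nose, mouth=0.05 * mouth, sample_rate=SR)
    assert e_nasalance(scaled) == pytest.approx(e_nasalance(rec), abs=1e-9)
    silent = DualChannelRecording(nose=np.zeros(SR), mouth=np.zeros(SR), sample_rate=SR)
    with pytest.raises(ValueError, match="undefined"):
        e_nasalance(silent)


def test_enasalance_config_validation():
    with pytest.raises(ValueError):
        ENasalanceConfig(center_hz=100, bandwidth_hz=300)
    assert ENasalanceConfig().band == (450.0, 750.0)


def test_speaker_enasalance_mean(rng):
    assert speaker_e_nasalance([40, 60]) == 50
    assert speaker_e_nasalance([33.3]) == 33.3
    vals = rng.uniform(0, 100, size=11)
    assert speaker_e_nasalance(vals) == pytest.approx(sum(vals) / 11)
    with pytest.raises(ValueError):
        speaker_e_nasalance([])


def _scores(values):
    return [SpeakerScore(speaker_id=f"s{i}", score=v, n=1) for i, v in enumerate(values)]


def test_scale_transform_rank_partition():
    scores = _scores([0.9, 0.1, 0.5, 0.3, 0.7])
    out = scale_transform(scores, ReferenceDistribution(2, 1, 1, 1))
    by_speaker = {s.speaker_id: s.level for s in out}
    assert by_speaker == {"s1": 0, "s3": 0, "s2": 1, "s4": 2, "s0": 3}
    # output preserves input order
    assert [s.speaker_id for s in out] == [s.speaker_id for s in scores]


def test_scale_transform_ties_stable_and_counts_exact():
    scores = _scores([0.5] * 6)
    out = scale_transform(scores, ReferenceDistribution(3, 1, 0, 2))
    assert [s.level for s in out] == [0, 0, 0, 1, 3, 3]


def test_scale_transform_degenerate_and_mismatch():
    scores = _scores([0.2, 0.8, 0.4])
    out = scale_transform(scores, ReferenceDistribution(3, 0, 0, 0))
    assert all(s.level == 0 for s in out)
    with pytest.raises(ValueError):
        scale_transform(scores, ReferenceDistribution(1, 1, 1, 1))


def test_scale_transform_levels_monotone_in_score(rng):
    scores = _scores(rng.uniform(0, 1, size=12))
    out = scale_transform(scores, ReferenceDistribution(3, 3, 3, 3))
    ordered = sorted(out, key=lambda s: s.score)
    levels = [s.level for s in ordered]
    assert levels == sorted(levels)


def test_speaker_score_validation():
    with pytest.raises(ValueError):
        SpeakerScore(speaker_id="x", score=1.5, n=1, kind="mfcc")
    with pytest.raises(ValueError):
        SpeakerScore(speaker_id="x", score=50.0, n=0, kind="energy")
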