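import numpy as np
import pytest

from nasalkit.audio_io import read_dual_wav
from nasalkit.features import FeatureConfig, segment_windows
from nasalkit.labeling import LabelingConfig, classify_phones, label_windows
from nasalkit.nasalance import e_nasalance
from nasalkit.synth import SynthConfig, generate_cohort, generate_speaker, write_cohort
from nasalkit.textgrid import read_textgrid


def test_same_seed_is_bit_identical():
    cfg = SynthConfig(seed=5, n_speakers=2, utterances_per_speaker=2)
    a = generate_speaker(cfg, 1)
    b = generate_speaker(cfg, 1)
    for (ra, iva), (rb, ivb) in zip(a, b):
        assert np.array_equal(ra.nose, rb.nose)
        assert np.array_equal(ra.mouth, rb.mouth)
        assert iva == ivb


def test_zero_nasality_has_no_nasal_material():
    cfg = SynthConfig(seed=3, n_speakers=1, utterances_per_speaker=3,
                      nasality_levels=(0.0,))
    for rec, intervals in generate_speaker(cfg, 0):
        classes = {iv.phone_class for iv in classify_phones(intervals)}
        assert "nasal_consonant" not in classes
        starts = [s for s, _ in segment_windows(rec)]
        assert set(label_windows(intervals, starts)) == {"oral"}


def test_annotations_tile_exactly():
    cfg = SynthConfig(seed=9, n_speakers=1, utterances_per_speaker=2)
    for rec, intervals in generate_speaker(cfg, 0):
        assert intervals[0].start_ms == 0
        for a, b in zip(intervals, intervals[1:]):
            assert b.start_ms == pytest.approx(a.end_ms, abs=1e-9)
        assert intervals[-1].end_ms == pytest.approx(rec.duration_ms, abs=1e-6)


def test_realized_nasal_fraction_tracks_level():
    level = 0.4
    cfg = SynthConfig(seed=11, n_speakers=1, utterances_per_speaker=20,
                      nasality_levels=(level,))
    nasal_ms = speech_ms = 0.0
    for _, intervals in generate_speaker(cfg, 0):
        for iv in classify_phones(intervals):
            if iv.phone_class == "silence":
                continue
            speech_ms += iv.duration_ms
            if iv.phone_class == "nasal_consonant":
                nasal_ms += iv.duration_ms
    assert nasal_ms / speech_ms == pytest.approx(level, abs=0.05)


def test_manifest_ranking_is_identity():
    cfg = SynthConfig(seed=2, n_speakers=10, utterances_per_speaker=1)
    cohort = generate_cohort(cfg)
    levels = cohort.manifest["nasality_level"].to_numpy()
    assert np.array_equal(np.argsort(levels), np.arange(10))
    assert len(cohort.utterances) == 10


def test_pure_nasal_enasalance_near_upper_boundary():
    cfg = SynthConfig(seed=4, n_speakers=1, utterances_per_speaker=1,
                      nasality_levels=(1.0,), nasal_mouth_leakage=0.01,
                      noise_floor=1e-5)
    rec, _ = generate_speaker(cfg, 0)[0]
    # analytic expectation: murmur band covers 450-750 Hz; mouth carries
    # only the 1% leakage, so the score approaches 100/(1 + 0.01)
    assert e_nasalance(rec) > 97.0


def test_energy_ratio_separates_classes_at_low_leakage():
    """With leakage near zero, the nose/mouth energy balance separates
    clearly nasal windows (>= 150 ms nasal time) from fully oral ones."""
    from nasalkit.labeling import classify_phones as _cls, nasal_overlap_ms, nasalize_vowels

    cfg = SynthConfig(seed=6, n_speakers=2, utterances_per_speaker=2,
                      nasality_levels=(0.35, 0.45), oral_leakage=1e-3,
                      nasal_mouth_leakage=1e-3, noise_floor=1e-6)
    fcfg = FeatureConfig()
    ratios, nasal_ms = [], []
    for rec, intervals in (generate_speaker(cfg, 0) + generate_speaker(cfg, 1)):
        spans = nasalize_vowels(_cls(intervals), LabelingConfig())
        for start, sl in segment_windows(rec, fcfg):
            nose_rms = np.sqrt(np.mean(sl[0] ** 2))
            mouth_rms = np.sqrt(np.mean(sl[1] ** 2))
            ratios.append(nose_rms / (nose_rms + mouth_rms))
            nasal_ms.append(nasal_overlap_ms(start, fcfg.window_ms, spans))
    ratios = np.array(ratios)
    nasal_ms = np.array(nasal_ms)
    strongly_nasal = nasal_ms >= 150
    fully_oral = nasal_ms == 0
    assert strongly_nasal.sum() >= 5 and fully_oral.sum() >= 5
    assert ratios[strongly_nasal].min() > ratios[fully_oral].max()


def test_write_cohort_files_and_refusal(tmp_path):
    cfg = SynthConfig(seed=8, n_speakers=2, utterances_per_speaker=1)
    out = write_cohort(cfg, tmp_path / "cohort")
    wavs = sorted(out.glob("*.wav"))
    assert len(wavs) == 2
    assert (out / "manifest.csv").exists()
    with pytest.raises(FileExistsError):
        write_cohort(cfg, out)
    # WAV + TextGrid round-trip preserves identity of the annotation
    rec = read_dual_wav(wavs[0])
    intervals = read_textgrid(out / (wavs[0].stem + ".TextGrid"))
    assert intervals[-1].end_ms == pytest.approx(rec.duration_ms, abs=1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(n_speakers=2, nasality_levels=(0.5,))
    with pytest.raises(ValueError):
        SynthConfig(n_speakers=1, nasality_levels=(1.5,))
    with pytest.raises(ValueError):
        SynthConfig(oral_leakage=0.0)
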