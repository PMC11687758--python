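import numpy as np
import pytest

from nasalkit.labeling import (
    LabelingConfig,
    NasalSpan,
    PhoneInterval,
    classify_phones,
    label_window,
    label_windows,
    merge_spans,
    nasal_overlap_ms,
    nasalize_vowels,
)

CFG = LabelingConfig()


def _seq(*phones):
    """Build contiguous intervals from (label, duration_ms) pairs."""
    out, t = [], 0.0
    for label, dur in phones:
        out.append(PhoneInterval(label=label, start_ms=t, end_ms=t + dur))
        t += dur
    return out


def test_classify_phone_classes():
    ivs = classify_phones(_seq(("m", 80), ("p", 50), ("a", 70), ("", 100), ("ɲ", 60)))
    assert [iv.phone_class for iv in ivs] == [
        "nasal_consonant", "oral", "vowel", "silence", "nasal_consonant"]


def test_unknown_symbol_is_oral_not_error():
    (iv,) = classify_phones(_seq(("zz9", 50)))
    assert iv.phone_class == "oral"


@pytest.mark.parametrize(
    "vowel_ms,expected_span_ms",
    [(50, 50), (80, 40), (100, 30), (60, 30), (90, 45)],
)
def test_vowel_nasalization_durations(vowel_ms, expected_span_ms):
    """Entire vowel below 60 ms, half between 60 and 90 ms, 30% above."""
    ivs = classify_phones(_seq(("p", 100), ("a", vowel_ms), ("m", 80)))
    spans = nasalize_vowels(ivs)
    vowel = ivs[1]
    # the merged span ends where the nasal consonant ends; the vowel part
    # abuts the shared boundary
    vowel_part = nasal_overlap_ms(vowel.start_ms, vowel.duration_ms, spans)
    assert vowel_part == pytest.approx(expected_span_ms)
    assert nasal_overlap_ms(vowel.start_ms, vowel.duration_ms - expected_span_ms, spans) == 0


def test_nasalized_section_position_follows_the_nasal():
    # vowel after the nasal: the section is vowel-initial
    ivs = classify_phones(_seq(("n", 80), ("a", 100), ("p", 60)))
    spans = nasalize_vowels(ivs)
    assert nasal_overlap_ms(80, 30, spans) == pytest.approx(30)   # first 30 ms nasal
    assert nasal_overlap_ms(110, 70, spans) == 0                  # rest of the vowel
    # vowel before the nasal: the section is vowel-final
    ivs = classify_phones(_seq(("p", 60), ("a", 100), ("n", 80)))
    spans = nasalize_vowels(ivs)
    assert nasal_overlap_ms(130, 30, spans) == pytest.approx(30)  # last 30 ms nasal
    assert nasal_overlap_ms(60, 70, spans) == 0                   # start of the vowel


def test_vowel_without_nasal_neighbor_has_no_span():
    ivs = classify_phones(_seq(("p", 60), ("a", 100), ("t", 60), ("m", 80)))
    spans = nasalize_vowels(ivs)
    vowel = ivs[1]
    assert nasal_overlap_ms(vowel.start_ms, vowel.duration_ms, spans) == 0


def test_silence_breaks_adjacency():
    ivs = classify_phones(_seq(("m", 80), ("", 20), ("a", 100)))
    spans = nasalize_vowels(ivs)
    assert nasal_overlap_ms(100, 100, spans) == 0


def test_flanking_nasals_merge_and_cap():
    # 50 ms vowel between two nasals: both sections cover the whole vowel
    ivs = classify_phones(_seq(("m", 80), ("a", 50), ("n", 80)))
    spans = nasalize_vowels(ivs)
    assert len(spans) == 1  # one contiguous nasal stretch
    assert spans[0].start_ms == 0 and spans[0].end_ms == pytest.approx(210)
    total = sum(sp.end_ms - sp.start_ms for sp in spans)
    speech = sum(iv.duration_ms for iv in ivs)
    assert total <= speech + 1e-9


@pytest.mark.parametrize(
    "overlap_ms,expected",
    [(80, "nasal"), (75, "nasal"), (74.5, "oral"), (0, "oral"), (250, "nasal")],
)
def test_window_threshold_inclusive_75ms(overlap_ms, expected):
    spans = [NasalSpan(0, overlap_ms)] if overlap_ms else []
    assert label_window(0.0, spans, CFG, window_ms=250.0) == expected


def test_label_window_accumulates_disjoint_spans():
    spans = [NasalSpan(0, 40), NasalSpan(100, 140), NasalSpan(240, 300)]
    # inside [0, 250): 40 + 40 + 10 = 90 ms >= 75
    assert label_window(0.0, spans) == "nasal"
    # inside [150, 400): only 60 ms -> oral
    assert label_window(150.0, spans) == "oral"


def test_monotonicity_adding_span_never_unnasalizes(rng):
    for _ in range(200):
        spans = merge_spans([
            NasalSpan(float(s), float(s) + float(rng.integers(1, 120)))
            for s in rng.integers(0, 800, size=rng.integers(1, 5))
        ])
        start = float(rng.integers(0, 600))
        extra = NasalSpan(float(rng.integers(0, 800)), 850.0)
        before = label_window(start, spans, CFG)
        after = label_window(start, spans + [extra], CFG)
        assert not (before == "nasal" and after == "oral")


def test_window_label_matches_per_millisecond_oracle(rng):
    """1 ms-discretized random annotations vs a brute-force counter."""
    for _ in range(1000):
        n_spans = int(rng.integers(0, 6))
        raw = []
        for _ in range(n_spans):
            s = int(rng.integers(0, 900))
            raw.append(NasalSpan(float(s), float(s + int(rng.integers(1, 200)))))
        spans = merge_spans(raw)
        start = int(rng.integers(0, 800))
        # brute force: mark each millisecond covered by any span
        grid = np.zeros(1200, dtype=bool)
        for sp in spans:
            grid[int(sp.start_ms) : int(sp.end_ms)] = True
        count = int(grid[start : start + 250].sum())
        expected = "nasal" if count >= 75 else "oral"
        assert label_window(float(start), spans, CFG) == expected


def test_diadochokinetic_utterance_is_all_oral():
    ivs = _seq(*[(c, 70) for _ in range(6) for c in ("p", "a")])
    starts = [0.0, 100.0, 200.0, 300.0]
    assert label_windows(ivs, starts) == ["oral"] * 4


def test_config_validation():
    with pytest.raises(ValueError):
        LabelingConfig(short_vowel_ms=90, long_vowel_ms=60)
    with pytest.raises(ValueError):
        LabelingConfig(mid_fraction=0.2, long_fraction=0.5)
    with pytest.raises(ValueError):
        PhoneInterval(label="a", start_ms=10, end_ms=10)
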