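"""Rule-based oral/nasal labels for analysis windows.

Phone-level alignments are turned into window labels in three steps:

1. phone symbols are classified as nasal consonant, vowel, silence, or oral;
2. nasal spans are derived — every nasal consonant in full, plus the section
   of each vowel in contact with a nasal consonant, whose length depends on
   vowel duration (the whole vowel below 60 ms, half between 60 and 90 ms,
   30% above 90 ms), anchored at the boundary shared with the nasal;
3. a 250 ms window is labeled *nasal* when the accumulated nasal-span time
   inside it reaches 30% of the window (75 ms), *oral* otherwise.

Times are milliseconds from utterance start; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

__all__ = [
    "PhoneInterval",
    "NasalSpan",
    "LabelingConfig",
    "classify_phones",
    "nasalize_vowels",
    "merge_spans",
    "label_window",
    "label_windows",
]

logger = logging.getLogger(__name__)

#: Symbols treated as silence/pause markers in alignments.
SILENCE_SYMBOLS = frozenset({"", "sil", "sp", "spn", "<sil>", "<p:>", "pause"})

#: Default vowel inventory (Spanish monophthongs plus stressed variants).
VOWELS = frozenset(
    {"a", "e", "i", "o", "u", "á", "é", "í", "ó", "ú", "w", "j"}
)


@dataclass(frozen=True)
class PhoneInterval:
    """A time-aligned phone; the unit the labeling rules operate on."""

    label: str
    start_ms: float
    end_ms: float
    phone_class: str = "unclassified"  # {oral, nasal_consonant, vowel, silence}

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError(
                f"empty interval [{self.start_ms}, {self.end_ms}) for {self.label!r}"
            )

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class NasalSpan:
    """A stretch of time counted as nasal when labeling windows."""

    start_ms: float
    end_ms: float
    source: str = "nasal_consonant"  # or "nasalized_vowel_section"

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("empty nasal span")


@dataclass(frozen=True)
class LabelingConfig:
    """Thresholds of the nasalization and window-accumulation rules."""

    nasal_consonants: frozenset[str] = frozenset({"m", "n", "ɲ"})
    vowels: frozenset[str] = VOWELS
    silence_symbols: frozenset[str] = SILENCE_SYMBOLS
    short_vowel_ms: float = 60.0
    long_vowel_ms: float = 90.0
    mid_fraction: float = 0.50
    long_fraction: float = 0.30
    window_nasal_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0 < self.long_fraction <= self.mid_fraction <= 1):
            raise ValueError("require 0 < long_fraction <= mid_fraction <= 1")
        if not self.short_vowel_ms < self.long_vowel_ms:
            raise ValueError("require short_vowel_ms < long_vowel_ms")
        if not (0 < self.window_nasal_fraction <= 1):
            raise ValueError("window_nasal_fraction must be in (0, 1]")


def classify_phones(
    intervals: list[PhoneInterval], cfg: LabelingConfig = LabelingConfig()
) -> list[PhoneInterval]:
    """Tag each interval with its phone class.

    Symbols are lower-cased and stress marks on known vowels are honored via
    the configured inventory.  A symbol in none of the inventories is
    logged and treated as oral — alignments routinely contain dialectal or
    tool-specific codes and they carry no nasality by default.
    """
    out = []
    for iv in _check_sorted(intervals):
        sym = iv.label.strip().lower()
        if sym in cfg.silence_symbols:
            cls = "silence"
        elif sym in cfg.nasal_consonants:
            cls = "nasal_consonant"
        elif sym in cfg.vowels:
            cls = "vowel"
        else:
            if not sym.isascii() or not sym.isalpha():
                logger.warning("unknown phone symbol %r treated as oral", iv.label)
            cls = "oral"
        out.append(replace(iv, phone_class=cls))
    return out


def _check_sorted(intervals: list[PhoneInterval]) -> list[PhoneInterval]:
    ivs = sorted(intervals, key=lambda iv: iv.start_ms)
    for a, b in zip(ivs, ivs[1:]):
        if b.start_ms < a.end_ms - 1e-9:
            raise ValueError(
                f"overlapping phone intervals: {a.label!r} and {b.label!r}"
            )
    return ivs


def _nasalized_duration(d: float, cfg: LabelingConfig) -> float:
    """Length of the nasalized vowel section for a vowel of duration ``d``."""
    if d < cfg.short_vowel_ms:
        return d
    if d <= cfg.long_vowel_ms:
        return cfg.mid_fraction * d
    return cfg.long_fraction * d


def nasalize_vowels(
    intervals: list[PhoneInterval], cfg: LabelingConfig = LabelingConfig()
) -> list[NasalSpan]:
    """Derive nasal spans from classified phone intervals.

    Every nasal consonant contributes its full extent.  A vowel sharing a
    boundary with a nasal consonant contributes a section abutting that
    boundary (vowel-initial after a nasal, vowel-final before one); a vowel
    flanked on both sides gets both sections, merged and capped at the full
    vowel.  Vowels with no nasal neighbor contribute nothing.
    """
    ivs = _check_sorted(intervals)
    spans: list[NasalSpan] = []
    eps = 1e-6
    for i, iv in enumerate(ivs):
        if iv.phone_class == "nasal_consonant":
            spans.append(NasalSpan(iv.start_ms, iv.end_ms, "nasal_consonant"))
        elif iv.phone_class == "vowel":
            d_prime = _nasalized_duration(iv.duration_ms, cfg)
            prev_nasal = (
                i > 0
                and ivs[i - 1].phone_class == "nasal_consonant"
                and abs(ivs[i - 1].end_ms - iv.start_ms) < eps
            )
            next_nasal = (
                i + 1 < len(ivs)
                and ivs[i + 1].phone_class == "nasal_consonant"
                and abs(iv.end_ms - ivs[i + 1].start_ms) < eps
            )
            pieces = []
            if prev_nasal:
                pieces.append((iv.start_ms, iv.start_ms + d_prime))
            if next_nasal:
                pieces.append((iv.end_ms - d_prime, iv.end_ms))
            for s, e in _merge_pairs(pieces):
                # cap at the vowel extent (relevant when both ends overlap)
                spans.append(
                    NasalSpan(max(s, iv.start_ms), min(e, iv.end_ms),
                              "nasalized_vowel_section")
                )
    return merge_spans(spans)


def _merge_pairs(pieces: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for s, e in sorted(pieces):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_spans(spans: list[NasalSpan]) -> list[NasalSpan]:
    """Merge overlapping/abutting nasal spans into a disjoint sorted list."""
    if not spans:
        return []
    merged: list[NasalSpan] = []
    for sp in sorted(spans, key=lambda s: s.start_ms):
        if merged and sp.start_ms <= merged[-1].end_ms + 1e-9:
            last = merged[-1]
            if sp.end_ms > last.end_ms:
                src = last.source if last.source == sp.source else "nasal_consonant"
                merged[-1] = NasalSpan(last.start_ms, sp.end_ms, src)
        else:
            merged.append(sp)
    return merged


def nasal_overlap_ms(
    start_ms: float, window_ms: float, spans: list[NasalSpan]
) -> float:
    """Accumulated nasal-span time inside ``[start_ms, start_ms + window_ms)``."""
    end = start_ms + window_ms
    total = 0.0
    for sp in spans:
        total += max(0.0, min(sp.end_ms, end) - max(sp.start_ms, start_ms))
    return total


def label_window(
    start_ms: float,
    spans: list[NasalSpan],
    cfg: LabelingConfig = LabelingConfig(),
    window_ms: float = 250.0,
) -> str:
    """Label one window *nasal* or *oral* by accumulated nasal time.

    The window is nasal when the nasal fraction reaches
    ``cfg.window_nasal_fraction`` (inclusive: 75 ms of a 250 ms window under
    defaults), oral otherwise.  Silence contributes nothing.
    """
    spans = merge_spans(spans)
    frac = nasal_overlap_ms(start_ms, window_ms, spans) / window_ms
    return "nasal" if frac >= cfg.window_nasal_fraction - 1e-12 else "oral"


def label_windows(
    intervals: list[PhoneInterval],
    window_starts_ms: list[float],
    cfg: LabelingConfig = LabelingConfig(),
    window_ms: float = 250.0,
) -> list[str]:
    """Classify phones, derive nasal spans, and label every window start."""
    spans = nasalize_vowels(classify_phones(intervals, cfg), cfg)
    return [label_window(s, spans, cfg, window_ms) for s in window_starts_ms]
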