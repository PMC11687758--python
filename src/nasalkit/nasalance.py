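"""Speaker-level nasalance scores and the 4-level clinical recode.

Two scores are computed:

* **mfccNasalance** — the mean posterior probability of *nasal*, from a
  trained window classifier, over all of a speaker's 250 ms windows; a
  value in [0, 1].
* **eNasalance** — the classic energy ratio: both channels are band-pass
  filtered to a 300 Hz band centered at 600 Hz and the score is
  ``100 * RMS(nose) / (RMS(nose) + RMS(mouth))``, a percentage.  Per-speaker
  eNasalance is the unweighted mean over utterance scores.

Either score can be recoded to the 4-level clinical scale (oral / mild /
moderate / severe) by rank: given a reference distribution of level counts,
the lowest-scoring speakers fill the oral group, the next the mild group,
and so on, preserving the reference group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import DualChannelRecording
from .features import FeatureWindow

__all__ = [
    "SpeakerScore",
    "ENasalanceConfig",
    "ReferenceDistribution",
    "mfcc_nasalance",
    "e_nasalance",
    "speaker_e_nasalance",
    "scale_transform",
]

LEVEL_NAMES = {0: "oral", 1: "mild", 2: "moderate", 3: "severe"}


@dataclass(frozen=True)
class SpeakerScore:
    """Per-speaker nasalance with an optional clinical level.

    ``score`` is in [0, 1] for kind="mfcc" and percent in [0, 100] for
    kind="energy"; ``n`` counts the windows or utterances averaged.
    """

    speaker_id: str
    score: float
    n: int
    kind: str = "mfcc"  # {"mfcc", "energy"}
    level: int | None = None  # {0 oral, 1 mild, 2 moderate, 3 severe}

    def __post_init__(self) -> None:
        hi = 1.0 if self.kind == "mfcc" else 100.0
        if self.kind not in ("mfcc", "energy"):
            raise ValueError(f"unknown score kind {self.kind!r}")
        if not (0.0 <= self.score <= hi):
            raise ValueError(f"{self.kind} score {self.score} outside [0, {hi}]")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.level is not None and self.level not in LEVEL_NAMES:
            raise ValueError(f"invalid level {self.level}")


@dataclass(frozen=True)
class ENasalanceConfig:
    """Band and filter of the energy nasalance (pinned for reproducibility)."""

    center_hz: float = 600.0
    bandwidth_hz: float = 300.0
    filter_order: int = 4  # Butterworth, applied zero-phase forward-backward

    def __post_init__(self) -> None:
        if self.center_hz - self.bandwidth_hz / 2 <= 0:
            raise ValueError("band must lie above 0 Hz")
        if self.filter_order <= 0:
            raise ValueError("filter_order must be positive")

    @property
    def band(self) -> tuple[float, float]:
        half = self.bandwidth_hz / 2
        return (self.center_hz - half, self.center_hz + half)


def mfcc_nasalance(
    windows: Sequence[FeatureWindow], model, speaker_id: str | None = None
) -> SpeakerScore:
    """Mean nasal posterior over one speaker's windows.

    ``model`` is anything exposing ``nasal_posterior(stacks)`` — a single
    trained fold model or a fitted cross-validation result (whose posterior
    is the mean over fold models; by linearity this equals the mean of the
    per-fold speaker scores).
    """
    windows = list(windows)
    if not windows:
        raise ValueError("mfcc_nasalance needs at least one window")
    speakers = {w.speaker_id for w in windows}
    if speaker_id is None:
        if len(speakers) > 1:
            raise ValueError(f"windows from multiple speakers: {sorted(speakers)}")
        speaker_id = next(iter(speakers))
    stacks = np.stack([w.stack for w in windows]).astype(np.float32)
    posteriors = np.asarray(model.nasal_posterior(stacks), dtype=np.float64)
    return SpeakerScore(
        speaker_id=speaker_id,
        score=float(np.mean(posteriors)),
        n=len(windows),
        kind="mfcc",
    )


def e_nasalance(
    rec: DualChannelRecording, cfg: ENasalanceConfig = ENasalanceConfig()
) -> float:
    """Energy nasalance of one utterance, in percent.

    Both channels are restricted to the configured band with a zero-phase
    Butterworth filter; the score is the nose share of the summed RMS
    energies.
    """
    lo, hi = cfg.band
    nyq = rec.sample_rate / 2
    if hi >= nyq:
        raise ValueError(f"band {cfg.band} exceeds Nyquist {nyq} Hz")
    sos = butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=rec.sample_rate,
                 output="sos")
    pad = min(3 * (2 * cfg.filter_order + 1), rec.n_samples - 1)
    nose = sosfiltfilt(sos, rec.nose, padlen=pad)
    mouth = sosfiltfilt(sos, rec.mouth, padlen=pad)
    rms_nose = float(np.sqrt(np.mean(nose**2)))
    rms_mouth = float(np.sqrt(np.mean(mouth**2)))
    total = rms_nose + rms_mouth
    if total == 0.0:
        raise ValueError("both filtered channels are zero; nasalance undefined")
    return 100.0 * rms_nose / total


def speaker_e_nasalance(utterance_scores: Sequence[float]) -> float:
    """Unweighted mean of per-utterance eNasalance percentages."""
    scores = list(utterance_scores)
    if not scores:
        raise ValueError("speaker_e_nasalance needs at least one utterance score")
    return float(np.mean(scores))


@dataclass(frozen=True)
class ReferenceDistribution:
    """Level counts to preserve when recoding scores to the 4-level scale."""

    n_oral: int
    n_mild: int
    n_moderate: int
    n_severe: int

    def __post_init__(self) -> None:
        if min(self.n_oral, self.n_mild, self.n_moderate, self.n_severe) < 0:
            raise ValueError("level counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_oral + self.n_mild + self.n_moderate + self.n_severe

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_oral, self.n_mild, self.n_moderate, self.n_severe)

    @classmethod
    def from_levels(cls, levels: Sequence[int]) -> "ReferenceDistribution":
        counts = [0, 0, 0, 0]
        for lv in levels:
            counts[int(lv)] += 1
        return cls(*counts)


def scale_transform(
    scores: Sequence[SpeakerScore], ref: ReferenceDistribution
) -> list[SpeakerScore]:
    """Assign 4-level clinical categories by rank, preserving group sizes.

    The ``ref.n_oral`` lowest scores become level 0, the next ``ref.n_mild``
    level 1, and so on; ties are broken by stable input order.  The result
    keeps the input order.
    """
    scores = list(scores)
    if ref.total != len(scores):
        raise ValueError(
            f"reference distribution totals {ref.total} but {len(scores)} "
            "scores were given"
        )
    order = sorted(range(len(scores)), key=lambda i: (scores[i].score, i))
    bounds = np.cumsum(ref.counts)
    out: list[SpeakerScore] = list(scores)
    for rank, idx in enumerate(order):
        level = int(np.searchsorted(bounds, rank, side="right"))
        out[idx] = replace(scores[idx], level=level)
    return out
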