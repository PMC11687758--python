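"""Perceptual nasality ratings: aggregation and the 4-level scale.

Experts rate each utterance 0 (normal), 1 (at least one nasalized vowel) or
2 (at least one nasalized consonant).  A speaker's nasality ratio is the
sum of their utterance scores divided by the maximum attainable score
(2 x number of utterances), giving a value in [0, 1], which the clinical
scale cuts at 0.05 / 0.25 / 0.50 into oral, mild, moderate and severe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "UtteranceRating",
    "PerceptualScale",
    "aggregate_ratings",
    "categorize",
    "merge_raters",
    "speaker_table",
]

MAX_SCORE_PER_UTTERANCE = 2


@dataclass(frozen=True)
class UtteranceRating:
    """One expert's 0-2 nasality score for one utterance."""

    utterance_id: str
    rater_id: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2):
            raise ValueError(f"rating must be 0, 1 or 2, got {self.score}")


@dataclass(frozen=True)
class PerceptualScale:
    """Upper cut points of the oral/mild/moderate categories."""

    cut_oral: float = 0.05
    cut_mild: float = 0.25
    cut_moderate: float = 0.50

    def __post_init__(self) -> None:
        if not (0 < self.cut_oral < self.cut_mild < self.cut_moderate < 1):
            raise ValueError("cuts must satisfy 0 < oral < mild < moderate < 1")


def aggregate_ratings(ratings: Sequence[UtteranceRating]) -> float:
    """Speaker nasality ratio: sum of scores over the maximum (2 per utterance).

    Expects one consolidated rating per utterance (rater disagreements are
    resolved upstream, see :func:`merge_raters`); order-invariant.
    """
    ratings = list(ratings)
    if not ratings:
        raise ValueError("aggregate_ratings needs at least one rating")
    return sum(r.score for r in ratings) / (MAX_SCORE_PER_UTTERANCE * len(ratings))


def categorize(ratio: float, scale: PerceptualScale = PerceptualScale()) -> int:
    """4-level category of a nasality ratio; boundaries belong to the lower level."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"nasality ratio {ratio} outside [0, 1]")
    if ratio <= scale.cut_oral:
        return 0
    if ratio <= scale.cut_mild:
        return 1
    if ratio <= scale.cut_moderate:
        return 2
    return 3


def merge_raters(
    ratings: Sequence[UtteranceRating],
    adjudicator_id: str | None = None,
) -> list[UtteranceRating]:
    """Consolidate multiple raters into one rating per utterance.

    When the primary raters agree, their common score stands.  When they
    disagree, the adjudicator's score is used; a disagreement with no
    adjudicator rating is an error.
    """
    by_utt: dict[str, list[UtteranceRating]] = {}
    for r in ratings:
        by_utt.setdefault(r.utterance_id, []).append(r)
    merged = []
    for utt, rs in by_utt.items():
        adj = [r for r in rs if r.rater_id == adjudicator_id]
        primary = [r for r in rs if r.rater_id != adjudicator_id]
        scores = {r.score for r in primary}
        if len(scores) == 1:
            score = scores.pop()
        elif adj:
            score = adj[0].score
        else:
            raise ValueError(f"raters disagree on {utt!r} and no adjudicator rating given")
        merged.append(UtteranceRating(utterance_id=utt, rater_id="consensus", score=score))
    return merged


def speaker_table(
    ratings_by_speaker: dict[str, Sequence[UtteranceRating]],
    scale: PerceptualScale = PerceptualScale(),
) -> pd.DataFrame:
    """Per-speaker nasality ratios and levels as a DataFrame."""
    rows = []
    for speaker, ratings in ratings_by_speaker.items():
        ratio = aggregate_ratings(ratings)
        rows.append({
            "speaker_id": speaker,
            "ratio": ratio,
            "level": categorize(ratio, scale),
            "n_utterances": len(list(ratings)),
        })
    return pd.DataFrame(rows).set_index("speaker_id")
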