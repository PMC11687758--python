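"""Agreement between nasalance scores and perceptual ratings.

The accuracy of a nasalance measure is its Spearman rank correlation with
the experts' perceptual nasality, computed per kernel configuration,
utterance type and cross-validation fold, then averaged over folds.  Rank
correlation (with average ranks for ties) is used rather than Pearson
because nasalance scores are not normally distributed in clinical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EvaluationRecord", "spearman_rho", "aggregate_grid", "summarize_best"]

UTTERANCE_TYPES = ("syllables", "words", "sentences")


@dataclass(frozen=True)
class EvaluationRecord:
    """One correlation measurement for a (config, utterance type, fold) cell."""

    config_id: str
    utterance_type: str
    fold: int  # -1 marks a mean-over-folds record
    rho: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3 for a defined correlation")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Both vectors are ranked (ties receive the mean of the ranks they span)
    and the Pearson correlation of the ranks is returned.  Requires equal
    lengths of at least 3 and variation in both vectors.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for an all-tied vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def aggregate_grid(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Mean rho over folds for every (config, utterance type) cell.

    Input records must be per-fold; every cell must carry the same number of
    folds.  The result has one row per cell (permutation-invariant over the
    input order) with columns ``mean_rho`` and ``n_folds``.
    """
    if not records:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame([r.__dict__ for r in records])
    if (df["fold"] < 0).any():
        raise ValueError("aggregate_grid expects per-fold records only")
    grouped = df.groupby(["config_id", "utterance_type"], sort=True)
    counts = grouped["fold"].count()
    if counts.nunique() > 1:
        ragged = counts[counts != counts.iloc[0]]
        raise ValueError(f"ragged fold counts for {list(ragged.index)}")
    out = grouped["rho"].mean().to_frame("mean_rho")
    out["n_folds"] = counts
    return out.reset_index()


def summarize_best(aggregated: pd.DataFrame) -> dict[str, dict]:
    """Best configuration per utterance type from an aggregated grid."""
    best = {}
    for utype, grp in aggregated.groupby("utterance_type"):
        row = grp.loc[grp["mean_rho"].idxmax()]
        best[str(utype)] = {
            "config_id": str(row["config_id"]),
            "mean_rho": float(row["mean_rho"]),
        }
    return best
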