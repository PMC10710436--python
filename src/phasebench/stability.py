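"""Stability of rankings across variant representations.

Given a table of per-submission Q-scores measured under several
representations of the same callset (original plus the four design
points), two statistics summarize how much the choice of representation
matters:

* AMRC (Average Maximum Rank Change): for each submission, how many rank
  positions it would move among the other submissions' median scores if
  judged by its best rather than its worst representation, averaged over
  submissions.  0 means ranking is representation-independent.
* R-squared of per-representation Q-scores against each submission's mean
  Q-score, pooled over representations; 1 means all representations agree.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REPRESENTATIONS = ("O", "A", "B", "C", "D")


@dataclass
class ScoreTable:
    """Q-scores per submission and representation."""

    #: submission id -> {representation -> Q-score}
    scores: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreTable":
        """Build from a table with columns submission, representation, qscore."""
        t = cls()
        for _, row in df.iterrows():
            t.scores.setdefault(str(row["submission"]), {})[
                str(row["representation"])] = float(row["qscore"])
        return t

    def matrix(self) -> np.ndarray:
        reps = self.representations()
        return np.array([[self.scores[s][r] for r in reps]
                         for s in self.scores])

    def representations(self) -> tuple[str, ...]:
        any_sub = next(iter(self.scores.values()), {})
        return tuple(r for r in REPRESENTATIONS if r in any_sub) or \
            tuple(sorted(any_sub))


def _median(values: np.ndarray) -> float:
    # middle order statistic of an odd-length set, no interpolation
    return float(np.sort(values)[len(values) // 2])


def amrc(t: ScoreTable) -> float:
    """Average rank swing between each submission's best and worst score.

    Ranks are positions in the sorted sequence of the other submissions'
    median Q-scores (the submission's own median is removed before
    ranking); ``pos`` is the leftmost insertion index.
    """
    mat = t.matrix()
    if mat.size == 0:
        raise ValueError("empty score table")
    n = mat.shape[0]
    medians = [_median(row) for row in mat]
    M = sorted(medians)
    total = 0
    for i in range(n):
        others = list(M)
        others.pop(bisect_left(others, medians[i]))
        b, w = float(np.max(mat[i])), float(np.min(mat[i]))
        total += bisect_left(others, b) - bisect_left(others, w)
    return total / n


def stability_r2(t: ScoreTable) -> float:
    """Pooled R-squared of per-representation scores vs submission means."""
    mat = t.matrix()
    if mat.shape[0] < 2:
        raise ValueError("need at least two submissions")
    means = mat.mean(axis=1)
    x = np.repeat(means, mat.shape[1])
    y = mat.ravel()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in scores")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
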