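"""Event-locked analysis of valence responses to questions.

The 10 s following each question onset is divided into five
non-overlapping 2 s segments.  For every participant, the fraction of
sympathetic and of parasympathetic valence emissions per segment
(NA emissions discarded) is averaged over that participant's
questions, and a paired two-sided Student's t-test compares the
sympathetic and parasympathetic fractions across participants, one
test per segment.

Segment membership uses half-open intervals ``(t0 + (k-1)*L, t0 + k*L]``
so that each 2 s valence emission falls in exactly one segment; an
emission exactly at the question onset is excluded.  When consecutive
question windows overlap, the most recent question claims the shared
emissions (logged).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .valence import ValenceSeries

__all__ = [
    "QuestionEvent",
    "SegmentSpec",
    "epoch_valence",
    "participant_average",
    "segment_test",
]

logger = logging.getLogger(__name__)

_BRANCHES = ("sympathetic", "parasympathetic")


@dataclass(frozen=True)
class QuestionEvent:
    participant_id: str
    question_id: str
    onset_time: float

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("question onset must be non-negative")


@dataclass(frozen=True)
class SegmentSpec:
    """Post-question window split into equal non-overlapping segments."""

    post_window: float = 10.0
    n_segments: int = 5
    segment_length: float = 2.0

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.segment_length <= 0:
            raise ValueError("segments must be positive")
        if not np.isclose(self.n_segments * self.segment_length, self.post_window):
            raise ValueError(
                "n_segments * segment_length must equal the post-question window"
            )


EpochCounts = dict[tuple[str, str], dict[int, dict[str, int]]]


def epoch_valence(
    valence: ValenceSeries,
    events: list[QuestionEvent],
    spec: SegmentSpec = SegmentSpec(),
) -> EpochCounts:
    """Count sympathetic/parasympathetic emissions per post-question segment.

    Returns ``counts[(participant, question)][segment 1..n][branch]``.
    NA emissions are discarded.  An emission belongs to segment k of the
    event at t0 iff ``t0 + (k-1)*L < t <= t0 + k*L``; when post-question
    windows of consecutive questions overlap, the latest question wins.
    """
    evs = sorted(events, key=lambda e: e.onset_time)
    onsets = [e.onset_time for e in evs]
    counts: EpochCounts = {
        (e.participant_id, e.question_id): {
            k: {b: 0 for b in _BRANCHES} for k in range(1, spec.n_segments + 1)
        }
        for e in evs
    }
    n_overlap = sum(
        1
        for a, b in zip(onsets[:-1], onsets[1:])
        if b - a < spec.post_window
    )
    if n_overlap:
        logger.warning(
            "%d consecutive question windows overlap; shared emissions are "
            "assigned to the most recent question",
            n_overlap,
        )
    for em in valence.emissions:
        if em.label not in _BRANCHES:
            continue
        i = bisect_left(onsets, em.time) - 1  # latest onset strictly before t
        if i < 0:
            continue
        ev = evs[i]
        dt = em.time - ev.onset_time
        if dt > spec.post_window + 1e-9:
            continue
        k = max(1, ceil(dt / spec.segment_length - 1e-9))
        counts[(ev.participant_id, ev.question_id)][k][em.label] += 1
    return counts


def participant_average(epochs: EpochCounts) -> pd.DataFrame:
    """Normalized per-segment fractions, averaged over each participant's questions.

    Per question and segment, the sympathetic (parasympathetic) fraction
    is the branch count over the segment's non-NA count; segments with
    no emissions are skipped.  The per-participant value is the
    unweighted mean over that participant's defined question/segment
    cells.  Participants with no usable cells are excluded (logged).

    Returns a tidy frame with columns ``participant_id``, ``segment``,
    ``frac_sympathetic``, ``frac_parasympathetic``.
    """
    rows = []
    for (pid, qid), segs in epochs.items():
        for k, c in segs.items():
            total = c["sympathetic"] + c["parasympathetic"]
            if total == 0:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "question_id": qid,
                    "segment": k,
                    "frac_sympathetic": c["sympathetic"] / total,
                    "frac_parasympathetic": c["parasympathetic"] / total,
                }
            )
    columns = ["participant_id", "segment", "frac_sympathetic", "frac_parasympathetic"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["participant_id", "segment"], as_index=False)[
            ["frac_sympathetic", "frac_parasympathetic"]
        ].mean()
    )
    all_pids = {pid for pid, _ in epochs}
    dropped = all_pids - set(out["participant_id"])
    if dropped:
        logger.warning(
            "participants with no usable segments excluded: %s", sorted(dropped)
        )
    return out[columns]


def segment_test(
    fractions: pd.DataFrame, n_segments: int = 5
) -> pd.DataFrame:
    """Paired two-sided t-test of sympathetic vs parasympathetic fractions.

    One test per segment across participants.  If the paired differences
    have zero variance the test statistic is undefined and the segment
    is flagged (``zero_variance``); all-zero differences report t = 0.

    Returns one row per segment with columns ``segment``,
    ``mean_frac_sympathetic``, ``mean_frac_parasympathetic``,
    ``mean_diff`` (sympathetic - parasympathetic), ``t``, ``p``, ``n``,
    ``zero_variance``.
    """
    rows = []
    for k in range(1, n_segments + 1):
        sub = fractions[fractions["segment"] == k]
        n = len(sub)
        row = {
            "segment": k,
            "mean_frac_sympathetic": np.nan,
            "mean_frac_parasympathetic": np.nan,
            "mean_diff": np.nan,
            "t": np.nan,
            "p": np.nan,
            "n": n,
            "zero_variance": False,
        }
        if n >= 2:
            s = sub["frac_sympathetic"].to_numpy()
            p = sub["frac_parasympathetic"].to_numpy()
            d = s - p
            row["mean_frac_sympathetic"] = s.mean()
            row["mean_frac_parasympathetic"] = p.mean()
            row["mean_diff"] = d.mean()
            if d.std(ddof=1) == 0:
                row["zero_variance"] = True
                if np.all(d == 0):
                    row["t"] = 0.0
            else:
                t_stat, p_val = stats.ttest_rel(s, p)
                row["t"] = float(t_stat)
                row["p"] = float(p_val)
        rows.append(row)
    return pd.DataFrame(rows)
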