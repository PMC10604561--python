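"""Fusion of valence and arousal into six circumplex affective states.

Russell's circumplex tiles the valence x arousal plane; here the
3-level arousal axis and 2-sided valence axis yield six named states:

=========  =========  ==========
arousal    positive   negative
=========  =========  ==========
high       excited    tense
medium     focused    cautious
low        calm       bored
=========  =========  ==========

Every valence emission (2 s cadence) is paired with the most recent
arousal emission at or before its time, so the fused stream updates
every 2 s regardless of the 1 s arousal cadence.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .arousal import ArousalSeries
from .valence import VALENCE_TO_SIGN, ValenceSeries

__all__ = [
    "AffectiveState",
    "StateOccurrenceTable",
    "STATE_OF",
    "STATE_ATTRS",
    "SIX_STATES",
    "fuse_affective_state",
    "summarize_states",
    "aggregate_occurrence",
]

#: (arousal level, valence sign) -> state name.
STATE_OF: dict[tuple[str, str], str] = {
    ("high", "positive"): "excited",
    ("high", "negative"): "tense",
    ("medium", "positive"): "focused",
    ("medium", "negative"): "cautious",
    ("low", "positive"): "calm",
    ("low", "negative"): "bored",
}

#: state name -> (arousal level, valence sign); inverse of STATE_OF.
STATE_ATTRS: dict[str, tuple[str, str]] = {v: k for k, v in STATE_OF.items()}

SIX_STATES: tuple[str, ...] = (
    "excited",
    "tense",
    "focused",
    "cautious",
    "calm",
    "bored",
)


@dataclass(frozen=True)
class AffectiveState:
    """One fused emission: state label plus its source labels."""

    label: str  # one of SIX_STATES or "NA"
    emission_time: float
    source_valence: str | None = None
    source_arousal: str | None = None


def fuse_affective_state(
    valence: ValenceSeries, arousal: ArousalSeries
) -> list[AffectiveState]:
    """Pair each valence emission with the latest arousal at or before it.

    Emits NA when the valence is NA or no arousal emission exists yet
    ("simultaneous" across the 2 s and 1 s grids is resolved as
    most-recent-at-or-before).
    """
    ar = sorted(arousal.emissions, key=lambda e: e.time)
    ar_times = [e.time for e in ar]
    out: list[AffectiveState] = []
    for ve in valence.emissions:
        i = bisect_right(ar_times, ve.time) - 1
        ar_label = ar[i].label if i >= 0 else None
        if ve.label == "NA" or ar_label is None:
            out.append(AffectiveState("NA", ve.time, ve.label, ar_label))
        else:
            state = STATE_OF[(ar_label, VALENCE_TO_SIGN[ve.label])]
            out.append(AffectiveState(state, ve.time, ve.label, ar_label))
    return out


@dataclass
class StateOccurrenceTable:
    """Percentage of non-NA emissions spent in each of the six states.

    Percentages are reported to 2 decimals without renormalization, so
    their sum can differ from 100 by rounding.
    """

    percentages: dict[str, float] = field(default_factory=dict)
    n_total: int = 0
    n_na: int = 0
    empty: bool = False


def summarize_states(states: list[AffectiveState]) -> StateOccurrenceTable:
    """Tally state occurrences, excluding NA from the denominator."""
    labels = [s.label for s in states]
    n_total = len(labels)
    n_na = sum(1 for lab in labels if lab == "NA")
    n = n_total - n_na
    if n == 0:
        return StateOccurrenceTable(
            percentages={s: 0.0 for s in SIX_STATES},
            n_total=n_total,
            n_na=n_na,
            empty=True,
        )
    pct = {s: round(100.0 * labels.count(s) / n, 2) for s in SIX_STATES}
    return StateOccurrenceTable(percentages=pct, n_total=n_total, n_na=n_na)


def aggregate_occurrence(
    table: StateOccurrenceTable,
    arousal_levels: set[str],
    valence_signs: set[str],
) -> float:
    """Sum the table percentages over a (arousal, valence) selector.

    Operates on the rounded table cells, so an all-states selector
    reproduces any rounding artifact of the printed table rather than
    renormalizing to 100.  An empty selector returns 0.
    """
    total = sum(
        table.percentages[state]
        for state, (arousal, sign) in STATE_ATTRS.items()
        if arousal in arousal_levels and sign in valence_signs
    )
    return round(total, 2)
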