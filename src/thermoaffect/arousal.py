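"""Arousal classification from the nose-minus-glabella thermal slope.

Sympathetic activation constricts the peripheral vessels of the nose
tip, cooling it relative to the glabella reference, so the slope of the
difference signal tracks arousal: the more negative the slope, the
stronger the ongoing cooling and the higher the arousal.  Each 8 s
window (advanced by 1 s) is z-normalized and fitted with an ordinary
least-squares line; the slope is thresholded into low / medium / high.

Per-window z-normalization makes the slope scale-free and invariant to
any additive offset of either input series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imaging import ThermalTimeSeries, difference_signal
from .valence import DEFAULT_SUFFICIENCY, Window, WindowSpec, window_signal

__all__ = [
    "ArousalThresholds",
    "ArousalEmission",
    "ArousalSeries",
    "AROUSAL_WINDOW",
    "arousal_slope",
    "calibrate_arousal_thresholds",
    "classify_arousal",
]

AROUSAL_WINDOW = WindowSpec(length=8.0, stride=1.0)

DEFAULT_PERCENTILES = (10.0, 50.0)


@dataclass
class ArousalThresholds:
    """Slope cut points (1/s on the z-normalized signal).

    ``t_high`` < ``t_low``: slopes at or below ``t_high`` classify as
    high arousal (strong cooling), slopes above ``t_low`` as low.
    ``degenerate`` marks a calibration whose slope distribution had no
    spread (both cut points equal).
    """

    t_high: float
    t_low: float
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_high) or not np.isfinite(self.t_low):
            raise ValueError("thresholds must be finite")
        if self.t_high > self.t_low:
            raise ValueError(
                "threshold ordering violated: t_high must not exceed t_low"
            )
        if self.t_high == self.t_low:
            self.degenerate = True

    def save(self, path: str | Path, source: str = "") -> None:
        doc = {
            "t_high": self.t_high,
            "t_low": self.t_low,
            "percentiles": list(self.percentiles),
            "degenerate": self.degenerate,
            "source": source,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ArousalThresholds":
        doc = json.loads(Path(path).read_text())
        return cls(
            t_high=float(doc["t_high"]),
            t_low=float(doc["t_low"]),
            percentiles=tuple(doc.get("percentiles", DEFAULT_PERCENTILES)),
            degenerate=bool(doc.get("degenerate", False)),
        )


def arousal_slope(
    window: Window, sufficiency: float = DEFAULT_SUFFICIENCY
) -> float | None:
    """OLS slope (1/s) of the z-normalized window against time.

    The window is standardized (its own mean subtracted, its own
    standard deviation divided out) before the fit.  A zero-variance
    window returns slope 0; a window with fewer than ``sufficiency``
    present samples returns None (missing emission).
    """
    if window.present_fraction < sufficiency:
        return None
    v = window.filled()
    sd = float(v.std())
    if sd == 0.0:
        return 0.0
    z = (v - v.mean()) / sd
    t = np.arange(len(v)) / window.sampling_rate
    return float(np.polyfit(t, z, 1)[0])


def calibrate_arousal_thresholds(
    difference: ThermalTimeSeries,
    spec: WindowSpec = AROUSAL_WINDOW,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
    min_duration: float = 60.0,
    sufficiency: float = DEFAULT_SUFFICIENCY,
) -> ArousalThresholds:
    """Data-driven thresholds from a baseline difference signal.

    All 8 s / 1 s-stride slopes of the baseline are enumerated and the
    cut points taken as percentiles of that slope distribution
    (defaults: 10th for high, 50th for low).  The published system's
    calibration corpus is unavailable, so the percentiles are
    configurable and persisted with the thresholds.
    """
    if difference.duration < min_duration:
        raise ValueError(
            f"baseline of {difference.duration:.1f} s is shorter than the "
            f"required {min_duration:.0f} s"
        )
    slopes = [
        s
        for w in window_signal(difference, spec)
        if (s := arousal_slope(w, sufficiency)) is not None
    ]
    if not slopes:
        raise ValueError("baseline contains no usable windows")
    p_high, p_low = percentiles
    t_high = float(np.percentile(slopes, p_high))
    t_low = float(np.percentile(slopes, p_low))
    return ArousalThresholds(t_high=t_high, t_low=t_low, percentiles=percentiles)


@dataclass(frozen=True)
class ArousalEmission:
    time: float
    label: str  # low | medium | high
    slope: float
    window_start: float


@dataclass
class ArousalSeries:
    """Arousal labels emitted every second, timestamped at window end."""

    emissions: list[ArousalEmission]

    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.emissions])

    def labels(self) -> list[str]:
        return [e.label for e in self.emissions]

    def __len__(self) -> int:
        return len(self.emissions)


def label_slope(slope: float, thresholds: ArousalThresholds) -> str:
    """Threshold one slope; ties resolve towards the stronger response."""
    if slope <= thresholds.t_high:
        return "high"
    if slope <= thresholds.t_low:
        return "medium"
    return "low"


def classify_arousal(
    nose: ThermalTimeSeries,
    glabella: ThermalTimeSeries,
    thresholds: ArousalThresholds,
    spec: WindowSpec = AROUSAL_WINDOW,
    sufficiency: float = DEFAULT_SUFFICIENCY,
) -> ArousalSeries:
    """Classify arousal over every 8 s window of the difference signal.

    Windows with insufficient data produce no emission.
    """
    if thresholds.t_high > thresholds.t_low:
        raise ValueError("threshold ordering violated")
    diff = difference_signal(nose, glabella)
    emissions = []
    for w in window_signal(diff, spec):
        slope = arousal_slope(w, sufficiency)
        if slope is None:
            continue
        emissions.append(
            ArousalEmission(
                time=w.start_time + spec.length,
                label=label_slope(slope, thresholds),
                slope=slope,
                window_start=w.start_time,
            )
        )
    return ArousalSeries(emissions)
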