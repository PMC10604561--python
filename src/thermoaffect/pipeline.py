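"""Pipeline configuration and end-to-end composition.

:class:`PipelineConfig` houses every numeric constant of the method
(window geometries, spectral bands, segment layout, calibration
percentiles, sufficiency fraction) so that no operation hard-codes
them; the defaults are the published values.  :func:`run_pipeline`
composes the module operations deterministically and can write all
intermediate artifacts together with a manifest carrying the config
hash so that re-runs are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .arousal import (
    ArousalSeries,
    ArousalThresholds,
    calibrate_arousal_thresholds,
    classify_arousal,
)
from .events import (
    QuestionEvent,
    SegmentSpec,
    epoch_valence,
    participant_average,
    segment_test,
)
from .fusion import (
    AffectiveState,
    StateOccurrenceTable,
    fuse_affective_state,
    summarize_states,
)
from .imaging import (
    LandmarkSet,
    PlanarTransform,
    ThermalFrameStack,
    ThermalTimeSeries,
    build_roi_mask,
    difference_signal,
    extract_roi_series,
    project_landmarks,
)
from .valence import ValenceModel, ValenceSeries, WindowSpec, classify_valence

__all__ = [
    "ConfigError",
    "InputError",
    "PipelineConfig",
    "PipelineResult",
    "extract_series_from_frames",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class InputError(ValueError):
    """Invalid or inconsistent input data."""


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with published defaults."""

    valence_window: tuple[float, float] = (20.0, 2.0)  # length, stride (s)
    arousal_window: tuple[float, float] = (8.0, 1.0)
    lf_band: tuple[float, float] = (0.04, 0.15)  # Hz
    hf_band: tuple[float, float] = (0.15, 0.4)
    post_window: float = 10.0  # s after each question
    n_segments: int = 5
    segment_length: float = 2.0
    threshold_percentiles: tuple[float, float] = (10.0, 50.0)
    sufficiency: float = 0.8
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        try:
            self.valence_spec()
            self.arousal_spec()
            self.segment_spec()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        for lo, hi in (self.lf_band, self.hf_band):
            if not 0 <= lo < hi:
                raise ConfigError(f"invalid frequency band ({lo}, {hi})")
        if not 0 < self.sufficiency <= 1:
            raise ConfigError("sufficiency must be in (0, 1]")
        if self.svm_c <= 0:
            raise ConfigError("svm_c must be positive")
        p_hi, p_lo = self.threshold_percentiles
        if not (0 <= p_hi <= 100 and 0 <= p_lo <= 100 and p_hi <= p_lo):
            raise ConfigError("threshold percentiles must satisfy 0 <= high <= low <= 100")

    def valence_spec(self) -> WindowSpec:
        return WindowSpec(*self.valence_window)

    def arousal_spec(self) -> WindowSpec:
        return WindowSpec(*self.arousal_window)

    def segment_spec(self) -> SegmentSpec:
        return SegmentSpec(self.post_window, self.n_segments, self.segment_length)

    def to_dict(self) -> dict:
        return {
            "valence_window": list(self.valence_window),
            "arousal_window": list(self.arousal_window),
            "lf_band": list(self.lf_band),
            "hf_band": list(self.hf_band),
            "post_window": self.post_window,
            "n_segments": self.n_segments,
            "segment_length": self.segment_length,
            "threshold_percentiles": list(self.threshold_percentiles),
            "sufficiency": self.sufficiency,
            "svm_c": self.svm_c,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        for key in (
            "valence_window",
            "arousal_window",
            "lf_band",
            "hf_band",
            "threshold_percentiles",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    valence: ValenceSeries
    arousal: ArousalSeries
    states: list[AffectiveState]
    occurrence: StateOccurrenceTable
    segment_stats: pd.DataFrame | None
    thresholds: ArousalThresholds
    manifest: dict = field(default_factory=dict)


def extract_series_from_frames(
    stack: ThermalFrameStack,
    landmarks_vis: list[LandmarkSet],
    transform: PlanarTransform,
) -> tuple[ThermalTimeSeries, ThermalTimeSeries]:
    """Frames + VIS landmarks + calibration -> (nose, glabella) series."""
    if transform is None:
        raise InputError("a VIS-to-IR calibration is required with frame input")
    if len(landmarks_vis) != len(stack):
        raise InputError("one landmark set per frame is required")
    nose_masks, glab_masks = [], []
    for lm in landmarks_vis:
        lm_ir = project_landmarks(lm, transform, stack.meta)
        nose_masks.append(build_roi_mask(lm_ir, "nose_tip", stack.meta))
        glab_masks.append(build_roi_mask(lm_ir, "glabella", stack.meta))
    return (
        extract_roi_series(stack, nose_masks),
        extract_roi_series(stack, glab_masks),
    )


def run_pipeline(
    nose: ThermalTimeSeries,
    glabella: ThermalTimeSeries,
    config: PipelineConfig,
    model: ValenceModel,
    thresholds: ArousalThresholds | None = None,
    events: list[QuestionEvent] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run valence, arousal, fusion and (optionally) event analysis.

    When ``thresholds`` is None they are calibrated from the
    recording's own difference signal.  When ``events`` are given the
    event-locked segment statistics are computed.  With ``out_dir``
    every artifact is written as CSV/JSON plus a ``manifest.json``
    carrying the config hash; identical inputs and config produce
    byte-identical outputs.
    """
    feature_kwargs = dict(
        lf_band=config.lf_band,
        hf_band=config.hf_band,
        sufficiency=config.sufficiency,
    )
    if thresholds is None:
        diff = difference_signal(nose, glabella)
        thresholds = calibrate_arousal_thresholds(
            diff,
            spec=config.arousal_spec(),
            percentiles=config.threshold_percentiles,
            sufficiency=config.sufficiency,
        )
        logger.info(
            "calibrated arousal thresholds t_high=%.4f t_low=%.4f",
            thresholds.t_high,
            thresholds.t_low,
        )

    valence = classify_valence(nose, model, config.valence_spec(), **feature_kwargs)
    arousal = classify_arousal(
        nose, glabella, thresholds, config.arousal_spec(), config.sufficiency
    )
    states = fuse_affective_state(valence, arousal)
    occurrence = summarize_states(states)

    segment_stats = None
    if events:
        epochs = epoch_valence(valence, events, config.segment_spec())
        fractions = participant_average(epochs)
        segment_stats = segment_test(fractions, config.n_segments)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "seed": config.seed,
        "version": __version__,
        "n_samples": nose.n,
        "n_valence_emissions": len(valence),
        "n_arousal_emissions": len(arousal),
        "n_events": len(events) if events else 0,
        "thresholds": {"t_high": thresholds.t_high, "t_low": thresholds.t_low},
    }
    result = PipelineResult(
        valence, arousal, states, occurrence, segment_stats, thresholds, manifest
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), result, config)
    return result


def _write_outputs(
    out_dir: Path, result: PipelineResult, config: PipelineConfig
) -> None:
    from . import io as taio

    out_dir.mkdir(parents=True, exist_ok=True)
    h = config.hash
    taio.write_valence(out_dir / "valence.csv", result.valence, config_hash=h)
    taio.write_arousal(out_dir / "arousal.csv", result.arousal, config_hash=h)
    taio.write_states(out_dir / "states.csv", result.states, config_hash=h)
    taio.write_occurrence(out_dir / "occurrence.json", result.occurrence, config_hash=h)
    result.thresholds.save(out_dir / "thresholds.json", source=h)
    if result.segment_stats is not None:
        taio.write_segment_stats(
            out_dir / "segment_stats.csv", result.segment_stats, config_hash=h
        )
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
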