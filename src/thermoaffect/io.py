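"""File formats: TIFF frame stacks, CSV series/landmarks/events, JSON
calibration and metadata.

All tabular data go through pandas; frame stacks are multi-page
grayscale TIFF (page order = time order) written via tifffile with a
JSON sidecar holding the recording metadata.  Count images are stored
as 16-bit integers on disk (rounded), while the in-memory pipeline
works in float.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .arousal import ArousalSeries
from .events import QuestionEvent
from .fusion import SIX_STATES, AffectiveState, StateOccurrenceTable
from .imaging import (
    N_LANDMARKS,
    LandmarkSet,
    PlanarTransform,
    RecordingMeta,
    ThermalFrameStack,
    ThermalTimeSeries,
)
from .valence import ValenceSeries

__all__ = [
    "write_frames",
    "read_frames",
    "write_landmarks",
    "read_landmarks",
    "write_calibration",
    "read_calibration",
    "write_series",
    "read_series",
    "write_events",
    "read_events",
    "write_valence",
    "write_arousal",
    "write_states",
    "write_occurrence",
    "write_segment_stats",
]


def _to_csv(path: str | Path, df: pd.DataFrame, header_comment: str | None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_frames(path: str | Path, stack: ThermalFrameStack) -> None:
    """Write a frame stack as multi-page uint16 TIFF plus JSON sidecar."""
    path = Path(path)
    data = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
    meta = {
        "sampling_rate": stack.meta.sampling_rate,
        "ir_shape": list(stack.meta.ir_shape),
        "vis_shape": list(stack.meta.vis_shape),
        "duration": len(stack) / stack.meta.sampling_rate,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_frames(path: str | Path) -> ThermalFrameStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        meta = RecordingMeta(
            sampling_rate=doc["sampling_rate"],
            ir_shape=tuple(doc["ir_shape"]),
            vis_shape=tuple(doc.get("vis_shape", (480, 640))),
            duration=doc.get("duration"),
        )
    else:
        meta = RecordingMeta(ir_shape=frames.shape[1:])
    timestamps = np.arange(len(frames)) / meta.sampling_rate
    return ThermalFrameStack(frames, timestamps, meta)


def write_landmarks(path: str | Path, tracks: list[LandmarkSet]) -> None:
    rows = []
    for lm in tracks:
        for j, (x, y) in enumerate(lm.points):
            rows.append(
                {
                    "frame_index": lm.frame_index,
                    "point_index": j,
                    "x": x,
                    "y": y,
                    "space": lm.space,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    tracks = []
    for frame_index, grp in df.groupby("frame_index", sort=True):
        grp = grp.sort_values("point_index")
        if len(grp) != N_LANDMARKS:
            raise ValueError(
                f"frame {frame_index} has {len(grp)} landmarks, expected {N_LANDMARKS}"
            )
        spaces = grp["space"].unique()
        if len(spaces) != 1:
            raise ValueError(f"frame {frame_index} mixes landmark spaces")
        tracks.append(
            LandmarkSet(
                grp[["x", "y"]].to_numpy(float),
                str(spaces[0]),
                frame_index=int(frame_index),
            )
        )
    return tracks


def write_calibration(path: str | Path, transform: PlanarTransform) -> None:
    Path(path).write_text(
        json.dumps({"matrix": transform.matrix.tolist()}, indent=2)
    )


def read_calibration(path: str | Path) -> PlanarTransform:
    doc = json.loads(Path(path).read_text())
    return PlanarTransform(np.array(doc["matrix"], dtype=float))


def write_series(
    path: str | Path, series: ThermalTimeSeries, config_hash: str | None = None
) -> None:
    _to_csv(
        path,
        pd.DataFrame(
            {
                "t_s": series.timestamps,
                "value_counts": series.values,
                "missing": series.missing.astype(int),
                "roi": series.roi_name,
            }
        ),
        f"config_hash: {config_hash}" if config_hash else None,
    )


def read_series(path: str | Path) -> ThermalTimeSeries:
    df = pd.read_csv(path, comment="#")
    roi = str(df["roi"].iloc[0]) if len(df) else ""
    return ThermalTimeSeries(
        df["t_s"].to_numpy(float),
        df["value_counts"].to_numpy(float),
        df["missing"].to_numpy(bool),
        roi_name=roi,
    )


def write_events(path: str | Path, events: list[QuestionEvent]) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "question_id": e.question_id,
                "onset_t_s": e.onset_time,
            }
            for e in events
        ],
        columns=["participant_id", "question_id", "onset_t_s"],
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[QuestionEvent]:
    df = pd.read_csv(path, comment="#")
    return [
        QuestionEvent(str(r.participant_id), str(r.question_id), float(r.onset_t_s))
        for r in df.itertuples()
    ]


def write_valence(
    path: str | Path, series: ValenceSeries, config_hash: str | None = None
) -> None:
    _to_csv(
        path,
        pd.DataFrame(
            [
                {"emission_t_s": e.time, "window_start_s": e.window_start, "label": e.label}
                for e in series.emissions
            ],
            columns=["emission_t_s", "window_start_s", "label"],
        ),
        f"config_hash: {config_hash}" if config_hash else None,
    )


def write_arousal(
    path: str | Path, series: ArousalSeries, config_hash: str | None = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "emission_t_s": e.time,
                "window_start_s": e.window_start,
                "slope": e.slope,
                "label": e.label,
            }
            for e in series.emissions
        ],
        columns=["emission_t_s", "window_start_s", "slope", "label"],
    )
    _to_csv(path, df, f"config_hash: {config_hash}" if config_hash else None)


def write_states(
    path: str | Path, states: list[AffectiveState], config_hash: str | None = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "emission_t_s": s.emission_time,
                "state": s.label,
                "valence": s.source_valence,
                "arousal": s.source_arousal,
            }
            for s in states
        ],
        columns=["emission_t_s", "state", "valence", "arousal"],
    )
    _to_csv(path, df, f"config_hash: {config_hash}" if config_hash else None)


def write_occurrence(
    path: str | Path, table: StateOccurrenceTable, config_hash: str | None = None
) -> None:
    """Occurrence table as JSON (a CSV twin is written alongside)."""
    path = Path(path)
    doc = {
        "percentages": {s: table.percentages.get(s, 0.0) for s in SIX_STATES},
        "n_total": table.n_total,
        "n_na": table.n_na,
        "empty": table.empty,
    }
    if config_hash:
        doc["config_hash"] = config_hash
    path.write_text(json.dumps(doc, indent=2))
    _to_csv(
        path.with_suffix(".csv"),
        pd.DataFrame(
            [{"state": s, "percent": table.percentages.get(s, 0.0)} for s in SIX_STATES]
        ),
        f"config_hash: {config_hash}" if config_hash else None,
    )


def write_segment_stats(
    path: str | Path, stats: pd.DataFrame, config_hash: str | None = None
) -> None:
    _to_csv(path, stats, f"config_hash: {config_hash}" if config_hash else None)
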