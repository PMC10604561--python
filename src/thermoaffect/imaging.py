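"""VIS-to-IR landmark co-registration, polygonal ROI masks, and ROI-mean
thermal time-series extraction.

The thermal camera records 16-bit count images (default 320x256 px at
10 Hz) while a visible-light camera provides 68-point facial landmark
tracks.  A planar homography, fitted once per recording from calibration
correspondences, projects the VIS landmarks into the IR frame.  Two
regions of interest are cut out as landmark polygons -- the glabella
(thermal reference, between the eyebrows) and the nose tip (highly
sensitive to sympathetic vasoconstriction) -- and each ROI is collapsed
to a 1-D signal by averaging the counts inside its mask on every frame.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, pixel
centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationError",
    "RecordingMeta",
    "LandmarkSet",
    "PlanarTransform",
    "ROIMask",
    "ThermalFrameStack",
    "ThermalTimeSeries",
    "ROI_LANDMARK_INDICES",
    "N_LANDMARKS",
    "fit_vis_to_ir_transform",
    "project_landmarks",
    "polygon_mask",
    "build_roi_mask",
    "extract_roi_series",
    "difference_signal",
]

N_LANDMARKS = 68

#: Which of the 68 standard annotation points bound each ROI polygon.
#: Glabella: triangle spanned by the inner brow ends (21, 22) and the
#: top of the nose bridge (27).  Nose tip: quadrilateral around the
#: nasal tip (30), the nostril corners (31, 35) and the subnasale (33).
#: Both are configurable via ``build_roi_mask(indices=...)``.
ROI_LANDMARK_INDICES: dict[str, tuple[int, ...]] = {
    "glabella": (21, 22, 27),
    "nose_tip": (30, 35, 33, 31),
}


class CalibrationError(ValueError):
    """Raised when a VIS-to-IR calibration cannot be fitted."""


@dataclass(frozen=True)
class RecordingMeta:
    """Acquisition geometry of one recording.

    Parameters
    ----------
    sampling_rate : float
        Frame rate in Hz.  Default 10 Hz.
    ir_shape, vis_shape : tuple of int
        (rows, cols) of the IR and VIS sensors.  Default IR 256 x 320.
    duration : float, optional
        Recording length in seconds, if known.
    """

    sampling_rate: float = 10.0
    ir_shape: tuple[int, int] = (256, 320)
    vis_shape: tuple[int, int] = (480, 640)
    duration: float | None = None

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        for shape in (self.ir_shape, self.vis_shape):
            if len(shape) != 2 or any(s <= 0 for s in shape):
                raise ValueError(f"invalid image shape {shape!r}")
        if self.duration is not None and self.duration < 0:
            raise ValueError("duration must be non-negative")


@dataclass
class LandmarkSet:
    """68 facial landmark coordinates in a named image space.

    ``points`` is a (68, 2) float array of (x, y) pairs; ``space`` is
    ``"VIS"`` or ``"IR"``.  ``out_of_frame`` marks points projected
    outside the frame bounds (set by :func:`project_landmarks`).
    """

    points: np.ndarray
    space: str
    frame_index: int = 0
    out_of_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} (x, y) landmark pairs, "
                f"got array of shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.space not in ("VIS", "IR"):
            raise ValueError(f"unknown landmark space {self.space!r}")
        if self.out_of_frame is not None:
            self.out_of_frame = np.asarray(self.out_of_frame, dtype=bool)
            if self.out_of_frame.shape != (N_LANDMARKS,):
                raise ValueError("out_of_frame must have one flag per point")


@dataclass
class PlanarTransform:
    """3x3 homogeneous planar transform mapping VIS to IR coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if abs(self.matrix[2, 2]) < 1e-12:
            raise ValueError("bottom-right entry must be non-zero")
        det = np.linalg.det(self.matrix)
        if abs(det) < 1e-12:
            raise ValueError("transform matrix must be invertible")
        self.matrix = self.matrix / self.matrix[2, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the homography to an (n, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float)
        homog = np.column_stack([pts, np.ones(len(pts))])
        proj = homog @ self.matrix.T
        return proj[:, :2] / proj[:, 2:3]

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(np.linalg.inv(self.matrix))


@dataclass
class ROIMask:
    """Polygonal ROI and its rasterized boolean mask on the IR grid."""

    name: str
    polygon: np.ndarray
    mask: np.ndarray
    frame_index: int = 0
    degraded: bool = False

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def usable(self) -> bool:
        return not (self.degraded or self.empty)


@dataclass
class ThermalFrameStack:
    """Time-ordered stack of 2-D thermal count images."""

    frames: np.ndarray
    timestamps: np.ndarray
    meta: RecordingMeta

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ThermalTimeSeries:
    """Regularly sampled 1-D ROI-mean signal in sensor counts.

    Missing samples (empty/degraded masks, tracking dropouts) carry
    ``missing=True`` and a NaN value; downstream windows decide their
    own sufficiency.
    """

    timestamps: np.ndarray
    values: np.ndarray
    missing: np.ndarray | None = None
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise ValueError("timestamps and values must be matching 1-D arrays")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing flags must match values")
        if len(self.timestamps) >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be strictly increasing and uniform")
        present = ~self.missing
        if not np.all(np.isfinite(self.values[present])):
            raise ValueError("values must be finite where not missing")
        self.values = self.values.copy()
        self.values[self.missing] = np.nan

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def sampling_rate(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("sampling rate undefined for series shorter than 2")
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])

    @property
    def duration(self) -> float:
        """Series length in seconds (n samples at 1/fs spacing)."""
        return self.n / self.sampling_rate


# ---------------------------------------------------------------------------
# calibration and projection
# ---------------------------------------------------------------------------

def fit_vis_to_ir_transform(
    vis_points: np.ndarray, ir_points: np.ndarray
) -> PlanarTransform:
    """Fit the VIS-to-IR homography from point correspondences.

    Solves the direct linear transform in inhomogeneous form (bottom-right
    entry fixed to 1) by linear least squares, which is exact for four
    correspondences in general position and the algebraic least-squares
    fit for more.

    Parameters
    ----------
    vis_points, ir_points : array-like, shape (n, 2)
        Paired (x, y) coordinates of the same physical points seen by
        the two cameras; n >= 4, not all collinear.

    Raises
    ------
    CalibrationError
        For fewer than 4 pairs or a degenerate configuration.
    """
    src = np.asarray(vis_points, dtype=float)
    dst = np.asarray(ir_points, dtype=float)
    if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
        raise CalibrationError("correspondences must be matching (n, 2) arrays")
    n = src.shape[0]
    if n < 4:
        raise CalibrationError("at least 4 correspondence pairs are required")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise CalibrationError("correspondence coordinates must be finite")

    x, y = src[:, 0], src[:, 1]
    u, v = dst[:, 0], dst[:, 1]
    a = np.zeros((2 * n, 8))
    b = np.zeros(2 * n)
    a[0::2, 0] = x
    a[0::2, 1] = y
    a[0::2, 2] = 1.0
    a[0::2, 6] = -u * x
    a[0::2, 7] = -u * y
    b[0::2] = u
    a[1::2, 3] = x
    a[1::2, 4] = y
    a[1::2, 5] = 1.0
    a[1::2, 6] = -v * x
    a[1::2, 7] = -v * y
    b[1::2] = v

    if np.linalg.matrix_rank(a) < 8:
        raise CalibrationError(
            "degenerate correspondence configuration (collinear points?)"
        )
    h, *_ = np.linalg.lstsq(a, b, rcond=None)
    matrix = np.append(h, 1.0).reshape(3, 3)
    try:
        return PlanarTransform(matrix)
    except ValueError as exc:  # singular result
        raise CalibrationError(str(exc)) from exc


def project_landmarks(
    landmarks: LandmarkSet,
    transform: PlanarTransform,
    meta: RecordingMeta | None = None,
) -> LandmarkSet:
    """Project a VIS-space landmark set into the IR domain.

    Points mapping outside the IR frame are retained but flagged
    ``out_of_frame`` when ``meta`` is given.
    """
    if landmarks.space != "VIS":
        raise ValueError("landmarks must be in VIS space to project into IR")
    pts = transform.apply(landmarks.points)
    oof = None
    if meta is not None:
        rows, cols = meta.ir_shape
        oof = (
            (pts[:, 0] < 0)
            | (pts[:, 0] > cols - 1)
            | (pts[:, 1] < 0)
            | (pts[:, 1] > rows - 1)
        )
    return LandmarkSet(pts, "IR", landmarks.frame_index, oof)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def polygon_mask(
    polygon: np.ndarray, shape: tuple[int, int], eps: float = 1e-9
) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by the even-odd rule.

    A pixel is inside when its center (integer coordinates) has odd
    crossing number against the polygon boundary; centers lying exactly
    on an edge count as inside.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (n >= 3, 2) vertex array")
    rows, cols = shape
    mask = np.zeros((rows, cols), dtype=bool)

    x0 = max(0, int(np.floor(poly[:, 0].min())))
    x1 = min(cols - 1, int(np.ceil(poly[:, 0].max())))
    y0 = max(0, int(np.floor(poly[:, 1].min())))
    y1 = min(rows - 1, int(np.ceil(poly[:, 1].max())))
    if x1 < x0 or y1 < y0:
        return mask

    gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    px = gx.ravel().astype(float)
    py = gy.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)

    verts = np.vstack([poly, poly[:1]])
    for (xa, ya), (xb, yb) in zip(verts[:-1], verts[1:]):
        # even-odd ray crossing (ray towards +x)
        crosses = (ya > py) != (yb > py)
        if np.any(crosses):
            xin = xa + (py[crosses] - ya) * (xb - xa) / (yb - ya)
            hit = np.zeros(px.shape, dtype=bool)
            hit[crosses] = px[crosses] < xin
            inside ^= hit
        # boundary inclusion: center exactly on the segment
        seg_len = max(1.0, float(np.hypot(xb - xa, yb - ya)))
        cross2 = (xb - xa) * (py - ya) - (yb - ya) * (px - xa)
        within = (
            (px >= min(xa, xb) - eps)
            & (px <= max(xa, xb) + eps)
            & (py >= min(ya, yb) - eps)
            & (py <= max(ya, yb) + eps)
        )
        on_edge |= within & (np.abs(cross2) <= eps * seg_len)

    mask[y0 : y1 + 1, x0 : x1 + 1] = (inside | on_edge).reshape(gy.shape)
    return mask


def build_roi_mask(
    landmarks_ir: LandmarkSet,
    roi_name: str,
    meta: RecordingMeta,
    indices: tuple[int, ...] | None = None,
    margin: float = 2.0,
) -> ROIMask:
    """Assemble an ROI polygon from landmark indices and rasterize it.

    The mask is flagged ``degraded`` when any required vertex lies
    outside the IR frame by more than ``margin`` pixels; an empty mask
    is allowed and reported through :attr:`ROIMask.empty`.
    """
    if landmarks_ir.space != "IR":
        raise ValueError("ROI masks are built from IR-space landmarks")
    if indices is None:
        if roi_name not in ROI_LANDMARK_INDICES:
            raise ValueError(f"unknown ROI {roi_name!r} and no indices given")
        indices = ROI_LANDMARK_INDICES[roi_name]
    if len(indices) < 3:
        raise ValueError("an ROI polygon needs at least 3 vertices")
    poly = landmarks_ir.points[list(indices)]
    rows, cols = meta.ir_shape
    degraded = bool(
        np.any(
            (poly[:, 0] < -margin)
            | (poly[:, 0] > cols - 1 + margin)
            | (poly[:, 1] < -margin)
            | (poly[:, 1] > rows - 1 + margin)
        )
    )
    mask = polygon_mask(poly, meta.ir_shape)
    return ROIMask(roi_name, poly, mask, landmarks_ir.frame_index, degraded)


# ---------------------------------------------------------------------------
# series extraction
# ---------------------------------------------------------------------------

def extract_roi_series(
    stack: ThermalFrameStack, masks: list[ROIMask]
) -> ThermalTimeSeries:
    """Average the counts inside the ROI mask on every frame.

    Frames whose mask is empty or degraded yield missing samples; the
    output always has one sample per frame.
    """
    if len(masks) != len(stack):
        raise ValueError("one mask per frame is required")
    names = {m.name for m in masks}
    if len(names) > 1:
        raise ValueError(f"masks mix ROI names: {sorted(names)}")
    n = len(stack)
    values = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    for i, (frame, m) in enumerate(zip(stack.frames, masks)):
        if frame.shape != m.mask.shape:
            raise ValueError(
                f"frame {i} shape {frame.shape} != mask shape {m.mask.shape}"
            )
        if not m.usable:
            missing[i] = True
        else:
            values[i] = float(frame[m.mask].mean(dtype=np.float64))
    return ThermalTimeSeries(
        stack.timestamps, values, missing, roi_name=next(iter(names))
    )


def difference_signal(
    nose: ThermalTimeSeries, glabella: ThermalTimeSeries
) -> ThermalTimeSeries:
    """Nose-tip minus glabella signal; missing where either input is."""
    if nose.n != glabella.n or not np.allclose(
        nose.timestamps, glabella.timestamps, rtol=0, atol=1e-9
    ):
        raise ValueError("nose and glabella series must share their timestamps")
    missing = nose.missing | glabella.missing
    values = nose.values - glabella.values
    return ThermalTimeSeries(
        nose.timestamps.copy(), values, missing, roi_name="nose_minus_glabella"
    )
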