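"""Autonomic valence classification from the nose-tip thermal signal.

The signal is cut into overlapping 20 s windows advanced by 2 s.  Each
window is summarized by eleven features (local means, Shannon entropy,
percentile ratio, first- and second-order polynomial fits, and the
LF/HF spectral power ratio) and classified by a linear soft-margin SVM
into ``sympathetic`` (negative valence) or ``parasympathetic``
(positive valence); windows with insufficient data emit ``NA``.  One
label is emitted every 2 s, timestamped at the window end, so each
label describes the 20 s leading up to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import periodogram

from .imaging import ThermalTimeSeries

__all__ = [
    "WindowSpec",
    "Window",
    "ValenceFeatureVector",
    "ValenceModel",
    "ValenceEmission",
    "ValenceSeries",
    "FEATURE_NAMES",
    "VALENCE_TO_SIGN",
    "LF_BAND",
    "HF_BAND",
    "window_signal",
    "compute_valence_features",
    "train_valence_model",
    "classify_valence",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mean_third1",
    "mean_third3",
    "diff_mean_t1_t2",
    "entropy",
    "pct_ratio_95_5",
    "lin_slope_t2t3",
    "lin_intercept_t2t3",
    "quad_a2",
    "quad_a1",
    "quad_a0",
    "band_power_ratio",
)

#: Valence sign carried by each autonomic branch.
VALENCE_TO_SIGN: dict[str, str] = {
    "sympathetic": "negative",
    "parasympathetic": "positive",
}

#: Low- and high-frequency bands (Hz) for the spectral power ratio.
LF_BAND: tuple[float, float] = (0.04, 0.15)
HF_BAND: tuple[float, float] = (0.15, 0.4)

#: Minimum fraction of present samples for a window to be classified.
DEFAULT_SUFFICIENCY = 0.8


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length and stride in seconds."""

    length: float = 20.0
    stride: float = 2.0

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.stride > 0):
            raise ValueError("window length and stride must be positive")


@dataclass
class Window:
    """One signal window: raw samples (NaN where missing) plus timing."""

    start_time: float
    values: np.ndarray
    sampling_rate: float

    @property
    def present_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.values)))

    def filled(self) -> np.ndarray:
        """Samples with gaps filled by linear interpolation.

        Interior gaps are interpolated between neighbours; leading and
        trailing gaps take the nearest present value.
        """
        v = self.values
        present = np.isfinite(v)
        if present.all():
            return v.astype(float, copy=True)
        if not present.any():
            raise ValueError("cannot fill an all-missing window")
        idx = np.arange(len(v), dtype=float)
        return np.interp(idx, idx[present], v[present])


def window_signal(series: ThermalTimeSeries, spec: WindowSpec) -> list[Window]:
    """Cut a series into overlapping windows starting at 0, stride, ...

    For a series of duration T >= length the window count is
    floor((T - length) / stride) + 1; shorter series yield no windows.
    """
    fs = series.sampling_rate if series.n >= 2 else 0.0
    if fs <= 0:
        return []
    n_len = int(round(spec.length * fs))
    n_stride = int(round(spec.stride * fs))
    if n_len <= 0 or n_stride <= 0:
        raise ValueError("window shorter than one sample at this rate")
    n = series.n
    if n < n_len:
        return []
    windows = []
    for k in range((n - n_len) // n_stride + 1):
        i0 = k * n_stride
        windows.append(
            Window(
                start_time=float(series.timestamps[i0]),
                values=series.values[i0 : i0 + n_len].copy(),
                sampling_rate=fs,
            )
        )
    return windows


@dataclass
class ValenceFeatureVector:
    """The eleven window features, with a validity flag.

    Thirds are contiguous equal splits of the window (the final third
    absorbs remainder samples).  Entropy is the Shannon entropy (nats)
    of a 16-bin histogram over the window's own range.  Polynomial fits
    are ordinary least squares against window-relative time in seconds.
    """

    mean_third1: float
    mean_third3: float
    diff_mean_t1_t2: float
    entropy: float
    pct_ratio_95_5: float
    lin_slope_t2t3: float
    lin_intercept_t2t3: float
    quad_a2: float
    quad_a1: float
    quad_a0: float
    band_power_ratio: float
    valid: bool = True
    reason: str = ""

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _invalid(reason: str) -> ValenceFeatureVector:
    nan = float("nan")
    return ValenceFeatureVector(
        nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan,
        valid=False, reason=reason,
    )


def shannon_entropy(values: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (nats) of a histogram over the sample range.

    A constant window has zero entropy.  The fixed bin count makes the
    estimate invariant to shifting or (positively) scaling the data.
    """
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def compute_valence_features(
    window: Window,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    sufficiency: float = DEFAULT_SUFFICIENCY,
    n_bins: int = 16,
    nfft: int = 1024,
) -> ValenceFeatureVector:
    """Compute the feature vector of one window.

    Returns an invalid (NaN) vector when fewer than ``sufficiency`` of
    the samples are present or when the high-frequency band carries no
    power; invalid vectors classify as NA downstream.

    The native spectral resolution of a 20 s window (0.05 Hz) is too
    coarse for the 0.04-0.15 Hz band, so the window is detrended (OLS
    line removed) and zero-padded to ``nfft`` points before the
    one-sided periodogram is integrated over each band by trapezoid.
    """
    if window.present_fraction < sufficiency:
        return _invalid("insufficient present samples")
    v = window.filled()
    n = len(v)
    fs = window.sampling_rate
    t = np.arange(n) / fs

    third = n // 3
    first, second, last = v[:third], v[third : 2 * third], v[2 * third :]
    mean1 = float(first.mean())
    mean2 = float(second.mean())
    mean3 = float(last.mean())

    entropy = shannon_entropy(v, n_bins=n_bins)
    p5, p95 = np.percentile(v, [5, 95])
    pct_ratio = float(p95 / p5) if p5 != 0 else float("inf")

    lin_slope, lin_intercept = np.polyfit(t[third:], v[third:], 1)
    quad_a2, quad_a1, quad_a0 = np.polyfit(t, v, 2)

    trend = np.polyval(np.polyfit(t, v, 1), t)
    residual = v - trend
    # a window that is flat (to machine precision) after detrending has a
    # degenerate spectrum: no genuine power in either band
    if np.max(np.abs(residual)) <= 1e-9 * max(1.0, float(np.max(np.abs(v)))):
        residual = np.zeros_like(residual)
    freqs, psd = periodogram(
        residual, fs=fs, nfft=nfft, window="boxcar", detrend=False
    )
    lf_mask = (freqs >= lf_band[0]) & (freqs <= lf_band[1])
    hf_mask = (freqs >= hf_band[0]) & (freqs <= hf_band[1])
    lf_power = float(np.trapezoid(psd[lf_mask], freqs[lf_mask]))
    hf_power = float(np.trapezoid(psd[hf_mask], freqs[hf_mask]))

    fv = ValenceFeatureVector(
        mean_third1=mean1,
        mean_third3=mean3,
        diff_mean_t1_t2=mean1 - mean2,
        entropy=entropy,
        pct_ratio_95_5=pct_ratio,
        lin_slope_t2t3=float(lin_slope),
        lin_intercept_t2t3=float(lin_intercept),
        quad_a2=float(quad_a2),
        quad_a1=float(quad_a1),
        quad_a0=float(quad_a0),
        band_power_ratio=lf_power / hf_power if hf_power > 0 else float("nan"),
    )
    if hf_power <= 0:
        fv.valid = False
        fv.reason = "zero high-frequency power"
    elif not np.all(np.isfinite(fv.to_array())):
        fv.valid = False
        fv.reason = "non-finite feature value"
    return fv


@dataclass
class ValenceModel:
    """Linear maximum-margin valence classifier.

    The decision value is ``w . (x - center) / scale + b``; positive
    margins map to ``parasympathetic`` (positive valence), negative to
    ``sympathetic``.
    """

    weights: np.ndarray
    bias: float
    center: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        k = len(self.feature_names)
        for name, arr in (
            ("weights", self.weights),
            ("center", self.center),
            ("scale", self.scale),
        ):
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per feature")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")

    def decision_value(self, features: np.ndarray) -> float:
        x = np.asarray(features, dtype=float)
        if x.shape != self.weights.shape:
            raise ValueError(
                f"feature vector of length {x.shape} does not match model "
                f"dimension {self.weights.shape}"
            )
        return float(((x - self.center) / self.scale) @ self.weights + self.bias)

    def predict(self, features: np.ndarray) -> str:
        return (
            "parasympathetic" if self.decision_value(features) >= 0 else "sympathetic"
        )

    def save(self, path: str | Path) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "feature_names": list(self.feature_names),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ValenceModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(doc["weights"]),
            bias=float(doc["bias"]),
            center=np.array(doc["center"]),
            scale=np.array(doc["scale"]),
            feature_names=tuple(doc["feature_names"]),
            meta=doc.get("meta", {}),
        )


def train_valence_model(
    features: list[ValenceFeatureVector],
    labels: list[str],
    c: float = 1.0,
) -> ValenceModel:
    """Train the linear soft-margin SVM on standardized features.

    Requires at least two examples of each class; training is
    deterministic given its inputs.
    """
    from sklearn.svm import SVC

    if len(features) != len(labels):
        raise ValueError("one label per feature vector required")
    classes = set(labels)
    if not classes <= {"sympathetic", "parasympathetic"}:
        raise ValueError(f"unknown labels: {sorted(classes - set(VALENCE_TO_SIGN))}")
    if len(classes) < 2:
        raise ValueError("training needs examples of both classes")
    y = np.array([1 if lab == "parasympathetic" else -1 for lab in labels])
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("training needs at least 2 examples per class")
    x = np.array([fv.to_array() for fv in features])
    if not np.all(np.isfinite(x)):
        raise ValueError("training features must all be valid (finite)")

    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - center) / scale
    clf = SVC(kernel="linear", C=c)
    clf.fit(z, y)
    # classes_ is sorted [-1, 1]: positive decision values mean class +1,
    # i.e. parasympathetic, matching ValenceModel's convention.
    return ValenceModel(
        weights=clf.coef_.ravel(),
        bias=float(clf.intercept_[0]),
        center=center,
        scale=scale,
        meta={"C": c, "n_train": int(len(y)), "n_sv": int(clf.n_support_.sum())},
    )


@dataclass(frozen=True)
class ValenceEmission:
    time: float
    label: str  # sympathetic | parasympathetic | NA
    window_start: float


@dataclass
class ValenceSeries:
    """Valence labels emitted every stride, timestamped at window end."""

    emissions: list[ValenceEmission]

    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.emissions])

    def labels(self) -> list[str]:
        return [e.label for e in self.emissions]

    def __len__(self) -> int:
        return len(self.emissions)


def classify_valence(
    series: ThermalTimeSeries,
    model: ValenceModel,
    spec: WindowSpec | None = None,
    **feature_kwargs,
) -> ValenceSeries:
    """Classify every window of a nose-tip series.

    Emits one label per window at the window-end time; windows whose
    feature vector is invalid emit NA.
    """
    spec = spec or WindowSpec()
    emissions = []
    for w in window_signal(series, spec):
        fv = compute_valence_features(w, **feature_kwargs)
        label = model.predict(fv.to_array()) if fv.valid else "NA"
        emissions.append(ValenceEmission(w.start_time + spec.length, label, w.start_time))
    return ValenceSeries(emissions)
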