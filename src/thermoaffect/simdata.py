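"""Synthetic thermal recordings with known autonomic ground truth.

No recordings are distributed with the published system, so every
pipeline stage is exercised on simulated data.  The generative model:

* glabella = baseline + slow sinusoidal drift + Gaussian sensor noise;
* nose tip = the glabella's deterministic part + a cumulative autonomic
  offset + independent noise.  The offset falls at the sympathetic
  cooling rate during sympathetic episodes (vasoconstriction), rises at
  the recovery rate during parasympathetic episodes (rewarming), and
  holds otherwise;
* each question onset triggers a configurable post-question episode
  (default: a parasympathetic rebound 4 s after the question, 2 s long,
  mirroring the direction of the empirical response pattern).

Ground truth is fully deterministic given the configuration: the
per-sample latent state, the majority-state label of every 20 s valence
window, the noiseless-slope arousal label of every 8 s window, and the
latent state sampled just before each 2 s emission (the stream an ideal
zero-lag valence classifier would produce).

The default episode amplitude (0.25 counts/s, i.e. 5 counts across a
20 s analysis window) against 0.5 counts of sensor noise defines the
reference signal-to-noise condition used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arousal import ArousalThresholds, label_slope
from .imaging import (
    N_LANDMARKS,
    LandmarkSet,
    PlanarTransform,
    RecordingMeta,
    ThermalFrameStack,
    ThermalTimeSeries,
)
from .valence import ValenceEmission, ValenceSeries, Window, WindowSpec

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedFrames",
    "simulate_recording",
    "simulate_frames",
    "simulate_training_windows",
    "training_features",
    "train_default_model",
    "default_episode_schedule",
]

STATES = ("neutral", "sympathetic", "parasympathetic")

#: Fixed cut points applied to the noiseless z-normalized slope to
#: define ground-truth arousal labels.  A clean monotone 8 s ramp has
#: |z-slope| ~ 0.43 1/s and a flat window 0, so +-0.2 separates the
#: three regimes with margin.
ORACLE_THRESHOLDS = ArousalThresholds(t_high=-0.2, t_low=0.2)


def default_episode_schedule(duration: float) -> list[tuple[float, float, str]]:
    """Alternating 30 s sympathetic/parasympathetic episodes.

    Episodes start after a 30 s neutral baseline and are separated by
    10 s neutral gaps, matching the tens-of-seconds time scale of
    nasal thermal responses.
    """
    schedule = []
    start, state = 30.0, "sympathetic"
    while start + 30.0 <= duration:
        schedule.append((start, start + 30.0, state))
        state = "parasympathetic" if state == "sympathetic" else "sympathetic"
        start += 40.0
    return schedule


@dataclass
class SimConfig:
    """Generative parameters of one synthetic recording.

    All rates are in counts per second; the seed is mandatory and fully
    determines every stochastic draw.
    """

    seed: int
    duration: float = 300.0
    sampling_rate: float = 10.0
    baseline_level: float = 7000.0
    drift_amplitude: float = 2.0
    drift_period: float = 120.0
    noise_sd: float = 0.5
    sympathetic_cooling_rate: float = 0.25
    recovery_rate: float = 0.25
    episode_schedule: list[tuple[float, float, str]] | None = None
    question_onsets: tuple[float, ...] = ()
    post_question_response: tuple[float, float, str] = (4.0, 2.0, "parasympathetic")
    participant_id: str = "sim"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("a seed is mandatory")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sympathetic_cooling_rate < 0 or self.recovery_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.episode_schedule is None:
            self.episode_schedule = default_episode_schedule(self.duration)
        for start, end, state in self.episode_schedule:
            if not (0 <= start < end <= self.duration):
                raise ValueError(f"episode ({start}, {end}) outside the recording")
            if state not in STATES:
                raise ValueError(f"unknown episode state {state!r}")
        latency, resp_dur, resp_state = self.post_question_response
        if latency < 0 or resp_dur <= 0 or resp_state not in STATES:
            raise ValueError("invalid post-question response")
        for q in self.question_onsets:
            if not 0 <= q <= self.duration:
                raise ValueError(f"question onset {q} outside the recording")


@dataclass
class GroundTruth:
    """Deterministic latent labels of a simulated recording."""

    sample_state: np.ndarray  # latent state name per sample
    valence_windows: list[tuple[float, str]]  # (window start, majority state)
    arousal_windows: list[tuple[float, str]]  # (window start, noiseless label)
    emission_states: list[tuple[float, str]]  # (emission time, state just before)
    arousal_thresholds: ArousalThresholds = field(
        default_factory=lambda: ORACLE_THRESHOLDS
    )


def _latent_states(config: SimConfig, n: int) -> np.ndarray:
    fs = config.sampling_rate
    t = np.arange(n) / fs
    state = np.full(n, "neutral", dtype=object)
    for start, end, s in config.episode_schedule:
        state[(t >= start) & (t < end)] = s
    latency, resp_dur, resp_state = config.post_question_response
    for q in config.question_onsets:
        a, b = q + latency, q + latency + resp_dur
        state[(t >= a) & (t < b)] = resp_state
    return state


def _majority(states: np.ndarray) -> str:
    # deterministic tie-break: sympathetic > parasympathetic > neutral
    order = ("sympathetic", "parasympathetic", "neutral")
    counts = {s: int(np.sum(states == s)) for s in order}
    return max(order, key=lambda s: counts[s])


def _window_starts(n: int, fs: float, spec: WindowSpec) -> list[int]:
    n_len = int(round(spec.length * fs))
    n_stride = int(round(spec.stride * fs))
    if n < n_len:
        return []
    return [k * n_stride for k in range((n - n_len) // n_stride + 1)]


def simulate_recording(
    config: SimConfig,
) -> tuple[ThermalTimeSeries, ThermalTimeSeries, GroundTruth, list]:
    """Generate one recording: nose and glabella series plus ground truth.

    Returns ``(nose, glabella, ground_truth, events)`` where ``events``
    is the list of :class:`~thermoaffect.events.QuestionEvent` derived
    from the configured question onsets.  Bit-for-bit reproducible for
    a given configuration.
    """
    from .events import QuestionEvent

    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    state = _latent_states(config, n)
    increment = np.zeros(n)
    increment[state == "sympathetic"] = -config.sympathetic_cooling_rate * dt
    increment[state == "parasympathetic"] = config.recovery_rate * dt
    offset = np.cumsum(increment)

    drift = config.drift_amplitude * np.sin(2 * np.pi * t / config.drift_period)
    glabella_det = config.baseline_level + drift
    glabella_vals = glabella_det + rng.normal(0.0, config.noise_sd, n)
    nose_vals = glabella_det + offset + rng.normal(0.0, config.noise_sd, n)

    nose = ThermalTimeSeries(t, nose_vals, np.zeros(n, bool), roi_name="nose_tip")
    glabella = ThermalTimeSeries(
        t, glabella_vals, np.zeros(n, bool), roi_name="glabella"
    )

    # ground truth ---------------------------------------------------------
    valence_spec = WindowSpec(20.0, 2.0)
    arousal_spec = WindowSpec(8.0, 1.0)
    n_val = int(round(valence_spec.length * fs))
    n_ar = int(round(arousal_spec.length * fs))

    valence_windows = [
        (t[i0], _majority(state[i0 : i0 + n_val]))
        for i0 in _window_starts(n, fs, valence_spec)
    ]
    # Ground-truth arousal: the expected value of the window's z-normalized
    # slope under the generative model -- the raw noiseless slope of the
    # difference signal divided by the total window standard deviation
    # (deterministic spread plus the 2*sigma^2 variance the two independent
    # noise draws add to the difference).  With noise_sd = 0 this is the
    # plain z-normalized slope of the noiseless signal.
    noise_var = 2.0 * config.noise_sd**2
    arousal_windows = []
    for i0 in _window_starts(n, fs, arousal_spec):
        seg = offset[i0 : i0 + n_ar]
        sd = float(np.sqrt(seg.var() + noise_var))
        slope = (
            0.0
            if sd == 0
            else float(np.polyfit(np.arange(n_ar) / fs, (seg - seg.mean()) / sd, 1)[0])
        )
        arousal_windows.append((t[i0], label_slope(slope, ORACLE_THRESHOLDS)))

    # idealized zero-lag emission stream: latent state of the sample just
    # before each 2 s emission instant
    emission_states = []
    for i0 in _window_starts(n, fs, valence_spec):
        i_emit = i0 + n_val  # first sample index at/after the emission time
        emission_states.append((t[i0] + valence_spec.length, str(state[i_emit - 1])))

    truth = GroundTruth(
        sample_state=state,
        valence_windows=valence_windows,
        arousal_windows=arousal_windows,
        emission_states=emission_states,
    )
    events = [
        QuestionEvent(config.participant_id, f"q{i:02d}", float(q))
        for i, q in enumerate(config.question_onsets)
    ]
    return nose, glabella, truth, events


def ideal_valence_series(
    truth: GroundTruth, window_length: float = 20.0
) -> ValenceSeries:
    """The valence stream an ideal zero-lag classifier would emit.

    Each 2 s emission carries the latent autonomic state just before
    the emission instant; neutral periods, which carry no valence
    information, emit NA.
    """
    return ValenceSeries(
        [
            ValenceEmission(t, s if s != "neutral" else "NA", t - window_length)
            for t, s in truth.emission_states
        ]
    )


# ---------------------------------------------------------------------------
# frame-stack simulation (exercises the imaging path end to end)
# ---------------------------------------------------------------------------

GLABELLA_PATCH = (slice(60, 82), slice(140, 182))  # rows, cols
NOSE_PATCH = (slice(150, 172), slice(140, 182))

#: VIS -> IR transform used by the frame simulator (half-scale + shift).
DEFAULT_VIS_TO_IR = np.array([[0.5, 0.0, 10.0], [0.0, 0.5, 20.0], [0.0, 0.0, 1.0]])


def _template_landmarks_ir() -> np.ndarray:
    """68 IR-space landmark positions for the synthetic face.

    Only the ROI vertices matter to the pipeline: the glabella triangle
    (21, 22, 27) sits inside the glabella patch and the nose-tip
    quadrilateral (30, 31, 33, 35) inside the nose patch.  The
    remaining points are placed on a face-outline ellipse.
    """
    pts = np.zeros((N_LANDMARKS, 2))
    angles = np.linspace(0.0, 2 * np.pi, N_LANDMARKS, endpoint=False)
    pts[:, 0] = 160 + 70 * np.cos(angles)
    pts[:, 1] = 118 + 95 * np.sin(angles)
    pts[21] = (148.0, 66.0)
    pts[22] = (172.0, 66.0)
    pts[27] = (160.0, 78.0)
    pts[30] = (160.0, 153.0)
    pts[35] = (172.0, 161.0)
    pts[33] = (160.0, 169.0)
    pts[31] = (148.0, 161.0)
    return pts


@dataclass
class SimulatedFrames:
    """A simulated IR recording with everything the imaging path needs."""

    stack: ThermalFrameStack
    landmarks_vis: list[LandmarkSet]
    transform: PlanarTransform
    nose: ThermalTimeSeries
    glabella: ThermalTimeSeries
    ground_truth: GroundTruth
    events: list


def simulate_frames(
    config: SimConfig,
    meta: RecordingMeta | None = None,
    jitter_sd: float = 0.0,
    glabella_patch: tuple[slice, slice] = GLABELLA_PATCH,
    nose_patch: tuple[slice, slice] = NOSE_PATCH,
) -> SimulatedFrames:
    """Render the simulated series into IR frames with landmark tracks.

    Each frame holds two flat patches whose pixel value equals the
    simulated glabella and nose series at that frame, over a noisy
    background; ROI extraction therefore recovers the series exactly
    when ``noise_sd`` is 0.  The 68 landmarks are emitted in VIS space,
    consistent with a known VIS-to-IR homography.

    Memory scales with duration (one float64 frame per sample); use
    short durations for frame-level work.
    """
    meta = meta or RecordingMeta(sampling_rate=config.sampling_rate)
    rows, cols = meta.ir_shape
    g_mask = np.zeros((rows, cols), bool)
    g_mask[glabella_patch] = True
    n_mask = np.zeros((rows, cols), bool)
    n_mask[nose_patch] = True
    if (g_mask & n_mask).any():
        raise ValueError("glabella and nose patches overlap")

    nose, glabella, truth, events = simulate_recording(config)
    rng = np.random.default_rng(config.seed + 1)
    n = nose.n
    background = 6000.0
    frames = np.empty((n, rows, cols))
    for i in range(n):
        frame = np.full((rows, cols), background)
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, (rows, cols))
        frame[glabella_patch] = glabella.values[i]
        frame[nose_patch] = nose.values[i]
        frames[i] = frame
    stack = ThermalFrameStack(frames, nose.timestamps.copy(), meta)

    transform = PlanarTransform(DEFAULT_VIS_TO_IR.copy())
    ir_template = _template_landmarks_ir()
    vis_template = transform.inverse().apply(ir_template)
    landmarks_vis = []
    for i in range(n):
        pts = vis_template.copy()
        if jitter_sd > 0:
            pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
        landmarks_vis.append(LandmarkSet(pts, "VIS", frame_index=i))
    return SimulatedFrames(
        stack, landmarks_vis, transform, nose, glabella, truth, events
    )


# ---------------------------------------------------------------------------
# labeled training windows for the valence classifier
# ---------------------------------------------------------------------------

def simulate_training_windows(
    n_per_class: int,
    seed: int,
    config: SimConfig | None = None,
    window: WindowSpec = WindowSpec(20.0, 2.0),
) -> tuple[list[Window], list[str]]:
    """Labeled 20 s nose-tip windows drawn from the generative model.

    Each window is baseline (jittered per window) + sinusoidal drift at
    a random phase + a full-window autonomic ramp (down for
    sympathetic, up for parasympathetic) + Gaussian noise, i.e. a
    window recorded deep inside an episode.
    """
    cfg = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    n = int(round(window.length * fs))
    t = np.arange(n) / fs
    windows: list[Window] = []
    labels: list[str] = []
    for label, rate in (
        ("sympathetic", -cfg.sympathetic_cooling_rate),
        ("parasympathetic", cfg.recovery_rate),
    ):
        for _ in range(n_per_class):
            phase = rng.uniform(0.0, cfg.drift_period)
            base = cfg.baseline_level + rng.uniform(-5.0, 5.0)
            drift = cfg.drift_amplitude * np.sin(
                2 * np.pi * (t + phase) / cfg.drift_period
            )
            values = base + drift + rate * t + rng.normal(0.0, cfg.noise_sd, n)
            windows.append(Window(0.0, values, fs))
            labels.append(label)
    return windows, labels


def training_features(
    windows: list[Window], labels: list[str], **feature_kwargs
) -> tuple[list, list[str]]:
    """Feature vectors of the valid training windows, with labels."""
    from .valence import compute_valence_features

    feats, kept = [], []
    for w, lab in zip(windows, labels):
        fv = compute_valence_features(w, **feature_kwargs)
        if fv.valid:
            feats.append(fv)
            kept.append(lab)
    return feats, kept


def train_default_model(seed: int, n_per_class: int = 400, c: float = 1.0):
    """Train a valence model on simulator-labeled windows."""
    from .valence import train_valence_model

    windows, labels = simulate_training_windows(n_per_class, seed)
    feats, kept = training_features(windows, labels)
    model = train_valence_model(feats, kept, c=c)
    model.meta["training_seed"] = seed
    model.meta["n_per_class"] = n_per_class
    return model
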