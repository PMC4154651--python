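"""Onset (ignition) detection from calcium-fluorescence traces.

A node ignition shows as an abrupt rise of the fluorescence signal above a
stable resting baseline, followed by a slow (~seconds) decay back.  The
detection chain per node is:

1. estimate the resting level F0 and background noise SD, removing a linear
   drift and iteratively discarding frames more than 2 SD above the mean;
2. express the corrected signal as dF/F = (F - F0) / F0;
3. mark an ignition where the derivative of the (lightly smoothed) signal
   has a local maximum while dF/F stays above 2 SD of the background for at
   least 5 consecutive frames;
4. optionally refine the onset below frame resolution by fitting one line
   to the pre-onset background points and one to the fast-rise points; the
   crossing abscissa is the refined onset time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EventTrain
from .synth import FluorescenceMovie


class DegenerateTraceError(ValueError):
    """Too few frames survive baseline estimation."""


@dataclass
class FluorescenceTrace:
    values: np.ndarray  # fluorescence per frame, arbitrary units
    frame_rate: float  # frames / s
    node_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.values) < 20:
            raise ValueError("need at least 20 frames")


@dataclass
class BaselineEstimate:
    f0: float  # resting fluorescence level, trace units
    background_sd: float  # residual SD of retained frames, trace units
    drift_slope: float  # trace units per second
    drift_t_ref: float  # seconds; drift is removed about this time
    n_retained: int = 0


@dataclass
class OnsetEvent:
    node_id: str
    time: float  # seconds
    frame: int
    refined: bool = False


def estimate_baseline(
    trace: FluorescenceTrace,
    sd_factor: float = 2.0,
    rel_tol: float = 0.01,
    max_iter: int = 50,
) -> BaselineEstimate:
    """Resting level and background noise by iterative outlier rejection.

    Repeatedly fits a linear trend to the retained frames and discards
    frames whose residual exceeds ``sd_factor`` times the residual SD
    (transients only push the signal up, so only high outliers are
    discarded), until the SD changes by less than ``rel_tol`` between
    passes.  F0 is the mean retained level after drift removal about the
    recording midpoint.
    """
    t = np.arange(len(trace.values)) / trace.frame_rate
    t_ref = float(t.mean())
    retained = np.ones(len(t), dtype=bool)
    prev_sd = np.inf
    slope = 0.0
    for _ in range(max_iter):
        if retained.sum() < 10:
            raise DegenerateTraceError(
                f"only {int(retained.sum())} frames retained for baseline"
            )
        slope, intercept = np.polyfit(t[retained], trace.values[retained], 1)
        residuals = trace.values - (slope * t + intercept)
        sd = float(residuals[retained].std())
        # float-rounding floor: an exact fit retains every frame
        if sd <= 1e-9 * max(1.0, float(np.abs(trace.values).max())):
            sd = 0.0
            break
        new_retained = residuals <= sd_factor * sd
        if prev_sd < np.inf and abs(prev_sd - sd) <= rel_tol * prev_sd:
            retained = new_retained if new_retained.sum() >= 10 else retained
            break
        prev_sd = sd
        retained = new_retained
    corrected = trace.values - slope * (t - t_ref)
    f0 = float(corrected[retained].mean())
    return BaselineEstimate(
        f0=f0,
        background_sd=float(residuals[retained].std()),
        drift_slope=float(slope),
        drift_t_ref=t_ref,
        n_retained=int(retained.sum()),
    )


def normalize(trace: FluorescenceTrace, baseline: BaselineEstimate) -> np.ndarray:
    """Relative signal dF/F = (F_corrected - F0) / F0 per frame.

    The linear drift is removed before normalizing.  Invariant under
    rescaling of the raw trace (both F and F0 scale together).
    """
    if baseline.f0 <= 0:
        raise ValueError(f"cannot normalize with F0 = {baseline.f0}")
    t = np.arange(len(trace.values)) / trace.frame_rate
    corrected = trace.values - baseline.drift_slope * (t - baseline.drift_t_ref)
    return (corrected - baseline.f0) / baseline.f0


def _boxcar(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def detect_onsets(
    norm_signal: np.ndarray,
    background_sd_norm: float,
    frame_rate: float,
    node_id: str = "",
    sd_factor: float = 2.0,
    min_frames: int = 5,
    smooth_window: int = 3,
) -> "list[OnsetEvent]":
    """Find ignition onsets in a normalized (dF/F) signal.

    An onset requires the smoothed signal to exceed
    ``sd_factor * background_sd_norm`` for at least ``min_frames``
    consecutive frames, with a local maximum of the derivative at the start
    of the excursion that itself clears the background derivative noise —
    this rejects re-crossings where a slowly decaying transient hovers at
    the amplitude threshold.  The onset frame is the last sub-threshold
    frame before the excursion.  Events closer than ``min_frames`` are
    merged into the earlier one.  A flat signal yields no events.
    """
    if background_sd_norm < 0:
        raise ValueError("background_sd_norm must be nonnegative")
    smoothed = _boxcar(np.asarray(norm_signal, dtype=float), smooth_window)
    thr = sd_factor * background_sd_norm
    above = smoothed > thr
    if not above.any():
        return []
    deriv = np.diff(smoothed, prepend=smoothed[0])
    # run-length encode the suprathreshold stretches
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(above)]))
    # smoothing leaves ~sd*sqrt(2/3) of frame-to-frame noise on the
    # derivative; a true rise must clear it
    deriv_thr = sd_factor * background_sd_norm * np.sqrt(2.0 / 3.0)
    events: list[OnsetEvent] = []
    for s, e in zip(starts, ends):
        if e - s < min_frames:
            continue
        window = deriv[max(s - 1, 0) : min(s + min_frames, e)]
        if window.max() <= deriv_thr:
            continue
        onset_frame = max(s - 1, 0)
        if events and onset_frame - events[-1].frame < min_frames:
            continue
        events.append(
            OnsetEvent(
                node_id=node_id,
                time=onset_frame / frame_rate,
                frame=onset_frame,
                refined=False,
            )
        )
    return events


def refine_onset_subframe(
    norm_signal: np.ndarray,
    event: OnsetEvent,
    frame_rate: float,
    n_background: int = 10,
    n_rise: int = 5,
) -> OnsetEvent:
    """Refine an onset below frame resolution with a two-line fit.

    A least-squares line through the ``n_background`` frames preceding the
    onset and another through the ``n_rise`` frames of the fast rise
    (starting at the onset frame) intersect at the refined onset time.
    Falls back to the frame time (``refined=False``) when there are too few
    frames, the lines are near-parallel, or the crossing lands more than
    one frame away from the detected onset.
    """
    x = np.asarray(norm_signal, dtype=float)
    f = event.frame
    if f < n_background or f + n_rise > len(x):
        return OnsetEvent(event.node_id, event.time, f, refined=False)
    tb = np.arange(f - n_background, f) / frame_rate
    tr = np.arange(f, f + n_rise) / frame_rate
    m1, b1 = np.polyfit(tb, x[f - n_background : f], 1)
    m2, b2 = np.polyfit(tr, x[f : f + n_rise], 1)
    scale = max(abs(m1), abs(m2), 1e-12)
    if abs(m2 - m1) < 1e-6 * scale:
        return OnsetEvent(event.node_id, event.time, f, refined=False)
    t_cross = (b1 - b2) / (m2 - m1)
    if abs(t_cross - event.time) > 1.0 / frame_rate:
        return OnsetEvent(event.node_id, event.time, f, refined=False)
    return OnsetEvent(event.node_id, float(t_cross), f, refined=True)


def events_from_traces(
    movie: FluorescenceMovie,
    sd_factor: float = 2.0,
    min_frames: int = 5,
    smooth_window: int = 3,
    refine: bool = True,
    n_background: int = 10,
    n_rise: int = 5,
) -> EventTrain:
    """Full per-node detection chain over a trace matrix.

    Baseline -> dF/F -> onset detection (-> sub-frame refinement) for every
    node column, pooled into one time-sorted event train.
    """
    ev_nodes: list[str] = []
    ev_times: list[float] = []
    for j, node in enumerate(movie.node_ids):
        trace = FluorescenceTrace(
            movie.values[:, j], frame_rate=movie.frame_rate, node_id=node
        )
        baseline = estimate_baseline(trace)
        norm = normalize(trace, baseline)
        sd_norm = baseline.background_sd / baseline.f0
        events = detect_onsets(
            norm,
            sd_norm,
            movie.frame_rate,
            node_id=node,
            sd_factor=sd_factor,
            min_frames=min_frames,
            smooth_window=smooth_window,
        )
        for ev in events:
            if refine:
                ev = refine_onset_subframe(
                    norm, ev, movie.frame_rate, n_background, n_rise
                )
            ev_nodes.append(node)
            ev_times.append(ev.time)
    return EventTrain(np.array(ev_nodes, dtype=object), np.array(ev_times))
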