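"""Stepwise detection of spontaneous postsynaptic-current events.

The detector runs four stages per sweep:

1. **smoothing** — Savitzky-Golay local polynomial regression
   (``sg_smooth``), parameterised by polynomial order and side points
   (half-window);
2. **initial search** — local peaks (negative-going: valleys) of the
   smoothed trace deviating more than a fixed threshold (default 3 pA)
   from the slowly varying trend of the trace (``estimate_trend``,
   ``initial_search``);
3. **baseline search** — a backward scan from each candidate peak for the
   preceding local extremum of opposite polarity, identified by a
   first-difference sign change confirmed by the discrete second
   derivative (``baseline_search``);
4. **final search** — the amplitude (peak minus baseline on the smoothed
   trace) is compared against the user's minimum amplitude; smaller
   candidates are discarded (``finalize_events``).

Editing utilities (per-sweep re-detection with overridden parameters,
deletion, contiguous selection), a single-exponential decay fit and the
per-sweep / whole-record summary tables round out the stage.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .signalio import Recording

__all__ = [
    "DetectionError",
    "DetectionParams",
    "Event",
    "EventSet",
    "FitResult",
    "sg_smooth",
    "estimate_trend",
    "initial_search",
    "baseline_search",
    "finalize_events",
    "detect",
    "fit_decay",
    "redetect_sweep",
    "delete_event",
    "select_events",
    "sweep_summaries",
    "summarize_events",
]


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    """User-adjustable detector parameters.

    ``polarity`` is the direction of the events ("negative" for inward
    currents such as EPSCs at a negative holding potential). The minimum
    amplitude (default 10 pA) is the final-search acceptance criterion;
    ``poly_order`` / ``side_points`` control the Savitzky-Golay smoothing;
    ``initial_threshold_pa`` (default 3 pA) is the deviation from the trend
    a local extremum must exceed in the initial search.
    """

    polarity: str = "negative"
    min_amplitude_pa: float = 10.0
    poly_order: int = 3
    side_points: int = 14
    initial_threshold_pa: float = 3.0
    baseline_max_lookback_ms: float = 10.0
    min_separation_ms: float = 2.0
    trend_window_s: float = 0.5
    strict_amplitude: bool = False  # True: amplitude must exceed (>) the minimum

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise DetectionError(f"polarity must be negative|positive, got {self.polarity!r}")
        if self.poly_order < 1:
            raise DetectionError("poly_order must be >= 1")
        if 2 * self.side_points + 1 <= self.poly_order:
            raise DetectionError(
                f"window 2*{self.side_points}+1 must exceed poly_order {self.poly_order}"
            )
        if self.min_amplitude_pa <= 0 or self.initial_threshold_pa <= 0:
            raise DetectionError("amplitude thresholds must be positive")


@dataclass
class Event:
    """One detected PSC: peak and baseline location/value, amplitude, flags."""

    sweep_index: int
    peak_index: int
    peak_time_s: float
    peak_value_pa: float
    baseline_index: int
    baseline_value_pa: float
    amplitude_pa: float
    selected: int = 0
    decay_tau_ms: float | None = None
    fit_ok: bool | None = None


@dataclass
class EventSet:
    """Events of a whole recording in absolute-time order.

    ``overrides`` logs per-sweep parameter overrides applied through
    ``redetect_sweep``.
    """

    events: list[Event] = field(default_factory=list)
    params_used: DetectionParams = field(default_factory=DetectionParams)
    overrides: dict[int, DetectionParams] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time_s for e in self.events], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e.amplitude_pa for e in self.events], dtype=float)

    @property
    def selected_mask(self) -> np.ndarray:
        return np.array([e.selected for e in self.events], dtype=int)

    def events_of_sweep(self, sweep_index: int) -> list[Event]:
        return [e for e in self.events if e.sweep_index == sweep_index]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "sweep_index",
            "peak_index",
            "peak_time_s",
            "peak_value_pa",
            "baseline_index",
            "baseline_value_pa",
            "amplitude_pa",
            "selected",
            "decay_tau_ms",
            "fit_ok",
        ]
        return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in self.events],
                            columns=cols)


# ---------------------------------------------------------------------------
# stage 1: smoothing

def sg_smooth(trace: np.ndarray, poly_order: int, side_points: int) -> np.ndarray:
    """Savitzky-Golay smoothing with shrinking windows at the edges.

    Interior points get the classic filter: the value at the centre of the
    least-squares polynomial of degree ``poly_order`` fitted over the
    centred window of ``2*side_points + 1`` samples. Near the edges the
    window shrinks asymmetrically to the available samples (the polynomial
    degree drops with it when fewer points than coefficients remain), so no
    margin is lost.
    """
    trace = np.asarray(trace, dtype=float)
    window = 2 * side_points + 1
    if window <= poly_order:
        raise DetectionError("window must exceed poly_order")
    n = trace.size
    if n <= window:
        raise DetectionError(f"trace length {n} must exceed window {window}")
    out = savgol_filter(trace, window, poly_order, mode="interp")
    for i in range(side_points):  # left edge: window [0, i+side]
        out[i] = _polyfit_at(trace, 0, i + side_points + 1, i, poly_order)
    for i in range(n - side_points, n):  # right edge: window [i-side, n)
        lo = i - side_points
        out[i] = _polyfit_at(trace, lo, n, i, poly_order)
    return out


def _polyfit_at(trace: np.ndarray, lo: int, hi: int, at: int, poly_order: int) -> float:
    x = np.arange(lo, hi, dtype=float) - at
    y = trace[lo:hi]
    deg = min(poly_order, x.size - 1)
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg)
    return float(coeffs[0])


# ---------------------------------------------------------------------------
# stage 2: trend + initial search

def estimate_trend(
    trace: np.ndarray,
    sampling_rate_hz: float,
    window_s: float = 0.5,
    eval_stride: int | None = None,
) -> np.ndarray:
    """Slowly varying holding-current level of a sweep.

    A centred moving median over a 0.5 s window (reflect-padded at the
    edges). The median is evaluated on a stride of one tenth of the window
    and linearly interpolated in between, which changes nothing at the time
    scale of the trend but keeps the cost at a fraction of the full rolling
    median. Robustness of the median makes the estimate essentially blind
    to individual PSCs riding on the baseline and exactly invariant to
    adding a constant.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    w = int(round(window_s * sampling_rate_hz))
    w = max(3, w | 1)  # odd
    if w >= n:
        return np.full(n, float(np.median(trace)))
    half = w // 2
    padded = np.pad(trace, half, mode="reflect")
    stride = eval_stride if eval_stride is not None else max(1, w // 10)
    centers = np.arange(0, n, stride)
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    windows = sliding_window_view(padded, w)  # windows[i] is centred on sample i
    med = np.empty(centers.size)
    chunk = max(1, int(2e7) // w)
    for s in range(0, centers.size, chunk):
        idx = centers[s : s + chunk]
        med[s : s + chunk] = np.median(windows[idx], axis=1)
    if centers.size == n:
        return med
    return np.interp(np.arange(n), centers, med)


def initial_search(
    smoothed: np.ndarray,
    trend: np.ndarray,
    polarity: str = "negative",
    initial_threshold_pa: float = 3.0,
    sampling_rate_hz: float | None = None,
    min_separation_ms: float = 2.0,
    min_prominence_pa: float = 0.0,
) -> np.ndarray:
    """Candidate peaks: local extrema deviating > threshold from the trend.

    Emulates a multiscale peak search: local extrema of
    ``smoothed - trend`` in the polarity direction that exceed the
    threshold, separated by at least ``min_separation_ms`` (the larger
    extremum wins within a separation window). ``min_prominence_pa``
    additionally requires a candidate to climb that far out of its own
    surroundings — an event rises from the trend so its prominence is its
    whole amplitude, whereas a noise ripple riding on the decay tail of a
    larger event only has the ripple swing to its name. Returns strictly
    increasing sample indices.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.shape != np.shape(trend):
        raise DetectionError("smoothed and trend must have the same length")
    deviation = smoothed - np.asarray(trend, dtype=float)
    signal = -deviation if polarity == "negative" else deviation
    if sampling_rate_hz is not None:
        distance = max(1, int(round(min_separation_ms * 1e-3 * sampling_rate_hz)))
    else:
        distance = 1
    peaks, _ = find_peaks(signal, height=initial_threshold_pa, distance=distance)
    strict = signal[peaks] > initial_threshold_pa
    peaks = peaks[strict]
    if min_prominence_pa > 0 and peaks.size:
        wlen = 2 * int(0.05 * (sampling_rate_hz or 1e4)) + 1
        prominences = peak_prominences(signal, peaks, wlen=wlen)[0]
        peaks = peaks[prominences >= min_prominence_pa]
    return peaks


# ---------------------------------------------------------------------------
# stage 3: baseline search

def _baseline_bulk(
    smoothed: np.ndarray,
    peak_indices: np.ndarray,
    polarity: str,
    baseline_max_lookback_ms: float,
    sampling_rate_hz: float,
    trend: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised backward baseline search for many peaks at once.

    With a trend estimate the baseline is the nearest preceding sample at
    or above the local trend — the point where the trace last left the
    holding-current level before diving into the event. Candidates whose
    whole lookback window stays below the trend (e.g. events riding on the
    decay of a previous event) fall back to the most opposite-going local
    max in the window (first-difference sign change confirmed by the
    second derivative); with no extremum at all, the window edge is used.
    Without a trend the nearest such local max is returned directly.
    """
    s = np.asarray(smoothed, dtype=float)
    if polarity == "positive":
        s = -s
    # local maxima of s: first difference changes sign from >=0 to <0,
    # which also makes the central second difference (d[i] - d[i-1]) negative.
    d = np.diff(s)
    is_max = (d[:-1] >= 0) & (d[1:] < 0)
    second = d[1:] - d[:-1]
    maxima = np.flatnonzero(is_max & (second <= 0)) + 1
    lookback = max(1, int(round(baseline_max_lookback_ms * 1e-3 * sampling_rate_hz)))
    peaks = np.asarray(peak_indices, dtype=int)
    if np.any(peaks <= 0):
        raise DetectionError("peak at index 0 leaves no room for a baseline")
    edge = np.maximum(peaks - lookback, 0)
    lo = np.searchsorted(maxima, edge)
    hi = np.searchsorted(maxima, peaks)
    values = s[maxima] if maxima.size else maxima.astype(float)
    out = edge.copy()
    if trend is not None:
        strend = np.asarray(trend, dtype=float)
        if polarity == "positive":
            strend = -strend
        at_trend = np.flatnonzero(s >= strend)
        tlo = np.searchsorted(at_trend, edge)
        thi = np.searchsorted(at_trend, peaks)
    for k in range(peaks.size):
        if trend is not None and thi[k] > tlo[k]:
            out[k] = at_trend[thi[k] - 1]  # last at-trend sample before the peak
        elif hi[k] > lo[k]:
            a, b = lo[k], hi[k]
            if trend is not None:  # below-trend window: most opposite-going max
                out[k] = maxima[a + int(np.argmax(values[a:b]))]
            else:  # no trend context: nearest confirmed local max
                out[k] = maxima[b - 1]
    return out


def baseline_search(
    smoothed: np.ndarray,
    peak_index: int,
    polarity: str = "negative",
    baseline_max_lookback_ms: float = 10.0,
    sampling_rate_hz: float = 10000.0,
    trend: np.ndarray | None = None,
) -> int:
    """Backward search for the pre-event baseline of one peak.

    Scanning back from the peak (at most ``baseline_max_lookback_ms``), the
    baseline is a preceding local extremum of opposite polarity — a
    first-difference sign change whose discrete second derivative has the
    confirming sign. When a ``trend`` estimate is supplied, the nearest
    such extremum at or above the local trend wins (the point where the
    trace last left the holding-current level), which stops the measured
    amplitude from collapsing onto noise ripples riding on the event's
    edge; if every extremum lies below the trend the most opposite-going
    one in the window is used. With no extremum in the window at all, the
    window edge is returned.
    """
    if peak_index <= 0:
        raise DetectionError("peak at index 0 leaves no room for a baseline")
    if peak_index >= len(smoothed):
        raise DetectionError("peak_index outside trace")
    return int(
        _baseline_bulk(
            smoothed,
            np.array([peak_index]),
            polarity,
            baseline_max_lookback_ms,
            sampling_rate_hz,
            trend,
        )[0]
    )


def _dominant_peaks(
    smoothed: np.ndarray,
    peak_indices: np.ndarray,
    baseline_indices: np.ndarray,
    polarity: str,
) -> np.ndarray:
    """Mask of candidates that dominate their own baseline-to-peak segment.

    A candidate whose segment contains a sample more extreme than its own
    peak is a ripple riding on the flank of a larger event, not an event
    of its own; the larger extremum carries its own candidate.
    """
    s = np.asarray(smoothed, dtype=float)
    if polarity == "positive":
        s = -s
    keep = np.ones(peak_indices.size, dtype=bool)
    for k, (p, b) in enumerate(zip(peak_indices, baseline_indices)):
        if p > b and s[b:p].min() < s[p]:
            keep[k] = False
    return keep


# ---------------------------------------------------------------------------
# stage 4: final search

def finalize_events(
    smoothed: np.ndarray,
    peak_indices: np.ndarray,
    baseline_indices: np.ndarray,
    params: DetectionParams,
    sampling_rate_hz: float,
    sweep_index: int = 0,
    sweep_duration_s: float | None = None,
    trend: np.ndarray | None = None,
) -> list[Event]:
    """Keep candidates whose amplitude meets the minimum-amplitude criterion.

    The amplitude is the smoothed-trace peak measured against the baseline
    level. When the trend estimate locates the baseline (the point where
    the trace last sat at the holding level), the baseline level is the
    trend value there — the trace's own sample at that point carries the
    residual smoothed noise and would bias every amplitude upward by a
    fraction of it. Candidates whose amplitude has the wrong sign
    (baseline on the wrong side of the peak) are discarded outright. The
    acceptance boundary is inclusive (``>=``) unless
    ``params.strict_amplitude``.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    base_level = smoothed if trend is None else np.asarray(trend, dtype=float)
    sign = -1.0 if params.polarity == "negative" else 1.0
    duration = sweep_duration_s if sweep_duration_s is not None else (
        len(smoothed) / sampling_rate_hz
    )
    events: list[Event] = []
    seen: set[int] = set()
    for p, b in zip(np.asarray(peak_indices, int), np.asarray(baseline_indices, int)):
        if p in seen:
            continue
        amplitude = sign * (smoothed[p] - base_level[b])
        if amplitude <= 0:
            continue
        if params.strict_amplitude:
            if amplitude <= params.min_amplitude_pa:
                continue
        elif amplitude < params.min_amplitude_pa:
            continue
        seen.add(int(p))
        events.append(
            Event(
                sweep_index=sweep_index,
                peak_index=int(p),
                peak_time_s=sweep_index * duration + p / sampling_rate_hz,
                peak_value_pa=float(smoothed[p]),
                baseline_index=int(b),
                baseline_value_pa=float(base_level[b]),
                amplitude_pa=float(amplitude),
            )
        )
    return events


def _detect_sweep(
    trace: np.ndarray,
    sampling_rate_hz: float,
    params: DetectionParams,
    sweep_index: int,
    sweep_duration_s: float,
) -> list[Event]:
    smoothed = sg_smooth(trace, params.poly_order, params.side_points)
    trend = estimate_trend(smoothed, sampling_rate_hz, params.trend_window_s)
    candidates = initial_search(
        smoothed,
        trend,
        params.polarity,
        params.initial_threshold_pa,
        sampling_rate_hz,
        params.min_separation_ms,
    )
    candidates = candidates[candidates > 0]
    if candidates.size == 0:
        return []
    baselines = _baseline_bulk(
        smoothed, candidates, params.polarity, params.baseline_max_lookback_ms,
        sampling_rate_hz, trend,
    )
    keep = _dominant_peaks(smoothed, candidates, baselines, params.polarity)
    candidates, baselines = candidates[keep], baselines[keep]
    return finalize_events(
        smoothed, candidates, baselines, params, sampling_rate_hz,
        sweep_index, sweep_duration_s, trend,
    )


def detect(recording: Recording, params: DetectionParams | None = None) -> EventSet:
    """Run the four-step detector over every sweep of a recording."""
    params = params or DetectionParams()
    events: list[Event] = []
    for i in range(recording.n_sweeps):
        events.extend(
            _detect_sweep(
                recording.sweeps[i],
                recording.sampling_rate_hz,
                params,
                i,
                recording.sweep_duration_s,
            )
        )
    events.sort(key=lambda e: e.peak_time_s)
    return EventSet(events=events, params_used=params)


# ---------------------------------------------------------------------------
# decay fit

@dataclass
class FitResult:
    tau_ms: float | None
    y_inf_pa: float | None
    ok: bool
    message: str = ""
    rmse_pa: float | None = None


def fit_decay(
    trace: np.ndarray,
    event: Event,
    sampling_rate_hz: float,
    window_ms: float = 50.0,
    end_index: int | None = None,
) -> FitResult:
    """Single-exponential fit of the post-peak decay of one event.

    Fits ``y(t) = y_inf + (y_peak - y_inf) * exp(-(t - t_peak)/tau)`` by
    least squares over the samples from the peak to ``window_ms`` later
    (optionally capped at ``end_index``, e.g. the onset of the next event).
    A fit is flagged as failed — never silently zero — when the optimiser
    does not converge, the segment is degenerate, or tau falls outside
    (0, 1000] ms.
    """
    trace = np.asarray(trace, dtype=float)
    p = event.peak_index
    stop = min(len(trace), p + int(round(window_ms * 1e-3 * sampling_rate_hz)) + 1)
    if end_index is not None:
        stop = min(stop, end_index)
    y = trace[p:stop]
    if y.size < 10:
        return FitResult(None, None, False, "fewer than 10 samples after the peak")
    if np.ptp(y) < 1e-9:
        return FitResult(None, None, False, "flat post-peak segment")
    t = np.arange(y.size) / sampling_rate_hz  # s, relative to the peak
    y_peak = y[0]

    def model(tt: np.ndarray, y_inf: float, tau_s: float) -> np.ndarray:
        return y_inf + (y_peak - y_inf) * np.exp(-tt / tau_s)

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(float(y[-1]), 5e-3),
            bounds=((-np.inf, 1e-6), (np.inf, 10.0)),
            maxfev=2000,
        )
    except (RuntimeError, ValueError) as exc:
        return FitResult(None, None, False, f"no convergence: {exc}")
    y_inf, tau_s = float(popt[0]), float(popt[1])
    tau_ms = tau_s * 1e3
    if not (0.0 < tau_ms <= 1000.0):
        return FitResult(None, None, False, f"tau {tau_ms:.3g} ms outside (0, 1000]")
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return FitResult(tau_ms, y_inf, True, "", rmse)


def fit_all_decays(recording: Recording, eventset: EventSet,
                   window_ms: float = 50.0) -> EventSet:
    """Fit every event's decay in place (capped at the next event's onset)."""
    by_sweep: dict[int, list[Event]] = {}
    for e in eventset.events:
        by_sweep.setdefault(e.sweep_index, []).append(e)
    for i, evs in by_sweep.items():
        trace = recording.sweeps[i]
        evs.sort(key=lambda e: e.peak_index)
        for k, e in enumerate(evs):
            end = evs[k + 1].baseline_index if k + 1 < len(evs) else None
            res = fit_decay(trace, e, recording.sampling_rate_hz, window_ms, end)
            e.decay_tau_ms = res.tau_ms
            e.fit_ok = res.ok
    return eventset


# ---------------------------------------------------------------------------
# editing

def redetect_sweep(
    recording: Recording,
    eventset: EventSet,
    sweep_index: int,
    params_override: DetectionParams,
) -> EventSet:
    """Re-run detection in one sweep with new parameters, others untouched."""
    if not (0 <= sweep_index < recording.n_sweeps):
        raise DetectionError(f"sweep_index {sweep_index} out of range")
    kept = [copy.copy(e) for e in eventset.events if e.sweep_index != sweep_index]
    fresh = _detect_sweep(
        recording.sweeps[sweep_index],
        recording.sampling_rate_hz,
        params_override,
        sweep_index,
        recording.sweep_duration_s,
    )
    events = sorted(kept + fresh, key=lambda e: e.peak_time_s)
    overrides = dict(eventset.overrides)
    overrides[sweep_index] = params_override
    return EventSet(events=events, params_used=eventset.params_used, overrides=overrides)


def delete_event(eventset: EventSet, event_index: int) -> EventSet:
    """Remove one event by its position in the time-ordered list."""
    if not (0 <= event_index < eventset.n_events):
        raise DetectionError(f"no event with index {event_index}")
    events = [copy.copy(e) for k, e in enumerate(eventset.events) if k != event_index]
    return EventSet(events=events, params_used=eventset.params_used,
                    overrides=dict(eventset.overrides))


def select_events(eventset: EventSet, start_event_index: int, n: int) -> EventSet:
    """Flag ``n`` consecutive events (global time order) as selected.

    Any previous selection is overwritten; all other events get flag 0.
    """
    total = eventset.n_events
    if start_event_index < 0 or n < 0:
        raise DetectionError("start index and count must be non-negative")
    if start_event_index + n > total:
        deficit = start_event_index + n - total
        raise DetectionError(
            f"cannot select {n} events from index {start_event_index}: "
            f"{deficit} event(s) short of the {total} available"
        )
    events = [copy.copy(e) for e in eventset.events]
    for k, e in enumerate(events):
        e.selected = int(start_event_index <= k < start_event_index + n)
    return EventSet(events=events, params_used=eventset.params_used,
                    overrides=dict(eventset.overrides))


# ---------------------------------------------------------------------------
# summaries

def sweep_summaries(recording: Recording, eventset: EventSet) -> pd.DataFrame:
    """Per-sweep table: mean holding current, event count, mean amplitude."""
    rows = []
    for i in range(recording.n_sweeps):
        evs = eventset.events_of_sweep(i)
        rows.append(
            {
                "sweep_index": i,
                "mean_holding_current_pa": float(np.mean(recording.sweeps[i])),
                "n_events": len(evs),
                "mean_amplitude_pa": (
                    float(np.mean([e.amplitude_pa for e in evs])) if evs else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def _block_stats(times: np.ndarray, amps: np.ndarray) -> dict:
    n = times.size
    ieis = np.diff(times) if n >= 2 else np.empty(0)
    return {
        "n": int(n),
        "mean_amplitude_pa": float(np.mean(amps)) if n else np.nan,
        "mean_iei_s": float(np.mean(ieis)) if ieis.size else np.nan,
    }


def summarize_events(eventset: EventSet) -> pd.DataFrame:
    """Totals over all events and over the selected block.

    Inter-event intervals are differences of consecutive *absolute* peak
    times (n-1 intervals); with fewer than two events the mean IEI is
    reported as missing.
    """
    times = eventset.peak_times
    amps = eventset.amplitudes
    sel = eventset.selected_mask.astype(bool)
    table = pd.DataFrame(
        [_block_stats(times, amps), _block_stats(times[sel], amps[sel])],
        index=["total", "selected"],
    )
    return table
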