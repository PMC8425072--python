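"""Biexponential PSC simulation and detector benchmarking.

The unitary event is the classic difference-of-exponentials quantal
conductance

    g(t) = (A / A') * [ -exp(-t/tau1) + exp(-t/tau2) ]    for t > 0,
    g(t) = 0                                              otherwise,

with rise constant tau1 < decay constant tau2 and the normalisation
factor A' = tau2**(tau1/(tau1 - tau2)) / tau1. The standard benchmark
scatters 250 such events uniformly over a 250-s zero-baseline sweep
sampled at 10 kHz; each event's time constants are jittered by a normal
factor (mean 1, SD 0.3) — one shared factor per event by default, so the
kinetics vary while every analytic peak stays equal — and one global
scale maps conductance units to current so that the mean true peak is
27.85 pA (negative-going). Calibrated white Gaussian noise (typically
sigma = 2, 6 or 10 pA) is added on top.

Scoring matches detected against true peak times one-to-one within a
tolerance (default 5 ms) and tallies a confusion matrix from which
precision, recall and the F1 score are derived. ``parameter_sweep`` runs
the whole detect-and-score pipeline over a grid of smoothing parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable
import warnings

import numpy as np
import pandas as pd

from .detection import DetectionParams, EventSet, detect
from .signalio import Recording

__all__ = [
    "KernelParams",
    "SimConfig",
    "ConfusionMatrix",
    "psc_kernel",
    "kernel_peak",
    "simulate_recording",
    "add_noise",
    "match_events",
    "precision_recall_f1",
    "parameter_sweep",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "onset_time_s",
    "peak_time_s",
    "true_peak_amplitude_pa",
    "tau1_ms",
    "tau2_ms",
]


@dataclass(frozen=True)
class KernelParams:
    """Nominal kernel: peak-conductance coefficient (nS) and tau's (ms)."""

    a_ns: float = -12.783
    tau1_ms: float = 0.5
    tau2_ms: float = 3.0

    def __post_init__(self) -> None:
        if not (self.tau2_ms > self.tau1_ms > 0):
            raise ValueError("need tau2 > tau1 > 0")
        if self.a_ns == 0:
            raise ValueError("peak amplitude A must be nonzero")

    @property
    def norm_factor(self) -> float:
        """A' = tau2**(tau1/(tau1-tau2)) / tau1, at the nominal tau's."""
        t1, t2 = self.tau1_ms, self.tau2_ms
        return t2 ** (t1 / (t1 - t2)) / t1


def _biexp(t_ms: np.ndarray, coeff: float, tau1_ms: float, tau2_ms: float) -> np.ndarray:
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = coeff * (-np.exp(-tp / tau1_ms) + np.exp(-tp / tau2_ms))
    return out


def psc_kernel(
    params: KernelParams,
    t_ms: np.ndarray,
    tau1_ms: float | None = None,
    tau2_ms: float | None = None,
    renormalize: bool = False,
) -> np.ndarray:
    """Evaluate the quantal-conductance kernel at times ``t_ms``.

    ``tau1_ms`` / ``tau2_ms`` override the nominal time constants (for
    jittered events) while the normalisation A' stays fixed at the nominal
    values. With ``renormalize`` the A' of the effective tau's is used
    instead, as if the overridden constants were the nominal ones.
    """
    t1 = params.tau1_ms if tau1_ms is None else tau1_ms
    t2 = params.tau2_ms if tau2_ms is None else tau2_ms
    if not (t2 > t1 > 0):
        raise ValueError("need tau2 > tau1 > 0")
    if renormalize:
        aprime = t2 ** (t1 / (t1 - t2)) / t1
    else:
        aprime = params.norm_factor
    return _biexp(t_ms, params.a_ns / aprime, t1, t2)


def kernel_peak(
    params: KernelParams,
    tau1_ms: float | None = None,
    tau2_ms: float | None = None,
) -> tuple[float, float]:
    """Closed-form (peak time ms, peak value) of the kernel.

    The stationary point of the biexponential bracket is at
    ``t* = tau1*tau2/(tau2-tau1) * ln(tau2/tau1)``.
    """
    t1 = params.tau1_ms if tau1_ms is None else tau1_ms
    t2 = params.tau2_ms if tau2_ms is None else tau2_ms
    t_star = t1 * t2 / (t2 - t1) * np.log(t2 / t1)
    value = float(psc_kernel(params, np.array([t_star]), t1, t2)[0])
    return float(t_star), value


@dataclass(frozen=True)
class SimConfig:
    """Benchmark geometry, jitter and calibration settings.

    Defaults are the standard benchmark: 250 events uniformly placed in a
    250-s sweep at 10 kHz, tau jitter N(1, 0.3) truncated below 0.1
    (shared between tau1 and tau2 per event; see ``tau_jitter``), and a
    global amplitude calibration pinning the mean true peak to 27.85 pA.
    ``sigma_noise_pa`` is the white-noise SD applied by the CLI pipeline
    (``add_noise`` itself takes sigma explicitly).
    """

    n_events: int = 250
    duration_s: float = 250.0
    sampling_rate_hz: float = 10000.0
    tau_scale_mean: float = 1.0
    tau_scale_sd: float = 0.3
    tau_jitter: str = "shared"
    sigma_noise_pa: float = 0.0
    seed: int = 0
    amp_calibration_mean_pa: float = 27.85
    min_tau_scale: float = 0.1
    onset_margin_s: float = 0.05

    def __post_init__(self) -> None:
        if self.n_events < 0 or self.duration_s <= 0:
            raise ValueError("need n_events >= 0 and duration > 0")
        if self.sigma_noise_pa < 0:
            raise ValueError("noise SD must be >= 0")
        if self.tau_jitter not in ("shared", "independent"):
            raise ValueError("tau_jitter must be 'shared' or 'independent'")


def _draw_tau_scales(rng: np.random.Generator, config: SimConfig,
                     kernel: KernelParams) -> tuple[float, float]:
    """Jitter factors for (tau1, tau2), resampled while a draw is
    <= min_tau_scale or the scaled tau's would violate tau2 > tau1.

    In the default "shared" mode one factor multiplies both time constants
    — a pure time rescaling of the biexponential, so analytic peak
    amplitudes stay equal while the kinetics vary. "independent" draws a
    separate factor per constant, which also spreads the amplitudes.
    """
    while True:
        if config.tau_jitter == "shared":
            s = rng.normal(config.tau_scale_mean, config.tau_scale_sd)
            s1 = s2 = float(s)
        else:
            s1, s2 = rng.normal(config.tau_scale_mean, config.tau_scale_sd, size=2)
        if s1 <= config.min_tau_scale or s2 <= config.min_tau_scale:
            continue
        if kernel.tau2_ms * s2 > kernel.tau1_ms * s1:
            return float(s1), float(s2)


def simulate_recording(
    config: SimConfig | None = None,
    kernel: KernelParams | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Build the clean (noise-free) benchmark trace and its truth table.

    Returns a single-sweep, zero-baseline, negative-going ``Recording``
    plus a ground-truth table with one row per event: onset time, analytic
    peak time and amplitude (pA, magnitude), and the jittered tau's.
    Overlapping events are permitted — placement is uniform on
    ``(0, duration - onset_margin)``.
    """
    config = config or SimConfig()
    kernel = kernel or KernelParams()
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.sampling_rate_hz * config.duration_s))
    trace = np.zeros(n_samples)
    n = config.n_events
    if n == 0:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        rec = Recording(config.sampling_rate_hz, config.duration_s, trace[None, :],
                        source_path="<simulated>")
        return rec, truth

    onsets = np.sort(rng.uniform(0.0, config.duration_s - config.onset_margin_s, size=n))
    scales = np.array([_draw_tau_scales(rng, config, kernel) for _ in range(n)])
    tau1 = kernel.tau1_ms * scales[:, 0]
    tau2 = kernel.tau2_ms * scales[:, 1]

    peak_t_ms = np.empty(n)
    peak_mag = np.empty(n)
    for i in range(n):
        t_star, value = kernel_peak(kernel, tau1[i], tau2[i])
        peak_t_ms[i] = t_star
        peak_mag[i] = abs(value)
    scale = config.amp_calibration_mean_pa / float(np.mean(peak_mag))

    rate = config.sampling_rate_hz
    sign = -1.0 if kernel.a_ns < 0 else 1.0
    for i in range(n):
        start = int(np.ceil(onsets[i] * rate))
        support_s = 15.0 * tau2[i] * 1e-3
        stop = min(n_samples, int(np.ceil((onsets[i] + support_s) * rate)) + 1)
        if start >= stop:
            continue
        t_ms = (np.arange(start, stop) / rate - onsets[i]) * 1e3
        trace[start:stop] += scale * psc_kernel(kernel, t_ms, tau1[i], tau2[i])

    truth = pd.DataFrame(
        {
            "onset_time_s": onsets,
            "peak_time_s": onsets + peak_t_ms * 1e-3,
            "true_peak_amplitude_pa": scale * peak_mag,
            "tau1_ms": tau1,
            "tau2_ms": tau2,
        }
    )
    rec = Recording(config.sampling_rate_hz, config.duration_s, trace[None, :],
                    source_path="<simulated>")
    return rec, truth


def add_noise(recording: Recording, sigma_pa: float, seed: int = 0) -> Recording:
    """Add i.i.d. zero-mean Gaussian noise of SD ``sigma_pa`` samplewise."""
    if sigma_pa < 0:
        raise ValueError("noise SD must be >= 0")
    sweeps = recording.sweeps.copy()
    if sigma_pa > 0:
        rng = np.random.default_rng(seed)
        sweeps = sweeps + rng.normal(0.0, sigma_pa, size=sweeps.shape)
    return Recording(
        recording.sampling_rate_hz,
        recording.sweep_duration_s,
        sweeps,
        source_path=recording.source_path,
        unit_original=recording.unit_original,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN tallies from one-to-one event matching.

    TN counts 1-s grid segments containing neither a true nor a detected
    event; it is reported for completeness and plays no role in precision,
    recall or F1.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    tolerance_ms: float = 5.0

    @property
    def precision(self) -> float:
        p, _, _ = precision_recall_f1(self)
        return p

    @property
    def recall(self) -> float:
        _, r, _ = precision_recall_f1(self)
        return r

    @property
    def f1(self) -> float:
        _, _, f = precision_recall_f1(self)
        return f


def match_events(
    detected: "EventSet | np.ndarray",
    truth: pd.DataFrame,
    tolerance_ms: float = 5.0,
    duration_s: float | None = None,
    tn_segment_s: float = 1.0,
) -> ConfusionMatrix:
    """Greedy one-to-one matching of detected vs true peak times.

    Candidate pairs within ``tolerance_ms`` are taken in order of
    ascending time difference; each detected and each true event is used
    at most once. Matches are TP, surplus detections FP, unmatched truth
    rows FN.
    """
    if tolerance_ms <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(detected, EventSet):
        det = np.sort(detected.peak_times)
    else:
        det = np.sort(np.asarray(detected, dtype=float))
    true = np.sort(np.asarray(truth["peak_time_s"], dtype=float))
    tol = tolerance_ms * 1e-3

    pairs: list[tuple[float, int, int]] = []
    lo = np.searchsorted(true, det - tol, side="left")
    hi = np.searchsorted(true, det + tol, side="right")
    for i, (a, b) in enumerate(zip(lo, hi)):
        for j in range(a, b):
            pairs.append((abs(det[i] - true[j]), i, j))
    pairs.sort()
    used_det = np.zeros(det.size, dtype=bool)
    used_true = np.zeros(true.size, dtype=bool)
    tp = 0
    for _, i, j in pairs:
        if used_det[i] or used_true[j]:
            continue
        used_det[i] = used_true[j] = True
        tp += 1
    fp = int(det.size - tp)
    fn = int(true.size - tp)

    if duration_s is None:
        times = np.concatenate([det, true])
        duration_s = float(np.ceil(times.max())) if times.size else tn_segment_s
    n_seg = max(1, int(np.ceil(duration_s / tn_segment_s)))
    occupied = np.zeros(n_seg, dtype=bool)
    for t in np.concatenate([det, true]):
        occupied[min(n_seg - 1, int(t / tn_segment_s))] = True
    tn = int(n_seg - occupied.sum())
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn, tolerance_ms=tolerance_ms)


def precision_recall_f1(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """precision = TP/(TP+FP); recall = TP/(TP+FN); F1 = harmonic mean.

    A ratio with a zero denominator is reported as missing (nan); F1 is 0
    whenever its harmonic mean is undefined.
    """
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else float("nan")
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def parameter_sweep(
    noisy: Recording,
    truth: pd.DataFrame,
    poly_orders: Iterable[int] = (3, 4),
    side_points_range: Iterable[int] = range(2, 51),
    min_amplitude_pa: float = 10.0,
    tolerance_ms: float = 5.0,
    polarity: str = "negative",
) -> pd.DataFrame:
    """Detect-and-score over a grid of smoothing parameters.

    One row per (poly_order, side_points) pair with the confusion-matrix
    counts, precision/recall/F1 and the mean detected amplitude. Window
    combinations violating ``2*side + 1 > poly`` are skipped with a
    warning.
    """
    sides = list(side_points_range)
    rows = []
    for poly in poly_orders:
        for side in sides:
            if 2 * side + 1 <= poly:
                warnings.warn(
                    f"skipping poly={poly}, side={side}: window too small",
                    stacklevel=2,
                )
                continue
            params = DetectionParams(
                polarity=polarity,
                min_amplitude_pa=min_amplitude_pa,
                poly_order=poly,
                side_points=side,
            )
            evset = detect(noisy, params)
            cm = match_events(evset, truth, tolerance_ms,
                              duration_s=noisy.sweep_duration_s * noisy.n_sweeps)
            precision, recall, f1 = precision_recall_f1(cm)
            amps = evset.amplitudes
            rows.append(
                {
                    "poly_order": poly,
                    "side_points": side,
                    "n_detected": evset.n_events,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "tn": cm.tn,
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                    "mean_detected_amplitude_pa": (
                        float(np.mean(amps)) if amps.size else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
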