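"""Shared fixtures: tiny synthetic recordings and the standard benchmark.

The benchmark fixtures are session-scoped because simulating the 250-s,
10-kHz trace and detecting on it dominates the runtime of the acceptance
checks; everything else uses small, fast synthetic inputs.
"""

import numpy as np
import pytest

from psckit.detection import DetectionParams, detect
from psckit.signalio import Recording, UnitRecord
from psckit.simulation import KernelParams, SimConfig, add_noise, psc_kernel, simulate_recording

BENCH_SEED = 11
NOISE_SEED = 12
RATE = 10000.0


@pytest.fixture(scope="session")
def benchmark():
    """Standard 250-event / 250-s clean benchmark and its truth table."""
    clean, truth = simulate_recording(SimConfig(seed=BENCH_SEED))
    return clean, truth


@pytest.fixture(scope="session")
def benchmark_sigma6(benchmark):
    clean, truth = benchmark
    return add_noise(clean, 6.0, seed=NOISE_SEED), truth


@pytest.fixture(scope="session")
def benchmark_sigma10(benchmark):
    clean, truth = benchmark
    return add_noise(clean, 10.0, seed=NOISE_SEED), truth


def single_event_recording(
    amplitude_pa: float = 30.0,
    onset_s: float = 0.5,
    duration_s: float = 2.0,
    rate_hz: float = RATE,
    baseline_pa: float = 0.0,
) -> Recording:
    """One nominal-kinetics PSC on a flat baseline (negative-going)."""
    kernel = KernelParams()
    n = int(round(rate_hz * duration_s))
    t_ms = (np.arange(n) / rate_hz - onset_s) * 1e3
    wave = psc_kernel(kernel, t_ms)
    peak = np.abs(wave).max()
    trace = baseline_pa + wave * (amplitude_pa / peak)
    return Recording(rate_hz, duration_s, trace[None, :])


@pytest.fixture
def one_event_recording():
    return single_event_recording()


@pytest.fixture
def small_eventset():
    """Detected events of a 3-event recording (for editing/selection tests)."""
    kernel = KernelParams()
    rate, dur = RATE, 4.0
    n = int(round(rate * dur))
    trace = np.zeros(n)
    for onset in (0.5, 1.7, 3.1):
        t_ms = (np.arange(n) / rate - onset) * 1e3
        wave = psc_kernel(kernel, t_ms)
        trace += wave * (30.0 / np.abs(wave).max())
    rec = Recording(rate, dur, trace[None, :])
    return rec, detect(rec, DetectionParams())


def make_unit(name: str, times, amps, selected) -> UnitRecord:
    return UnitRecord(name, np.asarray(times, float), np.asarray(amps, float),
                      np.asarray(selected, int))
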