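"""Raw-trace preprocessing and capture-event statistics.

Converts sampled ionic-current recordings into normalized, median-decimated
capture events (the unit of all downstream HMM analysis) and computes
capture-rate and event-lifetime statistics with bootstrap errors plus
exponential voltage fits.

Conventions: currents in pA, voltages in mV, times in s; event currents are
normalized by the local open-pore current I0 so the emission variable is the
dimensionless blockade level I/I0.  Indexing is 0-based with half-open
intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "RawTrace",
    "Event",
    "CaptureStats",
    "ExpFit",
    "DT_S",
    "median_decimate",
    "detect_events",
    "capture_rate",
    "fit_exponential_voltage",
    "event_lifetime_stats",
    "event_histogram",
]

#: default decimation interval: 2.99 ms per datapoint (299 samples at 100 kHz)
DT_S = 0.00299


@dataclass
class RawTrace:
    """A sampled current recording at one applied voltage."""

    samples: np.ndarray          # current, pA
    sampling_rate_hz: float
    voltage_mV: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass
class Event:
    """One capture event: median-decimated normalized currents (I/I0).

    ``lifetime_s`` is exactly ``n_points * dt_s`` — the event clock ticks in
    decimated datapoints.
    """

    values: np.ndarray           # I/I0, dimensionless
    voltage_mV: float
    baseline_pA: float = float("nan")
    dt_s: float = DT_S
    class_label: str | None = None
    event_id: int | None = None
    start_time_s: float = float("nan")   # capture time within the source trace

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("an event needs at least one datapoint")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("event values must be finite")

    @property
    def n_points(self) -> int:
        return self.values.size

    @property
    def lifetime_s(self) -> float:
        return self.n_points * self.dt_s


@dataclass
class ExpFit:
    """Exponential voltage-dependence fit ``y = prefactor * exp(V / scale)``."""

    prefactor: float
    voltage_scale_mV: float
    prefactor_se: float
    scale_se: float
    slope: float
    slope_se: float
    r_squared: float


@dataclass
class CaptureStats:
    """Per-voltage capture statistics and the exponential voltage fit."""

    voltages_mV: np.ndarray
    counts: np.ndarray
    open_pore_time_s: np.ndarray
    rates_hz: np.ndarray
    rate_se_hz: np.ndarray
    fit: ExpFit | None = None


def median_decimate(trace: RawTrace | np.ndarray, block_s: float = DT_S,
                    sampling_rate_hz: float | None = None) -> np.ndarray:
    """Median-filter a trace to one datapoint per ``block_s``.

    The trace is partitioned into consecutive non-overlapping blocks of
    ``round(block_s * sampling_rate_hz)`` raw samples (299 at 100 kHz); each
    complete block is reduced to its median and a trailing partial block is
    dropped, so the output length is ``floor(N / block)``.
    """
    if isinstance(trace, RawTrace):
        x = trace.samples
        fs = trace.sampling_rate_hz
    else:
        x = np.asarray(trace, dtype=float)
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for a bare array")
        fs = sampling_rate_hz
    if x.size == 0:
        raise ValueError("cannot decimate an empty trace")
    block = int(round(block_s * fs))
    if block < 1:
        raise ValueError("block must contain at least one raw sample")
    n = (x.size // block) * block
    if n == 0:
        return np.empty(0)
    return np.median(x[:n].reshape(-1, block), axis=1)


def detect_events(
    decimated: np.ndarray,
    baseline_pA: float,
    *,
    enter_frac: float = 0.8,
    exit_frac: float = 0.9,
    voltage_mV: float = float("nan"),
    dt_s: float = DT_S,
    min_baseline_points: int = 10,
) -> list[Event]:
    """Threshold-with-hysteresis event detection on a decimated series (pA).

    An event starts at the first point below ``enter_frac * I0`` and ends
    before the first subsequent point at or above ``exit_frac * I0``; the two
    thresholds differ (hysteresis) to prevent chattering at event edges.
    Each event is normalized by the local open-pore current, the mean of the
    immediately preceding open-pore run (of at least ``min_baseline_points``
    points, else the global ``baseline_pA``).  Events touching either trace
    edge, with no flanking baseline on both sides, are discarded.
    """
    if baseline_pA <= 0:
        raise ValueError("baseline must be positive")
    if not (enter_frac < exit_frac <= 1.0):
        raise ValueError("require enter_frac < exit_frac <= 1")
    x = np.asarray(decimated, dtype=float)

    events: list[Event] = []
    n = x.size
    i = 0
    run_start = 0            # start of the current open-pore run
    event_id = 0
    while i < n:
        if x[i] < enter_frac * baseline_pA:
            run = x[run_start:i]
            if run.size >= min_baseline_points:
                local_i0 = float(run.mean())
            else:
                local_i0 = baseline_pA
            # walk to the end of the blockade
            j = i + 1
            while j < n and x[j] < exit_frac * local_i0:
                j += 1
            if i > 0 and j < n:   # flanking baseline on both sides
                events.append(Event(
                    values=x[i:j] / local_i0,
                    voltage_mV=voltage_mV,
                    baseline_pA=local_i0,
                    dt_s=dt_s,
                    event_id=event_id,
                    start_time_s=i * dt_s,
                ))
                event_id += 1
            run_start = j
            i = j
        else:
            i += 1
    return events


def capture_rate(
    events: Sequence,
    open_pore_time_s: float,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, bool]:
    """Capture rate (events per second of open-pore time) with bootstrap SE.

    The rate is ``count / open_pore_time_s``.  Its standard error is the SD
    of the rate across ``n_boot`` bootstrap resamples of the inter-capture
    waiting-time sequence.  Returns ``(rate, se, warning_flag)``; with zero
    events the rate and SE are 0 and the flag is set.
    """
    if open_pore_time_s <= 0:
        raise ValueError("open_pore_time_s must be positive")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(events)
    if n == 0:
        return 0.0, 0.0, True
    rate = n / open_pore_time_s

    starts = np.sort(np.asarray([e.start_time_s for e in events], dtype=float))
    if np.any(~np.isfinite(starts)):
        # events without capture times (e.g. directly simulated pools):
        # model waiting times as exponential at the point-estimate rate
        waits = np.full(n, open_pore_time_s / n)
    else:
        waits = np.diff(np.concatenate([[0.0], starts]))
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_rates = n / np.maximum(waits[idx].sum(axis=1), 1e-300)
    return rate, float(boot_rates.std()), False


def fit_exponential_voltage(x, y) -> ExpFit:
    """Fit ``y = R0 * exp(V / V_scale)`` by least squares on ``ln y`` vs V.

    Returns the prefactor ``exp(intercept)`` and voltage scale ``1/slope``
    with standard errors propagated from the linear fit.  Requires at least
    two distinct voltages and strictly positive ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("all y must be positive for a log-linear fit")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct voltages")
    res = _stats.linregress(x, np.log(y))
    slope = float(res.slope)
    intercept = float(res.intercept)
    slope_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    intercept_se = float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0
    prefactor = float(np.exp(intercept))
    scale = float(np.inf) if slope == 0 else 1.0 / slope
    scale_se = float(np.inf) if slope == 0 else abs(slope_se / slope**2)
    return ExpFit(
        prefactor=prefactor,
        voltage_scale_mV=scale,
        prefactor_se=prefactor * intercept_se,
        scale_se=scale_se,
        slope=slope,
        slope_se=slope_se,
        r_squared=float(res.rvalue**2),
    )


def event_lifetime_stats(events: Sequence) -> tuple[float, float, float]:
    """Mean, sample SD and SE of event lifetimes in seconds."""
    if len(events) == 0:
        raise ValueError("need at least one event")
    t = np.asarray([e.lifetime_s for e in events], dtype=float)
    mean = float(t.mean())
    sd = float(t.std(ddof=1)) if t.size > 1 else 0.0
    return mean, sd, sd / np.sqrt(t.size)


def event_histogram(events: Sequence, n_bins: int = 100,
                    value_range: tuple[float, float] | None = None):
    """All-point histogram of I/I0 over every decimated point of every event.

    Events are pooled across voltages, as in the all-point current histogram
    normalized by the open-pore current.  Returns ``(bin_edges, density)``
    with the density normalized to unit area.
    """
    if len(events) == 0:
        raise ValueError("need at least one event")
    pooled = np.concatenate([np.asarray(e.values, dtype=float) for e in events])
    density, edges = np.histogram(pooled, bins=n_bins, range=value_range, density=True)
    return edges, density
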