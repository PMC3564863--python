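"""Synthetic nanopore traces and labeled capture-event sets.

Emulates the statistical structure of a single-pore recording: an
open-pore baseline with Gaussian noise, exponentially distributed waiting
times to capture whose rate grows exponentially with voltage,
``R(V) = R0 * exp(V / V_R)``, and blockade events generated by a K-state
Markov chain with per-state Gaussian current levels expressed as fractions
of the open-pore current (I/I0).  Event termination ("escape" of the
molecule from the pore) is modeled as a per-step absorbing exit mass per
state, which makes event lifetimes geometric in datapoints — hence
exponential in time — and lets the mean lifetime scale exponentially with
voltage as observed.

Two default protein classes are provided: a wild-type-like model with a
narrow, well-defined deep-blockade (low) state near I/I0 ~ 0 that carries
appreciable occupancy, and a mutant-like model whose deep-blockade state is
nearly absent.  The numeric parameter values are fixtures chosen by this
package (the source histograms are only available graphically) and are
documented as such in the methods note.

The hidden state is held constant within each decimation block of raw
samples so that median decimation is information-preserving: the decimated
series reproduces the hidden chain one datapoint per step, which lets EM
recover the generating parameters exactly in expectation.  A
``per_sample_states`` flag switches the chain to per-raw-sample stepping
for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import HmmModel
from .signals import DT_S, Event, RawTrace

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_models",
    "default_escape_probs",
    "simulate_event",
    "simulate_trace",
    "simulate_event_pool",
]

#: reference voltage (mV) at which the per-step escape probabilities are defined
V_REF_MV = 200.0


def default_models() -> tuple[HmmModel, HmmModel]:
    """Three-state wild-type-like and mutant-like model fixtures.

    Wild-type: narrow low state near I/I0 ~ 0 with appreciable stationary
    occupancy; broader mid and high states.  Mutant: the deep-blockade
    regime is essentially unvisited (near absence of the I/I0 ~ 0 peak), and
    all states are shifted up and broadened.  States are ordered low < mid
    < high by emission mean ``q``.
    """
    wt = HmmModel(
        pi=np.array([0.05, 0.25, 0.70]),
        A=np.array([
            [0.996, 0.003, 0.001],
            [0.006, 0.934, 0.060],
            [0.002, 0.078, 0.920],
        ]),
        q=np.array([0.05, 0.35, 0.62]),
        b=np.array([0.012, 0.055, 0.065]),
        label="wild-type",
    ).validate()
    mut = HmmModel(
        pi=np.array([0.15, 0.45, 0.40]),
        A=np.array([
            [0.992, 0.006, 0.002],
            [0.020, 0.910, 0.070],
            [0.008, 0.082, 0.910],
        ]),
        q=np.array([0.20, 0.45, 0.70]),
        b=np.array([0.040, 0.080, 0.060]),
        label="mutant",
    ).validate()
    return wt, mut


def default_escape_probs() -> dict[str, np.ndarray]:
    """Per-step escape probability per state at the reference voltage.

    The low state is sticky (small escape mass) so that trajectories which
    reach the deep blockade produce the long-lifetime tail (events > 1 s)
    riding on a majority of short events.
    """
    return {
        "wt": np.array([0.0005, 0.065, 0.110]),
        "mut": np.array([0.0006, 0.040, 0.060]),
    }


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a single alpha-HL pore recording.

    The open-pore current is linear in voltage (~28 pA at +100 mV).  Capture
    waiting times are exponential with rate ``R(V) = capture_rate_prefactor
    * exp(V / capture_rate_voltage_scale)``; mean event lifetimes scale as
    ``exp(V / lifetime_voltage_scale)`` via voltage scaling of the per-step
    escape probabilities defined at the 200 mV reference.
    """

    open_pore_current_pA_per_mV: float = 0.28
    open_pore_noise_pA: float = 1.0
    within_block_noise_pA: float = 0.5
    sampling_rate_hz: float = 100_000.0
    dt_s: float = DT_S
    capture_rate_prefactor: float = 0.0135   # s^-1; R(200 mV) ~ 2 s^-1
    capture_rate_voltage_scale: float = 40.0  # mV
    lifetime_prefactor: float = 0.0040        # s; mean lifetime ~ exp(V/V_L)
    lifetime_voltage_scale: float = 80.0      # mV
    models: dict = field(default_factory=lambda: dict(zip(("wt", "mut"), default_models())))
    escape_probs: dict = field(default_factory=default_escape_probs)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("open_pore_current_pA_per_mV", "open_pore_noise_pA",
                     "within_block_noise_pA", "sampling_rate_hz", "dt_s",
                     "capture_rate_prefactor", "capture_rate_voltage_scale",
                     "lifetime_prefactor", "lifetime_voltage_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for cls, p in self.escape_probs.items():
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or np.any(p >= 1):
                raise ValueError(f"escape probabilities for {cls!r} must lie in [0, 1)")
            self.escape_probs[cls] = p
        for cls, m in self.models.items():
            m.validate()
            if self.escape_probs[cls].shape != (m.K,):
                raise ValueError(f"escape_probs for {cls!r} must have length K={m.K}")

    def open_pore_current_pA(self, voltage_mV: float) -> float:
        return self.open_pore_current_pA_per_mV * voltage_mV

    def capture_rate_hz(self, voltage_mV: float) -> float:
        return self.capture_rate_prefactor * np.exp(voltage_mV / self.capture_rate_voltage_scale)

    def escape_probs_at(self, class_label: str, voltage_mV: float) -> np.ndarray:
        """Escape probabilities at ``voltage_mV``: lifetimes grow ~ exp(V/V_L)."""
        scale = np.exp(-(voltage_mV - V_REF_MV) / self.lifetime_voltage_scale)
        return np.clip(self.escape_probs[class_label] * scale, 0.0, 0.999999)

    @property
    def block(self) -> int:
        return int(round(self.dt_s * self.sampling_rate_hz))


@dataclass
class GroundTruth:
    """Everything the generator knows about a simulated trace.

    Boundaries are raw-sample indices, 0-based and half-open, sorted and
    non-overlapping; state sequences are stored at raw-sample resolution.
    """

    class_labels: list = field(default_factory=list)
    state_seqs: list = field(default_factory=list)       # raw resolution
    boundaries: list = field(default_factory=list)       # (start, end) raw indices
    capture_times_s: list = field(default_factory=list)

    def validate(self) -> "GroundTruth":
        prev_end = -1
        for (s, e) in self.boundaries:
            if not (0 <= s < e):
                raise ValueError("boundaries must be 0-based half-open with start < end")
            if s <= prev_end:
                raise ValueError("boundaries must be sorted and non-overlapping")
            prev_end = e
        return self


def simulate_event(
    model: HmmModel,
    escape_probs,
    rng: np.random.Generator,
    max_len: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one capture event at decimated resolution.

    The first state is drawn from ``pi``; after each emitted datapoint the
    molecule escapes with the state's per-step escape probability, otherwise
    the next state is drawn from the corresponding row of ``A`` (i.e. the
    rows of ``A`` are renormalized after allotting the escape mass).  Each
    datapoint is Gaussian with mean ``q_s`` and SD ``b_s``.  Returns the
    hidden state sequence and the I/I0 values; both end on escape (or at
    ``max_len``, for fixed-length stress tests).
    """
    model.validate()
    e = np.asarray(escape_probs, dtype=float)
    if e.shape != (model.K,):
        raise ValueError(f"escape_probs must have length K={model.K}")
    if np.any(e < 0) or np.any(e > 1):
        raise ValueError("escape probabilities must lie in [0, 1]")

    states: list[int] = []
    values: list[float] = []
    s = int(rng.choice(model.K, p=model.pi))
    while True:
        states.append(s)
        values.append(rng.normal(model.q[s], model.b[s]))
        if max_len is not None and len(states) >= max_len:
            break
        if rng.random() < e[s]:
            break
        s = int(rng.choice(model.K, p=model.A[s]))
    return np.asarray(states, dtype=np.intp), np.asarray(values)


def simulate_trace(
    config: SyntheticConfig,
    duration_s: float,
    voltage_mV: float,
    class_label: str = "wt",
    rng: np.random.Generator | None = None,
    per_sample_states: bool = False,
) -> tuple[RawTrace, GroundTruth]:
    """Simulate a raw current recording with embedded capture events.

    Open-pore segments sit at the voltage's open-pore current with Gaussian
    noise; capture waiting times are exponential with rate ``R(V)``.  During
    an event the hidden state is held for one full decimation block of raw
    samples: the block's target level is drawn as ``N(q_s, b_s)`` (in I/I0)
    and raw samples scatter tightly around it, so the block median
    reproduces the hidden emission and decimation is information-preserving.
    With ``per_sample_states=True`` the chain instead steps every raw
    sample (stress testing the decimation assumption).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    fs = config.sampling_rate_hz
    block = config.block
    n_total = int(round(duration_s * fs))
    if n_total < block:
        raise ValueError("duration shorter than one decimation block")

    i0 = config.open_pore_current_pA(voltage_mV)
    rate = config.capture_rate_hz(voltage_mV)
    escape = config.escape_probs_at(class_label, voltage_mV)
    model = config.models[class_label]

    samples = np.empty(n_total)
    truth = GroundTruth()
    cursor = 0
    while cursor < n_total:
        wait_s = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        n_wait = int(round(wait_s * fs)) if np.isfinite(wait_s) else n_total - cursor
        n_wait = min(max(n_wait, 1), n_total - cursor)
        samples[cursor:cursor + n_wait] = rng.normal(i0, config.open_pore_noise_pA, n_wait)
        cursor += n_wait
        if cursor >= n_total:
            break

        start = cursor
        if per_sample_states:
            dec_states, dec_values = simulate_event(
                model, 1.0 - (1.0 - escape) ** (1.0 / block), rng)
            raw_states = dec_states
            raw = dec_values * i0 + rng.normal(0.0, config.within_block_noise_pA,
                                               dec_values.size)
        else:
            dec_states, dec_values = simulate_event(model, escape, rng)
            raw_states = np.repeat(dec_states, block)
            raw = (np.repeat(dec_values, block) * i0
                   + rng.normal(0.0, config.within_block_noise_pA, dec_states.size * block))
        n_ev = min(raw.size, n_total - start)
        samples[start:start + n_ev] = raw[:n_ev]
        truth.class_labels.append(class_label)
        truth.state_seqs.append(raw_states[:n_ev])
        truth.boundaries.append((start, start + n_ev))
        truth.capture_times_s.append(start / fs)
        cursor = start + n_ev

    trace = RawTrace(
        samples=samples,
        sampling_rate_hz=fs,
        voltage_mV=voltage_mV,
        metadata={
            "class_label": class_label,
            "open_pore_current_pA": i0,
            "temperature_C": 20.0,
        },
    )
    return trace, truth.validate()


def simulate_event_pool(
    config: SyntheticConfig,
    class_label: str,
    n_events: int,
    voltage_mV: float,
    rng: np.random.Generator,
    max_len: int = 100_000,
) -> list[Event]:
    """Generate ``n_events`` labeled events directly at decimated resolution.

    Bypasses raw-trace synthesis and detection — the scale path for the
    classification and kinetics protocols, where only the decimated I/I0
    sequences matter.
    """
    model = config.models[class_label]
    escape = config.escape_probs_at(class_label, voltage_mV)
    i0 = config.open_pore_current_pA(voltage_mV)
    pool = []
    for i in range(n_events):
        _, values = simulate_event(model, escape, rng, max_len=max_len)
        pool.append(Event(
            values=values,
            voltage_mV=voltage_mV,
            baseline_pA=i0,
            dt_s=config.dt_s,
            class_label=class_label,
            event_id=i,
        ))
    return pool
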