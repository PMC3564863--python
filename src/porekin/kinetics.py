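"""Viterbi-path kinetics: dwell segments, transition rates, and the
entry-conditioned mid-state analysis.

Each event is idealized to its Viterbi path under a (voltage-specific)
model; the path is run-length encoded into dwell segments annotated with
the state occupied immediately before entry and the state occupied after
exit.  State-to-state transition rates are estimated as ``k_{i->j} =
N_{i->j} / T_i`` — exit counts over occupancy time — the maximum-likelihood
rate estimator for a Markov jump process observed at discrete steps.
Event termination (escape of the molecule from the pore) is treated as
right-censoring: the final dwell's duration counts toward ``T_i`` but
contributes no transition count.

The entry-conditioned analysis partitions mid-state dwells by whether the
mid state was entered from the high or the low state.  If the two
partitions exit at clearly different rates, a single (memoryless) mid state
cannot describe the data and it is split into mid-high and mid-low states,
yielding a four-state aggregated-Markov model with shared mid emissions.

Bootstrap errors resample whole events (segments within an event are
dependent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm import HmmModel, ViterbiPath, baum_welch, viterbi
from .signals import ExpFit, fit_exponential_voltage

__all__ = [
    "ESCAPE",
    "DwellSegment",
    "RateTable",
    "ConditionedRates",
    "FourStateModel",
    "voltage_specific_refit",
    "dwell_segments",
    "segments_for_events",
    "transition_rates",
    "entry_conditioned_mid_stats",
    "build_four_state_model",
    "rate_voltage_dependence",
]

#: sentinel exit annotation for the last dwell of an event (right-censored)
ESCAPE = -1


@dataclass
class DwellSegment:
    """Maximal run of one hidden state within one event's Viterbi path."""

    event_id: int
    state: int
    entry_state: int | None      # None for the first segment of an event
    exit_state: int              # ESCAPE for the last segment of an event
    duration_points: int
    dt_s: float

    @property
    def duration_s(self) -> float:
        return self.duration_points * self.dt_s


@dataclass
class RateTable:
    """Per-voltage state-to-state transition rates with bootstrap errors.

    ``rate[i, j] = N[i, j] / T[i]`` for i != j; rows with zero occupancy
    time are flagged undefined rather than reported as 0.
    """

    K: int
    N: np.ndarray                # (K, K) exit counts
    T_s: np.ndarray              # (K,) occupancy time per state
    rate_hz: np.ndarray          # (K, K)
    se_hz: np.ndarray            # (K, K)
    undefined: np.ndarray        # (K,) rows with T_i == 0
    voltage_mV: float = float("nan")
    n_events: int = 0


@dataclass
class ConditionedRates:
    """Rates out of the mid state for one entry condition."""

    entry_state: int
    n_segments: int
    N_out: dict                  # to_state -> count
    T_s: float
    rate_hz: dict                # to_state -> rate (None if T == 0)
    se_hz: dict                  # to_state -> bootstrap SE
    defined: bool = True


@dataclass
class FourStateModel:
    """Aggregated-Markov four-state model: {H, M_H, M_L, L}.

    The mid state is split by entry: M_H receives all high->mid
    transitions, M_L all low->mid transitions; the two share the mid
    state's emission parameters ``(q, b)``.  ``A`` rows are ordered
    ``state_names``.
    """

    state_names: tuple
    A: np.ndarray
    q: np.ndarray
    b: np.ndarray
    provenance: dict = field(default_factory=dict)

    def validate(self) -> "FourStateModel":
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-9) or np.any(self.A < 0):
            raise ValueError("each row of A must be a probability vector")
        i_mh = self.state_names.index("M_H")
        i_ml = self.state_names.index("M_L")
        if self.q[i_mh] != self.q[i_ml] or self.b[i_mh] != self.b[i_ml]:
            raise ValueError("M_H and M_L must share emission parameters")
        return self


def voltage_specific_refit(events: Sequence, pooled_model: HmmModel,
                           max_iter: int = 100, tol: float = 1e-6):
    """Refit ``pi`` and ``A`` on the events of one voltage.

    Baum-Welch from the pooled (all-voltage) optimal model with the state
    levels ``q`` and noise widths ``b`` held fixed — only the initial
    condition and the transition probabilities are voltage dependent.
    Returns the :class:`~porekin.hmm.FitResult`.
    """
    return baum_welch(events, pooled_model, update_q=False, update_b=False,
                      max_iter=max_iter, tol=tol)


def dwell_segments(path: ViterbiPath | np.ndarray, event_id: int = 0,
                   dt_s: float = 0.00299) -> list[DwellSegment]:
    """Run-length encode a Viterbi path into entry/exit-annotated dwells."""
    states = path.states if isinstance(path, ViterbiPath) else np.asarray(path)
    if states.size == 0:
        raise ValueError("path must be non-empty")
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    segs = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        segs.append(DwellSegment(
            event_id=event_id,
            state=int(states[s]),
            entry_state=None if k == 0 else int(states[starts[k - 1]]),
            exit_state=ESCAPE if k == len(starts) - 1 else int(states[ends[k]]),
            duration_points=int(e - s),
            dt_s=dt_s,
        ))
    return segs


def segments_for_events(events: Sequence, model: HmmModel) -> list[DwellSegment]:
    """Viterbi-decode every event and pool the dwell segments."""
    segs: list[DwellSegment] = []
    for i, ev in enumerate(events):
        eid = ev.event_id if getattr(ev, "event_id", None) is not None else i
        segs.extend(dwell_segments(viterbi(ev, model), event_id=eid, dt_s=ev.dt_s))
    return segs


def _count_nt(segments: Sequence[DwellSegment], K: int):
    """Exit counts N (K x K) and occupancy times T (K,) from segments."""
    N = np.zeros((K, K))
    T = np.zeros(K)
    for s in segments:
        T[s.state] += s.duration_points * s.dt_s
        if s.exit_state != ESCAPE:
            N[s.state, s.exit_state] += 1
    return N, T


def _bootstrap_events(segments, stat, n_boot, rng):
    """Bootstrap SD of ``stat(list_of_segments)`` resampling whole events."""
    by_event: dict[int, list] = {}
    for s in segments:
        by_event.setdefault(s.event_id, []).append(s)
    groups = list(by_event.values())
    E = len(groups)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, E, size=E)
        draws.append(stat([s for i in idx for s in groups[i]]))
    return np.nanstd(np.asarray(draws, dtype=float), axis=0)


def transition_rates(segments: Sequence[DwellSegment], dt_s: float | None = None,
                     K: int | None = None, n_boot: int = 1000,
                     rng: np.random.Generator | None = None,
                     voltage_mV: float = float("nan")) -> RateTable:
    """Estimate ``k_{i->j} = N_{i->j} / T_i`` with event-level bootstrap SEs.

    ``N`` counts dwells in state i whose annotated exit is j; escape
    (event-end) exits are excluded from ``N`` but their durations still
    count toward ``T_i``.  ``dt_s`` is taken from the segments when not
    given.
    """
    if len(segments) == 0:
        raise ValueError("need at least one segment")
    if K is None:
        K = max(max(s.state for s in segments),
                max((s.exit_state for s in segments), default=0)) + 1
    N, T = _count_nt(segments, K)
    undefined = T == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(T[:, None] > 0, N / np.where(T[:, None] > 0, T[:, None], 1.0), np.nan)
    np.fill_diagonal(rate, 0.0)
    rate[undefined] = np.nan

    rng = np.random.default_rng() if rng is None else rng

    def stat(segs):
        n, t = _count_nt(segs, K)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(t[:, None] > 0, n / np.where(t[:, None] > 0, t[:, None], 1.0), np.nan)
        return r

    se = _bootstrap_events(segments, stat, n_boot, rng)
    n_events = len({s.event_id for s in segments})
    return RateTable(K=K, N=N, T_s=T, rate_hz=rate, se_hz=se,
                     undefined=undefined, voltage_mV=voltage_mV,
                     n_events=n_events)


def entry_conditioned_mid_stats(
    segments: Sequence[DwellSegment],
    mid_state: int,
    high_state: int,
    low_state: int,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, ConditionedRates]:
    """Rates out of the mid state, conditioned on how it was entered.

    Mid-state dwells are partitioned by ``entry_state`` (high vs low); an
    event's first dwell (entry None) contributes to neither partition.
    Within each partition the exit rates ``k_{M->H}`` and ``k_{M->L}`` are
    computed as exit counts over partition occupancy time, with event-level
    bootstrap SEs.  An empty partition is returned with ``defined=False``.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = {}
    for name, entry in (("from_high", high_state), ("from_low", low_state)):
        part = [s for s in segments if s.state == mid_state and s.entry_state == entry]
        if not part:
            out[name] = ConditionedRates(
                entry_state=entry, n_segments=0, N_out={}, T_s=0.0,
                rate_hz={high_state: None, low_state: None},
                se_hz={high_state: float("nan"), low_state: float("nan")},
                defined=False,
            )
            continue
        T = sum(s.duration_s for s in part)
        N = {high_state: sum(1 for s in part if s.exit_state == high_state),
             low_state: sum(1 for s in part if s.exit_state == low_state)}
        rate = {k: (n / T if T > 0 else None) for k, n in N.items()}

        def stat(segs, _part_entry=entry):
            p = [s for s in segs if s.state == mid_state and s.entry_state == _part_entry]
            t = sum(s.duration_s for s in p)
            if t == 0:
                return [np.nan, np.nan]
            return [sum(1 for s in p if s.exit_state == high_state) / t,
                    sum(1 for s in p if s.exit_state == low_state) / t]

        se = _bootstrap_events(segments, stat, n_boot, rng)
        out[name] = ConditionedRates(
            entry_state=entry, n_segments=len(part), N_out=N, T_s=T,
            rate_hz=rate,
            se_hz={high_state: float(se[0]), low_state: float(se[1])},
        )
    return out


def build_four_state_model(
    segments: Sequence[DwellSegment],
    three_state_model: HmmModel,
    mid_state: int = 1,
    high_state: int | None = None,
    low_state: int | None = None,
) -> FourStateModel:
    """Split the mid state by entry into M_H and M_L.

    M_H receives all high->mid transition mass from the three-state ``A``,
    M_L all low->mid mass.  The per-step exit probabilities of M_H (M_L)
    are estimated from the entry-conditioned dwell partitions: exits to H
    or L over total mid datapoints in the partition, remainder self-loop.
    Both inherit the mid state's emission parameters.  States are ordered
    (H, M_H, M_L, L).
    """
    K = three_state_model.K
    if high_state is None:
        high_state = K - 1
    if low_state is None:
        low_state = 0
    cond = entry_conditioned_mid_stats(segments, mid_state, high_state,
                                       low_state, n_boot=1,
                                       rng=np.random.default_rng(0))
    for name in ("from_high", "from_low"):
        if not cond[name].defined:
            raise ValueError(
                f"cannot split the mid state: the {name} partition is empty; "
                "more data (or longer events) is required"
            )

    A3 = three_state_model.A
    names = ("H", "M_H", "M_L", "L")
    idx = {n: i for i, n in enumerate(names)}
    A4 = np.zeros((4, 4))

    # H and L rows: mid-bound mass routed to the entry-specific mid state
    A4[idx["H"], idx["H"]] = A3[high_state, high_state]
    A4[idx["H"], idx["L"]] = A3[high_state, low_state]
    A4[idx["H"], idx["M_H"]] = A3[high_state, mid_state]
    A4[idx["L"], idx["L"]] = A3[low_state, low_state]
    A4[idx["L"], idx["H"]] = A3[low_state, high_state]
    A4[idx["L"], idx["M_L"]] = A3[low_state, mid_state]

    dt = segments[0].dt_s
    for name, row in (("from_high", "M_H"), ("from_low", "M_L")):
        c = cond[name]
        n_points = c.T_s / dt
        p_h = c.N_out[high_state] / n_points
        p_l = c.N_out[low_state] / n_points
        A4[idx[row], idx["H"]] = p_h
        A4[idx[row], idx["L"]] = p_l
        A4[idx[row], idx[row]] = 1.0 - p_h - p_l

    A4 /= A4.sum(axis=1, keepdims=True)
    q3, b3 = three_state_model.q, three_state_model.b
    q4 = np.array([q3[high_state], q3[mid_state], q3[mid_state], q3[low_state]])
    b4 = np.array([b3[high_state], b3[mid_state], b3[mid_state], b3[low_state]])
    prov = {
        "from_high": {"n_segments": cond["from_high"].n_segments,
                      "N_out": {str(k): v for k, v in cond["from_high"].N_out.items()},
                      "T_s": cond["from_high"].T_s},
        "from_low": {"n_segments": cond["from_low"].n_segments,
                     "N_out": {str(k): v for k, v in cond["from_low"].N_out.items()},
                     "T_s": cond["from_low"].T_s},
    }
    return FourStateModel(state_names=names, A=A4, q=q4, b=b4,
                          provenance=prov).validate()


def rate_voltage_dependence(rate_tables: Sequence[RateTable],
                            pair: tuple[int, int]):
    """Exponential (Arrhenius-like) voltage fit of one transition rate.

    Fits ``k(V) = k0 * exp(V / V_scale)`` across the tables' voltages.
    Returns ``(ExpFit, flat_flag)``; the flag is set when the slope is
    indistinguishable from zero (|slope| < 2 SE), in which case the voltage
    scale is unbounded.
    """
    i, j = pair
    volts, rates = [], []
    for t in rate_tables:
        r = t.rate_hz[i, j]
        if np.isfinite(r) and r > 0:
            volts.append(t.voltage_mV)
            rates.append(r)
    if len(set(volts)) < 2:
        raise ValueError("need defined positive rates at >= 2 voltages")
    fit = fit_exponential_voltage(volts, rates)
    flat = abs(fit.slope) < 2.0 * fit.slope_se
    if flat:
        fit = ExpFit(prefactor=fit.prefactor, voltage_scale_mV=float("inf"),
                     prefactor_se=fit.prefactor_se, scale_se=float("inf"),
                     slope=fit.slope, slope_se=fit.slope_se,
                     r_squared=fit.r_squared)
    return fit, flat
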